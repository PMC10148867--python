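"""Physical constants and monoisotopic masses.

Element masses come from the NIST table bundled with :mod:`pyteomics`;
isotope-labelled symbols (``13C``, ``15N``, ``2H``, ``18O``) resolve to the
corresponding isotope mass rather than the most abundant one.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

_NIST = _pmass.nist_mass

PROTON: float = 1.00727646677
WATER: float = 2 * _NIST["H"][0][0] + _NIST["O"][0][0]  # 18.010565
AMMONIA: float = 3 * _NIST["H"][0][0] + _NIST["N"][0][0]  # 17.026549
PHOSPHO_LOSS: float = (
    3 * _NIST["H"][0][0] + 4 * _NIST["O"][0][0] + _NIST["P"][0][0]
)  # H3PO4, 97.976895

#: symbol -> monoisotopic mass (Da); isotope labels are explicit entries
ELEMENT_MASSES: dict[str, float] = {
    sym: data[0][0] for sym, data in _NIST.items() if data[0][0] > 0
}
ELEMENT_MASSES.update(
    {
        "2H": _NIST["H"][2][0],
        "13C": _NIST["C"][13][0],
        "15N": _NIST["N"][15][0],
        "18O": _NIST["O"][18][0],
    }
)

#: the 20 canonical amino-acid residue monoisotopic masses (Da)
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: residues whose sequences we refuse to assign a mass to
AMBIGUOUS_RESIDUES = frozenset("BJXUZO")
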