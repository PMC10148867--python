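"""Synthetic DDA MS2 spectra with ground truth, for offline validation.

The generator digests a protein database, samples (modified) peptides,
and emits spectra containing the peptides' primary b/y ions with
log-normal intensities (y-ions brighter than b-ions, as typical of
HCD/CID), satellite ions at a configurable relative intensity for a
random fraction of primaries, uniformly placed noise peaks, and Gaussian
ppm jitter on every m/z.  Everything is reproducible from the seed.

The generator emulates the rank structure of real DDA spectra — which
is all the enrichment scorer consumes — but not isotope envelopes,
co-isolated precursors, or correlated (chemical) noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import PROTON
from .ions import SiteAssignment, enumerate_assignments, dispatchable, full_series
from .modifications import AminoAcidLookup, ModSet
from .proteolysis import ProteinRecord, digest_database
from .spectra import Spectrum

PRIMARY_FOR_SAT = {"b": ("b*", "b0", "b2"), "y": ("y*", "y0", "y2")}


@dataclass
class GroundTruth:
    """Planted content of one synthetic spectrum."""

    title: str
    peptide: str
    annotated: str
    set_index: int
    charge: int
    neutral_mass: float
    planted_mz: dict[str, list[float]]  # channel -> m/z values
    n_noise: int
    seed: int

    def to_row(self) -> dict:
        planted = ";".join(
            f"{ch}:" + ",".join(f"{v:.5f}" for v in vs)
            for ch, vs in sorted(self.planted_mz.items())
        )
        return {
            "title": self.title,
            "peptide": self.peptide,
            "sequence": self.annotated,
            "set_index": self.set_index,
            "charge": self.charge,
            "neutral_mass": round(self.neutral_mass, 6),
            "planted": planted,
            "n_noise": self.n_noise,
            "seed": self.seed,
        }

    @staticmethod
    def frame(truths: list["GroundTruth"]) -> pd.DataFrame:
        return pd.DataFrame([t.to_row() for t in truths])


def synth_spectra(
    records: list[ProteinRecord],
    modsets: list[ModSet],
    lookups: dict[int, AminoAcidLookup],
    n_peptides: int = 50,
    charges: tuple[int, ...] = (2, 3),
    satellite_fraction: float = 0.5,
    satellite_rel_intensity: float = 0.3,
    n_noise: int = 30,
    ppm_jitter: float = 2.0,
    intensity_mu: float = 10.0,
    intensity_sigma: float = 1.0,
    y_over_b: float = 1.5,
    enzyme: str = "trypsin/p",
    max_missed: int = 2,
    len_range: tuple[int, int] = (7, 40),
    mass_range: tuple[float, float] = (700.0, 4500.0),
    source_name: str = "synthetic",
    seed: int = 0,
) -> tuple[list[Spectrum], list[GroundTruth]]:
    """Generate ``n_peptides`` MS2 spectra of planted peptides.

    Each sampled candidate gets one site assignment drawn uniformly from
    its enumerated assignments under a randomly chosen compatible
    modification set.  Raises if the database does not yield
    ``n_peptides`` in-range candidates.
    """
    rng = np.random.default_rng(seed)
    candidates = digest_database(
        records, enzyme=enzyme, specificity="full",
        max_missed=max_missed, len_range=len_range,
    )
    pool: list[SiteAssignment] = []
    by_sequence: dict[str, list[SiteAssignment]] = {}
    for cand in candidates:
        for ms in modsets:
            if not dispatchable(cand, ms):
                continue
            for a in enumerate_assignments(cand, ms, lookups[ms.set_index]):
                if mass_range[0] <= a.neutral_mass <= mass_range[1]:
                    by_sequence.setdefault(cand.sequence, []).append(a)
    sequences = sorted(by_sequence)
    if n_peptides > len(sequences):
        raise ValueError(
            f"requested {n_peptides} peptides but only {len(sequences)} "
            f"in-range candidate sequences are available"
        )
    chosen_seqs = rng.choice(len(sequences), size=n_peptides, replace=False)

    spectra: list[Spectrum] = []
    truths: list[GroundTruth] = []
    for i, si in enumerate(sorted(chosen_seqs)):
        options = by_sequence[sequences[si]]
        a = options[rng.integers(len(options))]
        z = int(charges[rng.integers(len(charges))])
        series = full_series(a, lookups[a.set_index], precursor_charge=z)

        mz_list: list[float] = []
        int_list: list[float] = []
        planted: dict[str, list[float]] = {}
        n_frag = len(series["b"])
        b_int = rng.lognormal(intensity_mu, intensity_sigma, n_frag)
        y_int = rng.lognormal(intensity_mu, intensity_sigma, n_frag) * y_over_b

        def plant(mz: float, inten: float, channel: str) -> None:
            obs = mz * (1 + rng.normal(0.0, ppm_jitter) * 1e-6)
            mz_list.append(obs)
            int_list.append(inten)
            planted.setdefault(channel, []).append(mz)

        for idx in range(n_frag):
            plant(float(series["b"][idx]), float(b_int[idx]), "b")
            plant(float(series["y"][idx]), float(y_int[idx]), "y")
            for ch, base in (("b", b_int[idx]), ("y", y_int[idx])):
                if rng.random() < satellite_fraction:
                    sat_opts = [
                        s for s in PRIMARY_FOR_SAT[ch]
                        if s in series and np.isfinite(series[s][idx])
                    ]
                    if sat_opts:
                        s_ch = sat_opts[rng.integers(len(sat_opts))]
                        plant(
                            float(series[s_ch][idx]),
                            float(base) * satellite_rel_intensity
                            * float(rng.lognormal(0.0, 0.3)),
                            s_ch,
                        )

        if mz_list:
            lo_mz, hi_mz = 100.0, max(mz_list) * 1.05
        else:
            lo_mz, hi_mz = 100.0, 2000.0
        noise_mz = rng.uniform(lo_mz, hi_mz, n_noise)
        noise_int = rng.lognormal(intensity_mu - 2.0, intensity_sigma, n_noise)
        mz_list.extend(noise_mz.tolist())
        int_list.extend(noise_int.tolist())

        prec_mz = (a.neutral_mass + z * PROTON) / z
        prec_obs = prec_mz * (1 + rng.normal(0.0, ppm_jitter / 2.0) * 1e-6)
        scan = i + 1
        title = f"{source_name}.{scan}.{scan}.{z}"
        spectra.append(
            Spectrum(
                source=source_name,
                scan=str(scan),
                title=title,
                precursor_mz=prec_obs,
                precursor_charge=z,
                rt_seconds=60.0 * (i + 1),
                mz=np.array(mz_list),
                intensity=np.array(int_list),
            )
        )
        truths.append(
            GroundTruth(
                title=title,
                peptide=a.sequence,
                annotated=a.annotated(),
                set_index=a.set_index,
                charge=z,
                neutral_mass=a.neutral_mass,
                planted_mz=planted,
                n_noise=n_noise,
                seed=seed,
            )
        )
    return spectra, truths


def random_protein_fasta(
    path,
    n_proteins: int = 5,
    length: tuple[int, int] = (120, 240),
    seed: int = 0,
    prefix: str = "SYN",
    kr_every: int = 12,
) -> list[ProteinRecord]:
    """Write a random synthetic protein FASTA (labelled as such).

    Residue composition is uniform over the 20 canonical residues with
    K/R guaranteed at least every ``kr_every`` positions so that tryptic
    digestion yields in-range peptides.
    """
    from pathlib import Path

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = []
    for i in range(n_proteins):
        n = int(rng.integers(length[0], length[1] + 1))
        seq = list(alphabet[rng.integers(0, 20, n)])
        for j in range(kr_every - 1, n, kr_every):
            seq[j] = "K" if rng.random() < 0.5 else "R"
        records.append(
            ProteinRecord(
                f"{prefix}{i + 1:03d}",
                f"{prefix}{i + 1:03d} synthetic protein {i + 1}",
                "".join(seq),
            )
        )
    lines = []
    for r in records:
        lines.append(f">{r.description}")
        for k in range(0, len(r.sequence), 60):
            lines.append(r.sequence[k:k + 60])
    Path(path).write_text("\n".join(lines) + "\n")
    return records
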