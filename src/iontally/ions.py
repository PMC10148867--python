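"""Peptide masses, modification site assignments, and product-ion series.

A :class:`SiteAssignment` fixes which residue positions of a candidate
peptide carry which variable modifications.  Enumeration is capped (at
most five variably modified sites, at most three positions of the same
modification, at most 64 assignments per candidate and modification set)
and deterministic: assignments with fewer modified positions come first,
ties broken by leftmost positions.

Primary product ions are singly protonated b/y fragments; satellite
channels are ammonia loss (b*/y*), water loss (b0/y0), doubly charged
variants of all six, and modification-specific neutral losses (for
example the 97.9769 Da phosphate loss).  Loss channels are emitted only
when the contributing fragment contains a qualifying residue.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .constants import AMMONIA, PROTON, WATER
from .modifications import AminoAcidLookup, ModSet
from .proteolysis import PeptideCandidate

#: residues whose presence in a fragment licenses an ammonia-loss satellite
NH3_LOSS_RESIDUES = frozenset("RKNQ")
#: residues licensing a water-loss satellite
H2O_LOSS_RESIDUES = frozenset("STED")

PRIMARY_CHANNELS = ("b", "y")
SATELLITE_CHANNELS = (
    "b*", "y*", "b0", "y0", "b2", "y2", "b*2", "y*2", "b02", "y02",
)
NL_CHANNELS = ("b_nl", "y_nl")


@dataclass
class SiteAssignment:
    """One placement of variable modifications on a peptide candidate."""

    candidate: PeptideCandidate
    site_mods: tuple[str | None, ...]  # per-position modification title
    nterm_mod: str | None = None
    cterm_mod: str | None = None
    neutral_mass: float = 0.0
    set_index: int = 0

    @property
    def sequence(self) -> str:
        return self.candidate.sequence

    def annotated(self) -> str:
        """Human-readable modified-sequence literal, e.g. ``AM[Oxidation]K``."""
        parts = []
        if self.nterm_mod:
            parts.append(f"[{self.nterm_mod}]-")
        for aa, title in zip(self.sequence, self.site_mods):
            parts.append(aa if title is None else f"{aa}[{title}]")
        if self.cterm_mod:
            parts.append(f"-[{self.cterm_mod}]")
        return "".join(parts)

    def key(self) -> tuple:
        """Identity of the modified peptide form, independent of the set."""
        return (self.sequence, self.site_mods, self.nterm_mod,
                self.cterm_mod, self.candidate.is_decoy)


@dataclass
class IonSeries:
    """Theoretical m/z per channel, index i = 1..n-1; NaN where absent."""

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    charge: int = 1

    def __getitem__(self, key: str) -> np.ndarray:
        return self.channels[key]

    def __contains__(self, key: str) -> bool:
        return key in self.channels


def _position_mass(lookup: AminoAcidLookup, residue: str, title: str | None) -> float:
    try:
        return lookup.mass(residue, title)
    except KeyError:
        raise KeyError(
            f"no look-up entry for residue {residue!r} with modification "
            f"{title!r}"
        ) from None


def _terminal_mass(lookup: AminoAcidLookup, terminus: str, title: str | None) -> float:
    if (terminus, title) in lookup.entries:
        return lookup.mass(terminus, title)
    if title is None:
        # bare entry removed because a fixed terminal modification applies
        raise KeyError(f"{terminus} requires a modification in this set")
    raise KeyError(f"no look-up entry for {terminus} modification {title!r}")


def peptide_mass(assignment: SiteAssignment, lookup: AminoAcidLookup) -> float:
    """Neutral monoisotopic mass of a (modified) peptide."""
    total = WATER
    for pos, (aa, title) in enumerate(zip(assignment.sequence, assignment.site_mods)):
        try:
            total += _position_mass(lookup, aa, title)
        except KeyError as exc:
            raise KeyError(f"position {pos + 1}: {exc}") from None
    total += _terminal_mass(lookup, "N-term", assignment.nterm_mod)
    total += _terminal_mass(lookup, "C-term", assignment.cterm_mod)
    return total


def _terminal_options(
    candidate: PeptideCandidate,
    modset: ModSet,
    lookup: AminoAcidLookup,
    terminus: str,
) -> list[str | None] | None:
    """Applicable modification titles for one terminus (None = bare).

    Returns ``None`` when the candidate cannot satisfy a mandatory
    terminal modification (e.g. a required pyro-Glu on a peptide that
    does not start with Q), meaning no assignment exists in this set.
    """
    fixed_term = [m for m in modset.fixed if m.terminus == terminus]
    if fixed_term:
        m = fixed_term[0]
        if m.position.startswith("Protein") and not (
            candidate.is_protein_nterm if terminus == "N-term" else candidate.is_protein_cterm
        ):
            return None
        if m.site not in ("N-term", "C-term"):
            anchor = candidate.sequence[0] if terminus == "N-term" else candidate.sequence[-1]
            if anchor != m.site:
                return None
        return [m.title]

    var_term = [m for m in modset.variable if m.terminus == terminus]
    options: list[str | None] = [None]
    for m in var_term:
        applicable = True
        if m.position.startswith("Protein"):
            applicable = (
                candidate.is_protein_nterm if terminus == "N-term" else candidate.is_protein_cterm
            )
        if applicable and m.site not in ("N-term", "C-term"):
            anchor = candidate.sequence[0] if terminus == "N-term" else candidate.sequence[-1]
            applicable = anchor == m.site
        if m in modset.required:
            if not applicable:
                return None
            options = [m.title]
        elif applicable:
            options.append(m.title)
    return options


def dispatchable(candidate: PeptideCandidate, modset: ModSet) -> bool:
    """Fig-1-style dispatch: a candidate reaches a set only when it carries
    a site for every variable Anywhere modification of the set, and can
    satisfy the set's mandatory terminal modifications."""
    for m in modset.variable:
        if not m.is_terminal and m.site not in candidate.sequence:
            return False
    for m in modset.required:
        if m.is_terminal:
            if m.position.startswith("Protein"):
                ok = candidate.is_protein_nterm if m.terminus == "N-term" else candidate.is_protein_cterm
                if not ok:
                    return False
            if m.site not in ("N-term", "C-term"):
                anchor = candidate.sequence[0] if m.terminus == "N-term" else candidate.sequence[-1]
                if anchor != m.site:
                    return False
    return True


def enumerate_assignments(
    candidate: PeptideCandidate,
    modset: ModSet,
    lookup: AminoAcidLookup,
    max_sites: int = 5,
    max_per_mod: int = 3,
    max_perms: int = 64,
) -> list[SiteAssignment]:
    """All capped variable-modification placements for one candidate.

    Residue positions of a coerced site must carry one of the set's
    modifications for that site (the chemistry that motivated the
    coercion leaves no unmodified state); every other variable site is
    optionally modified.  Caps apply to the optional placements; the
    assignment list is truncated deterministically at ``max_perms``.
    """
    seq = candidate.sequence
    nt_options = _terminal_options(candidate, modset, lookup, "N-term")
    ct_options = _terminal_options(candidate, modset, lookup, "C-term")
    if nt_options is None or ct_options is None:
        return []

    var_anywhere = [m for m in modset.variable if not m.is_terminal]
    by_site: dict[str, list[str]] = {}
    for m in var_anywhere:
        by_site.setdefault(m.site, []).append(m.title)

    forced: list[tuple[int, list[str]]] = []  # coerced-site positions
    optional: list[tuple[int, list[str]]] = []
    for pos, aa in enumerate(seq):
        titles = by_site.get(aa)
        if not titles:
            continue
        if aa in modset.coverage_sites:
            forced.append((pos, titles))
        else:
            optional.append((pos, titles))

    def optional_placements():
        for j in range(0, min(max_sites, len(optional)) + 1):
            for subset in itertools.combinations(range(len(optional)), j):
                pools = [optional[i][1] for i in subset]
                for titles in itertools.product(*pools):
                    if any(c > max_per_mod for c in Counter(titles).values()):
                        continue
                    yield tuple(zip((optional[i][0] for i in subset), titles))

    def forced_placements():
        pools = [titles for _, titles in forced]
        for titles in itertools.product(*pools):
            yield tuple(zip((p for p, _ in forced), titles))

    assignments: list[SiteAssignment] = []
    for forced_choice in forced_placements():
        for opt_choice in optional_placements():
            for nt in nt_options:
                for ct in ct_options:
                    site_mods: list[str | None] = [None] * len(seq)
                    for pos, title in forced_choice + opt_choice:
                        site_mods[pos] = title
                    a = SiteAssignment(
                        candidate=candidate,
                        site_mods=tuple(site_mods),
                        nterm_mod=nt,
                        cterm_mod=ct,
                        set_index=modset.set_index,
                    )
                    a.neutral_mass = peptide_mass(a, lookup)
                    assignments.append(a)
                    if len(assignments) >= max_perms:
                        return assignments
    return assignments


def primary_series(
    assignment: SiteAssignment, lookup: AminoAcidLookup, charge: int = 1
) -> IonSeries:
    """Singly protonated b/y ion m/z arrays (length n-1)."""
    seq = assignment.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("need at least 2 residues for a fragment series")
    masses = np.array(
        [_position_mass(lookup, aa, t) for aa, t in zip(seq, assignment.site_mods)]
    )
    nterm = _terminal_mass(lookup, "N-term", assignment.nterm_mod)
    cterm = _terminal_mass(lookup, "C-term", assignment.cterm_mod)
    prefix = np.cumsum(masses)[:-1]
    suffix = np.cumsum(masses[::-1])[:-1]
    b = prefix + nterm + PROTON
    y = suffix + WATER + cterm + PROTON
    return IonSeries(channels={"b": b, "y": y}, charge=charge)


def satellite_series(
    primary: IonSeries,
    assignment: SiteAssignment,
    lookup: AminoAcidLookup,
    doubly_charged: bool = True,
) -> IonSeries:
    """Fill satellite channels onto a primary series.

    Loss channels are gated on fragment residue content: ammonia loss
    requires R/K/N/Q, water loss requires S/T/E/D, and a
    modification-specific loss requires a modified position whose
    look-up entry carries a neutral-loss ("nl+") attribute.  Doubly
    charged variants are emitted for the six singly charged channels.
    """
    seq = assignment.sequence
    n = len(seq)
    b, y = primary["b"], primary["y"]
    channels = dict(primary.channels)

    prefix_sets = [set(seq[: i + 1]) for i in range(n - 1)]
    suffix_sets = [set(seq[n - j - 1 :]) for j in range(n - 1)]

    def gated(base: np.ndarray, frag_sets: list[set], residues: frozenset, loss: float):
        out = np.full(n - 1, np.nan)
        for i in range(n - 1):
            if frag_sets[i] & residues:
                out[i] = base[i] - loss
        return out

    channels["b*"] = gated(b, prefix_sets, NH3_LOSS_RESIDUES, AMMONIA)
    channels["y*"] = gated(y, suffix_sets, NH3_LOSS_RESIDUES, AMMONIA)
    channels["b0"] = gated(b, prefix_sets, H2O_LOSS_RESIDUES, WATER)
    channels["y0"] = gated(y, suffix_sets, H2O_LOSS_RESIDUES, WATER)

    # modification-specific neutral losses (e.g. phospho-S/T)
    nl_positions = [
        (pos, lookup.neutral_losses(seq[pos], t))
        for pos, t in enumerate(assignment.site_mods)
        if t is not None and lookup.has_neutral_loss(seq[pos], t)
    ]
    if nl_positions:
        b_nl = np.full(n - 1, np.nan)
        y_nl = np.full(n - 1, np.nan)
        for i in range(n - 1):
            for pos, losses in nl_positions:
                if pos <= i:
                    b_nl[i] = b[i] - losses[0]
                if pos >= n - 1 - i:
                    y_nl[i] = y[i] - losses[0]
        channels["b_nl"] = b_nl
        channels["y_nl"] = y_nl

    if doubly_charged:
        for src, dst in (
            ("b", "b2"), ("y", "y2"), ("b0", "b02"), ("y0", "y02"),
            ("b*", "b*2"), ("y*", "y*2"),
        ):
            channels[dst] = (channels[src] + PROTON) / 2.0
    return IonSeries(channels=channels, charge=primary.charge)


def full_series(
    assignment: SiteAssignment,
    lookup: AminoAcidLookup,
    precursor_charge: int = 2,
) -> IonSeries:
    """Primary plus satellite channels; doubly charged satellites are
    generated for precursors of charge >= 3."""
    prim = primary_series(assignment, lookup)
    return satellite_series(
        prim, assignment, lookup, doubly_charged=precursor_charge >= 3
    )
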