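"""Target-decoy FDR with subclass transfer, site localization, protein groups.

FDR is calibrated within the *subclass* of rank-1 PSMs that yields the
most matches (subclasses are keyed by modification-set index, since
modification complexity shifts score distributions) and the resulting
score-to-q mapping is transferred to every PSM by step-function lookup.

Site localization uses a counting statistic over matched
site-determining ions: with counts n_A : n_B for two competing
placements, the leading placement gets probability n_A / (n_A + n_B);
a zero-count competitor concedes 100% regardless of the winner's count.

Protein grouping arranges accepted peptides x proteins in a sparse
incidence structure, connects proteins through shared peptides
(single-link clustering of a 0/1 share-distance cut at any height > 0,
i.e. connected components), and marks essential proteins per group by
greedy set cover.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# FDR

def fdr_curve(scores: np.ndarray, decoy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sorted descending scores, monotone q-values) for one subclass."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    d = decoy[order].astype(int)
    cum_d = np.cumsum(d)
    cum_t = np.cumsum(1 - d)
    fdr = cum_d / np.maximum(cum_t, 1)
    # q-value: minimum FDR at any threshold at or below this score
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return s, q


def compute_fdr(psms: pd.DataFrame, subclass_col: str = "set_index") -> pd.DataFrame:
    """Attach q-values to rank-1 PSMs by subclass-calibrated target-decoy.

    Requires columns ``score``, ``is_decoy`` and the subclass key.  The
    subclass with the most PSMs calibrates the score-to-q mapping, which
    is then applied to all PSMs as a conservative step function: a PSM's
    q-value is that of the weakest calibration score it still exceeds.
    """
    psms = psms.copy()
    if len(psms) == 0:
        psms["q_value"] = np.array([], dtype=float)
        return psms
    if subclass_col in psms.columns:
        sizes = psms.groupby(subclass_col).size()
        calib_key = sizes.idxmax()
        calib = psms[psms[subclass_col] == calib_key]
    else:
        calib = psms
    if int(calib["is_decoy"].sum()) == 0:
        logger.warning("no decoys in the calibration subclass; all q-values 0")
        psms["q_value"] = 0.0
        return psms
    s, q = fdr_curve(
        calib["score"].to_numpy(float), calib["is_decoy"].to_numpy(bool)
    )
    # step lookup: q(x) = q of the largest calibration score <= x;
    # scores above all calibration points take the best q, below all take 1.
    s_asc = s[::-1]
    q_asc = q[::-1]
    idx = np.searchsorted(s_asc, psms["score"].to_numpy(float), side="right") - 1
    qv = np.where(idx >= 0, q_asc[np.maximum(idx, 0)], 1.0)
    psms["q_value"] = qv
    return psms


# --------------------------------------------------------------------------
# Site localization

def localization_probability(counts: list[int]) -> tuple[list[float], bool]:
    """Counting-statistic localization over competing site placements.

    ``counts[i]`` is the number of matched site-determining ions for
    placement ``i``.  Probabilities are the count fractions; if every
    count is zero the placements are indistinguishable and the uniform
    fallback is flagged.
    """
    total = sum(counts)
    if total == 0:
        return [1.0 / len(counts)] * len(counts), True
    return [c / total for c in counts], False


def site_determining_counts(
    assignments: list,
    lookups: dict,
    spectrum,
    matched_by_assignment: list[dict] | None = None,
    tol: float = 20.0,
    mz_resolution: float = 1e-6,
) -> list[int]:
    """Matched site-determining primary-ion counts per competing placement.

    A primary ion is site-determining for placement *i* when its m/z does
    not occur (within ``mz_resolution`` relative) in any competing
    placement's primary series.
    """
    from .ions import primary_series
    from .search import match_primary

    series = [
        primary_series(a, lookups[a.set_index]) for a in assignments
    ]
    mz_sets = [
        np.concatenate([s["b"], s["y"]]) for s in series
    ]
    counts = []
    for i, a in enumerate(assignments):
        others = np.concatenate([mz_sets[j] for j in range(len(assignments)) if j != i])
        matched = (
            matched_by_assignment[i]
            if matched_by_assignment is not None
            else match_primary(spectrum, series[i], tol)
        )
        n = 0
        for (ch, idx), _peak in matched.items():
            mz = series[i][ch][idx]
            if not np.any(np.abs(others - mz) / mz <= mz_resolution):
                n += 1
        counts.append(n)
    return counts


def localize_sites(
    assignments: list,
    lookups: dict,
    spectrum,
    tol: float = 20.0,
) -> tuple[list[float], bool]:
    """Localization probabilities for >= 2 competing site placements."""
    if len(assignments) < 2:
        return [1.0], False
    counts = site_determining_counts(assignments, lookups, spectrum, tol=tol)
    return localization_probability(counts)


# --------------------------------------------------------------------------
# Protein grouping

@dataclass
class IncidenceMatrix:
    """Sparse peptide-by-protein incidence with the r1/r2, c1/c2 partition.

    Rows are peptides, columns proteins.  r1 rows are unique peptides
    (one protein), r2 rows are shared; c1 columns are proteins carrying
    at least one shared peptide, c2 columns carry none.
    """

    peptides: list[str]
    proteins: list[str]
    matrix: csr_matrix

    @classmethod
    def from_mapping(cls, peptide_to_proteins: dict[str, list[str]]) -> "IncidenceMatrix":
        peptides = sorted(peptide_to_proteins)
        proteins = sorted({p for ps in peptide_to_proteins.values() for p in ps})
        col = {p: j for j, p in enumerate(proteins)}
        rows, cols = [], []
        for i, pep in enumerate(peptides):
            for p in set(peptide_to_proteins[pep]):
                rows.append(i)
                cols.append(col[p])
        m = csr_matrix(
            (np.ones(len(rows), dtype=bool), (rows, cols)),
            shape=(len(peptides), len(proteins)),
        )
        return cls(peptides, proteins, m)

    @property
    def r2_mask(self) -> np.ndarray:
        """True for shared-peptide rows."""
        return np.asarray(self.matrix.sum(axis=1)).ravel() >= 2

    @property
    def c1_mask(self) -> np.ndarray:
        """True for proteins with at least one shared peptide."""
        if self.matrix.shape[0] == 0:
            return np.zeros(self.matrix.shape[1], dtype=bool)
        shared = self.matrix[self.r2_mask]
        return np.asarray(shared.sum(axis=0)).ravel() > 0


@dataclass
class ProteinGroup:
    group_id: int
    members: tuple[str, ...]
    essential: tuple[str, ...]
    peptide_counts: dict[str, int] = field(default_factory=dict)


def greedy_set_cover(
    sets: dict[str, frozenset], universe: frozenset
) -> list[str]:
    """Greedy cover: repeatedly pick the set covering the most uncovered
    elements; ties break by larger total set, then lexicographic key."""
    uncovered = set(universe)
    chosen: list[str] = []
    while uncovered:
        best = min(
            sets,
            key=lambda k: (-len(sets[k] & uncovered), -len(sets[k]), k),
        )
        gain = sets[best] & uncovered
        if not gain:
            break
        chosen.append(best)
        uncovered -= gain
    return chosen


def exact_min_cover(sets: dict[str, frozenset], universe: frozenset) -> list[str]:
    """Smallest cover by exhaustive search (oracle for small instances)."""
    keys = sorted(sets)
    for r in range(1, len(keys) + 1):
        for combo in itertools.combinations(keys, r):
            if frozenset().union(*(sets[k] for k in combo)) >= universe:
                return list(combo)
    return []


def group_proteins(incidence: IncidenceMatrix) -> list[ProteinGroup]:
    """Partition proteins into groups connected by shared peptides.

    Only the c1 x r2 block affects the topology: proteins sharing any
    peptide land in one group (single-link clustering of the 0/1
    "shares-no-peptide" distance, cut above height 0); c2 proteins each
    form their own group.  Within a group, essential proteins are a
    greedy set cover over the group's peptides.
    """
    m = incidence.matrix
    n_pep, n_prot = m.shape
    if n_prot == 0:
        return []
    # protein-protein adjacency through shared peptides (r2 rows only)
    shared_rows = m[incidence.r2_mask]
    adj = (shared_rows.T @ shared_rows).tocoo()
    graph = csr_matrix(
        (np.ones(len(adj.data), dtype=bool), (adj.row, adj.col)),
        shape=(n_prot, n_prot),
    )
    n_comp, labels = connected_components(graph, directed=False)

    prot_peps: list[frozenset] = []
    mT = m.T.tocsr()
    for j in range(n_prot):
        prot_peps.append(frozenset(mT.indices[mT.indptr[j]:mT.indptr[j + 1]]))

    groups: list[ProteinGroup] = []
    for comp in range(n_comp):
        member_idx = np.flatnonzero(labels == comp)
        members = tuple(incidence.proteins[j] for j in member_idx)
        universe = frozenset().union(*(prot_peps[j] for j in member_idx))
        sets = {incidence.proteins[j]: prot_peps[j] for j in member_idx}
        essential = tuple(greedy_set_cover(sets, universe))
        groups.append(
            ProteinGroup(
                group_id=len(groups),
                members=tuple(sorted(members)),
                essential=essential,
                peptide_counts={p: len(sets[p]) for p in members},
            )
        )
    groups.sort(key=lambda g: g.members)
    for i, g in enumerate(groups):
        g.group_id = i
    return groups


# --------------------------------------------------------------------------
# Entrapment

def entrapment_rate(
    accepted: pd.DataFrame, label_col: str = "is_entrapment"
) -> tuple[float, bool]:
    """Fraction of accepted (target) PSMs that come from the entrapment
    database.  An empty acceptance list reports 0 with a flag."""
    if len(accepted) == 0:
        return 0.0, True
    return float(accepted[label_col].mean()), False


def entrapment_curve(
    psms: pd.DataFrame, label_col: str = "is_entrapment"
) -> pd.DataFrame:
    """Cumulative entrapment rate along decreasing score."""
    df = psms.sort_values("score", ascending=False, kind="stable")
    cum_e = df[label_col].astype(int).cumsum()
    n = np.arange(1, len(df) + 1)
    return pd.DataFrame(
        {"score": df["score"].to_numpy(), "entrapment_rate": cum_e / n}
    )
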