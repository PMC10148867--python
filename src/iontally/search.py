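"""Two-stage spectrum matching and progressive hypergeometric scoring.

Stage one matches theoretical primary b/y ions to experimental peaks
within a ppm tolerance.  Stage two — attempted only when at least
``min_primary_matches`` primaries matched — locates satellite ions
(ammonia/water losses, doubly charged variants, modification-specific
losses) and adds their intensities onto the matched primary's intensity:

    I'_{b_i} = I_{b_i} + I_{b*_i} + I_{b0_i} + I_{b2_i} + I_{b*2_i} + I_{b02_i}

Satellites are never counted as independent evidence; they act solely
through the boosted intensities.  Scoring then asks whether matched
primaries concentrate among the most intense spectrum features: with N
retained features of which K matched a primary ion, the top-k features
by boosted intensity contain x_k matches, giving an upper-tail
hypergeometric probability p_k for every k; the best (minimum)
probability over the scan, calibrated to its exact null probability P,
yields the score -10*log10(P).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from functools import lru_cache
from math import comb
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .ions import (
    IonSeries,
    NL_CHANNELS,
    PRIMARY_CHANNELS,
    SATELLITE_CHANNELS,
    SiteAssignment,
    full_series,
)
from .modifications import AminoAcidLookup
from .spectra import Spectrum, ppm_error, preprocess

logger = logging.getLogger(__name__)

#: satellite channels tallied onto each primary channel
SATELLITES_OF = {
    "b": ("b*", "b0", "b2", "b*2", "b02", "b_nl"),
    "y": ("y*", "y0", "y2", "y*2", "y02", "y_nl"),
}


@dataclass
class SearchConfig:
    """Search parameters; defaults follow common closed-search practice."""

    precursor_tol: float = 20.0  # ppm
    product_tol: float = 20.0  # ppm
    top_n: int = 100
    min_primary_matches: int = 6
    enzyme: str = "trypsin/p"
    specificity: str = "full"
    max_missed: int = 4
    min_len: int = 7
    max_len: int = 40
    min_mass: float = 700.0
    max_mass: float = 4500.0
    max_sites: int = 5
    max_per_mod: int = 3
    max_perms: int = 64
    fdr_threshold: float = 0.01
    max_precursor_ppm: float = 10.0  # post-search precursor-error filter
    decoy_tag: str = "rev_"

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.product_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_primary_matches < 1:
            raise ValueError("min_primary_matches must be >= 1")

    @property
    def len_range(self) -> tuple[int, int]:
        return (self.min_len, self.max_len)

    @property
    def mass_range(self) -> tuple[float, float]:
        return (self.min_mass, self.max_mass)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SearchConfig":
        import dataclasses

        valid = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ValueError(
                    f"{path}:{ln}: unknown key {key!r}; valid keys: "
                    f"{sorted(valid)}"
                )
            typ = {"float": float, "int": int, "str": str}[valid[key]]
            kwargs[key] = typ(val)
        return cls(**kwargs)


@dataclass
class MatchResult:
    """One scored candidate for one spectrum (a PSM when rank 1)."""

    spectrum: Spectrum
    assignment: SiteAssignment
    is_decoy: bool
    matched: dict  # (channel, index) -> peak index, primaries only
    satellite_matched: dict  # (channel, index) -> peak index
    raw_intensity: dict  # peak index -> raw intensity (matched primaries)
    boosted_intensity: dict  # peak index -> boosted intensity
    trace: list  # (k, x, p) triples at match increments
    best_p: float
    score: float
    precursor_error_ppm: float

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def _finite_ions(series: IonSeries, channels=PRIMARY_CHANNELS):
    """(channel, index, m/z) triples for finite entries, stable order."""
    out = []
    for ch in channels:
        if ch not in series:
            continue
        arr = series[ch]
        for i, mz in enumerate(arr):
            if np.isfinite(mz):
                out.append((ch, i, float(mz)))
    return out


def _assign_nearest(
    ions: list[tuple[str, int, float]],
    spectrum: Spectrum,
    tol: float,
    used_peaks: set[int] | None = None,
) -> dict[tuple[str, int], int]:
    """Greedy one-to-one ion/peak assignment by ascending |ppm error|.

    Each theoretical ion takes at most one peak and vice versa; ties in
    |ppm| resolve by ion enumeration order, then by lower peak index.
    """
    mz = spectrum.mz
    pairs = []  # (|ppm|, ion_order, peak_idx, ion_key)
    for order, (ch, i, theo) in enumerate(ions):
        lo = theo * (1 - tol * 1e-6)
        hi = theo * (1 + tol * 1e-6)
        j0, j1 = np.searchsorted(mz, [lo, hi])
        for j in range(int(j0), int(j1)):
            if used_peaks and j in used_peaks:
                continue
            err = abs(ppm_error(mz[j], theo))
            if err <= tol:
                pairs.append((err, order, j, (ch, i)))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    matched: dict[tuple[str, int], int] = {}
    taken: set[int] = set()
    for _, _, j, key in pairs:
        if key in matched or j in taken:
            continue
        matched[key] = j
        taken.add(j)
    return matched


def match_primary(
    spectrum: Spectrum, series: IonSeries, tol: float
) -> dict[tuple[str, int], int]:
    """Match primary b/y ions to peaks; returns (channel, i) -> peak index."""
    return _assign_nearest(_finite_ions(series, PRIMARY_CHANNELS), spectrum, tol)


def tally_satellites(
    spectrum: Spectrum,
    series: IonSeries,
    primary_matches: dict[tuple[str, int], int],
    tol: float,
    n_min: int = 6,
) -> tuple[dict[int, float], dict[tuple[str, int], int]]:
    """Boosted intensities for matched primaries.

    Returns ``(boosted, satellite_matched)`` where ``boosted`` maps the
    matched primary's peak index to its tallied intensity.  The satellite
    stage only runs with at least ``n_min`` matched primaries; below that
    the boosted intensities equal the raw ones.
    """
    boosted = {j: float(spectrum.intensity[j]) for j in primary_matches.values()}
    if len(primary_matches) < n_min:
        return boosted, {}

    sat_channels = tuple(SATELLITE_CHANNELS) + tuple(NL_CHANNELS)
    wanted = []
    owner = {}  # satellite ion key -> primary peak index
    for (ch, i), peak_idx in primary_matches.items():
        for sat_ch in SATELLITES_OF[ch]:
            if sat_ch not in series:
                continue
            mz = series[sat_ch][i]
            if np.isfinite(mz):
                wanted.append((sat_ch, i, float(mz)))
                owner[(sat_ch, i)] = peak_idx
    sat_matched = _assign_nearest(
        wanted, spectrum, tol, used_peaks=set(primary_matches.values())
    )
    for key, j in sat_matched.items():
        boosted[owner[key]] += float(spectrum.intensity[j])
    return boosted, sat_matched


def hypergeom_tail(x: int, N: int, K: int, k: int) -> float:
    """P(X >= x) drawing k from N containing K successes."""
    return float(hypergeom.sf(x - 1, N, K, k))


@lru_cache(maxsize=64)
def _tail_table(N: int, K: int) -> np.ndarray:
    """Upper-tail probabilities p[k, x] = P(X >= x | N, K, k), k = 0..N."""
    k = np.arange(N + 1)[:, None]
    x = np.arange(K + 1)[None, :]
    table = hypergeom.sf(x - 1, N, K, k)
    table[:, 0] = 1.0
    return table


def min_tail_pvalue(min_p: float, N: int, K: int) -> float:
    """Exact null probability that the progressive scan attains a minimum
    tail probability <= ``min_p``.

    The minimum over the progressive scan is not itself a calibrated
    probability (it is a minimum over dependent tests), so the reported P
    is the exact probability, under random placement of the K matches
    among the N ranked features, that the scan minimum is at least as
    small as observed.  Computed by the standard lattice-path count over
    the (k, x) grid with cells in the rejection region removed.
    """
    if K <= 0 or K >= N:
        return 1.0
    table = _tail_table(N, K)
    thresh = min_p * (1.0 + 1e-9)
    prev = [0] * (K + 1)
    prev[0] = 1
    for k in range(1, N + 1):
        cur = [0] * (K + 1)
        x_lo = max(0, k - (N - K))
        x_hi = min(k, K)
        for x in range(x_lo, x_hi + 1):
            if table[k, x] <= thresh:
                continue  # rejection region: paths through here have hit
            cur[x] = prev[x] + (prev[x - 1] if x > 0 else 0)
        prev = cur
    surviving = prev[K]
    total = comb(N, K)
    return float(1 - Fraction(surviving, total))


def enrichment_score(
    spectrum: Spectrum, boosted: dict[int, float]
) -> tuple[list[tuple[int, int, float]], float, float]:
    """Progressive hypergeometric enrichment of matched primaries.

    Features are the N retained peaks ranked by boosted intensity
    (matched primaries use their tallied intensity; ties rank lower m/z
    first).  For every depth k, x_k matches among the top k features give
    p_k = P(X >= x_k | N, K, k); the scan minimum min_k p_k is then
    calibrated to its exact null probability P (see
    :func:`min_tail_pvalue`) and the score is -10*log10(P).  Degenerate
    cases K = 0 and K = N score 0.
    """
    N = len(spectrum)
    K = len(boosted)
    if K == 0 or K == N or N == 0:
        return [], 1.0, 0.0

    intensity = spectrum.intensity.astype(float).copy()
    for j, v in boosted.items():
        intensity[j] = v
    order = np.lexsort((spectrum.mz, -intensity))
    matched_flags = np.zeros(N, dtype=bool)
    matched_flags[list(boosted)] = True
    x = np.cumsum(matched_flags[order])
    k = np.arange(1, N + 1)
    p = hypergeom.sf(x - 1, N, K, k)
    p = np.where(x == 0, 1.0, p)
    min_p = max(float(np.min(p)), 1e-300)
    best_p = max(min_tail_pvalue(min_p, N, K), 1e-300)
    score = -10.0 * np.log10(best_p)
    # record the trace at match increments (where x steps up)
    steps = np.flatnonzero(np.diff(np.concatenate(([0], x))) > 0)
    trace = [(int(k[i]), int(x[i]), float(p[i])) for i in steps]
    return trace, best_p, max(score, 0.0)


def score_candidate(
    spectrum: Spectrum,
    assignment: SiteAssignment,
    lookup: AminoAcidLookup,
    config: SearchConfig,
) -> MatchResult | None:
    """Run both match stages and score one candidate assignment."""
    series = full_series(assignment, lookup, spectrum.precursor_charge)
    primary = match_primary(spectrum, series, config.product_tol)
    if len(primary) < config.min_primary_matches:
        return None
    boosted, sat_matched = tally_satellites(
        spectrum, series, primary, config.product_tol,
        n_min=config.min_primary_matches,
    )
    trace, best_p, score = enrichment_score(spectrum, boosted)
    prec_err = ppm_error(
        spectrum.precursor_neutral_mass, assignment.neutral_mass
    )
    return MatchResult(
        spectrum=spectrum,
        assignment=assignment,
        is_decoy=assignment.candidate.is_decoy,
        matched=primary,
        satellite_matched=sat_matched,
        raw_intensity={j: float(spectrum.intensity[j]) for j in primary.values()},
        boosted_intensity=boosted,
        trace=trace,
        best_p=best_p,
        score=score,
        precursor_error_ppm=float(prec_err),
    )


def search_spectrum(
    spectrum: Spectrum,
    binned,
    lookups: dict[int, AminoAcidLookup],
    config: SearchConfig,
) -> list[MatchResult]:
    """Score all candidate assignments within precursor tolerance.

    Returns results ranked by (score desc, |precursor ppm| asc).
    Duplicate modified-peptide forms arising from overlapping
    modification sets keep their best-scoring instance.
    """
    if spectrum.retained_n is None:
        spectrum = preprocess(spectrum, config.top_n)
    pmass = spectrum.precursor_neutral_mass
    if not (config.min_mass <= pmass <= config.max_mass):
        return []
    results: dict[tuple, MatchResult] = {}
    for _, assignment in binned.query(pmass, config.precursor_tol):
        res = score_candidate(
            spectrum, assignment, lookups[assignment.set_index], config
        )
        if res is None:
            continue
        key = assignment.key()
        prev = results.get(key)
        if prev is None or (res.score, -abs(res.precursor_error_ppm)) > (
            prev.score, -abs(prev.precursor_error_ppm)
        ):
            results[key] = res
    ranked = sorted(
        results.values(),
        key=lambda r: (-r.score, abs(r.precursor_error_ppm),
                       r.assignment.annotated()),
    )
    return ranked
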