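"""FASTA ingestion, in-silico digestion, decoy generation, precursor binning.

Digestion supports full, semi- and non-specific enzymatic modes for
trypsin/P (cleavage C-terminal to K or R with no proline exception) or a
user-supplied cut-site regex.  Decoys are full sequence reversals tagged
with a reserved accession prefix.  Candidates expanded to site assignments
are binned by neutral precursor mass on a log-mass grid so that a ±ppm
query touches at most two adjacent bins.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import fasta as _pfasta

from .constants import AMBIGUOUS_RESIDUES

logger = logging.getLogger(__name__)

DECOY_TAG = "rev_"

ENZYMES = {
    # cut C-terminal to the matched residue
    "trypsin/p": r"[KR]",
    "trypsin": r"[KR](?!P)",
    "lys-c": r"K",
    "arg-c": r"R",
}


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")


@dataclass
class PeptideCandidate:
    sequence: str
    protein_refs: tuple[str, ...]
    missed_cleavages: int = 0
    is_protein_nterm: bool = False
    is_protein_cterm: bool = False
    is_decoy: bool = False

    def __hash__(self) -> int:
        return hash((self.sequence, self.is_protein_nterm,
                     self.is_protein_cterm, self.is_decoy))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA database; accession = first token of the header.

    Duplicate accessions are deduplicated keeping the first occurrence,
    with a warning — concatenating a contaminant database to a target
    database routinely produces benign duplicates.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    with path.open() as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        line_no = next(
            i + 1 for i, l in enumerate(text.splitlines()) if l.strip()
        )
        raise ValueError(f"{path}:{line_no}: expected '>' header line")
    for header, seq in _pfasta.read(str(path)):
        accession = header.split()[0]
        if accession in seen:
            logger.warning("duplicate accession %s: keeping first", accession)
            continue
        seen[accession] = 1
        records.append(ProteinRecord(accession, header, seq.upper()))
    return records


def merge_databases(*record_lists: list[ProteinRecord]) -> list[ProteinRecord]:
    """Concatenate databases (target + contaminants + entrapment)."""
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for lst in record_lists:
        for r in lst:
            if r.accession in seen:
                continue
            seen.add(r.accession)
            out.append(r)
    return out


def make_decoys(records: list[ProteinRecord], tag: str = DECOY_TAG) -> list[ProteinRecord]:
    """Full-reversal decoys, accession prefixed with the decoy tag."""
    return [
        ProteinRecord(tag + r.accession, tag + r.description, r.sequence[::-1])
        for r in records
    ]


def _cleavage_sites(sequence: str, pattern: str) -> list[int]:
    """0-based positions *after* which the enzyme cuts."""
    return [m.start() for m in re.finditer(pattern, sequence)]


def digest(
    record: ProteinRecord,
    enzyme: str = "trypsin/p",
    specificity: str = "full",
    max_missed: int = 4,
    len_range: tuple[int, int] = (7, 40),
    clip_initiator_met: bool = True,
) -> list[PeptideCandidate]:
    """In-silico digestion of one protein.

    ``specificity``: ``full`` (both termini enzymatic), ``semi`` (at least
    one terminus enzymatic) or ``none`` (every substring in the length
    range).  In semi/non-specific modes the missed-cleavage count is not
    enforced.  When ``clip_initiator_met`` is set, peptides starting at
    position 2 after an initiator methionine are additionally flagged as
    protein N-terminal, so protein N-terminal modifications stay reachable
    on mature N-termini.
    """
    key = enzyme.lower()
    if key not in ENZYMES:
        raise ValueError(
            f"unknown enzyme {enzyme!r}; known: {sorted(ENZYMES)}"
        )
    pattern = ENZYMES[key]
    seq = record.sequence
    n = len(seq)
    lo, hi = len_range
    sites = _cleavage_sites(seq, pattern)
    # fragment start indices: 0 and site+1; end indices: site+1 and n
    starts = [0] + [s + 1 for s in sites if s + 1 < n]
    ends = [s + 1 for s in sites if s + 1 <= n] + ([n] if (not sites or sites[-1] != n - 1) else [])
    start_set, end_set = set(starts), set(ends)

    dropped_ambiguous = 0
    out: dict[tuple, PeptideCandidate] = {}

    def emit(i: int, j: int, missed: int) -> None:
        nonlocal dropped_ambiguous
        sub = seq[i:j]
        if not (lo <= len(sub) <= hi):
            return
        if AMBIGUOUS_RESIDUES.intersection(sub):
            dropped_ambiguous += 1
            return
        protein_nterm = i == 0 or (clip_initiator_met and i == 1 and seq[0] == "M")
        key_ = (sub, protein_nterm, j == n)
        if key_ not in out:
            out[key_] = PeptideCandidate(
                sequence=sub,
                protein_refs=(record.accession,),
                missed_cleavages=missed,
                is_protein_nterm=protein_nterm,
                is_protein_cterm=j == n,
                is_decoy=record.accession.startswith(DECOY_TAG),
            )

    if specificity == "full":
        all_starts = sorted(
            set(starts)
            | ({1} if clip_initiator_met and seq[:1] == "M" else set())
        )
        for i in all_starts:
            for j in sorted(end_set):
                if j <= i:
                    continue
                missed = sum(1 for s in sites if i <= s < j - 1)
                if missed > max_missed:
                    break
                emit(i, j, missed)
    elif specificity == "semi":
        for i in range(n):
            for j in range(i + lo, min(i + hi, n) + 1):
                if i in start_set or j in end_set or (
                    clip_initiator_met and i == 1 and seq[0] == "M"
                ):
                    missed = sum(1 for s in sites if i <= s < j - 1)
                    emit(i, j, missed)
    elif specificity == "none":
        for i in range(n):
            for j in range(i + lo, min(i + hi, n) + 1):
                missed = sum(1 for s in sites if i <= s < j - 1)
                emit(i, j, missed)
    else:
        raise ValueError(f"unknown specificity {specificity!r}")

    if dropped_ambiguous:
        logger.info(
            "%s: dropped %d peptide(s) containing ambiguous residues",
            record.accession, dropped_ambiguous,
        )
    return list(out.values())


def digest_database(
    records: list[ProteinRecord], **kwargs
) -> list[PeptideCandidate]:
    """Digest every record, merging shared peptides' protein references."""
    merged: dict[tuple, PeptideCandidate] = {}
    for rec in records:
        for cand in digest(rec, **kwargs):
            key = (cand.sequence, cand.is_protein_nterm,
                   cand.is_protein_cterm, cand.is_decoy)
            if key in merged:
                prev = merged[key]
                if cand.protein_refs[0] not in prev.protein_refs:
                    prev.protein_refs = prev.protein_refs + cand.protein_refs
            else:
                merged[key] = cand
    return list(merged.values())


@dataclass
class MassBin:
    index: int
    lower: float
    upper: float
    members: list = field(default_factory=list)  # (neutral_mass, payload)


class BinnedCandidates:
    """Log-mass binned index over (neutral mass, payload) pairs.

    Bin relative width is twice the query tolerance, so any ±tol ppm query
    interval spans at most two adjacent bins.
    """

    def __init__(
        self,
        entries: list[tuple[float, object]],
        mass_range: tuple[float, float] = (700.0, 4500.0),
        bin_width_ppm: float = 40.0,
    ):
        if bin_width_ppm <= 0:
            raise ValueError("bin width must be positive")
        self.mass_range = mass_range
        self.rel_width = bin_width_ppm * 1e-6
        self._log_lo = math.log(mass_range[0])
        self._log_w = math.log1p(self.rel_width)
        self.bins: dict[int, MassBin] = {}
        lo, hi = mass_range
        for m, payload in entries:
            if not (lo <= m <= hi):
                continue
            idx = self._bin_index(m)
            b = self.bins.get(idx)
            if b is None:
                b = MassBin(
                    idx,
                    math.exp(self._log_lo + idx * self._log_w),
                    math.exp(self._log_lo + (idx + 1) * self._log_w),
                )
                self.bins[idx] = b
            b.members.append((m, payload))

    def _bin_index(self, m: float) -> int:
        return int(math.floor((math.log(m) - self._log_lo) / self._log_w))

    def query(self, mass: float, tol_ppm: float) -> list[tuple[float, object]]:
        """All entries within ±tol_ppm of ``mass`` (inclusive bounds)."""
        lo = mass * (1 - tol_ppm * 1e-6)
        hi = mass * (1 + tol_ppm * 1e-6)
        i0, i1 = self._bin_index(max(lo, 1e-9)), self._bin_index(hi)
        hits = []
        for idx in range(i0, i1 + 1):
            b = self.bins.get(idx)
            if b is None:
                continue
            for m, payload in b.members:
                if abs((mass - m) / m) * 1e6 <= tol_ppm:
                    hits.append((m, payload))
        return hits

    def __len__(self) -> int:
        return sum(len(b.members) for b in self.bins.values())


def bin_candidates(
    entries: list[tuple[float, object]],
    mass_range: tuple[float, float] = (700.0, 4500.0),
    bin_width_ppm: float = 40.0,
) -> BinnedCandidates:
    return BinnedCandidates(entries, mass_range, bin_width_ppm)
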