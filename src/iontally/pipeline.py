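"""End-to-end search orchestration, result tables, and precursor caching.

``run_search`` executes compile -> digest -> enumerate -> bin -> search
-> filter -> FDR -> localize -> group and writes three tab-delimited
tables: ``psmC.txt`` (the complete ranked list, targets and decoys),
``psmQ.txt`` (the quality subset passing the FDR threshold at PSM,
peptide and protein level), and ``prot.txt`` (protein groups with
essential-member flags), plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .ions import SiteAssignment, dispatchable, enumerate_assignments
from .modifications import (
    ModRegistry,
    build_aa_lookup,
    compile_mod_sets,
    parse_mod_spec,
)
from .postsearch import (
    IncidenceMatrix,
    compute_fdr,
    fdr_curve,
    group_proteins,
    localization_probability,
    site_determining_counts,
)
from .proteolysis import (
    bin_candidates,
    digest_database,
    make_decoys,
    merge_databases,
    read_fasta,
)
from .search import MatchResult, SearchConfig, search_spectrum
from .spectra import preprocess, read_peaklist

logger = logging.getLogger(__name__)

PSM_COLUMNS = [
    "file", "scan", "title", "precursor_mz", "charge",
    "precursor_neutral_mass", "peptide", "sequence", "set_index",
    "proteins", "n_matched", "score", "best_p", "precursor_error_ppm",
    "rank", "is_decoy", "is_entrapment", "q_value", "localization",
]


def _digest_key(fasta_texts: list[str], modset_signatures, config: SearchConfig) -> str:
    h = hashlib.sha256()
    for t in fasta_texts:
        h.update(t.encode())
    h.update(repr(sorted(map(str, modset_signatures))).encode())
    h.update(
        repr((config.enzyme, config.specificity, config.max_missed,
              config.len_range, config.mass_range, config.max_sites,
              config.max_per_mod, config.max_perms)).encode()
    )
    return h.hexdigest()


def build_search_space(
    records,
    modsets,
    lookups,
    config: SearchConfig,
    cache_dir: str | Path | None = None,
    fasta_texts: list[str] | None = None,
):
    """Enumerate site assignments for all candidates and bin by mass.

    When a cache directory is given, the (mass, assignment) table is
    reused across runs with the same database/modification/digestion key.
    """
    cache_path = None
    if cache_dir is not None and fasta_texts is not None:
        key = _digest_key(fasta_texts, [m.signature() for m in modsets], config)
        cache_path = Path(cache_dir) / f"precursors-{key[:16]}.pkl"
        if cache_path.exists():
            with cache_path.open("rb") as fh:
                entries = pickle.load(fh)
            logger.info("precursor cache hit: %s", cache_path.name)
            return bin_candidates(entries, config.mass_range), key

    candidates = digest_database(
        records,
        enzyme=config.enzyme,
        specificity=config.specificity,
        max_missed=config.max_missed,
        len_range=config.len_range,
    )
    entries: list[tuple[float, SiteAssignment]] = []
    for cand in candidates:
        for ms in modsets:
            if not dispatchable(cand, ms):
                continue
            for a in enumerate_assignments(
                cand, ms, lookups[ms.set_index],
                max_sites=config.max_sites,
                max_per_mod=config.max_per_mod,
                max_perms=config.max_perms,
            ):
                entries.append((a.neutral_mass, a))

    key = None
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        with cache_path.open("wb") as fh:
            pickle.dump(entries, fh)
        key = cache_path.name
    return bin_candidates(entries, config.mass_range), key


def _result_row(spectrum, res: MatchResult, rank: int, entrap_accs: set) -> dict:
    a = res.assignment
    prots = sorted(a.candidate.protein_refs)
    return {
        "file": spectrum.source,
        "scan": spectrum.scan,
        "title": spectrum.title,
        "precursor_mz": spectrum.precursor_mz,
        "charge": spectrum.precursor_charge,
        "precursor_neutral_mass": spectrum.precursor_neutral_mass,
        "peptide": a.sequence,
        "sequence": a.annotated(),
        "set_index": a.set_index,
        "proteins": ";".join(prots),
        "n_matched": res.n_matched,
        "score": res.score,
        "best_p": res.best_p,
        "precursor_error_ppm": res.precursor_error_ppm,
        "rank": rank,
        "is_decoy": res.is_decoy,
        "is_entrapment": bool(prots) and all(p in entrap_accs for p in prots),
        "q_value": np.nan,
        "localization": "",
    }


def _localize(res: MatchResult, ranked: list[MatchResult], lookups, config) -> str:
    """Counting-statistic localization against positional isomers of the
    rank-1 assignment found among this spectrum's scored candidates."""
    a = res.assignment
    mods = sorted(t for t in a.site_mods if t is not None)
    if not mods:
        return ""
    # positional isomers: same sequence, same modification multiset,
    # different placement
    rivals = [
        r.assignment
        for r in ranked
        if r is not res
        and r.assignment.sequence == a.sequence
        and sorted(t for t in r.assignment.site_mods if t is not None) == mods
        and r.assignment.site_mods != a.site_mods
        and r.assignment.candidate.is_decoy == a.candidate.is_decoy
    ]
    if not rivals:
        return ""
    assignments = [a] + rivals
    counts = site_determining_counts(
        assignments, lookups, res.spectrum, tol=config.product_tol
    )
    probs, flagged = localization_probability(counts)
    positions = [
        ",".join(
            f"{aa}{i + 1}" for i, (aa, t) in
            enumerate(zip(x.sequence, x.site_mods)) if t is not None
        )
        for x in assignments
    ]
    tag = "~" if flagged else ""
    return ";".join(f"{p}:{pr:.3f}{tag}" for p, pr in zip(positions, probs))


def level_q_values(rank1: pd.DataFrame, key_col: str) -> pd.Series:
    """Simple level-wise target-decoy q-values (peptide or protein level):
    keep the best score per key, run the target-decoy curve over keys, and
    map back to rows."""
    best = (
        rank1.groupby([key_col, "is_decoy"])["score"].max().reset_index()
    )
    if int(best["is_decoy"].sum()) == 0:
        return pd.Series(0.0, index=rank1.index)
    s, q = fdr_curve(
        best["score"].to_numpy(float), best["is_decoy"].to_numpy(bool)
    )
    s_asc, q_asc = s[::-1], q[::-1]
    idx = np.searchsorted(s_asc, rank1["score"].to_numpy(float), side="right") - 1
    return pd.Series(
        np.where(idx >= 0, q_asc[np.maximum(idx, 0)], 1.0), index=rank1.index
    )


def write_psm_tables(
    psmC: pd.DataFrame,
    out_dir: str | Path,
    threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write psmC.txt (complete) and psmQ.txt (quality subset).

    psmQ holds rank-1 target PSMs with q <= threshold at the PSM level
    that also pass peptide- and protein-level target-decoy control at the
    same threshold.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    psmC = psmC[PSM_COLUMNS]
    psmC.to_csv(out_dir / "psmC.txt", sep="\t", index=False)

    rank1 = psmC[(psmC["rank"] == 1)].copy()
    if len(rank1):
        rank1["protein_lead"] = rank1["proteins"].str.split(";").str[0]
        pep_q = level_q_values(rank1, "peptide")
        prot_q = level_q_values(rank1, "protein_lead")
        keep = (
            (~rank1["is_decoy"])
            & (rank1["q_value"] <= threshold)
            & (pep_q <= threshold)
            & (prot_q <= threshold)
        )
        psmQ = rank1[keep].drop(columns=["protein_lead"])
    else:
        psmQ = rank1
    psmQ.to_csv(out_dir / "psmQ.txt", sep="\t", index=False)
    return psmC, psmQ


def write_protein_table(psmQ: pd.DataFrame, out_dir: str | Path):
    """Group proteins from accepted peptides and write prot.txt."""
    mapping: dict[str, list[str]] = {}
    for _, row in psmQ.iterrows():
        mapping.setdefault(row["peptide"], [])
        mapping[row["peptide"]] = sorted(
            set(mapping[row["peptide"]]) | set(row["proteins"].split(";"))
        )
    incidence = IncidenceMatrix.from_mapping(mapping)
    groups = group_proteins(incidence)
    rows = []
    for g in groups:
        for acc in g.members:
            rows.append(
                {
                    "group": g.group_id,
                    "protein": acc,
                    "essential": acc in g.essential,
                    "n_peptides": g.peptide_counts.get(acc, 0),
                }
            )
    df = pd.DataFrame(rows, columns=["group", "protein", "essential", "n_peptides"])
    df.to_csv(Path(out_dir) / "prot.txt", sep="\t", index=False)
    return groups, df


def run_search(
    fasta_paths: list[str | Path],
    peaklist_paths: list[str | Path],
    out_dir: str | Path,
    fixed: list[str] = (),
    variable: list[str] = (),
    config: SearchConfig | None = None,
    registry: ModRegistry | None = None,
    entrapment_fasta: str | Path | None = None,
    cache_dir: str | Path | None = None,
    localize: bool = True,
) -> dict:
    """Full closed search; returns the manifest dictionary.

    ``fixed``/``variable`` are modification specifications such as
    ``"Carbamidomethyl (C)"``.  An entrapment FASTA, when given, is
    appended to the target database before decoy reversal and its
    accessions are tracked in the ``is_entrapment`` output column.
    """
    t0 = time.time()
    config = config or SearchConfig()
    registry = registry or ModRegistry()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fixed_defs = [parse_mod_spec(s, registry) for s in fixed]
    var_defs = [parse_mod_spec(s, registry) for s in variable]
    modsets = compile_mod_sets(fixed_defs, var_defs)
    lookups = {m.set_index: build_aa_lookup(m) for m in modsets}

    targets = merge_databases(*[read_fasta(p) for p in fasta_paths])
    entrap_accs: set[str] = set()
    if entrapment_fasta is not None:
        entrap = read_fasta(entrapment_fasta)
        entrap_accs = {r.accession for r in entrap}
        targets = merge_databases(targets, entrap)
    records = targets + make_decoys(targets, tag=config.decoy_tag)
    fasta_texts = [Path(p).read_text() for p in fasta_paths] + (
        [Path(entrapment_fasta).read_text()] if entrapment_fasta else []
    )

    binned, cache_key = build_search_space(
        records, modsets, lookups, config,
        cache_dir=cache_dir, fasta_texts=fasta_texts,
    )
    logger.info("search space: %d site assignments in range", len(binned))

    spectra = []
    for p in peaklist_paths:
        spectra.extend(read_peaklist(p))
    counters = {
        "n_proteins_target": len(targets),
        "n_assignments": len(binned),
        "n_spectra": len(spectra),
        "n_searched": 0,
        "n_scored": 0,
    }

    rows = []
    for spec in spectra:
        spec = preprocess(spec, config.top_n)
        ranked = search_spectrum(spec, binned, lookups, config)
        if ranked:
            counters["n_searched"] += 1
        for rank, res in enumerate(ranked, start=1):
            row = _result_row(spec, res, rank, entrap_accs)
            if rank == 1 and localize:
                row["localization"] = _localize(res, ranked, lookups, config)
            rows.append(row)
            counters["n_scored"] += 1

    psmC = pd.DataFrame(rows, columns=PSM_COLUMNS)
    # post-search filters, then FDR on rank-1
    rank1 = psmC[
        (psmC["rank"] == 1)
        & (psmC["n_matched"] >= config.min_primary_matches)
        & (psmC["precursor_error_ppm"].abs() <= config.max_precursor_ppm)
    ]
    rank1 = compute_fdr(rank1)
    psmC.loc[rank1.index, "q_value"] = rank1["q_value"]

    psmC_out, psmQ = write_psm_tables(psmC, out_dir, config.fdr_threshold)
    groups, _ = write_protein_table(psmQ, out_dir)

    manifest = {
        "config": {k: v for k, v in config.__dict__.items()},
        "inputs": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for p in list(fasta_paths) + list(peaklist_paths)
        },
        "cache_key": cache_key,
        "counters": counters
        | {
            "n_rank1": int((psmC["rank"] == 1).sum()),
            "n_accepted": int(len(psmQ)),
            "n_groups": len(groups),
        },
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
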