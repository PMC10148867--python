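"""Synthetic-data generator, end-to-end pipeline, and output tables."""

import numpy as np
import pandas as pd
import pytest

from iontally.modifications import build_aa_lookup, compile_mod_sets
from iontally.pipeline import run_search, write_psm_tables, PSM_COLUMNS
from iontally.search import SearchConfig
from iontally.simulate import GroundTruth, random_protein_fasta, synth_spectra
from iontally.spectra import write_mgf


@pytest.fixture(scope="module")
def ox_setup(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("e2e")
    fasta = tmp / "target.fasta"
    records = random_protein_fasta(fasta, n_proteins=5, seed=7)
    modsets = compile_mod_sets([], [])
    from iontally.modifications import ModRegistry, parse_mod_spec

    reg = ModRegistry()
    modsets = compile_mod_sets(
        [parse_mod_spec("Carbamidomethyl (C)", reg)],
        [parse_mod_spec("Oxidation (M)", reg)],
    )
    lookups = {m.set_index: build_aa_lookup(m) for m in modsets}
    return tmp, fasta, records, modsets, lookups


@pytest.fixture(scope="module")
def e2e_run(ox_setup):
    """One full search of 50 noisy synthetic spectra, shared across tests."""
    tmp, fasta, records, modsets, lookups = ox_setup
    spectra, truths = synth_spectra(
        records, modsets, lookups, n_peptides=50, n_noise=30, seed=101
    )
    mgf = tmp / "run.mgf"
    write_mgf(spectra, mgf)
    out = tmp / "out"
    manifest = run_search(
        [fasta], [mgf], out,
        fixed=["Carbamidomethyl (C)"], variable=["Oxidation (M)"],
        cache_dir=tmp / "cache",
    )
    psmC = pd.read_csv(out / "psmC.txt", sep="\t")
    psmQ = pd.read_csv(out / "psmQ.txt", sep="\t")
    return manifest, psmC, psmQ, truths, (tmp, fasta, mgf)


class TestSimulate:
    def test_same_seed_identical_mgf_bytes(self, ox_setup, tmp_path):
        _, _, records, modsets, lookups = ox_setup
        files = []
        for name in ("a.mgf", "b.mgf"):
            spectra, _ = synth_spectra(
                records, modsets, lookups, n_peptides=10, seed=5
            )
            p = tmp_path / name
            write_mgf(spectra, p)
            files.append(p.read_bytes())
        assert files[0] == files[1]

    def test_different_seed_differs(self, ox_setup):
        _, _, records, modsets, lookups = ox_setup
        s1, _ = synth_spectra(records, modsets, lookups, n_peptides=5, seed=1)
        s2, _ = synth_spectra(records, modsets, lookups, n_peptides=5, seed=2)
        assert any(
            len(a) != len(b) or not np.allclose(a.mz, b.mz)
            for a, b in zip(s1, s2)
        )

    def test_too_many_peptides_states_maximum(self, ox_setup):
        _, _, records, modsets, lookups = ox_setup
        with pytest.raises(ValueError, match=r"only \d+"):
            synth_spectra(records, modsets, lookups, n_peptides=10_000)

    def test_ground_truth_round_trips(self, ox_setup, tmp_path):
        _, _, records, modsets, lookups = ox_setup
        _, truths = synth_spectra(records, modsets, lookups, n_peptides=8, seed=3)
        p = tmp_path / "truth.tsv"
        GroundTruth.frame(truths).to_csv(p, sep="\t", index=False)
        back = pd.read_csv(p, sep="\t")
        assert list(back["title"]) == [t.title for t in truths]
        assert list(back["sequence"]) == [t.annotated for t in truths]

    def test_planted_ions_present_within_jitter(self, ox_setup):
        _, _, records, modsets, lookups = ox_setup
        jitter = 2.0
        spectra, truths = synth_spectra(
            records, modsets, lookups, n_peptides=6, ppm_jitter=jitter, seed=4
        )
        for s, t in zip(spectra, truths):
            for ch, values in t.planted_mz.items():
                for mz in values:
                    err = np.min(np.abs(s.mz - mz) / mz) * 1e6
                    assert err <= 6 * jitter

    def test_noiseless_run_recovers_everything_rank1(self, ox_setup):
        from iontally.pipeline import build_search_space
        from iontally.proteolysis import make_decoys
        from iontally.search import search_spectrum
        from iontally.spectra import preprocess

        _, _, records, modsets, lookups = ox_setup
        spectra, truths = synth_spectra(
            records, modsets, lookups, n_peptides=25, n_noise=0,
            ppm_jitter=0.0, seed=9,
        )
        cfg = SearchConfig()
        binned, _ = build_search_space(
            records + make_decoys(records), modsets, lookups, cfg
        )
        for s, t in zip(spectra, truths):
            ranked = search_spectrum(preprocess(s), binned, lookups, cfg)
            assert ranked and ranked[0].assignment.annotated() == t.annotated


class TestEndToEnd:
    def test_recovery_at_one_percent_fdr(self, e2e_run):
        """At least 95% of planted peptides are recovered in psmQ."""
        _, _, psmQ, truths, _ = e2e_run
        truth_map = {t.title: t.annotated for t in truths}
        correct = sum(
            1 for _, r in psmQ.iterrows()
            if truth_map.get(r["title"]) == r["sequence"]
        )
        assert correct / len(truths) >= 0.95

    def test_psmq_subset_of_psmc(self, e2e_run):
        _, psmC, psmQ, _, _ = e2e_run
        assert list(psmQ.columns) == list(psmC.columns) == PSM_COLUMNS
        merged = psmQ.merge(psmC, on=["title", "sequence", "rank"], how="left",
                            indicator=True, suffixes=("", "_c"))
        assert (merged["_merge"] == "both").all()
        assert not psmQ["is_decoy"].any()

    def test_rerun_reproduces_psmc(self, e2e_run):
        manifest, psmC, _, _, (tmp, fasta, mgf) = e2e_run
        out2 = tmp / "out2"
        run_search(
            [fasta], [mgf], out2,
            fixed=["Carbamidomethyl (C)"], variable=["Oxidation (M)"],
        )
        again = pd.read_csv(out2 / "psmC.txt", sep="\t")
        pd.testing.assert_frame_equal(psmC, again)

    def test_cache_does_not_change_results(self, e2e_run):
        """Warm-cache rerun writes byte-identical psmC."""
        _, _, _, _, (tmp, fasta, mgf) = e2e_run
        out3 = tmp / "out3"
        run_search(
            [fasta], [mgf], out3,
            fixed=["Carbamidomethyl (C)"], variable=["Oxidation (M)"],
            cache_dir=tmp / "cache",  # warm from the fixture run
        )
        assert (tmp / "out" / "psmC.txt").read_text() == (
            out3 / "psmC.txt"
        ).read_text()

    def test_manifest_counts(self, e2e_run):
        manifest, psmC, psmQ, _, _ = e2e_run
        assert manifest["counters"]["n_spectra"] == 50
        assert manifest["counters"]["n_rank1"] == (psmC["rank"] == 1).sum()
        assert manifest["counters"]["n_accepted"] == len(psmQ)


class TestWriters:
    def make_psmc(self):
        rows = []
        for i, (score, q, decoy) in enumerate(
            [(50, 0.0, False), (40, 0.0, False), (30, 0.5, False), (20, 0.0, True)]
        ):
            row = {c: "" for c in PSM_COLUMNS}
            row.update(
                title=f"t.{i}.{i}.2", peptide=f"PEPTIDE{i}K",
                sequence=f"PEPTIDE{i}K", proteins=f"P{i}", rank=1,
                score=score, q_value=q, is_decoy=decoy, is_entrapment=False,
                n_matched=8, set_index=0, precursor_error_ppm=0.1,
                file="t", scan=str(i), precursor_mz=500.0, charge=2,
                precursor_neutral_mass=998.0, best_p=1e-5, localization="",
            )
            rows.append(row)
        return pd.DataFrame(rows, columns=PSM_COLUMNS)

    def test_threshold_one_keeps_all_targets(self, tmp_path):
        psmC, psmQ = write_psm_tables(self.make_psmc(), tmp_path, threshold=1.0)
        assert len(psmQ) == 3  # all targets, decoy excluded

    def test_threshold_zero_keeps_only_q_zero(self, tmp_path):
        _, psmQ = write_psm_tables(self.make_psmc(), tmp_path, threshold=0.0)
        assert set(psmQ["q_value"]) == {0.0}
        assert not psmQ["is_decoy"].any()

    def test_unknown_config_key_lists_valid(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("precursor_tol = 20\nnot_a_key = 1\n")
        with pytest.raises(ValueError, match="valid keys"):
            SearchConfig.from_file(p)

    def test_config_round_trip(self, tmp_path):
        cfg = SearchConfig(precursor_tol=15.0, top_n=80)
        p = tmp_path / "cfg.txt"
        cfg.to_file(p)
        assert SearchConfig.from_file(p) == cfg


class TestTallySignature:
    def test_satellites_raise_boosted_over_raw_ratio(self, ox_setup):
        """Paired runs at satellite_fraction 0.5 vs 0 show a strictly higher
        mean boosted/raw intensity ratio for matched primaries."""
        from iontally.pipeline import build_search_space
        from iontally.proteolysis import make_decoys
        from iontally.search import search_spectrum
        from iontally.spectra import preprocess

        _, _, records, modsets, lookups = ox_setup
        cfg = SearchConfig()
        binned, _ = build_search_space(
            records + make_decoys(records), modsets, lookups, cfg
        )
        ratios = {}
        for frac in (0.5, 0.0):
            spectra, truths = synth_spectra(
                records, modsets, lookups, n_peptides=25,
                satellite_fraction=frac, seed=77,
            )
            vals = []
            for s in spectra:
                ranked = search_spectrum(preprocess(s), binned, lookups, cfg)
                if not ranked:
                    continue
                r = ranked[0]
                raw = sum(r.raw_intensity.values())
                boosted = sum(r.boosted_intensity.values())
                vals.append(boosted / raw)
            ratios[frac] = float(np.mean(vals))
        # chance satellite hits from noise keep the baseline near (not at) 1
        assert ratios[0.0] == pytest.approx(1.0, abs=0.01)
        assert ratios[0.5] > ratios[0.0]
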