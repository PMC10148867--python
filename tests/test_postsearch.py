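"""FDR with subclass transfer, localization, protein grouping, entrapment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from iontally.postsearch import (
    IncidenceMatrix,
    compute_fdr,
    entrapment_curve,
    entrapment_rate,
    exact_min_cover,
    fdr_curve,
    greedy_set_cover,
    group_proteins,
    localization_probability,
)


def psm_frame(scores, decoys, set_index=None):
    return pd.DataFrame(
        {
            "score": scores,
            "is_decoy": decoys,
            "set_index": set_index if set_index is not None else [0] * len(scores),
        }
    )


class TestFdr:
    def test_targets_only_all_zero(self):
        df = compute_fdr(psm_frame([10, 8, 7], [False] * 3))
        assert (df["q_value"] == 0.0).all()

    def test_hand_computed_running_ratio(self):
        """Scores T:10 D:9 T:8 T:7 D:6 -> FDR at score 7 is 1/3 before
        monotonization; q-values are the monotone running minimum."""
        scores = np.array([10.0, 9.0, 8.0, 7.0, 6.0])
        decoy = np.array([False, True, False, False, True])
        s, q = fdr_curve(scores, decoy)
        raw = [0 / 1, 1 / 1, 1 / 2, 1 / 3, 2 / 3]
        # raw FDR at score 7 (4th entry) is 1/3
        assert raw[3] == pytest.approx(1 / 3)
        # q at score 7: min FDR over thresholds at or below = 1/3
        assert dict(zip(s, q))[7.0] == pytest.approx(1 / 3)
        # q at score 9 monotonizes down to the 1/3 achieved later
        assert dict(zip(s, q))[9.0] == pytest.approx(1 / 3)

    def test_q_monotone_in_score(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 200
            scores = rng.normal(20, 5, n)
            decoy = rng.random(n) < 0.4
            df = compute_fdr(psm_frame(scores, decoy))
            srt = df.sort_values("score", ascending=False)
            assert (np.diff(srt["q_value"].to_numpy()) >= -1e-12).all()

    def test_subclass_transfer(self):
        """A small-subclass PSM scoring above the calibration subclass's
        1%-FDR cutoff inherits q <= 0.01."""
        big_scores = list(np.linspace(50, 30, 200)) + list(np.linspace(15, 5, 8))
        big_decoy = [False] * 200 + [True] * 8
        big_set = [0] * 208
        small = psm_frame([45.0, 4.0], [False, False], [1, 1])
        df = compute_fdr(
            pd.concat(
                [psm_frame(big_scores, big_decoy, big_set), small],
                ignore_index=True,
            )
        )
        hi = df[(df["set_index"] == 1) & (df["score"] == 45.0)]
        lo = df[(df["set_index"] == 1) & (df["score"] == 4.0)]
        assert float(hi["q_value"].iloc[0]) <= 0.01
        assert float(lo["q_value"].iloc[0]) > 0.01

    def test_zero_decoys_in_calibration_warns(self, caplog):
        df = compute_fdr(
            psm_frame([10, 9, 8, 1], [False, False, False, True],
                      [0, 0, 0, 1])
        )
        assert (df["q_value"] == 0.0).all()


class TestLocalization:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([2, 1], [2 / 3, 1 / 3]),
            ([1, 0], [1.0, 0.0]),
            ([2, 0], [1.0, 0.0]),
            ([3, 3], [0.5, 0.5]),
        ],
    )
    def test_counting_statistic(self, counts, expected):
        probs, flagged = localization_probability(counts)
        assert probs == pytest.approx(expected)
        assert not flagged

    def test_two_to_one_rounds_to_067(self):
        probs, _ = localization_probability([2, 1])
        assert round(probs[0], 2) == 0.67

    def test_one_zero_equals_two_zero(self):
        p10, _ = localization_probability([1, 0])
        p20, _ = localization_probability([2, 0])
        assert p10 == p20 == [1.0, 0.0]

    def test_all_zero_flags_uniform(self):
        probs, flagged = localization_probability([0, 0, 0])
        assert flagged
        assert probs == pytest.approx([1 / 3] * 3)

    def test_site_determining_ions_from_spectra(self, spec):
        """Phospho on S2 vs S4 of ASGSAK: planting two site-determining ions
        for the S2 isomer and one for S4 gives 2:1 -> 0.67."""
        from iontally.ions import SiteAssignment, primary_series
        from iontally.modifications import build_aa_lookup, compile_mod_sets
        from iontally.postsearch import localize_sites
        from iontally.proteolysis import PeptideCandidate
        from iontally.spectra import Spectrum

        ms = next(
            m for m in compile_mod_sets([], [spec("Phospho (S)")]) if m.variable
        )
        lk = build_aa_lookup(ms)
        cand = PeptideCandidate(sequence="ASGSAK", protein_refs=("t",))
        a2 = SiteAssignment(cand, (None, "Phospho", None, None, None, None))
        a4 = SiteAssignment(cand, (None, None, None, "Phospho", None, None))
        s2 = primary_series(a2, lk)
        s4 = primary_series(a4, lk)
        # b2 and b3 distinguish the isomers (contain S2 but not S4);
        # y3 distinguishes as well (contains S4 but not S2)
        mz = [float(s2["b"][1]), float(s2["b"][2]), float(s4["y"][2])]
        spectrum = Spectrum(
            source="t", scan="1", title="t", precursor_mz=400.0,
            precursor_charge=2, rt_seconds=0.0,
            mz=np.array(sorted(mz)), intensity=np.array([10.0, 10.0, 10.0]),
        )
        spectrum.retained_n = 3
        probs, flagged = localize_sites([a2, a4], {0: lk}, spectrum, tol=10.0)
        assert not flagged
        assert probs[0] == pytest.approx(2 / 3, abs=1e-9)


def incidence(mapping):
    return IncidenceMatrix.from_mapping(mapping)


class TestGrouping:
    def test_disjoint_proteins_form_singleton_groups(self):
        groups = group_proteins(
            incidence({"p1": ["A"], "p2": ["B"], "p3": ["C"]})
        )
        assert len(groups) == 3
        for g in groups:
            assert len(g.members) == 1 and g.essential == g.members

    def test_shared_peptide_merges_and_both_essential(self):
        groups = group_proteins(
            incidence({"pep1": ["P1"], "pep2": ["P1", "P2"], "pep3": ["P2"]})
        )
        assert len(groups) == 1
        [g] = groups
        assert g.members == ("P1", "P2")
        assert set(g.essential) == {"P1", "P2"}

    def test_subset_protein_not_essential(self):
        groups = group_proteins(
            incidence(
                {
                    "pep1": ["P1"],
                    "pep2": ["P1", "P2"],
                    "pep3": ["P1", "P3"],
                }
            )
        )
        [g] = groups
        assert set(g.members) == {"P1", "P2", "P3"}
        assert g.essential == ("P1",)

    def test_grouping_invariant_to_permutations(self):
        mapping = {
            "a": ["P1", "P2"], "b": ["P2"], "c": ["P3"],
            "d": ["P3", "P4"], "e": ["P5"],
        }
        base = group_proteins(incidence(mapping))
        rng = np.random.default_rng(10)
        items = list(mapping.items())
        for _ in range(5):
            rng.shuffle(items)
            shuffled = dict(items)
            got = group_proteins(incidence(shuffled))
            assert [g.members for g in got] == [g.members for g in base]
            assert [g.essential for g in got] == [g.essential for g in base]

    def test_unique_peptides_do_not_affect_topology(self):
        """Deleting all unique-peptide rows leaves group membership intact."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            n_prot = int(rng.integers(3, 8))
            prots = [f"P{i}" for i in range(n_prot)]
            mapping = {}
            for p in range(int(rng.integers(4, 15))):
                k = int(rng.integers(1, 3))
                mapping[f"pep{p}"] = list(
                    rng.choice(prots, size=k, replace=False)
                )
            # ensure every protein appears
            for i, prot in enumerate(prots):
                mapping[f"anchor{i}"] = [prot]
            full = group_proteins(incidence(mapping))
            shared_only = {
                pep: ps for pep, ps in mapping.items() if len(set(ps)) >= 2
            }
            # add back each protein as a bare column via a unique peptide is
            # not allowed here; instead compare topologies restricted to
            # proteins that appear in the shared-only mapping
            if not shared_only:
                continue
            reduced = group_proteins(incidence(shared_only))
            reduced_groups = {g.members for g in reduced}
            covered = {p for ps in shared_only.values() for p in ps}
            full_groups_restricted = {
                tuple(sorted(set(g.members) & covered))
                for g in full
                if set(g.members) & covered
            }
            assert {tuple(sorted(m)) for m in reduced_groups} == full_groups_restricted

    def test_greedy_cover_covers_everything_and_matches_exact_small(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n_prot = int(rng.integers(2, 10))
            n_pep = int(rng.integers(n_prot, 2 * n_prot + 2))
            sets = {}
            universe = set()
            for i in range(n_prot):
                members = frozenset(
                    int(x) for x in rng.choice(
                        n_pep, size=int(rng.integers(1, n_pep + 1)),
                        replace=False,
                    )
                )
                sets[f"P{i}"] = members
                universe |= members
            universe = frozenset(universe)
            greedy = greedy_set_cover(sets, universe)
            assert frozenset().union(*(sets[k] for k in greedy)) >= universe
            exact = exact_min_cover(sets, universe)
            # greedy is within the usual ln(n) factor; on these small random
            # instances we additionally log and check the ratio bound
            assert len(greedy) <= max(
                len(exact), int(np.ceil(len(exact) * np.log(max(len(universe), 2))))
            )


class TestEntrapment:
    def test_rate_arithmetic(self):
        df = pd.DataFrame({"is_entrapment": [False] * 98 + [True] * 2})
        rate, flagged = entrapment_rate(df)
        assert rate == pytest.approx(0.02) and not flagged

    def test_empty_acceptance_flags(self):
        rate, flagged = entrapment_rate(pd.DataFrame({"is_entrapment": []}))
        assert rate == 0.0 and flagged

    def test_curve_is_cumulative_along_decreasing_score(self):
        df = pd.DataFrame(
            {"score": [50, 40, 30, 20], "is_entrapment": [False, True, False, False]}
        )
        curve = entrapment_curve(df)
        assert list(curve["entrapment_rate"]) == pytest.approx(
            [0.0, 0.5, 1 / 3, 0.25]
        )
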