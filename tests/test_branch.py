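"""Branch extraction, BD scoring, classification, histograms, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enzatlas import branch as br
from enzatlas.simulate import SimConfig, generate
from enzatlas.types import BranchRecord

from conftest import make_cpc, make_network

LINES = ["c1", "c2"]
TISS = ["breast", "lung"]


class TestExtraction:
    def test_simple_fork(self):
        net = make_network({"r1": (["A"], ["B"]), "r2": (["A"], ["C"]),
                            "r3": (["B"], ["D"])})
        branches = br.extract_branch_points(net)
        assert len(branches) == 1
        assert branches[0].metabolite == "A"
        assert branches[0].reactions == ("r1", "r2")

    def test_linear_chain_has_no_branches(self):
        net = make_network({"r1": (["A"], ["B"]), "r2": (["B"], ["C"])})
        assert br.extract_branch_points(net) == []

    def test_exclusion_list_removes_currency_metabolites(self):
        net = make_network({"r1": (["A", "atp"], ["B"]),
                            "r2": (["C", "atp"], ["D"])})
        assert len(br.extract_branch_points(net)) == 1  # atp only
        assert br.extract_branch_points(net, exclude_metabolites={"atp"}) == []

    def test_reversible_product_side_counts_only_when_enabled(self):
        net = make_network(
            {"r1": (["A"], ["X"]), "r2": (["B"], ["X"]), "r3": (["X"], ["C"])},
            meta={"r1": (1, "", ""), "r2": (1, "", ""), "r3": (0, "", "")},
        )
        assert br.extract_branch_points(net) == []
        both = br.extract_branch_points(net, reversible_both_sides=True)
        assert [b.metabolite for b in both] == ["X"]

    def test_repeat_branches_collapse_and_unmeasured_drop(self):
        net = make_network(
            {"r1": (["A", "B"], ["C"]), "r2": (["A", "B"], ["D"]),
             "r3": (["E"], ["F"]), "r4": (["E"], ["G"])},
            meta={"r1": (0, "e1", "pw"), "r2": (0, "e2", "pw"),
                  "r3": (0, "e3", "pw"), "r4": (0, "", "pw")},  # r4 unmeasured
        )
        m = make_cpc({"e1": [1, 1], "e2": [2, 2], "e3": [3, 3]}, LINES, TISS)
        raw = br.extract_branch_points(net)
        assert len(raw) == 3  # A, B (repeats), E
        kept = br.dedupe_and_filter(raw, m, net)
        assert [b.metabolite for b in kept] == ["A"]  # B repeat, E unmeasured

    def test_matches_bruteforce_on_random_networks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_mets, n_rxns = 12, 10
            mets = [f"M{i}" for i in range(n_mets)]
            reactions, meta = {}, {}
            for r in range(n_rxns):
                reac = list(rng.choice(mets, size=rng.integers(1, 3), replace=False))
                prod = list(rng.choice([m for m in mets if m not in reac],
                                       size=rng.integers(1, 3), replace=False))
                reactions[f"r{r}"] = (reac, prod)
                meta[f"r{r}"] = (0, f"e{r}", "pw")
            net = make_network(reactions, meta)
            found = {b.metabolite: set(b.reactions)
                     for b in br.extract_branch_points(net)}
            oracle = {}
            for m in mets:
                consuming = {rid for rid, (reac, _p) in reactions.items() if m in reac}
                if len(consuming) >= 2:
                    oracle[m] = consuming
            assert found == oracle


class TestScores:
    @pytest.mark.parametrize("ranked, expected", [
        ((100, 100), 0.0),
        ((100, 25), 0.75),
        ((1000, 1), 0.999),
    ])
    def test_bd_top2(self, ranked, expected):
        assert br.bd_top2(ranked) == pytest.approx(expected)

    @pytest.mark.parametrize("ranked, expected", [
        ((7, 7, 7), -1.0),
        ((60, 30, 30), 0.0),
        ((100, 10, 5), 0.85),
    ])
    def test_bd_top3(self, ranked, expected):
        assert br.bd_top3(ranked) == pytest.approx(expected)

    def test_zero_top_concentration_is_undefined(self):
        with pytest.raises(br.UndefinedScoreError):
            br.bd_top2([0.0, 0.0])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        c=st.lists(st.floats(min_value=1e-6, max_value=1e9), min_size=3,
                   max_size=6),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_bounds_ordering_and_scale_invariance(self, c, scale):
        ranked = sorted(c, reverse=True)
        bd2, bd3 = br.bd_top2(ranked), br.bd_top3(ranked)
        assert 0.0 <= bd2 <= 1.0
        assert -1.0 <= bd3 <= 1.0
        assert bd3 <= bd2
        scaled = [scale * x for x in ranked]
        assert br.bd_top2(scaled) == pytest.approx(bd2, rel=1e-9)
        assert br.bd_top3(scaled) == pytest.approx(bd3, rel=1e-9)

    def test_strictly_decreasing_in_lower_ranks(self):
        assert br.bd_top2([100, 30]) > br.bd_top2([100, 40])
        assert br.bd_top3([100, 30, 10]) > br.bd_top3([100, 40, 10])
        assert br.bd_top3([100, 30, 10]) > br.bd_top3([100, 30, 20])


class TestClassification:
    @pytest.mark.parametrize("bd2, bd3, expected", [
        (0.85, None, "one_sided"),
        (0.5, -0.1, "equally_distributed"),   # the bd3 "or" clause
        (0.8, None, "unclassified"),          # strict boundary
        (0.2, 0.5, "unclassified"),
        (0.1, None, "equally_distributed"),
    ])
    def test_threshold_rules(self, bd2, bd3, expected):
        b = BranchRecord("m", ("r1", "r2"), bd2=bd2, bd3=bd3)
        assert br.classify_branch(b) == expected

    def test_planted_branches_recovered(self, small_dataset):
        from enzatlas import proteome as prot
        filtered, _ = prot.filter_rare_proteins(small_dataset.cpc)
        analysis = br.BranchAnalysis.run(small_dataset.network, filtered)
        by_met = {b.metabolite: b for b in analysis.branches}
        for mid, truth in small_dataset.manifest["branches"].items():
            assert by_met[mid].label == truth["expected_class"]
            assert by_met[mid].bd2 == pytest.approx(truth["target_bd2"], abs=0.02)


class TestHistogram:
    def test_top_edge_folds_into_last_bin(self):
        b = BranchRecord("m", ("r1", "r2"), bd2=1.0)
        h = br.bd_histogram([b], "top2")
        assert h["count"].iloc[-1] == 1
        assert h["count"].sum() == 1

    def test_lower_end_inclusive_placement(self):
        branches = [BranchRecord("m", ("r1", "r2"), bd2=s)
                    for s in (0.05, 0.15, 0.15)]
        h = br.bd_histogram(branches, "top2")
        assert h.loc[0, "count"] == 1    # [0.0, 0.1)
        assert h.loc[1, "count"] == 2    # [0.1, 0.2)

    def test_matches_counting_oracle_on_random_scores(self):
        rng = np.random.default_rng(5)
        scores2 = rng.uniform(0, 1, size=200)
        scores3 = rng.uniform(-1, 1, size=200)
        branches = [BranchRecord("m", ("a", "b"), bd2=s2, bd3=s3)
                    for s2, s3 in zip(scores2, scores3)]
        for which, scores, lo in (("top2", scores2, 0.0), ("top3", scores3, -1.0)):
            h = br.bd_histogram(branches, which)
            for i, row in h.iterrows():
                last = i == len(h) - 1
                sel = (scores >= row["bin_low"]) & (
                    (scores <= row["bin_high"]) if last else (scores < row["bin_high"]))
                assert row["count"] == sel.sum()


def _branch_with(metabolite, enzymes, cpcs, label):
    b = BranchRecord(metabolite, tuple(f"{metabolite}_r{i}" for i in range(len(enzymes))))
    b.ranked = [(f"{metabolite}_r{i}", (e,), c)
                for i, (e, c) in enumerate(zip(enzymes, cpcs))]
    b.bd2 = br.bd_top2(cpcs)
    b.bd3 = br.bd_top3(cpcs) if len(cpcs) >= 3 else None
    b.label = label
    return b


class TestEnrichment:
    def _net_for(self, enzyme_pathways):
        reactions, meta = {}, {}
        for i, (enz, pw) in enumerate(enzyme_pathways.items()):
            reactions[f"r{i}"] = ([f"x{i}"], [f"y{i}"])
            meta[f"r{i}"] = (0, enz, pw)
        return make_network(reactions, meta)

    def test_symmetric_table_gives_p_one(self):
        # each class contributes 2 enzymes, one of which is in pathway "pw"
        net = self._net_for({"a1": "pw", "a2": "other", "b1": "pw", "b2": "other"})
        one = [_branch_with("m1", ["a1", "a2"], [100, 50], "one_sided")]
        eq = [_branch_with("m2", ["b1", "b2"], [60, 55], "equally_distributed")]
        df = br.pathway_enrichment(one, eq, net)
        assert np.allclose(df["p_value"], 1.0)

    def test_ratio_arithmetic(self):
        net = self._net_for({f"a{i}": "pw" for i in range(6)}
                            | {f"b{i}": "pw" for i in range(2)}
                            | {"c": "other"})
        one = [_branch_with("m1", ["a0", "a1"], [9, 8], "one_sided"),
               _branch_with("m2", ["a2", "a3"], [9, 8], "one_sided"),
               _branch_with("m3", ["a4", "a5"], [9, 8], "one_sided")]
        eq = [_branch_with("m4", ["b0", "b1"], [5, 5], "equally_distributed")]
        df = br.pathway_enrichment(one, eq, net).set_index("pathway_id")
        assert df.loc["pw", "one_sided_count"] == 6
        assert df.loc["pw", "equal_count"] == 2
        assert df.loc["pw", "ratio"] == pytest.approx(3.0)

    def test_empty_class_rejected(self):
        net = self._net_for({"a1": "pw"})
        one = [_branch_with("m1", ["a1", "a1"], [9, 8], "one_sided")]
        with pytest.raises(ValueError):
            br.pathway_enrichment(one, [], net)

    def test_p_values_match_hypergeometric_enumeration(self):
        """Spot-check the exact test against full enumeration over all
        tables with the observed margins (the acceptance suite sweeps all
        n <= 30 tables)."""
        for table in ([[5, 1], [2, 8]], [[3, 3], [4, 1]], [[0, 5], [5, 0]]):
            _odds, p = stats.fisher_exact(table)
            assert p == pytest.approx(_enumerate_fisher(table), abs=1e-12)


def _enumerate_fisher(table):
    """Two-sided Fisher p by brute-force enumeration with fixed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))
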