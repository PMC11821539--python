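import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vlptools import (
    build_graph,
    compare_groups,
    corr_pvalue,
    fisher_z,
    graph_summary,
    group_average_regions,
    pearson_matrix,
)
from vlptools.quant import ActivityTable
from conftest import block_spec
from oracles import corr_p_brute, pearson_brute
from vlptools.simulate import simulate_activity


def make_table(data: dict, groups=None) -> ActivityTable:
    df = pd.DataFrame(data)
    df.index = [f"a{i}" for i in range(len(df))]
    g = pd.Series(groups or ["G"] * len(df), index=df.index)
    meta = {c: (c, "AREA") for c in df.columns}
    return ActivityTable(values=df, groups=g, region_meta=meta)


class TestPearsonMatrix:
    def test_perfect_linear_pairs(self):
        t = make_table({"x": [1, 2, 3, 4], "y": [2, 4, 6, 8],
                        "z": [4, 3, 2, 1]})
        c = pearson_matrix(t)
        assert c.r.loc["x", "y"] == pytest.approx(1.0)
        assert c.r.loc["x", "z"] == pytest.approx(-1.0)
        assert c.p.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 5)),
                          columns=[f"R{i}" for i in range(5)])
        df.iloc[0, 1] = np.nan  # force a pairwise-complete pair
        c = pearson_matrix(df)
        for i in df.columns:
            for j in df.columns:
                if i == j:
                    continue
                expect = pearson_brute(df[i].tolist(), df[j].tolist())
                assert c.r.loc[i, j] == pytest.approx(expect, abs=1e-12)
                n = int(c.n.loc[i, j])
                assert c.p.loc[i, j] == pytest.approx(
                    corr_p_brute(c.r.loc[i, j], n), abs=1e-10)

    def test_constant_region_gives_missing(self):
        t = make_table({"x": [1, 2, 3, 4], "y": [5.0, 5.0, 5.0, 5.0]})
        c = pearson_matrix(t)
        assert np.isnan(c.r.loc["x", "y"])

    def test_single_animal_rejected(self):
        t = make_table({"x": [1], "y": [2]})
        with pytest.raises(ValueError, match="2 animals"):
            pearson_matrix(t)

    def test_permutation_pvalues_agree_with_t_for_moderate_n(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        ct = pearson_matrix(df, method="t")
        cp = pearson_matrix(df, method="permutation", n_perm=4000, seed=5)
        for i in "abc":
            for j in "abc":
                if i >= j:
                    continue
                assert cp.p.loc[i, j] == pytest.approx(ct.p.loc[i, j], abs=0.05)


class TestCorrPvalue:
    def test_null_centre(self):
        assert corr_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_critical_r_at_n4(self):
        # r = 0.95 at n = 4 sits exactly on the two-sided 5% t boundary
        assert corr_pvalue(0.9500, 4) == pytest.approx(0.05, abs=1e-3)
        t_crit = stats.t.ppf(0.975, 2)
        r_crit = t_crit / math.sqrt(t_crit ** 2 + 2)
        assert r_crit == pytest.approx(0.9500, abs=5e-5)

    def test_degenerate_and_undefined(self):
        assert corr_pvalue(1.0, 4) == 0.0
        assert math.isnan(corr_pvalue(0.5, 2))

    def test_monotone_in_r_and_n(self):
        ps = [corr_pvalue(r, 10) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert ps == sorted(ps, reverse=True)
        pn = [corr_pvalue(0.5, n) for n in (5, 10, 20, 40)]
        assert pn == sorted(pn, reverse=True)


class TestFisherZ:
    def test_reference_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.85) == pytest.approx(1.25615, abs=1e-5)

    def test_odd_symmetry(self):
        for r in np.arange(0.1, 1.0, 0.1):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_clipping_keeps_z_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))


class TestBuildGraph:
    def corr(self, r, p):
        regions = ["A", "B"]
        rm = pd.DataFrame([[1.0, r], [r, 1.0]], index=regions, columns=regions)
        pm = pd.DataFrame([[np.nan, p], [p, np.nan]], index=regions,
                          columns=regions)
        nm = pd.DataFrame(4, index=regions, columns=regions)
        from vlptools.network import CorrelationResult
        return CorrelationResult("G", regions, rm, pm, nm,
                                 {r_: (r_, "AREA") for r_ in regions})

    @pytest.mark.parametrize("r,p,signed,expected", [
        (0.9, 0.01, True, 1),
        (0.9, 0.10, True, 0),
        (-0.9, 0.01, True, 0),
        (-0.9, 0.01, False, 1),
        (np.nan, 0.01, True, 0),
    ])
    def test_edge_rule(self, r, p, signed, expected):
        g = build_graph(self.corr(r, p), signed=signed)
        assert g.edge_count == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="p_cut"):
            build_graph(self.corr(0.9, 0.01), p_cut=1.5)

    def test_p_condition_dominates_at_n4(self):
        # at n = 4 animals, p < 0.05 needs r >= 0.95, stronger than r > 0.85
        table = simulate_activity(block_spec(groups=("WT",), n=4, k=8, seed=3))
        c = pearson_matrix(table, group="WT")
        strict = build_graph(c, r_cut=0.85, p_cut=0.05)
        loose = build_graph(c, r_cut=0.95, p_cut=1.0)
        assert set(strict.graph.edges()) <= set(loose.graph.edges())

    def test_edges_invariant_under_row_permutation(self, small_table, rng):
        c1 = pearson_matrix(small_table, group="WT")
        shuffled = ActivityTable(
            values=small_table.values.sample(frac=1, random_state=11),
            groups=small_table.groups, region_meta=small_table.region_meta)
        c2 = pearson_matrix(shuffled, group="WT")
        g1 = build_graph(c1, r_cut=0.3, p_cut=0.5)
        g2 = build_graph(c2, r_cut=0.3, p_cut=0.5)
        assert sorted(g1.graph.edges()) == sorted(g2.graph.edges())


class TestCompareGroups:
    def test_identical_matrices_are_null(self, small_table):
        c = pearson_matrix(small_table, group="WT")
        comp = compare_groups(c, c)
        assert comp.records["Z"].abs().max() == pytest.approx(0.0)
        assert comp.records["p_diff"].min() == pytest.approx(1.0)

    def test_reference_z_and_p(self):
        # r_A = 0.9 vs r_B = 0 with four animals each
        regions = ["A", "B"]
        def corr(r):
            rm = pd.DataFrame([[1.0, r], [r, 1.0]], regions, regions)
            pm = pd.DataFrame(0.5, regions, regions)
            nm = pd.DataFrame(4, regions, regions)
            from vlptools.network import CorrelationResult
            return CorrelationResult("G", regions, rm, pm, nm)
        comp = compare_groups(corr(0.9), corr(0.0))
        rec = comp.records.iloc[0]
        assert rec["Z"] == pytest.approx(math.atanh(0.9) / math.sqrt(2),
                                         abs=1e-4)
        assert rec["Z"] == pytest.approx(1.0410, abs=1e-4)
        assert rec["p_diff"] == pytest.approx(0.2979, abs=1e-4)

    def test_swapping_groups_negates_z(self, small_table):
        cA = pearson_matrix(small_table, group="WT")
        cB = pearson_matrix(small_table, group="cKO")
        ab = compare_groups(cA, cB).records
        ba = compare_groups(cB, cA).records
        assert np.allclose(ab["Z"], -ba["Z"], equal_nan=True)
        assert np.allclose(ab["p_diff"], ba["p_diff"], equal_nan=True)

    def test_small_n_marked_missing_with_diagnostic(self):
        regions = ["A", "B"]
        from vlptools.network import CorrelationResult
        rm = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], regions, regions)
        pm = pd.DataFrame(0.5, regions, regions)
        c3 = CorrelationResult("G", regions, rm, pm,
                               pd.DataFrame(3, regions, regions))
        c5 = CorrelationResult("H", regions, rm, pm,
                               pd.DataFrame(5, regions, regions))
        rec = compare_groups(c3, c5).records.iloc[0]
        assert math.isnan(rec["Z"])
        assert "n_A=3" in rec["note"]

    def test_bh_flag_adds_column_without_changing_significance(self, small_table):
        cA = pearson_matrix(small_table, group="WT")
        cB = pearson_matrix(small_table, group="cKO")
        plain = compare_groups(cA, cB)
        flagged = compare_groups(cA, cB, bh=True)
        assert "q_bh" in flagged.records.columns
        assert flagged.records["significant"].equals(plain.records["significant"])


class TestGroupAveraging:
    def test_mean_singleton_and_missing_members(self):
        t = make_table({"A1": [10.0, 1.0], "A2": [30.0, np.nan],
                        "B1": [7.0, 8.0]})
        t.values.loc["a1", "A2"] = np.nan
        out = group_average_regions(t, {"A1": "A", "A2": "A", "B1": "B"})
        assert out.values.loc["a0", "A"] == 20.0  # mean of 10 and 30
        assert out.values.loc["a1", "A"] == 1.0   # missing member excluded
        assert out.values["B"].tolist() == [7.0, 8.0]  # singleton: identity

    def test_three_member_mean_with_one_missing(self):
        t = make_table({"A1": [10.0], "A2": [np.nan], "A3": [20.0],
                        "Z": [1.0]})
        out = group_average_regions(t, {"A1": "A", "A2": "A", "A3": "A",
                                        "Z": "Z"})
        assert out.values.loc["a0", "A"] == 15.0

    def test_uncovered_region_rejected(self):
        t = make_table({"A1": [1.0, 2.0], "B1": [3.0, 4.0]})
        with pytest.raises(KeyError, match="B1"):
            group_average_regions(t, {"A1": "A"})


class TestGraphSummary:
    def test_empty_and_complete_graphs(self):
        import networkx as nx
        from vlptools.network import ThresholdedGraph
        empty = ThresholdedGraph(nx.Graph(), 0.85, 0.05, True)
        s = graph_summary(empty)
        assert s["edge_count"] == 0
        g = nx.complete_graph(5)
        nx.set_node_attributes(g, "X", "area")
        s = graph_summary(ThresholdedGraph(g, 0, 1, True))
        assert s["edge_count"] == 10
        assert set(s["degrees"]) == {4}
        assert int(s["degrees"].sum()) == 2 * s["edge_count"]

    def test_summary_matches_enumeration(self, small_table):
        c = pearson_matrix(small_table, group="WT")
        g = build_graph(c, r_cut=0.2, p_cut=0.9)
        s = graph_summary(g)
        edges = list(g.graph.edges())
        assert s["edge_count"] == len(edges)
        for node, deg in s["degrees"].items():
            assert deg == sum(1 for u, v in edges if node in (u, v))
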