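import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import betweenness_floyd_warshall, expected_jaccard_hypergeometric
from conftest import make_network
from taxonet import (
    CountTable,
    centralities,
    compare_cores,
    core_def1,
    core_def2,
    hubs,
    jaccard_test,
)


class TestCentralities:
    def test_star_center_dominates(self):
        net = make_network([("hub", leaf, 0.5) for leaf in "wxyz"])
        cent = centralities(net)
        assert cent.loc["hub", ["degree_mm", "betweenness_mm", "closeness_mm"]].tolist() == [1, 1, 1]
        leaves = cent.drop(index="hub")
        assert (leaves["degree_mm"] == 0).all()
        assert (leaves["betweenness_mm"] == 0).all()

    def test_cycle_constant_betweenness_scales_to_zero(self):
        net = make_network([("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5), ("d", "a", 0.5)])
        cent = centralities(net)
        assert (cent["betweenness_mm"] == 0).all()

    def test_betweenness_matches_floyd_warshall_recount(self):
        rng = np.random.default_rng(17)
        g = nx.gnp_random_graph(20, 0.25, seed=11)
        net = make_network([(u, v, rng.uniform(0.15, 0.95)) for u, v in g.edges], nodes=g.nodes)
        cent = centralities(net)
        oracle = betweenness_floyd_warshall(net.graph, "dissimilarity")
        for v in sorted(net.graph.nodes):
            assert cent.loc[v, "betweenness_raw"] == pytest.approx(oracle[v], abs=1e-8)

    def test_isolated_node_closeness_zero(self):
        net = make_network([("a", "b", 0.5)], nodes=["a", "b", "lonely"])
        cent = centralities(net)
        assert cent.loc["lonely", "closeness_raw"] == 0.0

    def test_minmax_invariant_to_normalizer(self):
        # dividing raw centralities by any constant cannot change the scaled values
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(15, 0.3, seed=5)
        net = make_network([(u, v, rng.uniform(0.2, 0.8)) for u, v in g.edges], nodes=g.nodes)
        cent = centralities(net)
        raw = cent["betweenness_raw"]
        conventional = raw / ((len(raw) - 1) * (len(raw) - 2) / 2)
        rescaled = (conventional - conventional.min()) / (conventional.max() - conventional.min())
        assert np.allclose(cent["betweenness_mm"], rescaled)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            centralities(make_network([], nodes=["a"]))


class TestHubs:
    def _table(self, values):
        df = pd.DataFrame(values, columns=["degree_mm", "betweenness_mm", "closeness_mm"],
                          index=[f"g{i}" for i in range(len(values))])
        df["summed_mm"] = df.sum(axis=1)
        return df

    def test_dominant_node_is_unique_hub(self):
        values = [[1.0, 1.0, 1.0]] + [[x, x, x] for x in np.linspace(0, 0.5, 9)]
        hs = hubs(self._table(values), 0.90)
        assert hs.genera == frozenset({"g0"})

    def test_quantile_zero_excludes_minima(self):
        values = [[0.0, 0.0, 0.0], [0.5, 0.5, 0.5], [1.0, 1.0, 1.0]]
        table = self._table(values)
        hs = hubs(table, 0.0)
        oracle = {
            g for g in table.index
            if all(table.loc[g, c] > table[c].min()
                   for c in ["degree_mm", "betweenness_mm", "closeness_mm"])
        }
        assert hs.genera == frozenset(oracle)

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(23)
        table = self._table(rng.uniform(size=(40, 3)))
        prev = None
        for q in (0.5, 0.55, 0.575, 0.9, 0.95):
            hs = hubs(table, q)
            if prev is not None:
                assert hs.genera <= prev
            prev = hs.genera


class TestJaccardTest:
    def test_identical_sets(self):
        universe = [f"g{i}" for i in range(30)]
        res = jaccard_test(universe[:6], universe[:6], universe, seed=1)
        assert res.jaccard == 1.0
        assert res.p_greater < 0.05

    def test_disjoint_cover(self):
        universe = list("abcd")
        res = jaccard_test({"a", "b"}, {"c", "d"}, universe, seed=1)
        assert res.jaccard == 0.0

    def test_null_mean_matches_hypergeometric(self):
        universe = [f"g{i}" for i in range(20)]
        res = jaccard_test(universe[:5], universe[-5:], universe,
                           n_permutations=20000, seed=7)
        closed_form = expected_jaccard_hypergeometric(20, 5, 5)
        assert res.expected == pytest.approx(closed_form, abs=0.005)

    def test_empty_sets_degenerate(self):
        res = jaccard_test(set(), set(), list("abc"), seed=0)
        assert res.degenerate and res.jaccard == 0.0


class TestCores:
    def _counts(self, arr):
        return CountTable(pd.DataFrame(
            np.asarray(arr), index=[f"g{i}" for i in range(len(arr))],
            columns=[f"s{j}" for j in range(np.asarray(arr).shape[1])],
        ))

    def test_always_abundant_genus_is_core(self):
        t = self._counts([[20, 20, 20], [9980, 9980, 9980]])
        core = core_def1(t, detection=0.001, prevalence=0.5)
        assert "g0" in core.genera

    def test_prevalence_boundary(self):
        arr = np.zeros((2, 100), dtype=int)
        arr[0, :49] = 20          # 49% of samples above detection
        arr[1] = 10_000
        core = core_def1(self._counts(arr), detection=0.001, prevalence=0.5)
        assert "g0" not in core.genera

    def test_matches_brute_force(self):
        rng = np.random.default_rng(19)
        arr = rng.poisson(rng.gamma(0.5, 40, size=(5, 1)), size=(5, 30))
        arr[:, arr.sum(axis=0) == 0] += 1
        t = self._counts(arr)
        core = core_def1(t, detection=0.002, prevalence=0.4)
        rel = arr / arr.sum(axis=0)
        oracle = {
            f"g{i}"
            for i in range(5)
            if np.mean([rel[i, j] > 0.002 for j in range(30)]) >= 0.4
        }
        assert core.genera == oracle

    def _cent_table(self, n, rng):
        vals = np.sort(rng.uniform(size=n))[::-1]
        df = pd.DataFrame(
            {"degree_mm": vals, "betweenness_mm": vals, "closeness_mm": vals},
            index=[f"g{i}" for i in range(n)],
        )
        df["summed_mm"] = df.sum(axis=1)
        return df

    def test_def2_consistency_with_hub_set(self):
        rng = np.random.default_rng(29)
        table = self._cent_table(40, rng)
        base = hubs(table, 0.90)
        core = core_def2(table, target_count=len(base.genera))
        assert len(core.genera) == len(base.genera)
        assert core.params["quantile"] >= 0.90 - 1e-9

    def test_def2_totally_ordered_returns_top_k(self):
        rng = np.random.default_rng(31)
        table = self._cent_table(50, rng)
        core = core_def2(table, target_count=12)
        top12 = set(table.sort_values("summed_mm", ascending=False).index[:12])
        assert core.genera == top12

    def test_def2_unattainable_target_warns(self):
        rng = np.random.default_rng(2)
        table = self._cent_table(5, rng)
        core = core_def2(table, target_count=10)
        assert core.warning is not None

    def test_compare_cores_matches_naive_loops(self):
        rng = np.random.default_rng(41)
        arr = rng.poisson(5, size=(6, 12))
        arr[:, arr.sum(axis=0) == 0] += 1
        t = self._counts(arr)
        table = self._cent_table(6, rng)
        core = core_def1(t, detection=0.01, prevalence=0.2)
        got = compare_cores(core, t, table)
        members = sorted(core.genera)
        rows = [int(g[1:]) for g in members]
        prev = np.mean([
            100 * np.mean([arr[i, j] > 0 for i in rows]) for j in range(12)
        ])
        cum = np.mean([sum(arr[i, j] for i in rows) for j in range(12)])
        cent = np.mean([table.loc[g, "summed_mm"] for g in members])
        assert got.average_prevalence_pct == pytest.approx(prev)
        assert got.cumulative_abundance == pytest.approx(cum)
        assert got.mean_summed_centrality == pytest.approx(cent)

    def test_empty_core_rejected(self):
        t = self._counts([[5, 5], [5, 5]])
        rng = np.random.default_rng(0)
        from taxonet.centrality import CoreSet

        with pytest.raises(ValueError):
            compare_cores(CoreSet("x", frozenset()), t, self._cent_table(2, rng))
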