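import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from _oracles import orbit_counts_exhaustive
from conftest import make_network
from taxonet.graphlets import (
    GCM,
    NONREDUNDANT_ORBITS,
    OrbitCountMatrix,
    count_orbits,
    gcm,
    gcm_difference,
    map_genera,
    orbit_taxonomy,
    select_orbits,
)


class TestCountOrbits:
    def test_triangle(self):
        net = make_network([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)])
        counts = count_orbits(net).counts
        for v in "abc":
            row = counts.loc[v]
            assert row["o0"] == 2 and row["o3"] == 1
            assert row.drop(["o0", "o3"]).sum() == 0

    def test_path_p4_end_node(self):
        net = make_network([("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5)])
        row = count_orbits(net).counts.loc["a"]
        assert row["o0"] == 1 and row["o1"] == 1 and row["o4"] == 1
        assert row.drop(["o0", "o1", "o4"]).sum() == 0

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 16))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.7)), seed=int(rng.integers(10**6)))
        got = count_orbits(g).counts.to_numpy()
        assert np.array_equal(got, orbit_counts_exhaustive(g))

    def test_orbit0_is_degree_and_sums_to_2m(self):
        g = nx.gnp_random_graph(25, 0.2, seed=9)
        counts = count_orbits(g).counts
        degrees = [g.degree(v) for v in sorted(g.nodes)]
        assert counts["o0"].tolist() == degrees
        assert counts["o0"].sum() == 2 * g.number_of_edges()

    def test_reduced_view_has_eleven_columns(self):
        g = nx.path_graph(5)
        reduced = count_orbits(g).reduced
        assert list(reduced.columns) == [f"o{i}" for i in NONREDUNDANT_ORBITS]


class TestGCM:
    def test_identical_columns_correlate_fully(self):
        counts = pd.DataFrame(0, index=list("abcde"), columns=[f"o{i}" for i in range(15)])
        counts["o0"] = [1, 2, 3, 4, 5]
        counts["o1"] = [1, 2, 3, 4, 5]
        g = gcm(OrbitCountMatrix(counts))
        assert g.spearman.loc["o0", "o1"] == pytest.approx(1.0)
        assert g.n_rows == 6

    def test_rank_invariance_under_monotone_transform(self):
        counts = pd.DataFrame(0, index=list("abcdef"), columns=[f"o{i}" for i in range(15)])
        base = np.array([1, 3, 7, 2, 9, 5])
        counts["o0"] = base
        counts["o2"] = base**3          # strictly increasing transform
        g = gcm(OrbitCountMatrix(counts))
        assert g.spearman.loc["o0", "o2"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(77)
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(12, 15)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"o{i}" for i in range(15)],
        )
        mat = OrbitCountMatrix(counts)
        g = gcm(mat)
        data = np.vstack([mat.reduced.to_numpy(), np.ones(11)])
        ranks = np.column_stack([rankdata(data[:, k]) for k in range(11)])
        oracle = np.corrcoef(ranks, rowvar=False)
        assert np.allclose(g.spearman.to_numpy(), oracle, atol=1e-12)

    def test_relabeling_invariance(self):
        g1 = nx.gnp_random_graph(14, 0.3, seed=2)
        mapping = {v: f"z{(v * 3) % 14:02d}" for v in g1.nodes}
        g2 = nx.relabel_nodes(g1, mapping)
        m1 = gcm(count_orbits(g1)).spearman.to_numpy()
        m2 = gcm(count_orbits(g2)).spearman.to_numpy()
        assert np.allclose(m1, m2, equal_nan=True)

    def test_edgeless_graph_defined_via_pseudo_row(self):
        g = nx.empty_graph(5)
        m = gcm(count_orbits(g))
        # all columns identical (zeros plus the pseudo one) -> correlation 1
        assert m.spearman.loc["o0", "o1"] == pytest.approx(1.0)


class TestGCMDifference:
    def _gcm(self, fill, n_rows=88):
        labels = [f"o{i}" for i in NONREDUNDANT_ORBITS]
        mat = pd.DataFrame(fill, index=labels, columns=labels, dtype=float)
        np.fill_diagonal(mat.values, 1.0)
        return GCM(spearman=mat, n_rows=n_rows)

    def test_equal_gcms_give_null_result(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(-0.5, 0.5, size=(11, 11))
        vals = (vals + vals.T) / 2
        g = self._gcm(vals)
        diff = gcm_difference(g, g)
        assert np.allclose(diff.table["z"], 0.0)
        assert np.allclose(diff.table["p"], 1.0)
        assert not diff.table["significant"].any()

    def test_hand_value(self):
        g1 = self._gcm(np.full((11, 11), 0.9))
        g2 = self._gcm(np.full((11, 11), 0.2))
        diff = gcm_difference(g1, g2)
        # oracle: (atanh .9 - atanh .2) / sqrt(2/85)
        assert diff.table["z"].iloc[0] == pytest.approx(8.276, abs=0.01)
        assert diff.table["p"].iloc[0] < 1e-10

    def test_swap_negates_z_preserves_p(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(-0.8, 0.8, size=(11, 11))
        b = rng.uniform(-0.8, 0.8, size=(11, 11))
        g1, g2 = self._gcm((a + a.T) / 2), self._gcm((b + b.T) / 2)
        d12 = gcm_difference(g1, g2).table
        d21 = gcm_difference(g2, g1).table
        assert np.allclose(d12["z"], -d21["z"])
        assert np.allclose(d12["p"], d21["p"])

    def test_perfect_correlation_flagged(self):
        g1 = self._gcm(np.full((11, 11), 1.0))
        g2 = self._gcm(np.full((11, 11), 0.3))
        diff = gcm_difference(g1, g2)
        assert diff.table["degenerate"].all()
        assert (diff.table["p"] == 0.0).all()


class TestOrbitSelection:
    def _diff_with_significant(self, sig_pairs):
        rows = []
        labels = [f"o{i}" for i in NONREDUNDANT_ORBITS]
        from itertools import combinations

        for a, b in combinations(labels, 2):
            rows.append({
                "orbit_a": a, "orbit_b": b, "r1": 0.0, "r2": 0.0, "abs_diff": 0.0,
                "z": 0.0, "p": 1.0, "degenerate": False,
                "significant": (a, b) in sig_pairs,
            })
        from taxonet.graphlets import GCMDifference

        return GCMDifference(table=pd.DataFrame(rows), alpha=0.05)

    def test_no_significant_entries_empty(self):
        assert select_orbits(self._diff_with_significant(set())) == []

    def test_single_entry_selects_both_orbits(self):
        assert select_orbits(self._diff_with_significant({("o1", "o4")})) == [1, 4]

    def test_terminal_orbit_pattern(self):
        sig = {("o1", "o4"), ("o1", "o6"), ("o1", "o9"), ("o4", "o6"), ("o4", "o9"), ("o6", "o9")}
        assert select_orbits(self._diff_with_significant(sig)) == [1, 4, 6, 9]


class TestMapGenera:
    def _matrix(self, n, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(n, 15)),
            index=[f"g{i:02d}" for i in range(n)],
            columns=[f"o{i}" for i in range(15)],
        )
        return OrbitCountMatrix(counts)

    def test_single_orbit_full_topk_all_focal(self):
        mat = self._matrix(8, 1)
        report = map_genera(mat, [1], top_k=8)
        assert report.focal.all()

    def test_top_ranked_everywhere_is_focal_with_mean_occurrence(self):
        mat = self._matrix(10, 2)
        mat.counts.loc["g00", ["o1", "o4"]] = 1000
        report = map_genera(mat, [1, 4], top_k=3)
        assert report.focal["g00"]
        assert report.occurrence["g00"] == pytest.approx(
            mat.counts.loc["g00", ["o1", "o4"]].mean()
        )

    def test_focal_matches_brute_force_intersection(self):
        mat = self._matrix(30, 3)
        report = map_genera(mat, [1, 4], top_k=5)
        tops = []
        for col in ("o1", "o4"):
            ranked = sorted(mat.counts.index, key=lambda g: (-mat.counts.loc[g, col], g))
            tops.append(set(ranked[:5]))
        assert set(report.focal.index[report.focal]) == tops[0] & tops[1]

    def test_topk_clamped(self):
        report = map_genera(self._matrix(4, 4), [1], top_k=25)
        assert report.top_k == 4 and report.warning is not None


def test_orbit_taxonomy_counts():
    tax = orbit_taxonomy()
    assert tax["n_graphlets"] == 9
    assert tax["n_orbits"] == 15
    assert tax["n_nonredundant_orbits"] == 11


def test_redundancy_identities_on_random_graphs():
    # o3 = C(o0,2) - o2 and C(o0,3) = o7 + o11 + o13 + o14 and
    # o3*(o0-2) = o11 + 2*o13 + 3*o14 witness the dependent orbits
    from math import comb

    for seed in range(5):
        g = nx.gnp_random_graph(12, 0.4, seed=seed)
        c = count_orbits(g).counts
        for v in c.index:
            o = c.loc[v]
            assert o["o3"] == comb(int(o["o0"]), 2) - o["o2"]
            assert comb(int(o["o0"]), 3) == o["o7"] + o["o11"] + o["o13"] + o["o14"]
            assert o["o3"] * max(int(o["o0"]) - 2, 0) == o["o11"] + 2 * o["o13"] + 3 * o["o14"]
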