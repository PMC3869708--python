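import numpy as np
import pytest

from pridenet.metrics import (
    betweenness,
    density,
    find_cliques,
    network_report,
    node_degrees,
    random_network,
    strong_transitivity,
)
from pridenet.matrices import LabeledMatrix

from conftest import random_digraph
from oracles import brute_betweenness, brute_cliques, brute_density, brute_transitivity

IDS8 = [f"N{k}" for k in range(8)]


def complete(n, w=1.0):
    v = np.full((n, n), w)
    np.fill_diagonal(v, 0.0)
    return v


class TestDensity:
    def test_complete_undirected_is_one(self):
        assert density(complete(12), directed=False) == 1.0

    def test_empty_is_zero(self):
        assert density(np.zeros((5, 5)), directed=True) == 0.0

    def test_directed_count(self):
        v = np.zeros((4, 4))
        slots = [(0, 1), (0, 2), (1, 0), (1, 3), (2, 3), (3, 0), (3, 2)]
        for i, j in slots:
            v[i, j] = 2.0
        assert density(v, directed=True) == pytest.approx(7 / 12)

    def test_single_node_undefined(self):
        with pytest.raises(ValueError):
            density(np.zeros((1, 1)), directed=False)

    def test_monotone_in_edge_additions(self, rng):
        v = np.zeros((6, 6))
        prev = 0.0
        for _ in range(10):
            i, j = rng.choice(6, 2, replace=False)
            v[i, j] = 1.0
            d = density(v, directed=True)
            assert d >= prev
            prev = d

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("directed", [True, False])
    def test_matches_count_oracle(self, seed, directed):
        rng = np.random.default_rng(seed)
        v = random_digraph(rng, 7, density=0.4)
        if not directed:
            v = np.maximum(v, v.T)
        assert density(v, directed) == pytest.approx(brute_density(v, directed))


class TestStrongTransitivity:
    def test_complete_equal_weights_min_rule_is_100(self):
        assert strong_transitivity(complete(5, 2.0), rule="min") == 100.0

    def test_transitive_tournament_any_rule_is_100(self):
        v = np.triu(np.ones((4, 4)), 1)  # i -> j iff i < j
        assert strong_transitivity(v, rule="any") == 100.0

    @pytest.mark.parametrize("rule", ["min", "max", "any"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_triple_enumeration(self, rule, seed):
        rng = np.random.default_rng(100 + seed)
        v = random_digraph(rng, 6, density=0.5)
        assert strong_transitivity(v, rule) == pytest.approx(brute_transitivity(v, rule))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            strong_transitivity(complete(2), rule="min")

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown transitivity rule"):
            strong_transitivity(complete(4), rule="median")


class TestDegrees:
    def test_single_edge(self):
        v = np.zeros((3, 3))
        v[0, 1] = 5.0
        df = node_degrees(v, ["A", "B", "C"], directed=True)
        assert df.loc["A", "outdegree"] == 5 and df.loc["B", "indegree"] == 5
        assert df.loc["C", "indegree"] == 0 and df.loc["C", "outdegree"] == 0

    def test_equal_complete_digraph_normalizes_to_100(self):
        df = node_degrees(complete(5, 3.0), [*"ABCDE"], directed=True)
        assert np.allclose(df["indegree_norm"], 100.0)
        assert np.allclose(df["outdegree_norm"], 100.0)

    def test_in_out_totals_conserved(self, rng):
        v = random_digraph(rng, 7, density=0.6)
        df = node_degrees(v, [f"N{k}" for k in range(7)], directed=True)
        assert df["indegree"].sum() == pytest.approx(df["outdegree"].sum())
        assert df["indegree"].sum() == pytest.approx(v.sum())

    def test_all_zero_matrix_normalizes_to_zero(self):
        df = node_degrees(np.zeros((4, 4)), [*"ABCD"], directed=True)
        assert (df["indegree_norm"] == 0).all()


class TestBetweenness:
    def test_complete_graph_all_zero(self):
        df = betweenness(complete(12), [f"L{k}" for k in range(12)], directed=False)
        assert (df["betweenness"] == 0).all()

    def test_star_center(self):
        v = np.zeros((6, 6))
        v[0, 1:] = 1.0
        v[1:, 0] = 1.0
        df = betweenness(v, [*"CABDE F"][:6], directed=False)
        assert df["betweenness"].iloc[0] == pytest.approx(10.0)  # (n-1)(n-2)/2
        assert df["betweenness_norm"].iloc[0] == pytest.approx(100.0)
        assert (df["betweenness"].iloc[1:] == 0).all()

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("directed", [True, False])
    def test_matches_path_enumeration_oracle(self, seed, directed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(4, 9))
        v = random_digraph(rng, n, density=float(rng.uniform(0.2, 0.7)))
        got = betweenness(v, [f"N{k}" for k in range(n)], directed=directed)["betweenness"]
        np.testing.assert_allclose(got.to_numpy(), brute_betweenness(v, directed), atol=1e-9)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_cross_check_against_networkx(self, rng, weighted):
        nx = pytest.importorskip("networkx")
        v = random_digraph(rng, 9, density=0.45)
        g = nx.DiGraph()
        g.add_nodes_from(range(9))
        for i, j in zip(*np.nonzero(v)):
            g.add_edge(int(i), int(j), length=1.0 / v[i, j])
        expected = nx.betweenness_centrality(
            g, normalized=False, weight="length" if weighted else None
        )
        got = betweenness(v, [f"N{k}" for k in range(9)], directed=True, weighted=weighted)
        np.testing.assert_allclose(
            got["betweenness"].to_numpy(), [expected[k] for k in range(9)], atol=1e-9
        )

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            betweenness(np.zeros((2, 2)), ["A", "B"])


class TestCliques:
    def test_complete_graph_is_one_clique(self):
        assert find_cliques(complete(5), [*"ABCDE"]) == [("A", "B", "C", "D", "E")]

    def test_two_triangles_sharing_a_vertex(self):
        v = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (2, 4)]:
            v[i, j] = v[j, i] = 1.0
        assert find_cliques(v, [*"ABCDE"]) == [("A", "B", "C"), ("C", "D", "E")]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_power_set_enumeration(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(4, 11))
        v = random_digraph(rng, n, density=0.5, weighted=False)
        ids = [f"N{k}" for k in range(n)]
        got = {frozenset(ids.index(a) for a in c) for c in find_cliques(v, ids)}
        assert got == brute_cliques(v, min_size=3)

    def test_no_clique_is_subset_of_another(self, rng):
        v = random_digraph(rng, 9, density=0.6, weighted=False)
        cliques = [set(c) for c in find_cliques(v, [f"N{k}" for k in range(9)])]
        for a in cliques:
            for b in cliques:
                assert a == b or not a < b

    def test_intersection_symmetrization_is_stricter(self, rng):
        v = random_digraph(rng, 8, density=0.5, weighted=False)
        ids = [f"N{k}" for k in range(8)]
        union = find_cliques(v, ids, symmetrization="union")
        inter = find_cliques(v, ids, symmetrization="intersection")
        union_edges = {(a, b) for c in union for a in c for b in c if a < b}
        for c in inter:
            for a in c:
                for b in c:
                    if a < b:
                        assert (a, b) in union_edges

    def test_deterministic_lexicographic_order(self, rng):
        v = random_digraph(rng, 8, density=0.6, weighted=False)
        ids = [f"N{k}" for k in range(8)]
        out = find_cliques(v, ids)
        assert out == sorted(out)


class TestRandomNetwork:
    def test_density_extremes(self):
        full = random_network(6, 1.0, directed=True, seed=0)
        empty = random_network(6, 0.0, directed=True, seed=0)
        assert density(full.values, True) == 1.0
        assert density(empty.values, True) == 0.0

    @pytest.mark.parametrize("directed", [True, False])
    def test_exact_edge_count_per_draw(self, directed):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = random_network(10, 0.5, directed=directed, seed=rng)
            assert density(m.values, directed) == pytest.approx(0.5, abs=0.02)

    def test_reproducible_under_seed(self):
        a = random_network(8, 0.4, directed=True, seed=42)
        b = random_network(8, 0.4, directed=True, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            random_network(5, 1.5, directed=True, seed=0)


class TestRelabeling:
    def test_normalized_metrics_invariant_to_relabeling(self, rng):
        n = 7
        v = random_digraph(rng, n, density=0.5)
        ids = [f"N{k}" for k in range(n)]
        perm = rng.permutation(n)
        vp = v[np.ix_(perm, perm)]
        ids_p = [ids[k] for k in perm]
        a = network_report(LabeledMatrix(ids=ids, values=v, name="x"), directed=True)
        b = network_report(LabeledMatrix(ids=tuple(ids_p), values=vp, name="x"), directed=True)
        assert a.density == pytest.approx(b.density)
        assert a.strong_transitivity == pytest.approx(b.strong_transitivity)
        for col in ("indegree_norm", "outdegree_norm", "betweenness_norm"):
            for i in ids:
                assert a.node_metrics.loc[i, col] == pytest.approx(b.node_metrics.loc[i, col])
        assert {tuple(c) for c in a.cliques} == {tuple(c) for c in b.cliques}


def test_network_report_meta_documents_normalization(rng):
    v = random_digraph(rng, 6, density=0.5)
    rep = network_report(LabeledMatrix(ids=tuple("ABCDEF"), values=v, name="toy"), directed=True)
    assert "degree_normalization" in rep.meta
    assert rep.meta["n"] == 6
    d = rep.to_dict()
    assert d["network_name"] == "toy"
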