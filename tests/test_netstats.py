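import numpy as np
import pytest

from cflow.graph_core import GraphDomainError, WeightedGraph
from cflow.netstats import (
    Partition,
    best_partition,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    edge_betweenness,
    eigenvector_centrality,
    modularity,
    node_strength,
    shortest_path_lengths,
    summarize,
)
from conftest import random_graph
from oracles import (
    betweenness_oracle,
    clustering_oracle,
    distances_oracle,
    edge_betweenness_oracle,
    modularity_oracle,
    path_length_oracle,
)


def complete_graph(n):
    w = np.ones((n, n)) - np.eye(n)
    return WeightedGraph(w)


def chain(weights):
    n = len(weights) + 1
    w = np.zeros((n, n))
    for i, wt in enumerate(weights):
        w[i, i + 1] = w[i + 1, i] = wt
    return WeightedGraph(w)


def two_triangles():
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[a, b] = w[b, a] = 1.0
    return WeightedGraph(w)


class TestStrengthAndDistances:
    def test_strength_sums_incident_weights(self):
        g = chain([0.2, 0.3])
        np.testing.assert_allclose(node_strength(g), [0.2, 0.5, 0.3])

    def test_isolated_node_strength_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        assert node_strength(WeightedGraph(w))[2] == 0.0

    def test_unit_triangle_strengths(self, triangle):
        np.testing.assert_allclose(node_strength(triangle), [2, 2, 2])

    def test_chain_distance_is_sum_of_inverse_weights(self):
        g = chain([0.5, 0.25])
        d = shortest_path_lengths(g)
        assert d[0, 2] == pytest.approx(2 + 4)

    def test_ring_of_four_opposite_distance(self):
        w = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[a, b] = w[b, a] = 1.0
        d = shortest_path_lengths(WeightedGraph(w))
        assert d[0, 2] == 2.0

    def test_disconnected_pair_is_infinite(self):
        d = shortest_path_lengths(WeightedGraph(np.zeros((2, 2))))
        assert np.isinf(d[0, 1])


class TestPathLength:
    def test_unit_path_of_three(self):
        assert characteristic_path_length(chain([1.0, 1.0])) == pytest.approx(4 / 3)

    def test_complete_graph_L_is_one(self):
        for n in (3, 5, 8):
            assert characteristic_path_length(complete_graph(n)) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        w = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (2, 3), (0, 3), (0, 2)]:
            w[a, b] = w[b, a] = 1.0
        g = WeightedGraph(w)
        assert characteristic_path_length(g) == pytest.approx(path_length_oracle(w))

    def test_edgeless_graph_undefined(self):
        with pytest.raises(GraphDomainError):
            characteristic_path_length(WeightedGraph(np.zeros((5, 5))))

    def test_finite_fraction_reported(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        L, frac = characteristic_path_length(
            WeightedGraph(w), return_finite_fraction=True
        )
        assert L == 1.0 and frac == pytest.approx(2 / 6)


class TestClustering:
    def test_unit_triangle_fully_clustered(self, triangle):
        ci, c = clustering_coefficient(triangle)
        np.testing.assert_allclose(ci, 1.0)
        assert c == 1.0

    def test_star_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert clustering_coefficient(WeightedGraph(w))[1] == 0.0

    def test_half_weight_triangle(self):
        g = WeightedGraph(np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]))
        ci, c = clustering_coefficient(g)
        np.testing.assert_allclose(ci, 0.5)
        assert c == pytest.approx(0.5)


class TestBetweenness:
    def test_path_middle_node_carries_everything(self):
        bc = betweenness(chain([1.0, 1.0]))
        np.testing.assert_allclose(bc, [0.0, 1.0, 0.0])

    def test_complete_graph_all_zero(self):
        np.testing.assert_allclose(betweenness(complete_graph(5)), 0.0)

    def test_too_small_graph_rejected(self):
        with pytest.raises(GraphDomainError):
            betweenness(WeightedGraph(np.zeros((2, 2))))

    def test_single_edge_ebc_is_one(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.7
        assert edge_betweenness(WeightedGraph(w))[(0, 1)] == pytest.approx(1.0)

    def test_bridge_between_triangles_is_max_ebc(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
            w[a, b] = w[b, a] = 1.0
        ebc = edge_betweenness(WeightedGraph(w))
        assert max(ebc, key=ebc.get) == (2, 3)


class TestOracleParity:
    """BC, EBC, distances, C agree with exhaustive enumeration on small graphs."""

    @pytest.mark.parametrize("weighted", [True, False])
    def test_random_small_graphs(self, rng, weighted):
        for _ in range(25):
            n = int(rng.integers(4, 8))
            g = random_graph(rng, n, 0.5, weighted=weighted)
            w = g.weights
            np.testing.assert_allclose(
                shortest_path_lengths(g), distances_oracle(w), rtol=1e-8
            )
            np.testing.assert_allclose(
                betweenness(g), betweenness_oracle(w), atol=1e-8
            )
            ebc, ebc_o = edge_betweenness(g), edge_betweenness_oracle(w)
            assert set(ebc) == set(ebc_o)
            for e in ebc:
                assert ebc[e] == pytest.approx(ebc_o[e], abs=1e-8)
            np.testing.assert_allclose(
                clustering_coefficient(g)[0], clustering_oracle(w)[0], atol=1e-8
            )


class TestScaleAndMonotonicity:
    def test_uniform_weight_scaling_scales_distances_keeps_bc_order(self, rng):
        g = random_graph(rng, 7, 0.5)
        alpha = 0.37
        scaled = WeightedGraph(g.weights * alpha)
        d, ds = shortest_path_lengths(g), shortest_path_lengths(scaled)
        finite = np.isfinite(d)
        np.testing.assert_allclose(ds[finite], d[finite] / alpha, rtol=1e-9)
        np.testing.assert_array_equal(
            np.argsort(betweenness(g), kind="stable"),
            np.argsort(betweenness(scaled), kind="stable"),
        )

    def test_adding_edge_never_increases_distances(self, rng):
        for _ in range(10):
            g = random_graph(rng, 6, 0.4)
            w = g.weights.copy()
            zeros = [(i, j) for i in range(6) for j in range(i + 1, 6) if w[i, j] == 0]
            if not zeros:
                continue
            i, j = zeros[int(rng.integers(len(zeros)))]
            w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
            d0, d1 = shortest_path_lengths(g), shortest_path_lengths(WeightedGraph(w))
            assert np.all(d1 <= d0 + 1e-12)


class TestEigenvectorCentrality:
    def test_ring_is_uniform(self):
        w = np.zeros((6, 6))
        for i in range(6):
            w[i, (i + 1) % 6] = w[(i + 1) % 6, i] = 1.0
        np.testing.assert_allclose(eigenvector_centrality(WeightedGraph(w)), 1.0)

    def test_star_center_dominates(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        ec = eigenvector_centrality(WeightedGraph(w))
        assert ec[0] == 1.0 and np.all(ec[1:] < 1.0)

    def test_matches_dense_eigendecomposition(self, rng):
        g = random_graph(rng, 5, 0.7)
        vals, vecs = np.linalg.eigh(g.weights)
        lead = np.abs(vecs[:, np.argmax(vals)])
        np.testing.assert_allclose(
            eigenvector_centrality(g), lead / lead.max(), atol=1e-8
        )

    def test_edgeless_graph_rejected(self):
        with pytest.raises(GraphDomainError):
            eigenvector_centrality(WeightedGraph(np.zeros((3, 3))))

    def test_disconnected_minor_component_scores_zero(self):
        w = np.zeros((5, 5))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4)]:
            w[a, b] = w[b, a] = 1.0
        ec = eigenvector_centrality(WeightedGraph(w))
        assert np.all(ec[3:] == 0.0) and ec[:3].max() == 1.0


class TestModularity:
    def test_component_partition_of_two_triangles(self):
        g = two_triangles()
        part = Partition(module_of=np.array([0, 0, 0, 1, 1, 1]), gamma=1.0)
        assert modularity(g, part) == pytest.approx(0.5)

    def test_one_module_matches_direct_double_sum(self, rng):
        g = random_graph(rng, 6, 0.6)
        part = Partition(module_of=np.zeros(6, dtype=int), gamma=1.0)
        assert modularity(g, part) == pytest.approx(
            modularity_oracle(g.weights, part.module_of), abs=1e-10
        )

    def test_random_partitions_match_oracle_with_gamma(self, rng):
        for _ in range(20):
            g = random_graph(rng, 7, 0.5)
            if g.n_edges == 0:
                continue
            labels = rng.integers(0, 3, size=7)
            gamma = float(rng.uniform(0.5, 2.0))
            part = Partition(module_of=labels, gamma=gamma)
            # Partition compacts labels; the oracle only needs co-membership
            assert modularity(g, part) == pytest.approx(
                modularity_oracle(g.weights, part.module_of, gamma), abs=1e-10
            )

    def test_edgeless_graph_rejected(self):
        g = WeightedGraph(np.zeros((3, 3)))
        with pytest.raises(GraphDomainError):
            modularity(g, Partition(module_of=np.arange(3), gamma=1.0))


class TestLouvain:
    def test_two_triangles_recovered(self):
        part = best_partition(two_triangles(), gamma=1.0, seed=0)
        m = part.module_of
        assert m[0] == m[1] == m[2] != m[3] == m[4] == m[5]

    def test_never_below_trivial_partitions(self):
        g = two_triangles()
        for gamma in (1.0, 1.15):
            part = best_partition(g, gamma=gamma, seed=1)
            q = modularity(g, part)
            q_one = modularity(g, Partition(np.zeros(6, dtype=int), gamma))
            q_single = modularity(g, Partition(np.arange(6), gamma))
            assert q >= q_one - 1e-12 and q >= q_single - 1e-12

    def test_planted_three_blocks_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat([0, 1, 2], 4)
        scores = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            w = np.zeros((12, 12))
            for i in range(12):
                for j in range(i + 1, 12):
                    same = truth[i] == truth[j]
                    if local.random() < (0.95 if same else 0.08):
                        w[i, j] = w[j, i] = 1.0
            part = best_partition(WeightedGraph(w), gamma=1.0, seed=seed)
            scores.append(adjusted_rand_score(truth, part.module_of))
        assert np.mean(scores) >= 0.9


class TestSummarize:
    def test_k5_panel(self):
        s = summarize(complete_graph(5), seed=0)
        assert s.clustering_C == pytest.approx(1.0)
        assert s.path_length_L == pytest.approx(1.0)
        assert s.mean_node_bc == pytest.approx(0.0)
        assert s.n_nodes == 5

    def test_edgeless_graph_propagates_undefined_L(self):
        with pytest.raises(GraphDomainError):
            summarize(WeightedGraph(np.zeros((5, 5))), seed=0)

    def test_deterministic_under_fixed_seed(self, rng):
        g = random_graph(rng, 50, 0.15)
        a = summarize(g, gamma=1.15, seed=7)
        b = summarize(g, gamma=1.15, seed=7)
        assert a == b
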