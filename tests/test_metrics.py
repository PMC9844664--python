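"""Centrality, density and predictability against hand-worked examples."""

import numpy as np
import pytest

from conftest import make_dataset
from oracles import brute_force_centrality, random_weighted_network
from symnet.correlations import spearman_matrix
from symnet.metrics import (
    centrality_table,
    network_density,
    node_predictability,
    shortest_path_distances,
)
from symnet.network import PCorNetwork


def net_from(W, labels=None):
    W = np.asarray(W, dtype=float)
    labels = labels or [f"n{i}" for i in range(W.shape[0])]
    return PCorNetwork(W, labels, 0.1, 0.5)


class TestDistances:
    def test_single_edge_reciprocal_length(self):
        D = shortest_path_distances(net_from([[0, 0.5], [0.5, 0]]))
        assert D[0, 1] == pytest.approx(2.0)

    def test_detour_beats_weak_direct_edge(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        W[0, 2] = W[2, 0] = 0.1
        D = shortest_path_distances(net_from(W))
        assert D[0, 2] == pytest.approx(4.0)  # min(1/0.1, 2 + 2)

    def test_disconnected_pair_is_infinite(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        D = shortest_path_distances(net_from(W))
        assert np.isinf(D[0, 2]) and np.isinf(D[1, 2])


class TestCentrality:
    def test_star_graph_strengths(self):
        p = 5
        W = np.zeros((p, p))
        W[0, 1:] = W[1:, 0] = 0.5
        ct = centrality_table(net_from(W))
        assert ct["strength"][0] == pytest.approx(0.5 * (p - 1))
        assert np.allclose(ct["strength"][1:], 0.5)

    def test_path_graph_betweenness(self):
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 0.5
        ct = centrality_table(net_from(W))
        assert list(ct["betweenness"]) == [0, 2, 2, 0]

    def test_isolated_node_conventions(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = -0.4
        ct = centrality_table(net_from(W))
        assert ct["strength"][2] == 0.0
        assert ct["closeness"][2] == 0.0
        assert ct["betweenness"][2] == 0.0
        assert ct["expected_influence"][0] == pytest.approx(-0.4)

    def test_handshake_identity(self):
        rng = np.random.default_rng(1)
        W = random_weighted_network(7, rng)
        ct = centrality_table(net_from(W))
        assert ct["strength"].sum() == pytest.approx(
            2 * np.abs(W[np.triu_indices(7, 1)]).sum()
        )

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            W = random_weighted_network(6, rng)
            net = net_from(W)
            ct = centrality_table(net)
            s, c, b, d = brute_force_centrality(W)
            assert np.allclose(ct["strength"], s, atol=1e-12)
            assert np.allclose(ct["closeness"], c, atol=1e-10)
            assert np.allclose(ct["betweenness"], b, atol=1e-9)
            assert np.allclose(shortest_path_distances(net), d)


class TestDensity:
    def test_identity_matrix_zero(self):
        assert network_density(np.eye(6)).value == 0.0

    def test_hand_arithmetic(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.5
        R[0, 2] = R[2, 0] = -0.2
        R[1, 2] = R[2, 1] = 0.1
        assert network_density(R).value == pytest.approx(0.8)

    def test_upper_bound_all_perfect(self):
        R = np.ones((13, 13))
        assert network_density(R).value == pytest.approx(78.0)

    def test_relabeling_invariance_and_monotonicity(self):
        rng = np.random.default_rng(3)
        R = spearman_matrix(rng.integers(0, 5, (50, 5)).astype(float)).R
        perm = rng.permutation(5)
        assert network_density(R[np.ix_(perm, perm)]).value == pytest.approx(
            network_density(R).value
        )
        R2 = R.copy()
        R2[0, 1] = R2[1, 0] = np.sign(R2[0, 1] or 1) * (abs(R2[0, 1]) + 0.1)
        assert network_density(R2).value > network_density(R).value

    def test_edge_weight_basis(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        dv = network_density(net_from(W))
        assert dv.basis == "edge_weights"
        assert dv.value == pytest.approx(0.5)


class TestPredictability:
    def test_exact_copy_of_sole_neighbor(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 10, 100)
        data = make_dataset(np.column_stack([x, x]))
        W = np.array([[0, 0.9], [0.9, 0]])
        pt = node_predictability(data, net_from(W, data.item_labels))
        assert np.allclose(pt["r_squared"], 1.0)

    def test_isolated_node_is_zero(self):
        rng = np.random.default_rng(5)
        data = make_dataset(rng.integers(0, 10, (50, 3)))
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        pt = node_predictability(data, net_from(W, data.item_labels))
        assert pt["r_squared"][2] == 0.0

    def test_single_edge_matches_squared_rank_correlation(self):
        from symnet.simulate import _standardize_precision, default_thresholds
        from symnet import generate_ordinal_dataset

        K = np.array([[1.0, -0.6], [-0.6, 1.0]])
        data = generate_ordinal_dataset(
            5000, _standardize_precision(K), default_thresholds()[:2], seed=6
        )
        rho = spearman_matrix(data.values()).R[0, 1]
        W = np.array([[0, 0.5], [0.5, 0]])
        pt = node_predictability(data, net_from(W, data.item_labels))
        assert pt["r_squared"][0] == pytest.approx(rho**2, abs=0.05)

    def test_collinear_neighbors_flagged(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 10, 80)
        y = rng.integers(0, 10, 80)
        data = make_dataset(np.column_stack([y, x, x]))
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        W[0, 2] = W[2, 0] = 0.4
        pt = node_predictability(data, net_from(W, data.item_labels))
        assert bool(pt["flagged"][0])
        assert 0.0 <= pt["r_squared"][0] <= 1.0

    def test_monotone_recoding_of_predictors_invariant(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 4, 120)  # squares stay on the 0-10 scale
        y = np.clip(x + rng.integers(-2, 3, 120), 0, 10)
        data1 = make_dataset(np.column_stack([y, x]))
        data2 = make_dataset(np.column_stack([y, x**2]))  # monotone recode
        W = np.array([[0, 0.5], [0.5, 0]])
        r1 = node_predictability(data1, net_from(W, data1.item_labels))
        r2 = node_predictability(data2, net_from(W, data2.item_labels))
        assert r1["r_squared"][0] == pytest.approx(r2["r_squared"][0], abs=1e-12)
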