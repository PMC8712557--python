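"""Similarity indices: worked examples, reduction identities and oracles."""

import numpy as np
import pytest

import netfunc as nf
from netfunc import IndexSpec, ValidationError
from netfunc.similarity import DivergenceError, rwr_steady_state, spectral_radius

from conftest import random_connected_network, random_network


def dense_adjacency(net, weighted=False):
    nodes = list(net.nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, w in net.edges():
        A[pos[u], pos[v]] = A[pos[v], pos[u]] = w if weighted else 1.0
    return nodes, A


class TestLocalIndices:
    def test_common_neighbors_examples(self, triangle, path3):
        assert nf.common_neighbors(triangle, "b", "c") == 1
        assert nf.common_neighbors(path3, "a", "b") == 0
        assert nf.common_neighbors(path3, "a", "c") == 1

    def test_unknown_node_rejected(self, triangle):
        with pytest.raises(ValidationError):
            nf.common_neighbors(triangle, "a", "zzz")

    def test_jaccard_examples(self, triangle):
        # triangle: N_b = {a, c}, N_c = {a, b} -> intersection {a}, union {a, b, c}
        assert nf.jaccard(triangle, "b", "c") == pytest.approx(1 / 3)
        twin = nf.ProteinNetwork.from_edges([("u", "x"), ("u", "y"), ("v", "x"), ("v", "y")])
        assert nf.jaccard(twin, "u", "v") == 1.0
        lonely = nf.ProteinNetwork.from_edges([("a", "b")], nodes=["a", "b", "i", "j"])
        assert nf.jaccard(lonely, "i", "j") == 0.0

    def test_fs_identical_neighborhoods_give_one(self):
        # u and v share all d neighbors; with n_avg <= d each factor is
        # 2d / (0 + 2d + 0) = 1
        edges = [("u", f"x{i}") for i in range(3)] + [("v", f"x{i}") for i in range(3)]
        net = nf.ProteinNetwork.from_edges(edges)
        assert nf.functional_similarity(net, "u", "v", n_avg=2.0) == pytest.approx(1.0)

    def test_fs_disjoint_neighborhoods_zero(self):
        net = nf.ProteinNetwork.from_edges([("u", "x"), ("v", "y")])
        assert nf.functional_similarity(net, "u", "v") == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_fs_symmetric(self, seed):
        net = random_network(10, 0.4, seed)
        nodes = net.nodes
        for u in nodes[:5]:
            for v in nodes[5:]:
                assert nf.functional_similarity(net, u, v) == pytest.approx(
                    nf.functional_similarity(net, v, u)
                )

    def test_fs_low_degree_penalty_monotone(self):
        # the u-side denominator grows by lambda = max(0, n_avg - |N_u|)
        edges = [("u", "w"), ("v", "w")]
        net = nf.ProteinNetwork.from_edges(edges)
        no_pen = nf.functional_similarity(net, "u", "v", n_avg=1.0)
        pen = nf.functional_similarity(net, "u", "v", n_avg=4.0)
        assert pen < no_pen

    def test_fsr_hand_value(self):
        # single shared neighbor w with r_uw = r_vw = 0.5 and no other
        # neighbors: each factor = 2*0.25 / (0.5 + 0.25 + 0) = 2/3
        net = nf.ProteinNetwork.from_edges([("u", "w", 0.5), ("v", "w", 0.5)])
        got = nf.fs_weighted(net, "u", "v", n_avg=0.0)
        assert got == pytest.approx((2 / 3) ** 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_fsr_reduces_to_fs_with_unit_weights(self, seed):
        net = random_network(9, 0.35, seed)
        nodes = net.nodes
        for u in nodes:
            for v in nodes:
                if u < v:
                    assert nf.fs_weighted(net, u, v) == nf.functional_similarity(net, u, v)

    def test_fs_combine_sum_option(self, triangle):
        prod = nf.functional_similarity(triangle, "b", "c", n_avg=0.0)
        summ = nf.functional_similarity(triangle, "b", "c", n_avg=0.0, fs_combine="sum")
        assert summ > prod  # each factor < 1 here, so product < sum


class TestKatz:
    def test_two_node_geometric_series(self):
        # odd-length walks a-b: beta/(1 - beta^2)
        net = nf.ProteinNetwork.from_edges([("a", "b")])
        sim = nf.katz_matrix(net, IndexSpec("katz", katz_beta=0.1))
        assert sim.score("a", "b") == pytest.approx(0.1 / (1 - 0.01), abs=1e-12)

    def test_small_beta_limit_is_adjacency(self, triangle):
        beta = 1e-8
        sim = nf.katz_matrix(triangle, IndexSpec("katz", katz_beta=beta))
        _, A = dense_adjacency(triangle)
        assert np.allclose(sim.scores / beta, A, atol=1e-6)

    def test_divergent_beta_rejected(self, triangle):
        rho = 2.0  # spectral radius of the triangle
        with pytest.raises(DivergenceError, match="0.5"):
            nf.katz_matrix(triangle, IndexSpec("katz", katz_beta=1 / rho))

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_matches_series_oracle(self, seed):
        net = random_network(12, 0.3, seed)
        _, A = dense_adjacency(net)
        rho = spectral_radius(A)
        if rho == 0:
            pytest.skip("empty graph draw")
        beta = 0.5 / rho
        closed = nf.katz_matrix(net, IndexSpec("katz", katz_beta=beta)).scores
        # independent truncated-series oracle
        S, term = np.zeros_like(A), np.eye(len(A))
        for _ in range(40):
            term = beta * term @ A
            S += term
        np.fill_diagonal(S, 0.0)
        assert np.max(np.abs(closed - S)) < 1e-8

    def test_truncated_series_mode(self, path3):
        closed = nf.katz_matrix(path3, IndexSpec("katz", katz_beta=0.2)).scores
        trunc = nf.katz_matrix(path3, IndexSpec("katz", katz_beta=0.2, katz_max_len=60)).scores
        assert np.allclose(closed, trunc, atol=1e-10)


class TestRWR:
    def test_two_node_closed_form(self):
        net = nf.ProteinNetwork.from_edges([("a", "b")])
        _, R = rwr_steady_state(net, IndexSpec("rwr", rwr_c=0.9))
        assert R[1, 0] == pytest.approx(0.9 / 1.9, abs=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_power_iteration_matches_linear_solve(self, seed):
        net = random_connected_network(15, 0.25, seed, weighted=True)
        spec = IndexSpec("rwr", rwr_c=0.8)
        nodes, R = rwr_steady_state(net, spec)
        # independent dense-solve oracle: R = (1-c) (I - c W~^T)^{-1}
        _, W = dense_adjacency(net, weighted=True)
        Wt = W / W.sum(axis=1, keepdims=True)
        n = len(nodes)
        oracle = (1 - 0.8) * np.linalg.inv(np.eye(n) - 0.8 * Wt.T)
        assert np.max(np.abs(R - oracle)) < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_steady_states_are_distributions(self, seed):
        net = random_connected_network(12, 0.3, seed)
        _, R = rwr_steady_state(net, IndexSpec("rwr", rwr_c=0.9))
        assert np.all(R >= -1e-12)
        assert np.allclose(R.sum(axis=0), 1.0, atol=1e-8)

    def test_restart_limit(self, path3):
        _, R = rwr_steady_state(path3, IndexSpec("rwr", rwr_c=1e-9))
        assert np.allclose(R, np.eye(3), atol=1e-6)

    def test_isolated_node_zero_row(self, caplog):
        import logging

        net = nf.ProteinNetwork.from_edges([("a", "b")], nodes=["a", "b", "z"])
        with caplog.at_level(logging.WARNING, logger="netfunc"):
            sim = nf.rwr_matrix(net)
        assert np.all(sim.row("z") == 0.0)
        assert "isolated" in caplog.text


class TestDispatch:
    def test_cn_and_jaccard_on_triangle(self, triangle):
        cn = nf.compute_similarity(triangle, IndexSpec("cn"))
        jac = nf.compute_similarity(triangle, IndexSpec("jaccard"))
        off = ~np.eye(3, dtype=bool)
        assert np.all(cn.scores[off] == 1.0)
        assert np.allclose(jac.scores[off], 1 / 3)

    def test_sequence_rejected(self, triangle):
        with pytest.raises(ValidationError, match="sequence"):
            nf.compute_similarity(triangle, IndexSpec("sequence"))

    def test_unknown_index_rejected(self):
        with pytest.raises(ValidationError):
            IndexSpec("resistance_distance")

    @pytest.mark.parametrize("name", ["cn", "jaccard", "fs", "fsr", "katz", "rwr"])
    @pytest.mark.parametrize("seed", [3, 11])
    def test_all_indices_symmetric_nonneg_zero_diagonal(self, name, seed):
        net = random_connected_network(10, 0.3, seed, weighted=True)
        sim = nf.compute_similarity(net, IndexSpec(name))
        assert np.allclose(sim.scores, sim.scores.T)
        assert np.all(sim.scores >= 0)
        assert np.all(np.diag(sim.scores) == 0)

    @pytest.mark.parametrize("seed", [2, 9])
    def test_matrix_agrees_with_pairwise_functions(self, seed):
        net = random_network(8, 0.4, seed)
        cn = nf.compute_similarity(net, IndexSpec("cn"))
        fs = nf.compute_similarity(net, IndexSpec("fs"))
        for u in net.nodes:
            for v in net.nodes:
                if u < v:
                    assert cn.score(u, v) == nf.common_neighbors(net, u, v)
                    assert fs.score(u, v) == pytest.approx(nf.functional_similarity(net, u, v))
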