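"""Weighted graph indices against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synchnet import netmetrics as nm

TRIANGLE = np.array([[0.0, 0.6, 0.3],
                     [0.6, 0.0, 0.2],
                     [0.3, 0.2, 0.0]])


def random_plv_matrix(rng, n=10, density=1.0):
    w = rng.uniform(0.05, 1.0, (n, n))
    if density < 1.0:
        w[rng.uniform(size=(n, n)) > density] = 0.0
    w = np.triu(w, 1)
    return w + w.T


def floyd_warshall_oracle(W):
    n = W.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nz = W > 0
    d[nz] = 1.0 / W[nz]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def triple_sum_cc_oracle(W):
    n = W.shape[0]
    wh = W / W.max()
    out = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(W[i])
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        out[i] = acc / (k * (k - 1))
    return out


class TestStrength:
    def test_triangle_nodal_and_global(self):
        s, g = nm.strength(TRIANGLE)
        assert np.allclose(s, [0.9, 0.8, 0.5])
        assert g == pytest.approx(2.2 / 3)

    def test_complete_uniform_closed_form(self):
        n, w = 8, 0.4
        W = w * (1 - np.eye(n))
        _, g = nm.strength(W)
        assert g == pytest.approx((n - 1) * w)

    def test_zero_matrix(self):
        s, g = nm.strength(np.zeros((4, 4)))
        assert g == 0 and np.all(s == 0)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nm.strength(np.array([[0.0, 1.0], [0.5, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            nm.strength(np.array([[0.0, -0.1], [-0.1, 0.0]]))  # negative


class TestClustering:
    def test_triangle_worked_example(self):
        # normalized weights 1, 0.5, 1/3: each C_i = (1 * 0.5 * 1/3)^(1/3)
        cc = nm.nodal_cc(TRIANGLE)
        assert np.allclose(cc, (1.0 / 6.0) ** (1.0 / 3.0))
        assert cc[0] == pytest.approx(0.5503, abs=1e-3)

    def test_complete_uniform_graph_fully_clustered(self):
        W = 0.7 * (1 - np.eye(6))
        assert np.allclose(nm.nodal_cc(W), 1.0)

    def test_star_graph_has_no_triangles(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.8
        assert np.all(nm.nodal_cc(W) == 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        W = random_plv_matrix(rng, n=10, density=0.7)
        assert np.abs(nm.nodal_cc(W) - triple_sum_cc_oracle(W)).max() <= 1e-12

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning):
            assert np.all(nm.nodal_cc(np.zeros((3, 3))) == 0)


class TestDistances:
    def test_triangle_worked_example(self):
        d = nm.distances(TRIANGLE)
        assert d[0, 1] == pytest.approx(1.0 / 0.6)
        assert d[0, 2] == pytest.approx(1.0 / 0.3)
        assert d[1, 2] == pytest.approx(5.0)

    def test_two_node_link(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert nm.distances(W)[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        W = random_plv_matrix(rng, n=10, density=0.5)
        assert np.allclose(nm.distances(W), floyd_warshall_oracle(W),
                           atol=1e-12, equal_nan=False)

    def test_adding_a_link_never_increases_distances(self):
        rng = np.random.default_rng(5)
        W = random_plv_matrix(rng, n=8, density=0.4)
        d0 = nm.distances(W)
        W2 = W.copy()
        i, j = 0, 7
        W2[i, j] = W2[j, i] = max(W2[i, j], 0.9)
        d1 = nm.distances(W2)
        assert np.all(d1 <= d0 + 1e-12)


class TestPathLengthEfficiency:
    def test_triangle_worked_example(self):
        pl, eff = nm.path_length_and_efficiency(nm.distances(TRIANGLE))
        assert pl == pytest.approx(10.0 / 3.0, abs=1e-4)
        # every direct link is the shortest path, so efficiency = mean weight
        assert eff == pytest.approx(1.1 / 3.0, abs=1e-4)

    def test_complete_uniform_closed_form(self):
        w = 0.25
        W = w * (1 - np.eye(7))
        pl, eff = nm.path_length_and_efficiency(nm.distances(W))
        assert pl == pytest.approx(1.0 / w)
        assert eff == pytest.approx(w)

    def test_fully_synchronized_network_degenerate_maximum(self):
        W = 1.0 * (1 - np.eye(5))
        ix = nm.network_indices(W)
        assert ix.pl == pytest.approx(1.0)
        assert ix.efficiency == pytest.approx(1.0)
        assert ix.cc == pytest.approx(1.0)
        assert ix.strength == pytest.approx(4.0)

    def test_disconnected_pairs_excluded_from_pl_zero_in_efficiency(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.5
        pl, eff = nm.path_length_and_efficiency(nm.distances(W))
        assert pl == pytest.approx(2.0)          # only finite pairs
        assert eff == pytest.approx((4 * 0.5) / 12.0)  # 1/inf = 0 elsewhere

    def test_fully_disconnected_rejected(self):
        with pytest.raises(ValueError):
            nm.path_length_and_efficiency(nm.distances(np.zeros((3, 3))))


class TestMonotonicityAndRanges:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_uniform_weight_increase_improves_integration(self, seed):
        rng = np.random.default_rng(seed)
        W = random_plv_matrix(rng, n=8, density=0.8)
        if W.max() == 0:
            return
        W2 = np.clip(W * 1.2, 0, 1.0)
        _, s0 = nm.strength(W)
        _, s1 = nm.strength(W2)
        pl0, e0 = nm.path_length_and_efficiency(nm.distances(W))
        pl1, e1 = nm.path_length_and_efficiency(nm.distances(W2))
        assert s1 >= s0 - 1e-12
        assert e1 >= e0 - 1e-12
        assert pl1 <= pl0 + 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_indices_within_documented_ranges(self, seed):
        rng = np.random.default_rng(seed)
        W = random_plv_matrix(rng, n=9)
        ix = nm.network_indices(W)
        assert 0 <= ix.strength <= 8
        assert 0 <= ix.cc <= 1
        assert 0 <= ix.efficiency <= 1
        assert ix.pl >= 1.0 / W.max()
        assert np.all((ix.nodal_cc >= 0) & (ix.nodal_cc <= 1))
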