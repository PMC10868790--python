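"""Communication models against closed forms and independent oracles."""

import heapq
import itertools

import numpy as np
import pytest

from connscale import (
    communicability,
    communication_set,
    negative_search_information,
    scaled_morphospace,
    search_information,
    shortest_path_efficiency,
)
from connscale.communication import lattice_reference, random_reference
from conftest import random_weighted_graph


def dijkstra_oracle(weights, source):
    """Plain binary-heap Dijkstra over lengths 1/w (independent of scipy)."""
    n = len(weights)
    dist = [np.inf] * n
    dist[source] = 0.0
    heap = [(0.0, source)]
    done = [False] * n
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v in range(n):
            if weights[u][v] > 0:
                nd = d + 1.0 / weights[u][v]
                if nd < dist[v]:
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
    return dist


class TestShortestPathEfficiency:
    def test_closed_forms(self):
        k2 = np.array([[0, 0.5], [0.5, 0]])
        assert shortest_path_efficiency(k2)[0, 1] == pytest.approx(0.5)
        p3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        spe = shortest_path_efficiency(p3)
        assert spe[0, 2] == pytest.approx(0.5)
        assert spe[0, 1] == pytest.approx(1.0)

    def test_against_dijkstra_oracle_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 31))
            w = random_weighted_graph(n, 0.3, rng, connected=False)
            if w.sum() == 0:
                continue
            spe = shortest_path_efficiency(w)
            for src in range(n):
                dist = dijkstra_oracle(w.tolist(), src)
                for j in range(n):
                    if j == src:
                        continue
                    expected = 0.0 if np.isinf(dist[j]) else 1.0 / dist[j]
                    assert spe[src, j] == pytest.approx(expected, abs=1e-10)

    def test_unreachable_pairs_are_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        spe = shortest_path_efficiency(w)
        assert spe[0, 2] == 0.0 and spe[1, 3] == 0.0


class TestSearchInformation:
    def test_single_edge_has_zero_information(self):
        k2 = np.array([[0, 2.0], [2.0, 0]])
        si = search_information(k2)
        assert si[0, 1] == pytest.approx(0.0)
        assert negative_search_information(k2)[0, 1] == pytest.approx(0.0)

    def test_unit_triangle_one_bit(self):
        tri = np.ones((3, 3)) - np.eye(3)
        si = search_information(tri)
        assert si[0, 1] == pytest.approx(1.0)  # P = 1/2 along the direct edge
        assert negative_search_information(tri)[0, 1] == pytest.approx(-1.0)

    def test_against_exhaustive_path_enumeration(self, rng):
        """On graphs with n <= 8, enumerate every simple path, find the
        minimum-length one (lexicographic tie-break) and multiply transition
        probabilities directly."""
        for _ in range(20):
            n = int(rng.integers(4, 9))
            w = random_weighted_graph(n, 0.5, rng)
            si = search_information(w)
            strength = w.sum(axis=1)
            for i, j in itertools.permutations(range(n), 2):
                best = None
                for r in range(n - 1):
                    for mid in itertools.permutations([k for k in range(n) if k not in (i, j)], r):
                        path = (i, *mid, j)
                        if any(w[u, v] == 0 for u, v in zip(path[:-1], path[1:])):
                            continue
                        length = sum(1.0 / w[u, v] for u, v in zip(path[:-1], path[1:]))
                        if best is None or length < best[0] - 1e-12 or (
                            abs(length - best[0]) <= 1e-12 and path < best[1]
                        ):
                            best = (length, path)
                logp = sum(
                    np.log2(w[u, v] / strength[u])
                    for u, v in zip(best[1][:-1], best[1][1:])
                )
                assert si[i, j] == pytest.approx(-logp, abs=1e-8)

    def test_nsi_symmetric_and_masked_when_disconnected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        nsi = negative_search_information(w)
        assert np.isnan(nsi[0, 2])
        assert np.allclose(nsi, nsi.T, equal_nan=True)


class TestCommunicability:
    def test_empty_graph_is_identity(self):
        w = np.zeros((3, 3))
        cmy = communicability(w)
        assert np.allclose(cmy, np.eye(3))

    def test_k2_normalizes_any_weight_to_sinh_cosh(self):
        for weight in (0.1, 1.0, 7.3):
            w = np.array([[0, weight], [weight, 0]])
            cmy = communicability(w)
            assert cmy[0, 1] == pytest.approx(np.sinh(1), abs=1e-12)
            assert cmy[0, 0] == pytest.approx(np.cosh(1), abs=1e-12)

    def test_unit_triangle_closed_form(self):
        tri = np.ones((3, 3)) - np.eye(3)
        cmy = communicability(tri)
        assert cmy[0, 1] == pytest.approx((np.e - np.exp(-0.5)) / 3, abs=1e-12)

    def test_against_power_series_oracle(self, rng):
        """expm result equals the 30-term series of the normalized matrix."""
        from math import factorial

        for _ in range(10):
            w = random_weighted_graph(12, 0.4, rng)
            s = w.sum(axis=1)
            norm = w / np.sqrt(np.outer(s, s))
            series = np.zeros_like(norm)
            term = np.eye(len(w))
            for k in range(30):
                series += term / factorial(k)
                term = term @ norm
            assert np.allclose(communicability(w), series, atol=1e-8)

    def test_scale_invariance_after_normalization(self, rng):
        w = random_weighted_graph(15, 0.4, rng)
        assert np.allclose(communicability(w), communicability(10 * w), atol=1e-12)

    def test_isolated_node_masked(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        cmy = communicability(w)
        assert np.isnan(cmy[2]).all() and np.isnan(cmy[:, 2]).all()
        assert np.isfinite(cmy[0, 1])


class TestMorphospace:
    def test_lattice_input_sits_near_zero(self):
        n, n_edges = 100, 400
        gen = np.random.default_rng(0)
        multiset = gen.lognormal(0, 0.5, n_edges)
        latt = lattice_reference(n, multiset, gen)
        point = scaled_morphospace(latt, n_realizations=10, seed=123)
        assert abs(point.spe_scaled) <= 0.05

    def test_random_input_sits_near_one(self):
        n, n_edges = 100, 400
        gen = np.random.default_rng(0)
        multiset = gen.lognormal(0, 0.5, n_edges)
        rnd = random_reference(n, multiset, gen)
        point = scaled_morphospace(rnd, n_realizations=10, seed=123)
        assert abs(point.spe_scaled - 1.0) <= 0.1

    def test_affine_invariance_under_weight_scaling(self, small_bundle):
        p1 = scaled_morphospace(small_bundle.weights, n_realizations=5, seed=3)
        p2 = scaled_morphospace(10.0 * small_bundle.weights, n_realizations=5, seed=3)
        assert p2.spe_scaled == pytest.approx(p1.spe_scaled, abs=1e-8)
        assert p2.cmy_scaled == pytest.approx(p1.cmy_scaled, abs=1e-8)


def test_communication_set_masks_are_consistent(small_bundle):
    comm = communication_set(small_bundle.weights)
    assert not comm.valid.diagonal().any()
    assert np.allclose(comm.spe, comm.spe.T)
    assert np.allclose(comm.nsi[comm.valid], comm.nsi.T[comm.valid])
    assert np.isfinite(comm.cmy[comm.valid]).all()
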