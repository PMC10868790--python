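"""Modularity scoring, Louvain optimization, MRCC and module features."""

import itertools

import numpy as np
import pytest

from connscale import (
    coclassification_matrix,
    consensus_from_cc,
    interhemispheric_cc,
    modularity_score,
    mrcc_ensemble,
    optimize_partition,
    partition_features,
)
from connscale.modularity import Partition
from conftest import random_weighted_graph, sbm_graph


def _partitions_of(n):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield np.array(prefix)
            return
        for lab in range(k + 1):
            yield from rec(prefix + [lab], max(k, lab + 1))
    yield from rec([0], 1)


class TestModularityScore:
    def test_two_disconnected_dyads(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        assert modularity_score(w, [0, 0, 1, 1], 1.0) == pytest.approx(0.5)

    def test_single_module_is_zero_at_unit_resolution(self, rng):
        w = random_weighted_graph(10, 0.5, rng)
        assert modularity_score(w, np.zeros(10), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_decreasing_in_gamma(self, rng):
        w = random_weighted_graph(10, 0.5, rng)
        labels = np.arange(10) % 3
        qs = [modularity_score(w, labels, g) for g in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(qs) < 0)

    def test_matches_networkx_on_random_graphs(self, rng):
        """Independent cross-check of the configuration-null Q."""
        import networkx as nx

        for _ in range(5):
            w = random_weighted_graph(12, 0.5, rng)
            labels = rng.integers(0, 3, size=12)
            g = nx.from_numpy_array(w)
            communities = [
                {i for i in range(12) if labels[i] == m} for m in np.unique(labels)
            ]
            expected = nx.community.modularity(g, communities, weight="weight")
            assert modularity_score(w, labels, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            modularity_score(np.zeros((3, 3)), [0, 1, 2], 1.0)


class TestOptimizePartition:
    def test_two_cliques_recovered_and_globally_optimal(self):
        """Louvain recovers the two 4-cliques and matches exhaustive
        maximization over all 4140 partitions of 8 nodes."""
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0
        w[3, 4] = w[4, 3] = 1.0
        part = optimize_partition(w, 1.0, seed=0)
        best_q = max(modularity_score(w, labels, 1.0) for labels in _partitions_of(8))
        assert part.q == pytest.approx(best_q)
        assert len(np.unique(part.labels[:4])) == 1
        assert len(np.unique(part.labels[4:])) == 1
        assert part.labels[0] != part.labels[7]

    def test_disconnected_components_not_merged(self):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        w[3, 4] = w[4, 3] = w[4, 5] = w[5, 4] = 1.0
        part = optimize_partition(w, 1.0, seed=1)
        assert part.labels[0] == part.labels[1] == part.labels[2]
        assert part.labels[3] == part.labels[4] == part.labels[5]
        assert part.labels[0] != part.labels[3]

    def test_deterministic_under_seed(self, rng):
        w = random_weighted_graph(30, 0.3, rng)
        p1 = optimize_partition(w, 1.3, seed=7, n_restarts=3)
        p2 = optimize_partition(w, 1.3, seed=7, n_restarts=3)
        assert np.array_equal(p1.labels, p2.labels)
        assert p1.q == p2.q

    def test_never_below_trivial_baselines(self, rng):
        for gamma in (0.05, 1.0, 5.0):
            w = random_weighted_graph(15, 0.4, rng)
            part = optimize_partition(w, gamma, seed=0)
            assert part.q >= modularity_score(w, np.zeros(15), gamma) - 1e-12
            assert part.q >= modularity_score(w, np.arange(15), gamma) - 1e-12


class TestMrccEnsemble:
    def test_planted_blocks_found_and_window_respected(self, rng):
        from sklearn.metrics import adjusted_rand_score

        w, truth = sbm_graph(60, 4, 0.5, 0.05, rng)
        ens = mrcc_ensemble(w, n_gamma=60, seed=2)
        assert len(ens) <= 60
        aris = [adjusted_rand_score(truth, p.labels) for p in ens.partitions]
        assert max(aris) == pytest.approx(1.0)
        for p in ens.partitions:
            assert 2 <= p.n_modules <= 30

    def test_gamma_grid_log_spaced(self, rng):
        w, _ = sbm_graph(40, 2, 0.5, 0.1, rng)
        ens = mrcc_ensemble(w, n_gamma=30, seed=0)
        ratios = ens.gammas[1:] / ens.gammas[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_uniform_complete_graph_rejected(self):
        w = np.ones((8, 8)) - np.eye(8)
        with pytest.raises(ValueError, match="2 modules"):
            mrcc_ensemble(w, n_gamma=20, coarse_range=(1e-4, 1e-3), seed=0)


class TestCoclassification:
    def test_identical_partitions_give_block_matrix(self):
        labels = np.array([0, 0, 1, 1, 2])
        parts = [Partition(labels=labels, gamma=1.0, q=0.0)] * 5
        cc = coclassification_matrix(parts)
        expected = (labels[:, None] == labels[None, :]).astype(float)
        np.fill_diagonal(expected, 1.0)
        assert np.array_equal(cc, expected)

    def test_hand_counted_two_partition_ensemble(self):
        # {AB|C} and {A|BC}: AB and BC agree half the time, AC never
        p1 = Partition(labels=np.array([0, 0, 1]), gamma=1, q=0)
        p2 = Partition(labels=np.array([0, 1, 1]), gamma=1, q=0)
        cc = coclassification_matrix([p1, p2])
        assert cc[0, 1] == pytest.approx(0.5)
        assert cc[1, 2] == pytest.approx(0.5)
        assert cc[0, 2] == pytest.approx(0.0)

    def test_entries_are_multiples_of_inverse_ensemble_size(self, rng):
        w, _ = sbm_graph(30, 3, 0.6, 0.1, rng)
        ens = mrcc_ensemble(w, n_gamma=20, seed=1)
        cc = coclassification_matrix(ens)
        scaled = cc * len(ens)
        assert np.allclose(scaled, np.round(scaled), atol=1e-9)
        assert np.allclose(cc, cc.T)
        assert np.all(np.diag(cc) == 1.0)


class TestConsensus:
    def test_block_cc_reproduced_exactly(self):
        labels = np.repeat([0, 1, 2], 5)
        cc = (labels[:, None] == labels[None, :]).astype(float)
        cons = consensus_from_cc(cc, seed=0, n_restarts=5)
        assert len(np.unique(cons.labels)) == 3
        for m in range(3):
            assert len(np.unique(cons.labels[labels == m])) == 1

    def test_relabeling_invariance(self, rng):
        from sklearn.metrics import adjusted_rand_score

        w, _ = sbm_graph(40, 4, 0.6, 0.05, rng)
        cc = coclassification_matrix(mrcc_ensemble(w, n_gamma=30, seed=3))
        perm = rng.permutation(40)
        c1 = consensus_from_cc(cc, seed=5, n_restarts=10)
        c2 = consensus_from_cc(cc[np.ix_(perm, perm)], seed=5, n_restarts=10)
        assert adjusted_rand_score(c1.labels[perm], c2.labels) == pytest.approx(1.0)

    def test_consensus_ari_nondecreasing_with_block_contrast(self, rng):
        """Stronger planted structure is never harder to recover (10 seeds)."""
        from sklearn.metrics import adjusted_rand_score

        weak, strong = [], []
        for s in range(10):
            r = np.random.default_rng(s)
            for p_in, acc in ((0.15, weak), (0.6, strong)):
                w, truth = sbm_graph(40, 4, p_in, 0.08, r)
                ens = mrcc_ensemble(w, n_gamma=30, seed=s)
                cons = consensus_from_cc(coclassification_matrix(ens), seed=s, n_restarts=20)
                acc.append(adjusted_rand_score(truth, cons.labels))
        assert np.mean(strong) >= np.mean(weak)


class TestPartitionFeatures:
    def test_two_planted_cliques_have_unit_imd(self):
        w = np.zeros((5, 5))
        for block in ((0, 1, 2), (3, 4)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0
        ed = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        feats = partition_features(w, ed, np.array([0, 0, 0, 1, 1]))
        assert feats["imd"] == pytest.approx(1.0)

    def test_single_module_has_zero_longdist_fraction(self, rng):
        w = random_weighted_graph(10, 0.6, rng)
        ed = rng.uniform(1, 2, size=(10, 10))
        ed = (ed + ed.T) / 2
        feats = partition_features(w, ed, np.zeros(10, dtype=int))
        assert feats["longdist_fraction"] == 0.0

    def test_longest_bridging_edge_counted_per_definition(self):
        """20 edges, top 5% = 1 edge; it bridges the 2 modules -> 1/2."""
        rng = np.random.default_rng(0)
        n = 10
        labels = np.array([0] * 5 + [1] * 5)
        coords = np.concatenate([rng.uniform(0, 1, (5, 1)), rng.uniform(5, 6, (5, 1))])
        ed = np.abs(coords - coords.T)
        w = np.zeros((n, n))
        within_pairs = [(i, j) for i, j in itertools.combinations(range(n), 2)
                        if labels[i] == labels[j]]
        for i, j in within_pairs[:19]:
            w[i, j] = w[j, i] = 1.0
        w[0, 9] = w[9, 0] = 1.0  # the single longest (bridging) edge
        feats = partition_features(w, ed, labels)
        assert feats["longdist_fraction"] == pytest.approx(0.5)

    def test_all_singletons_rejected(self):
        w = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="singleton"):
            partition_features(w, w, np.arange(4))


class TestInterhemispheric:
    def test_hemisphere_aligned_modules_score_zero(self):
        labels = np.array(["L", "L", "R", "R"])
        cc = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
        )
        assert interhemispheric_cc(cc, labels) == 0.0

    def test_constant_cc_scores_one(self):
        cc = np.full((6, 6), 0.4)
        np.fill_diagonal(cc, 1.0)
        labels = np.array(["L"] * 3 + ["R"] * 3)
        assert interhemispheric_cc(cc, labels) == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        labels = np.array(["L", "L", "R", "R"])
        cc = np.array(
            [
                [1.0, 0.8, 0.2, 0.4],
                [0.8, 1.0, 0.6, 0.2],
                [0.2, 0.6, 1.0, 0.5],
                [0.4, 0.2, 0.5, 1.0],
            ]
        )
        # inter pairs: (0,2),(0,3),(1,2),(1,3) -> mean 0.35
        # intra pairs: (0,1),(2,3) -> mean 0.65
        assert interhemispheric_cc(cc, labels) == pytest.approx(0.35 / 0.65)
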