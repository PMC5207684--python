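"""Viewer network: percolation threshold, modularity, communities."""

import numpy as np
import pytest

from gazetherm.network import (build_network, detect_communities,
                               exact_max_modularity, modularity,
                               percolation_threshold, reorder_matrix)


def two_cliques_with_bridge(n_per: int = 5, bridge: float = 0.5) -> np.ndarray:
    n = 2 * n_per
    J = np.zeros((n, n))
    for block in (slice(0, n_per), slice(n_per, n)):
        J[block, block] = 1.0
    J[0, n_per] = J[n_per, 0] = bridge
    np.fill_diagonal(J, 0.0)
    return J


def clique_adjacency(blocks: list[int]) -> np.ndarray:
    n = sum(blocks)
    A = np.zeros((n, n))
    start = 0
    for b in blocks:
        A[start:start + b, start:start + b] = 1.0
        start += b
    np.fill_diagonal(A, 0.0)
    return A


def brute_force_emergence(J: np.ndarray, frac: float = 0.5) -> float:
    """Independent oracle: highest unique coupling level at which the
    largest connected component (edges J >= level) exceeds frac of nodes."""
    import networkx as nx
    n = J.shape[0]
    off = ~np.eye(n, dtype=bool)
    for level in sorted(np.unique(J[off]))[::-1]:
        g = nx.from_numpy_array(((J >= level) & off).astype(float))
        if max(len(c) for c in nx.connected_components(g)) > frac * n:
            return level
    return float(np.min(J[off]))


class TestPercolationThreshold:
    def test_bridge_edge_triggers_emergence(self):
        J = two_cliques_with_bridge(bridge=0.5)
        level = brute_force_emergence(J)
        assert level == 0.5
        j_o = percolation_threshold(J)
        # giant component spans all nodes exactly once J_o drops below 0.5
        assert j_o < 0.5
        adj = (J > j_o) & ~np.eye(J.shape[0], dtype=bool)
        assert brute_force_emergence(J) <= 0.5
        assert adj[0, 5]  # bridge included

    def test_all_equal_couplings_degenerate(self):
        J = np.zeros((4, 4))
        with pytest.warns(UserWarning):
            j_o = percolation_threshold(J)
        assert j_o == 0.0

    def test_uniform_couplings_emerge_immediately(self):
        c = 0.7
        J = c * (np.ones((5, 5)) - np.eye(5))
        with pytest.warns(UserWarning):
            assert percolation_threshold(J) == pytest.approx(c)

    def test_shift_equivariance(self):
        """Adding a constant to all off-diagonal couplings shifts the
        threshold by the same constant."""
        rng = np.random.default_rng(2)
        J = rng.uniform(0, 1, size=(8, 8))
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0.0)
        base = percolation_threshold(J)
        shifted = J + 0.3
        np.fill_diagonal(shifted, 0.0)
        assert percolation_threshold(shifted) == pytest.approx(base + 0.3)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            percolation_threshold(np.zeros((2, 2)))


class TestModularity:
    def test_single_community_complete_graph_is_zero(self):
        A = clique_adjacency([4])
        assert modularity(A, np.zeros(4)) == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques_give_half(self):
        A = clique_adjacency([4, 4])
        labels = np.array([0] * 4 + [1] * 4)
        assert modularity(A, labels) == pytest.approx(0.5)

    def test_random_labels_centre_on_zero(self, rng):
        """Averaged over random graphs and random labelings, the
        null-model centring keeps Q near zero (small finite-size bias)."""
        qs = []
        for _ in range(60):
            A = (rng.random((12, 12)) < 0.4).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            if A.sum() == 0:
                continue
            qs.extend(modularity(A, rng.integers(0, 3, size=12))
                      for _ in range(10))
        assert abs(np.mean(qs)) < 0.1

    def test_double_sum_equals_per_community_form(self, rng):
        """Eq-by-eq identity: the full double sum equals
        sum_c (e_c - (a_c / 2m)^2) on random graphs."""
        for _ in range(10):
            A = (rng.random((8, 8)) < 0.5).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            if A.sum() == 0:
                continue
            labels = rng.integers(0, 3, size=8)
            two_m = A.sum()
            q_comm = 0.0
            for c in np.unique(labels):
                in_c = labels == c
                e_c = A[np.ix_(in_c, in_c)].sum() / two_m
                a_c = A[in_c].sum() / two_m
                q_comm += e_c - a_c ** 2
            assert modularity(A, labels) == pytest.approx(q_comm)

    def test_literal_normalisation_hand_sum(self):
        """With the prefactor and null model taken over twice the total
        degree: two 4-cliques give (24 - 288/48)/48 = 0.375 by hand."""
        A = clique_adjacency([4, 4])
        labels = np.array([0] * 4 + [1] * 4)
        q_lit = modularity(A, labels, literal_normalisation=True)
        assert q_lit == pytest.approx(0.375, abs=1e-12)
        assert q_lit < modularity(A, labels)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(np.zeros((3, 3)), np.zeros(3))


class TestDetectCommunities:
    def test_two_cliques_recovered_exactly(self):
        A = clique_adjacency([5, 5])
        labels = detect_communities(A, seed=1)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_planted_partition_recovered(self, rng):
        n_per = 8
        n = 2 * n_per
        truth = np.array([0] * n_per + [1] * n_per)
        p = np.where(truth[:, None] == truth[None, :], 0.9, 0.05)
        A = (rng.random((n, n)) < p).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        labels = detect_communities(A, seed=2)
        # recovered up to relabelling
        same_truth = truth[:, None] == truth[None, :]
        same_found = labels[:, None] == labels[None, :]
        agreement = (same_truth == same_found)[np.triu_indices(n, 1)].mean()
        assert agreement > 0.9

    def test_heuristic_never_beats_exhaustive_optimum(self, rng):
        for trial in range(5):
            A = (rng.random((7, 7)) < 0.45).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            if A.sum() == 0:
                continue
            labels = detect_communities(A, seed=trial)
            q_heur = modularity(A, labels)
            _, q_best = exact_max_modularity(A)
            assert q_heur <= q_best + 1e-12

    def test_relabelling_invariance(self, rng):
        A = clique_adjacency([4, 3, 5])
        perm = rng.permutation(12)
        labels = detect_communities(A, seed=3)
        labels_p = detect_communities(A[np.ix_(perm, perm)], seed=3)
        same = labels[:, None] == labels[None, :]
        same_p = labels_p[:, None] == labels_p[None, :]
        np.testing.assert_array_equal(same[np.ix_(perm, perm)], same_p)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(np.zeros((4, 4)))


class TestExactMaxModularity:
    def test_finds_clique_partition(self):
        A = clique_adjacency([3, 3])
        labels, q = exact_max_modularity(A)
        assert q == pytest.approx(0.5)
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]

    def test_large_graph_rejected(self):
        with pytest.raises(ValueError):
            exact_max_modularity(np.zeros((13, 13)))


class TestReorderMatrix:
    def test_blocks_become_contiguous(self, rng):
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        M = np.where(labels[:, None] == labels[None, :], 1.0, 0.05)
        np.fill_diagonal(M, 0.0)
        perm = reorder_matrix(M, labels=labels)
        reordered = labels[perm]
        changes = np.abs(np.diff(reordered)).astype(bool).sum()
        assert changes == 1  # one boundary between two contiguous blocks

    def test_trivial_matrix(self):
        np.testing.assert_array_equal(reorder_matrix(np.zeros((1, 1))), [0])

    def test_already_ordered_blocks_stay_ordered(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        M = np.where(labels[:, None] == labels[None, :], 1.0, 0.0)
        np.fill_diagonal(M, 0.0)
        perm = reorder_matrix(M, labels=labels)
        assert np.abs(np.diff(labels[perm])).astype(bool).sum() == 1


class TestBuildNetwork:
    def test_end_to_end_on_block_couplings(self):
        J = two_cliques_with_bridge()
        net = build_network(J, seed=4)
        assert net.q > 0.3
        assert net.n_communities == 2
        assert net.adjacency.shape == J.shape
        np.testing.assert_array_equal(net.adjacency, net.adjacency.T)
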