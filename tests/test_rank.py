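import math

import numpy as np
import pytest

from metanmf import (
    cluster_samples,
    connectivity,
    consensus,
    cophenetic_coefficient,
    generate_dataset,
    scan_ranks,
)


def block_consensus(block_sizes):
    """Perfect 0/1 consensus matrix with the given block sizes."""
    n = sum(block_sizes)
    C = np.zeros((n, n))
    start = 0
    for s in block_sizes:
        C[start:start + s, start:start + s] = 1.0
        start += s
    return C


def brute_force_cophenetic(D):
    """O(n^3) average-linkage agglomeration; returns cophenetic distances.

    Independent of scipy: clusters are merged at the smallest average
    original distance, and every cross pair of a merge records that
    height as its cophenetic distance.
    """
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        keys = list(clusters)
        best, best_d = None, math.inf
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                d = float(np.mean([D[i, j] for i in clusters[a] for j in clusters[b]]))
                if d < best_d:
                    best, best_d = (a, b), d
        a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = best_d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return coph


class TestClusterSamples:
    def test_column_maximum_wins(self):
        H = np.array([[0.1], [0.9], [0.3]])
        assert cluster_samples(H)[0] == 1  # the second metagene

    def test_tie_goes_to_smallest_index(self):
        H = np.full((3, 2), 0.5)
        assert cluster_samples(H).tolist() == [0, 0]

    def test_matches_argmax_oracle(self, rng):
        H = rng.random((4, 20))
        assignment = cluster_samples(H)
        for j in range(20):
            best = max(range(4), key=lambda i: (H[i, j], -i))
            assert assignment[j] == best

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(np.empty((0, 0)))


class TestConnectivity:
    def test_single_cluster_all_ones(self):
        assert np.array_equal(connectivity(np.zeros(5, int)), np.ones((5, 5)))

    def test_all_singletons_identity(self):
        assert np.array_equal(connectivity(np.arange(4)), np.eye(4))

    def test_two_blocks(self):
        C = connectivity(np.array([1, 1, 2, 2]))
        expected = block_consensus([2, 2])
        assert np.array_equal(C, expected)

    def test_invariant_to_relabeling(self, rng):
        a = rng.integers(0, 3, size=12)
        relabeled = np.array([{0: 7, 1: 2, 2: 5}[v] for v in a])
        assert np.array_equal(connectivity(a), connectivity(relabeled))


class TestConsensus:
    def test_mean_of_identical_inputs_is_input(self):
        C = connectivity(np.array([0, 0, 1]))
        res = consensus([C, C, C])
        assert np.array_equal(res.consensus, C)

    def test_half_probability_pair(self):
        c1 = connectivity(np.array([0, 0]))
        c2 = connectivity(np.array([0, 1]))
        assert consensus([c1, c2]).consensus[0, 1] == 0.5

    def test_matches_pairwise_cocluster_frequencies(self, rng):
        assignments = [rng.integers(0, 3, size=10) for _ in range(50)]
        res = consensus([connectivity(a) for a in assignments])
        for i in range(10):
            for j in range(10):
                freq = np.mean([a[i] == a[j] for a in assignments])
                assert res.consensus[i, j] == pytest.approx(freq)

    def test_entries_are_multiples_of_one_over_runs(self, rng):
        runs = 8
        res = consensus([connectivity(rng.integers(0, 2, 6)) for _ in range(runs)])
        scaled = res.consensus * runs
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            consensus([np.ones((3, 3)), np.ones((4, 4))])


class TestCopheneticCoefficient:
    @pytest.mark.parametrize("blocks", [[1, 5], [3, 3], [2, 6], [4, 4, 4], [2, 3, 4, 5]])
    def test_perfect_block_consensus_is_exactly_one(self, blocks):
        assert cophenetic_coefficient(block_consensus(blocks)) == 1.0

    def test_all_ones_consensus_undefined(self):
        assert math.isnan(cophenetic_coefficient(np.ones((6, 6))))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((8, 8))
        C = (A + A.T) / 2
        np.fill_diagonal(C, 1.0)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        coph = brute_force_cophenetic(D)
        iu = np.triu_indices(8, 1)
        expected = float(np.corrcoef(D[iu], coph[iu])[0, 1])
        assert cophenetic_coefficient(C) == pytest.approx(expected, abs=1e-10)


class TestScanRanks:
    def test_single_run_consensus_is_binary(self, small_planted):
        expr, *_ = small_planted
        V = np.clip(expr.to_numpy(), 0, None)
        (res,) = scan_ranks(V, [3], runs_per_k=1, seed=0)
        assert set(np.unique(res.consensus)) <= {0.0, 1.0}
        assert res.ccc == 1.0 or math.isnan(res.ccc)

    def test_profile_deterministic_for_fixed_seed(self, small_planted):
        expr, *_ = small_planted
        V = np.clip(expr.to_numpy(), 0, None)
        p1 = scan_ranks(V, [2, 3], runs_per_k=3, seed=11)
        p2 = scan_ranks(V, [2, 3], runs_per_k=3, seed=11)
        for a, b in zip(p1, p2):
            assert a.k == b.k and a.ccc == b.ccc
            assert np.array_equal(a.consensus, b.consensus)

    def test_consensus_invariants(self, small_planted):
        expr, *_ = small_planted
        V = np.clip(expr.to_numpy(), 0, None)
        (res,) = scan_ranks(V, [3], runs_per_k=5, seed=2)
        C = res.consensus
        assert np.array_equal(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert C.min() >= 0.0 and C.max() <= 1.0
        np.testing.assert_allclose(C * 5, np.round(C * 5), atol=1e-12)

    def test_invalid_k_rejected(self, small_planted):
        expr, *_ = small_planted
        V = np.clip(expr.to_numpy(), 0, None)
        with pytest.raises(ValueError, match="k="):
            scan_ranks(V, [40], runs_per_k=1, seed=0)
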