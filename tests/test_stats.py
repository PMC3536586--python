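import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from metanmf import (
    build_network,
    derive_cluster_sets,
    generate_dataset,
    hypergeom_p,
    kw_zvalues,
    overlap_heatmap,
)
from metanmf.stats import activity_matrix, spearman_edge_test


def permutation_with_spearman(n, rho):
    """Permutation of 0..n-1 whose Spearman correlation with identity is
    exactly ``rho`` (via sum of squared rank differences); greedy disjoint
    transpositions."""
    target = Fraction(1 - rho) * n * (n * n - 1) / 6  # required sum d^2
    assert target.denominator == 1
    remaining = int(target)
    perm = np.arange(n)
    used = set()
    while remaining > 0:
        placed = False
        for d in range(int(math.isqrt(remaining // 2)), 0, -1):
            for i in range(n - d):
                if i in used or i + d in used:
                    continue
                perm[i], perm[i + d] = perm[i + d], perm[i]
                used.update((i, i + d))
                remaining -= 2 * d * d
                placed = True
                break
            if placed:
                break
        assert placed, "no decomposition found"
    return perm


class TestKwZvalues:
    def test_group_at_grand_mean_rank_has_zero_z(self):
        # symmetric groups {1,4} and {2,3}: both mean ranks equal 2.5
        z = kw_zvalues(np.array([1.0, 2.0, 3.0, 4.0]), np.array(["a", "b", "b", "a"]))
        assert z["a"] == pytest.approx(0.0, abs=1e-12)

    def test_two_group_example_from_rank_formula(self):
        # ranks 1..4, groups {s1,s2} vs {s3,s4}: z2 = 1 / sqrt(5/12)
        z = kw_zvalues(np.array([1.0, 2.0, 3.0, 4.0]), np.array(["g1", "g1", "g2", "g2"]))
        assert z["g2"] == pytest.approx(1.549, abs=5e-4)
        assert z["g1"] == pytest.approx(-1.549, abs=5e-4)

    @given(st.integers(0, 2**31 - 1))
    def test_weighted_rank_deviations_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        groups = rng.choice(["a", "b", "c"], size=30)
        if len(set(groups)) < 2:
            return
        ranks = sps.rankdata(x)
        total = 0.0
        for lab in set(groups):
            mask = groups == lab
            total += mask.sum() * (ranks[mask].mean() - ranks.mean())
        assert abs(total) < 1e-9
        kw_zvalues(x, groups)  # must be finite and not raise
        assert np.isfinite(kw_zvalues(x, groups).to_numpy()).all()

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=40)
        groups = rng.choice(["a", "b", "c", "d"], size=40)
        z1 = kw_zvalues(x, groups)
        z2 = kw_zvalues(np.exp(x), groups)
        z3 = kw_zvalues(x**3, groups)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(z1.to_numpy(), z3.to_numpy(), atol=1e-12)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            kw_zvalues(rng.normal(size=5), np.array(["a"] * 5))

    def test_planted_series_signs(self):
        _, _, ann, truth = generate_dataset(80, 40, 3, noise_sd=0.1, seed=9)
        act = activity_matrix(truth.H_true, ann["series"].to_numpy())
        for series, metagenes in truth.series_design.items():
            for m in metagenes:
                assert act.z.iloc[m][series] > 0


class TestSpearmanEdgeTest:
    def test_exact_half_correlation_at_study_scale(self):
        # n = 783 with Spearman r exactly 0.5: t = 0.5 sqrt(781)/sqrt(0.75)
        n = 783
        perm = permutation_with_spearman(n, 0.5)
        r, t, p = spearman_edge_test(np.arange(n, dtype=float), perm.astype(float))
        assert r == pytest.approx(0.5, abs=1e-12)
        assert t == pytest.approx(16.1349, abs=5e-4)
        assert p < 1e-12

    def test_zero_correlation_gives_p_one(self):
        # x symmetric, y an even function of x: Spearman r = 0 by symmetry
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([4.0, 1.0, 1.0, 4.0])
        r, t, p = spearman_edge_test(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_correlation_unbounded_statistic(self):
        x = np.arange(10, dtype=float)
        r, t, p = spearman_edge_test(x, x**3)
        assert (r, t, p) == (1.0, math.inf, 0.0)
        r, t, p = spearman_edge_test(x, -x)
        assert (r, t, p) == (-1.0, -math.inf, 0.0)

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert spearman_edge_test(x, y) == spearman_edge_test(y, x)

    def test_agrees_with_scipy_spearmanr(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=50), rng.normal(size=50)
            r, t, p = spearman_edge_test(x, y)
            ref = sps.spearmanr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestBuildNetwork:
    def test_df_is_n_minus_two(self, rng):
        H = rng.random((3, 783))
        net = build_network(H, alpha=1e-12)
        assert net.df == 781 and net.n_samples == 783

    def test_correlated_rows_form_signed_edges(self, rng):
        base = rng.normal(size=200)
        H = np.vstack([base, base + 1e-3 * rng.normal(size=200),
                       -base + 1e-3 * rng.normal(size=200), rng.normal(size=200)])
        H = H - H.min() + 0.1
        net = build_network(H, alpha=1e-12)
        edges = {(r.source, r.target): r.sign for r in net.edges.itertuples()}
        assert edges[("metagene_1", "metagene_2")] == 1
        assert edges[("metagene_1", "metagene_3")] == -1
        assert ("metagene_1", "metagene_4") not in edges

    def test_constant_row_pairs_skipped_with_warning(self, rng):
        H = np.vstack([np.ones(30), rng.random((2, 30))])
        with pytest.warns(UserWarning, match="constant"):
            net = build_network(H, alpha=0.5)
        assert "metagene_1" not in set(net.edges["source"]) | set(net.edges["target"])

    def test_edges_unique_per_unordered_pair(self, rng):
        H = rng.random((5, 40))
        net = build_network(H, alpha=1.0)
        pairs = list(zip(net.edges["source"], net.edges["target"]))
        assert len(pairs) == len(set(pairs)) == net.n_tests
        assert all(s < t for s, t in pairs)

    def test_to_networkx_carries_attributes(self, rng):
        H = rng.random((3, 40))
        net = build_network(H, alpha=1.0, activity=np.array([3.0, 2.0, 1.0]))
        G = net.to_networkx()
        assert G.number_of_nodes() == 3
        assert G.nodes["metagene_1"]["activity"] == 3.0
        assert G.graph["df"] == 38


class TestHypergeomP:
    def test_zero_overlap_gives_total_probability(self):
        assert hypergeom_p(0, 5, 4, 10) == 1.0

    def test_enumerated_example(self):
        # only the single full-overlap draw counts: C(5,4)C(5,0)/C(10,4)
        assert hypergeom_p(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_nonincreasing_in_overlap(self):
        ps = [hypergeom_p(x, 8, 6, 30) for x in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_large_universe_stays_finite(self):
        p = hypergeom_p(150, 300, 400, 7000)
        assert 0 < p < 1e-50

    def test_agrees_with_scipy_survival_function(self, rng):
        for _ in range(20):
            N = int(rng.integers(20, 2000))
            ms = int(rng.integers(1, N))
            cs = int(rng.integers(1, N))
            x = int(rng.integers(0, min(ms, cs) + 1))
            ref = float(sps.hypergeom.sf(x - 1, N, ms, cs))
            assert hypergeom_p(x, ms, cs, N) == pytest.approx(max(ref, 0.0), rel=1e-9, abs=1e-300)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            hypergeom_p(5, 4, 6, 10)
        with pytest.raises(ValueError, match="background"):
            hypergeom_p(1, 4, 11, 10)


class TestOverlapHeatmap:
    def test_identical_set_attains_row_minimum(self):
        mg = {"m1": ["a", "b", "c"], "m2": ["d", "e", "f"]}
        cl = {"c1": ["a", "b", "c"], "c2": ["a", "d", "f"]}
        ov = overlap_heatmap(mg, cl, background=[chr(103 + i) for i in range(20)] + list("abcdef"))
        assert ov.p.loc["m1"].idxmin() == "c1"

    def test_disjoint_sets_give_p_one_and_log_zero(self):
        ov = overlap_heatmap({"m": ["a", "b"]}, {"c": ["x", "y"]},
                             background=["a", "b", "x", "y", "z1", "z2"])
        assert ov.p.loc["m", "c"] == 1.0
        assert ov.log10_p.loc["m", "c"] == 0.0

    def test_out_of_universe_genes_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="outside the background"):
            ov = overlap_heatmap({"m": ["a", "b"]}, {"c": ["a", "qq"]},
                                 background=["a", "b", "c", "d"])
        # cluster size counted in-universe: cs=1, x=1 -> p = 2/4... enumerate:
        # C(2,1)C(2,0)/C(4,1) = 2/4
        assert ov.p.loc["m", "c"] == pytest.approx(0.5)

    def test_planted_clusters_match_on_the_diagonal(self):
        _, _, _, truth = generate_dataset(120, 30, 3, noise_sd=0.1, seed=5)
        clusters = derive_cluster_sets(truth, top_m=20, jitter=0.0, seed=0)
        ids = np.asarray(truth.gene_ids)
        planted = {
            f"metagene_{c + 1}": list(ids[np.argsort(-truth.W_true[:, c], kind="stable")[:20]])
            for c in range(3)
        }
        ov = overlap_heatmap(planted, clusters, background=truth.gene_ids)
        for c in range(3):
            row = ov.p.loc[f"metagene_{c + 1}"]
            assert row.idxmin() == f"cluster_{c + 1}"
        assert set(ov.row_order) == set(planted)
        assert set(ov.col_order) == set(clusters)
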