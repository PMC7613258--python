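"""Binned correlation/PCA, rank-binned comparison and overlap significance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tadapipe as tp
from conftest import make_uniform_map
from tadapipe.compare import BinnedMatrix


def matrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    return BinnedMatrix(values=values, sample_ids=ids or [f"s{i}" for i in range(len(values))],
                        mode="gatc", filter_log={})


class TestBuildBinnedMatrix:
    def test_gatc_mode_one_bin_per_fragment(self, small_experiment):
        e = small_experiment
        bm = tp.build_binned_matrix(e.samples, e.frag_map, mode="gatc")
        n_dropped = bm.filter_log["n_dropped_zero"]
        assert bm.values.shape == (4, e.frag_map.n_fragments() - n_dropped)

    def test_window_mode_preserves_totals(self, small_experiment):
        e = small_experiment
        bm = tp.build_binned_matrix(e.samples, e.frag_map, mode="window", bin_size=1000)
        assert np.allclose(bm.values.sum(axis=1), [s.counts.sum() for s in e.samples])

    def test_gene_mode_mean_occupancy(self, small_experiment):
        e = small_experiment
        coding = [g for g in e.annotation if g.biotype == "protein_coding"]
        bm = tp.build_binned_matrix([e.profile], e.frag_map, mode="gene", genes=coding)
        g0 = coding[0]
        expected = tp.mean_gene_occupancy(e.profile, g0, e.frag_map)[0]
        assert bm.values[0, 0] == pytest.approx(expected)

    def test_bad_bin_size_rejected(self, small_experiment):
        with pytest.raises(ValueError):
            tp.build_binned_matrix(small_experiment.samples,
                                   small_experiment.frag_map, bin_size=0)


class TestPearsonMatrix:
    def test_identical_samples_correlate_perfectly(self):
        rng = np.random.default_rng(25)
        x = rng.poisson(20, 2000).astype(float)
        r = tp.pearson_matrix(matrix([x, x.copy()]))
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_affine_relation_gives_unit_correlation(self):
        x = np.arange(1.0, 1001.0)
        r = tp.pearson_matrix(matrix([x, 2 * x + 1]))
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_samples_uncorrelated(self):
        rng = np.random.default_rng(26)
        r = tp.pearson_matrix(matrix(rng.normal(10, 1, size=(2, 10_000))))
        assert abs(r.iloc[0, 1]) < 0.05

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(27)
        r = tp.pearson_matrix(matrix(rng.poisson(5, size=(4, 500)).astype(float)))
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)

    def test_joint_outlier_excluded(self):
        rng = np.random.default_rng(28)
        x = rng.normal(10, 1, 3000)
        y = rng.normal(10, 1, 3000)
        r_clean = tp.pearson_matrix(matrix([x, y])).iloc[0, 1]
        x_out, y_out = x.copy(), y.copy()
        x_out[0] = y_out[0] = 1e5  # shared PCR-stack-like artefact
        r_filtered = tp.pearson_matrix(matrix([x_out, y_out])).iloc[0, 1]
        r_naive = stats.pearsonr(x_out, y_out)[0]
        assert abs(r_filtered - r_clean) < 0.01
        assert abs(r_naive - r_clean) > 0.1

    def test_zero_variance_flagged_nan(self):
        r = tp.pearson_matrix(matrix([np.ones(100), np.arange(100.0)]))
        assert np.isnan(r.iloc[0, 1])


class TestPca:
    def _two_groups(self, seed=29):
        rng = np.random.default_rng(seed)
        base_a, base_b = rng.normal(0, 1, 800), rng.normal(0, 1, 800)
        rows = [base_a + rng.normal(0, 0.3, 800) for _ in range(3)] + [
            base_b + rng.normal(0, 0.3, 800) for _ in range(3)
        ]
        return matrix(rows, ids=list("abcdef"))

    def test_pc1_separates_groups(self):
        from sklearn.metrics import silhouette_score

        coords, _var = tp.pca(self._two_groups())
        labels = [0, 0, 0, 1, 1, 1]
        assert silhouette_score(coords[["PC1"]], labels) > 0.5

    def test_variance_fractions_non_increasing_and_bounded(self):
        _c, var = tp.pca(self._two_groups())
        assert np.all(np.diff(var) <= 1e-12)
        assert var.sum() <= 1 + 1e-9

    def test_sample_order_invariance_of_distances(self):
        bm = self._two_groups()
        c1, _ = tp.pca(bm)
        perm = [3, 1, 5, 0, 2, 4]
        bm2 = matrix(bm.values[perm], ids=[bm.sample_ids[i] for i in perm])
        c2, _ = tp.pca(bm2)
        d1 = np.linalg.norm(c1.loc["a"] - c1.loc["f"])
        d2 = np.linalg.norm(c2.loc["a"] - c2.loc["f"])
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            tp.pca(matrix(np.ones((2, 10))))


class TestRankBinCompare:
    def test_monotone_external_strictly_decreasing(self):
        genes = [f"g{i}" for i in range(1500)]
        tada = pd.Series(np.linspace(10, 0, 1500), index=genes)
        ext = pd.Series(np.linspace(100, 0, 1500), index=genes)
        out = tp.rank_bin_compare(tada, ext, bin_size=500)
        assert np.all(np.diff(out["mean_external"]) < 0)

    def test_remainder_bin_sizes(self):
        genes = [f"g{i}" for i in range(1200)]
        rng = np.random.default_rng(30)
        out = tp.rank_bin_compare(
            pd.Series(rng.normal(size=1200), index=genes),
            pd.Series(rng.normal(size=1200), index=genes),
            bin_size=500,
        )
        assert out["n_genes"].tolist() == [500, 500, 200]

    def test_independent_external_flat(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(5000)]
        out = tp.rank_bin_compare(
            pd.Series(rng.normal(size=5000), index=genes),
            pd.Series(rng.normal(size=5000), index=genes),
            bin_size=500,
        )
        slope, _i, _r, p, _se = stats.linregress(out["bin"], out["mean_external"])
        assert p > 0.05  # slope CI contains 0

    def test_self_comparison_non_increasing(self):
        rng = np.random.default_rng(32)
        vals = pd.Series(rng.normal(size=999), index=[f"g{i}" for i in range(999)])
        out = tp.rank_bin_compare(vals, vals, bin_size=100)
        assert np.all(np.diff(out["mean_external"]) <= 0)

    def test_missing_genes_dropped_and_logged(self):
        tada = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        ext = pd.Series([5.0, 4.0], index=["b", "d"])
        out = tp.rank_bin_compare(tada, ext, bin_size=10)
        assert out["n_genes"].sum() == 1
        assert out.attrs["n_dropped"] == 3


def hypergeom_enumeration(n1, n2, k, universe):
    """Brute-force P(|A ∩ B| >= k) over all subsets B for a fixed A."""
    from itertools import combinations
    from math import comb

    a = set(range(n1))
    hits = sum(
        1 for b in combinations(range(universe), n2) if len(a & set(b)) >= k
    )
    return hits / comb(universe, n2)


class TestHypergeometricOverlap:
    def test_zero_overlap_upper_tail_is_one(self):
        assert tp.hypergeometric_overlap(5, 5, 0, 10).p_value == pytest.approx(1.0)

    def test_complete_overlap_small_universe(self):
        res = tp.hypergeometric_overlap(3, 3, 3, 6)
        assert res.p_value == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(25):
            universe = int(rng.integers(4, 13))
            n1 = int(rng.integers(1, universe + 1))
            n2 = int(rng.integers(1, universe + 1))
            k_max = min(n1, n2)
            k = int(rng.integers(max(0, n1 + n2 - universe), k_max + 1))
            expected = hypergeom_enumeration(n1, n2, k, universe)
            got = tp.hypergeometric_overlap(n1, n2, k, universe).p_value
            assert got == pytest.approx(expected, rel=1e-9)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            tp.hypergeometric_overlap(5, 5, 6, 10)
        with pytest.raises(ValueError):
            tp.hypergeometric_overlap(11, 5, 2, 10)


class TestMultisetIntersection:
    def test_pairwise_path_equals_hypergeometric(self):
        a, b = set(range(40)), set(range(20, 50))
        res = tp.multiset_intersection_test([a, b], universe=100)
        exact = tp.hypergeometric_overlap(40, 30, 20, 100)
        assert res.method == "hypergeometric"
        assert res.p_value == exact.p_value

    def test_identical_sets_extreme_p(self):
        s = set(range(30))
        res = tp.multiset_intersection_test([s, s, s], universe=1000, n_draws=20_000,
                                            seed=1)
        assert res.p_value == pytest.approx(1 / 20_001)

    def test_monte_carlo_matches_enumeration(self):
        from itertools import combinations as comb_iter
        from math import comb

        universe, sizes = 8, (3, 4, 3)
        sets = [set(range(3)), set(range(1, 5)), {0, 1, 5}]
        observed = len(set.intersection(*sets))
        # enumerate over B, C with A fixed (p depends on sizes only)
        a = set(range(sizes[0]))
        hits = total = 0
        for b in comb_iter(range(universe), sizes[1]):
            for c in comb_iter(range(universe), sizes[2]):
                total += 1
                hits += len(a & set(b) & set(c)) >= observed
        exact = hits / total
        n_draws = 40_000
        res = tp.multiset_intersection_test(sets, universe=universe, n_draws=n_draws,
                                            seed=2)
        se = np.sqrt(exact * (1 - exact) / n_draws)
        assert abs(res.p_value - exact) <= 3 * se + 1 / n_draws

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            tp.multiset_intersection_test([{1, 2}])
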