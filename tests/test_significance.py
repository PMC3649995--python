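import numpy as np
import pytest
from scipy import stats

from tissueqtl.significance import (
    anova_lr_test,
    call_egenes,
    gene_seed,
    overlap_table,
    pairwise_pi1,
    permutation_pvalue,
    storey_pi0,
    storey_qvalues,
    tbt_min_p,
)


class TestPermutationPvalue:
    def test_observed_above_all_permutations(self):
        # statistic maximal for the identity labelling only
        def stat(perm):
            return 1.0 if np.array_equal(perm, np.arange(6)) else 0.0

        p = permutation_pvalue(stat, 6, n_perm=100, seed=0)
        assert p == pytest.approx(1 / 101)

    def test_observed_below_all_permutations(self):
        def stat(perm):
            return 0.0 if np.array_equal(perm, np.arange(6)) else 1.0

        assert permutation_pvalue(stat, 6, n_perm=50, seed=0) == 1.0

    def test_smaller_is_extreme_mode(self):
        def stat(perm):
            return 0.0 if np.array_equal(perm, np.arange(6)) else 1.0

        p = permutation_pvalue(stat, 6, 100, 0, larger_is_extreme=False)
        assert p == pytest.approx(1 / 101)

    def test_seed_reproducibility(self, rng):
        y = rng.standard_normal(30)
        g = rng.binomial(2, 0.3, 30).astype(float)

        def stat(perm):
            return abs(np.corrcoef(y[perm], g)[0, 1])

        p1 = permutation_pvalue(stat, 30, 99, seed=5)
        p2 = permutation_pvalue(stat, 30, 99, seed=5)
        assert p1 == p2

    def test_gene_seed_stable_and_bounded(self):
        s = gene_seed(17, "ENSG000001")
        assert s == gene_seed(17, "ENSG000001")
        assert 0 <= s < 2**31
        assert s != gene_seed(18, "ENSG000001")


class TestStoreyQvalues:
    def test_all_ones(self):
        p = np.ones(50)
        q, pi0 = storey_qvalues(p)
        assert pi0 == 1.0
        assert np.all(q == 1.0)

    def test_uniform_pvalues_pi0_near_one(self, rng):
        p = rng.uniform(size=5000)
        _, pi0 = storey_qvalues(np.clip(p, 1e-12, 1))
        assert 0.9 <= pi0 <= 1.0

    def test_half_signal_mixture(self, rng):
        p = np.concatenate([rng.uniform(size=2500), rng.uniform(size=2500) * 1e-4])
        _, pi0 = storey_qvalues(np.clip(p, 1e-12, 1))
        assert pi0 == pytest.approx(0.5, abs=0.1)

    def test_small_input_falls_back_to_bh(self, rng):
        p = rng.uniform(0.01, 1, size=10)
        with pytest.warns(UserWarning, match="pi0 = 1"):
            q, pi0 = storey_qvalues(p)
        assert pi0 == 1.0

    def test_qvalues_monotone_in_p(self, rng):
        p = np.clip(rng.uniform(size=200), 1e-12, 1)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.5, 1.2]))


class TestEGeneCalls:
    def test_simple_thresholding(self):
        q = np.array([0.01, 0.04, 0.06])
        assert call_egenes(q, 0.05).sum() == 2
        assert call_egenes(np.ones(5), 0.05).sum() == 0

    def test_realized_fdr_bounded_on_mixture(self, rng):
        m = 2000
        is_null = rng.random(m) < 0.5
        p = np.where(is_null, rng.uniform(size=m), rng.beta(0.05, 1, size=m))
        p = np.clip(p, 1e-300, 1)
        q, _ = storey_qvalues(p)
        calls = call_egenes(q, 0.05)
        assert calls.sum() > 100
        fdp = (calls & is_null).sum() / max(calls.sum(), 1)
        assert fdp <= 1.5 * 0.05


class TestBaselines:
    def test_min_p_single_pair_is_regression_p(self, rng):
        y = rng.standard_normal(40)
        g = rng.binomial(2, 0.3, 40).astype(float)
        res = stats.linregress(g, y)
        assert tbt_min_p([y], g[None, :]) == pytest.approx(res.pvalue)

    def test_min_p_decreases_with_more_snps(self, rng):
        n = 60
        y = rng.standard_normal(n)
        G1 = rng.binomial(2, 0.3, (1, n)).astype(float)
        G10 = np.vstack([G1, rng.binomial(2, 0.3, (9, n)).astype(float)])
        assert tbt_min_p([y], G10) <= tbt_min_p([y], G1)

    def test_perfect_association_tiny_p(self, rng):
        g = rng.binomial(2, 0.3, 50).astype(float)
        y = g + 1e-6 * rng.standard_normal(50)
        assert tbt_min_p([y], g[None, :]) < 1e-20

    def test_anova_single_tissue_equals_squared_t(self, rng):
        y = rng.standard_normal(50)
        g = rng.binomial(2, 0.3, 50).astype(float)
        F, p = anova_lr_test([y], g)
        res = stats.linregress(g, y)
        t2 = (res.slope / res.stderr) ** 2
        assert F == pytest.approx(t2)
        assert p == pytest.approx(res.pvalue)

    def test_anova_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 2000
        for _ in range(reps):
            ys = [rng.standard_normal(60) for _ in range(3)]
            gs = [rng.binomial(2, 0.3, 60).astype(float) for _ in range(3)]
            hits += anova_lr_test(ys, gs)[1] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.015)

    def test_anova_monomorphic_rejected(self, rng):
        ys = [rng.standard_normal(20), rng.standard_normal(20)]
        gs = [np.ones(20), rng.binomial(2, 0.3, 20).astype(float)]
        with pytest.raises(ValueError, match="singular"):
            anova_lr_test(ys, gs)


class TestOverlapAndSharing:
    def test_identical_calls_all_shared(self):
        calls = {t: {"a", "b", "c"} for t in ("x", "y", "z")}
        pat = overlap_table(calls)
        assert pat[(1, 1, 1)] == 1.0

    def test_disjoint_calls_all_singletons(self):
        calls = {"x": {"a"}, "y": {"b"}, "z": {"c"}}
        pat = overlap_table(calls)
        singles = sum(v for k, v in pat.items() if sum(k) == 1)
        assert singles == pytest.approx(1.0)
        assert pat[(1, 1, 1)] == 0.0

    def test_fractions_sum_to_one(self, rng):
        genes = [f"g{i}" for i in range(50)]
        calls = {
            t: {g for g in genes if rng.random() < 0.4} for t in ("a", "b")
        }
        if set().union(*calls.values()):
            assert sum(overlap_table(calls).values()) == pytest.approx(1.0)

    def test_pi1_extremes(self, rng):
        assert pairwise_pi1(np.full(100, 1e-8)) > 0.9
        assert pairwise_pi1(np.clip(rng.uniform(size=2000), 1e-9, 1)) < 0.15

    def test_pi1_partial_sharing(self, rng):
        # 80% of discoveries replicate in the second tissue
        n = 2000
        shared = rng.random(n) < 0.8
        p = np.where(shared, rng.beta(0.03, 1, n), rng.uniform(size=n))
        assert pairwise_pi1(np.clip(p, 1e-300, 1)) == pytest.approx(0.8, abs=0.1)

    def test_pi1_needs_enough_genes(self):
        with pytest.raises(ValueError, match="at least 20"):
            pairwise_pi1(np.full(10, 0.5))


class TestStoreyPi0Smoother:
    def test_deterministic(self, rng):
        p = np.clip(rng.uniform(size=500), 1e-9, 1)
        assert storey_pi0(p) == storey_pi0(p)
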