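import numpy as np
import pytest

from tissueqtl.bf import (
    bf_config,
    bf_config_gridpoint,
    log_bf_gridpoint,
    log_bf_table,
)
from tissueqtl.configs import Configuration, enumerate_configs
from tissueqtl.oracle import bf_exact_oracle
from tissueqtl.priors import Grid, GridPoint, build_grid
from tissueqtl.regression import ResidualCorr, fit_tissue_regression

from conftest import simulate_pair


def _summaries(rng, S=2, b=0.3, n=100):
    out = []
    ys, gs = [], []
    for _ in range(S):
        y, g = simulate_pair(rng, n=n, b=b)
        out.append(fit_tissue_regression(y, g))
        ys.append(y)
        gs.append(g)
    return out, ys, gs


class TestGridpointBF:
    def test_null_prior_gives_unit_bf(self, rng):
        summ, *_ = _summaries(rng)
        bf = bf_config_gridpoint(summ, Configuration((1, 1)), GridPoint(0.0, 0.0))
        assert bf == pytest.approx(1.0)

    def test_zero_estimate_bf_below_one(self):
        lb = log_bf_gridpoint(np.zeros(2), np.array([0.2, 0.3]), 0.1, 0.3)
        # density ratio at the origin is the sqrt determinant ratio < 1
        V = np.diag([0.04, 0.09])
        prior = 0.01 * np.eye(2) + 0.09
        expect = 0.5 * (np.linalg.slogdet(V)[1] - np.linalg.slogdet(V + prior)[1])
        assert lb == pytest.approx(expect)
        assert lb < 0

    def test_single_tissue_closed_form(self):
        # z = 5 with omega = 0.4: BF = sqrt(se^2/(se^2+w)) exp(z^2 w / (2(se^2+w)))
        lb = log_bf_gridpoint(np.array([0.5]), np.array([0.1]), 0.0, 0.4)
        assert np.exp(lb) == pytest.approx(3.12e4, rel=2e-3)

    def test_monotone_in_estimate_magnitude(self):
        bs = np.linspace(0.0, 1.0, 21)
        vals = [
            log_bf_gridpoint(np.array([b]), np.array([0.15]), 0.0, 0.4) for b in bs
        ]
        assert np.all(np.diff(vals) > 0)

    def test_bf_at_null_decreases_with_prior_variance(self):
        sizes = [0.1, 0.2, 0.4, 0.8]
        vals = [
            log_bf_gridpoint(np.zeros(3), np.full(3, 0.2), 0.0, w) for w in sizes
        ]
        assert np.all(np.diff(vals) < 0)

    def test_depends_only_on_active_tissues(self, rng):
        summ, *_ = _summaries(rng, S=3)
        gamma = Configuration((1, 0, 1))
        gp = GridPoint(0.2, 0.35)
        a = bf_config_gridpoint(summ, gamma, gp)
        summ2 = [summ[0], None, summ[2]]
        assert bf_config_gridpoint(summ2, gamma, gp) == pytest.approx(a)

    def test_expression_scale_invariance(self, rng):
        y, g = simulate_pair(rng, b=0.4)
        s1 = fit_tissue_regression(y, g)
        s2 = fit_tissue_regression(123.4 * y, g)
        gp = GridPoint(0.1, 0.3)
        assert bf_config_gridpoint([s1], Configuration((1,)), gp) == pytest.approx(
            bf_config_gridpoint([s2], Configuration((1,)), gp)
        )


class TestGridAveragedBF:
    def test_single_point_grid_reduces_to_gridpoint(self, rng):
        summ, *_ = _summaries(rng)
        grid = Grid(points=[GridPoint(0.1, 0.3)])
        gamma = Configuration((1, 1))
        assert bf_config(summ, gamma, grid) == pytest.approx(
            bf_config_gridpoint(summ, gamma, grid.points[0])
        )

    def test_weighted_mean_and_convexity(self, rng):
        summ, *_ = _summaries(rng, b=0.5)
        grid = build_grid("default")
        gamma = Configuration((1, 1))
        per_point = np.array(
            [bf_config_gridpoint(summ, gamma, p) for p in grid.points]
        )
        avg = bf_config(summ, gamma, grid)
        assert avg == pytest.approx(per_point.mean(), rel=1e-10)
        assert per_point.min() <= avg <= per_point.max()


class TestBatchedTable:
    def test_matches_scalar_path(self, rng):
        bhat = rng.normal(size=(4, 3))
        se = rng.uniform(0.1, 0.3, size=(4, 3))
        configs = enumerate_configs(3)
        grid = build_grid("default")
        table = log_bf_table(bhat, se, configs, grid)
        for ci, cfg in enumerate(configs):
            idx = list(cfg.active)
            for li, p in enumerate(grid.points):
                expect = log_bf_gridpoint(bhat[2, idx], se[2, idx], p.phi, p.omega)
                assert table[2, ci, li] == pytest.approx(expect, rel=1e-10)

    def test_correlated_reduces_to_independent_at_identity(self, rng):
        bhat = rng.normal(size=(2, 3))
        se = rng.uniform(0.1, 0.3, size=(2, 3))
        configs = enumerate_configs(3)
        grid = build_grid("default", sizes=[0.4], heterogeneity=[0.0, 0.5])
        rcorr = ResidualCorr(tissues=["a", "b", "c"], matrix=np.eye(3))
        t_ind = log_bf_table(bhat, se, configs, grid)
        t_cor = log_bf_table(bhat, se, configs, grid, rcorr=rcorr)
        np.testing.assert_allclose(t_ind, t_cor, rtol=1e-10)

    def test_correlated_residuals_shift_consistent_config(self, rng):
        # positively correlated errors make concordant estimates less
        # surprising under the null, lowering the consistent-config BF
        bhat = np.array([[0.5, 0.5]])
        se = np.array([[0.15, 0.15]])
        grid = Grid(points=[GridPoint(0.0, 0.4)])
        cfg = [Configuration((1, 1))]
        R = ResidualCorr(tissues=["a", "b"], matrix=np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert log_bf_table(bhat, se, cfg, grid, rcorr=R)[0, 0, 0] < log_bf_table(
            bhat, se, cfg, grid
        )[0, 0, 0]


class TestOracleCrossCheck:
    """Small, fast spot checks; the full 50-pair agreement suite runs in
    the acceptance tests."""

    def test_unit_bf_at_null_prior(self, rng):
        y, g = simulate_pair(rng)
        assert bf_exact_oracle([y], [g], Configuration((1,)), GridPoint(0, 0)) == 1.0

    @pytest.mark.parametrize("b_true", [0.0, 0.4])
    def test_agreement_single_tissue(self, rng, b_true):
        y, g = simulate_pair(rng, b=b_true)
        s = fit_tissue_regression(y, g)
        gp = GridPoint(0.0, 0.4)
        exact = bf_exact_oracle([y], [g], Configuration((1,)), gp)
        approx = bf_config_gridpoint([s], Configuration((1,)), gp)
        assert approx == pytest.approx(exact, rel=0.05)

    def test_oracle_monotone_in_signal(self, rng):
        g = rng.binomial(2, 0.3, 80).astype(float)
        noise = rng.standard_normal(80)
        gp = GridPoint(0.0, 0.4)
        vals = [
            bf_exact_oracle([b * g + noise], [g], Configuration((1,)), gp)
            for b in (0.0, 0.2, 0.4)
        ]
        assert vals[0] < vals[1] < vals[2]
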