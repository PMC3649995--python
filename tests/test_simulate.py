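import numpy as np
import pytest

from tissueqtl.configs import Configuration
from tissueqtl.priors import GridPoint
from tissueqtl.regression import fit_tissue_regression
from tissueqtl.simulate import (
    SimScenario,
    consistent_sharing_scenario,
    grid_scaled_to_pve,
    power_scenario,
    sharing_recovery_scenario,
    sim_effects,
    sim_expression,
    sim_genotypes,
    sim_study,
    standardized_effect_for_pve,
)


class TestGenotypes:
    def test_moments_match_binomial(self):
        g = sim_genotypes(10_000, 0.3, np.random.default_rng(0))
        assert g.mean() == pytest.approx(0.6, abs=0.05)
        assert set(np.unique(g)) <= {0.0, 1.0, 2.0}

    def test_half_maf_variance(self):
        g = sim_genotypes(10_000, 0.5, np.random.default_rng(1))
        assert g.var() == pytest.approx(0.5, abs=0.05)

    def test_seed_determinism(self):
        a = sim_genotypes(100, 0.3, 42)
        b = sim_genotypes(100, 0.3, 42)
        np.testing.assert_array_equal(a, b)


class TestEffects:
    def test_pve_identity_scale(self):
        # PVE = b^2 v/(b^2 v + 1) with v = 2*0.3*0.7 solved at 20%
        assert standardized_effect_for_pve(0.2, 0.3) == pytest.approx(0.7715, abs=2e-4)

    def test_zero_heterogeneity_gives_identical_effects(self):
        gamma = Configuration((1, 1, 1, 0))
        b = sim_effects(gamma, None, 0.2, 0.3, 5, heterogeneity=0.0)
        active = b[list(gamma.active)]
        assert np.all(active == active[0])
        assert b[3] == 0.0

    def test_inactive_tissues_exactly_zero(self):
        gamma = Configuration((0, 1, 0))
        b = sim_effects(gamma, GridPoint(0.2, 0.6), None, 0.3, 3)
        assert b[0] == 0.0 and b[2] == 0.0 and b[1] != 0.0

    def test_mean_square_matches_pve_target(self):
        gamma = Configuration((1,))
        rng = np.random.default_rng(0)
        draws = np.array(
            [sim_effects(gamma, None, 0.2, 0.3, rng)[0] for _ in range(4000)]
        )
        assert np.mean(draws**2) == pytest.approx(
            standardized_effect_for_pve(0.2, 0.3) ** 2, rel=0.1
        )

    def test_invalid_pve_rejected(self):
        with pytest.raises(ValueError):
            sim_effects(Configuration((1,)), None, 1.0, 0.3, 0)


class TestExpression:
    def test_null_variance_matches_error_variance(self):
        rng = np.random.default_rng(3)
        g = sim_genotypes(20_000, 0.3, rng)
        (y0, y1) = sim_expression([g, g], np.zeros(2), [1.0, 2.0], 0.0, rng)
        assert y0.var() == pytest.approx(1.0, rel=0.05)
        assert y1.var() == pytest.approx(2.0, rel=0.05)

    def test_intra_individual_correlation(self):
        rng = np.random.default_rng(4)
        g = sim_genotypes(10_000, 0.3, rng)
        y = sim_expression([g, g], np.zeros(2), [1.0, 1.0], 0.5, rng)
        assert np.corrcoef(y[0], y[1])[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_regression_recovers_simulated_slope(self):
        rng = np.random.default_rng(5)
        g = sim_genotypes(2000, 0.3, rng)
        b = 0.8
        (y,) = sim_expression([g], np.array([b]), [1.5], 0.0, rng)
        s = fit_tissue_regression(y, g)
        assert abs(s.betahat - b * np.sqrt(1.5)) < 2 * s.se


class TestStudy:
    def test_truth_table_counts(self):
        sc = SimScenario(
            n_s=[50, 50],
            config_counts={(0, 0): 30, (1, 1): 20},
            seed=0,
        )
        study = sim_study(sc)
        assert study.is_null.sum() == 30
        assert len(study.gene_ids) == 50
        assert study.effects.shape == (50, 2)
        assert np.all(study.effects[study.is_null] == 0)

    def test_seed_gives_byte_identical_data(self):
        sc1 = power_scenario(3, n_pairs=40, seed=9)
        sc2 = power_scenario(3, n_pairs=40, seed=9)
        a, b = sim_study(sc1), sim_study(sc2)
        for s in range(5):
            np.testing.assert_array_equal(a.expression[s], b.expression[s])
            np.testing.assert_array_equal(a.genotypes[s], b.genotypes[s])

    def test_shared_individuals_reuse_genotypes(self):
        sc = consistent_sharing_scenario(n_genes=20, seed=1)
        study = sim_study(sc)
        np.testing.assert_array_equal(study.genotypes[0], study.genotypes[1])

    def test_unshared_tissues_have_distinct_genotypes(self):
        study = sim_study(sharing_recovery_scenario(genes_per_config=2, n_null=2))
        assert study.genotypes[1].shape != study.genotypes[0].shape or not np.array_equal(
            study.genotypes[1], study.genotypes[2]
        )

    def test_scenario_validation(self):
        with pytest.raises(ValueError, match="wrong length"):
            SimScenario(n_s=[10, 10], config_counts={(1,): 5})
        with pytest.raises(ValueError, match="equal per-tissue"):
            SimScenario(
                n_s=[10, 20], config_counts={(0, 0): 5}, shared_individuals=True
            )
        with pytest.raises(ValueError, match="shared individuals"):
            SimScenario(n_s=[10, 10], config_counts={(0, 0): 5}, intra_corr=0.3)


class TestScenarioBuilders:
    def test_grid_rescaled_to_expected_pve(self):
        pts = grid_scaled_to_pve(0.2, 0.3)
        v = 2 * 0.3 * 0.7
        sizes = sorted({round(np.sqrt(p.total_variance), 6) for p in pts})
        x = np.array(sizes) ** 2 * v
        assert np.mean(x / (x + 1)) == pytest.approx(0.2, abs=1e-6)

    def test_sharing_recovery_design_shape(self):
        sc = sharing_recovery_scenario()
        assert sc.n_s == [60, 100, 100, 100, 100]
        assert sum(sc.config_counts.values()) == 1800
        assert sc.config_counts[(0,) * 5] == 200
        assert len([g for g in sc.config_counts if sum(g) > 0]) == 8

    def test_consistent_sharing_fraction(self):
        sc = consistent_sharing_scenario(n_genes=2000, pi0=0.5)
        alt = {g: c for g, c in sc.config_counts.items() if sum(g) > 0}
        total = sum(alt.values())
        assert total == 1000
        assert alt[(1, 1, 1)] / total == pytest.approx(0.88, abs=0.005)
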