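import numpy as np
import pytest

from tissueqtl.bf import log_bf_table
from tissueqtl.configs import ConfigWeights, Configuration, enumerate_configs
from tissueqtl.hm import (
    GeneBFBundle,
    HMParams,
    default_init,
    em_fit,
    hm_confidence_intervals,
    hm_loglik,
)
from tissueqtl.pipeline import (
    GenePair,
    bundles_from_pairs,
    relax_single_eqtl,
    top_snp_index,
)
from tissueqtl.priors import Grid, GridPoint, build_grid


def _single_tissue_bundles(rng, n_genes, pi0, omega=0.6, se=0.15):
    """Generate log-BF bundles straight from the model: S=1, L=1, m_g=1.

    z | null ~ N(0,1); z | eQTL ~ N(0, 1 + omega^2/se^2); the Bayes factor
    is the exact normal density ratio, so EM is fitting a correctly
    specified mixture.
    """
    cfgs = [Configuration((1,))]
    is_null = rng.random(n_genes) < pi0
    sd_alt = np.sqrt(1 + omega**2 / se**2)
    z = np.where(is_null, rng.standard_normal(n_genes),
                 sd_alt * rng.standard_normal(n_genes))
    bhat = z * se
    log_bf = (
        0.5 * np.log(se**2 / (se**2 + omega**2))
        + 0.5 * bhat**2 * omega**2 / (se**2 * (se**2 + omega**2))
    )
    bundles = [
        GeneBFBundle(f"g{i}", np.array([[[log_bf[i]]]])) for i in range(n_genes)
    ]
    grid = Grid(points=[GridPoint(0.0, omega)])
    eta = ConfigWeights(configs=cfgs, eta=np.array([1.0]))
    return bundles, eta, grid, is_null


class TestLoglik:
    def test_all_null_model_is_reference_zero(self, rng):
        bundles, eta, grid, _ = _single_tissue_bundles(rng, 50, 0.5)
        params = HMParams(pi0=1.0, eta=eta, lam=np.array([1.0]))
        assert hm_loglik(params, bundles) == pytest.approx(0.0)

    def test_unit_bfs_flat_likelihood(self):
        cfgs = [Configuration((1,))]
        eta = ConfigWeights(configs=cfgs, eta=np.array([1.0]))
        bundles = [GeneBFBundle("a", np.zeros((1, 1, 1))),
                   GeneBFBundle("b", np.zeros((3, 1, 1)))]
        for pi0 in (0.0, 0.3, 0.9):
            params = HMParams(pi0=pi0, eta=eta, lam=np.array([1.0]))
            assert hm_loglik(params, bundles) == pytest.approx(0.0)

    def test_matches_hand_computed_sum(self):
        cfgs = [Configuration((1, 0)), Configuration((0, 1))]
        eta = ConfigWeights(configs=cfgs, eta=np.array([0.4, 0.6]))
        lam = np.array([0.5, 0.5])
        bf_g1 = np.array([[[1.0, 2.0], [3.0, 4.0]]])  # m=1
        bf_g2 = np.array([[[2.0, 2.0], [1.0, 1.0]], [[5.0, 1.0], [1.0, 1.0]]])
        bundles = [GeneBFBundle("g1", np.log(bf_g1)), GeneBFBundle("g2", np.log(bf_g2))]
        pi0 = 0.7
        a1 = 0.4 * 1.5 + 0.6 * 3.5
        a2 = 0.5 * (0.4 * 2.0 + 0.6 * 1.0) + 0.5 * (0.4 * 3.0 + 0.6 * 1.0)
        expect = np.log(pi0 + 0.3 * a1) + np.log(pi0 + 0.3 * a2)
        params = HMParams(pi0=pi0, eta=eta, lam=lam)
        assert hm_loglik(params, bundles) == pytest.approx(expect)


class TestEMFit:
    def test_recovers_pi0_in_correctly_specified_mixture(self, rng):
        bundles, eta, grid, _ = _single_tissue_bundles(rng, 2000, 0.5)
        init = HMParams(pi0=0.9, eta=eta, lam=np.array([1.0]))
        fit = em_fit(bundles, init=init)
        assert fit.pi0 == pytest.approx(0.5, abs=0.05)
        assert fit.converged

    def test_degenerate_config_support(self, rng):
        # two configurations in the model, all signal in the first
        cfgs = [Configuration((1, 0)), Configuration((0, 1))]
        eta = ConfigWeights(configs=cfgs, eta=np.array([0.5, 0.5]))
        lb = np.zeros((60, 1, 2, 1))
        lb[:, 0, 0, 0] = 25.0  # strong BF for config 1 in every gene
        lb[:, 0, 1, 0] = -8.0
        bundles = [GeneBFBundle(f"g{i}", lb[i]) for i in range(60)]
        init = HMParams(pi0=0.5, eta=eta, lam=np.array([1.0]))
        fit = em_fit(bundles, init=init)
        assert fit.eta.eta[0] > 0.999

    def test_trace_is_monotone_nondecreasing(self, rng):
        bundles, eta, grid, _ = _single_tissue_bundles(rng, 300, 0.7)
        fit = em_fit(bundles, init=HMParams(pi0=0.9, eta=eta, lam=np.array([1.0])))
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_fixed_point_stability(self, rng):
        bundles, eta, grid, _ = _single_tissue_bundles(rng, 500, 0.4)
        fit = em_fit(bundles, init=HMParams(pi0=0.9, eta=eta, lam=np.array([1.0])))
        refit = em_fit(bundles, init=fit, max_iter=2)
        assert refit.pi0 == pytest.approx(fit.pi0, abs=1e-3)

    def test_fixed_parameters_are_held(self, rng):
        bundles, eta, grid, _ = _single_tissue_bundles(rng, 200, 0.5)
        init = HMParams(pi0=0.33, eta=eta, lam=np.array([1.0]))
        fit = em_fit(bundles, init=init, fixed={"pi0"})
        assert fit.pi0 == 0.33

    def test_requires_two_genes(self, rng):
        bundles, eta, grid, _ = _single_tissue_bundles(rng, 1, 0.5)
        with pytest.raises(ValueError, match="at least 2"):
            em_fit(bundles, init=HMParams(pi0=0.5, eta=eta, lam=np.array([1.0])))


class TestConfidenceIntervals:
    def test_identical_genes_give_tight_interval(self):
        cfgs = [Configuration((1,))]
        eta = ConfigWeights(configs=cfgs, eta=np.array([1.0]))
        bundles = [GeneBFBundle(f"g{i}", np.full((1, 1, 1), 3.0)) for i in range(40)]
        params = em_fit(bundles, init=HMParams(pi0=0.5, eta=eta, lam=np.array([1.0])))
        cis = hm_confidence_intervals(params, bundles, n_boot=25, seed=1)
        lo, hi = cis["pi0"]
        assert hi - lo < 1e-6

    def test_interval_contains_point_estimate(self, rng):
        bundles, eta, grid, _ = _single_tissue_bundles(rng, 150, 0.5)
        fit = em_fit(bundles, init=HMParams(pi0=0.9, eta=eta, lam=np.array([1.0])))
        cis = hm_confidence_intervals(fit, bundles, n_boot=30, seed=2)
        lo, hi = cis["pi0"]
        assert lo - 1e-9 <= fit.pi0 <= hi + 1e-9

    def test_coverage_at_reduced_replication(self, rng):
        hits = 0
        n_datasets = 25
        for _ in range(n_datasets):
            bundles, eta, grid, _ = _single_tissue_bundles(rng, 120, 0.5)
            fit = em_fit(bundles, init=HMParams(pi0=0.9, eta=eta, lam=np.array([1.0])))
            lo, hi = hm_confidence_intervals(fit, bundles, n_boot=40, seed=3)["pi0"]
            hits += lo <= 0.5 <= hi
        assert hits / n_datasets >= 0.8

    def test_rejects_tiny_bootstrap(self, rng):
        bundles, eta, grid, _ = _single_tissue_bundles(rng, 50, 0.5)
        fit = em_fit(bundles, init=HMParams(pi0=0.9, eta=eta, lam=np.array([1.0])))
        with pytest.raises(ValueError, match="n_boot"):
            hm_confidence_intervals(fit, bundles, n_boot=5)


def _two_snp_pair(rng, gene, b1=0.0, b2=0.0, n=150):
    g1 = rng.binomial(2, 0.3, n).astype(float)
    g2 = rng.binomial(2, 0.3, n).astype(float)
    ys, gs = [], []
    for _ in range(2):  # two tissues
        y = b1 * g1 + b2 * g2 + rng.standard_normal(n)
        ys.append(y)
        gs.append(np.vstack([g1, g2]))
    return GenePair(gene, [f"{gene}_s1", f"{gene}_s2"], ys, gs)


@pytest.fixture(scope="module")
def relaxation_setup():
    rng = np.random.default_rng(7)
    grid = build_grid("default")
    configs = enumerate_configs(2)
    pairs = [
        _two_snp_pair(rng, "one_eqtl", b1=0.6, b2=0.0),
        _two_snp_pair(rng, "two_eqtl", b1=0.6, b2=0.6),
        _two_snp_pair(rng, "null", b1=0.0, b2=0.0),
    ]
    bundles = bundles_from_pairs(pairs, configs, grid)
    params = default_init(configs, len(grid), pi0=0.3)
    new_pairs, new_bundles = relax_single_eqtl(pairs, bundles, params, grid)
    return pairs, bundles, params, grid, new_pairs, new_bundles


class TestRelaxation:
    def test_top_snp_identified(self, relaxation_setup):
        pairs, bundles, params, *_ = relaxation_setup
        assert top_snp_index(bundles[0], params) == 0

    def test_residualized_single_eqtl_gene_is_null(self, relaxation_setup):
        *_, new_bundles = relaxation_setup
        art = {b.gene_id: b for b in new_bundles}["one_eqtl::resid"]
        assert art.log_bf.max() < np.log(10)

    def test_second_signal_survives_residualization(self, relaxation_setup):
        *_, new_bundles = relaxation_setup
        art = {b.gene_id: b for b in new_bundles}["two_eqtl::resid"]
        assert art.log_bf.max() > np.log(100)

    def test_null_gene_stays_null(self, relaxation_setup):
        *_, new_bundles = relaxation_setup
        art = {b.gene_id: b for b in new_bundles}["null::resid"]
        assert art.log_bf.max() < np.log(10)

    def test_output_contains_originals_plus_artificials(self, relaxation_setup):
        pairs, bundles, _, _, new_pairs, new_bundles = relaxation_setup
        assert len(new_pairs) == 2 * len(pairs)
        assert len(new_bundles) == 2 * len(bundles)
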