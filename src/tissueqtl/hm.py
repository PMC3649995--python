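"""Hierarchical model across genes, fit by EM.

Each gene either has no eQTL (probability pi0) or exactly one, at a SNP
chosen uniformly among its m_g cis candidates, with activity configuration
gamma drawn with probability eta_gamma and prior scale drawn from the grid
with probability lambda_l.  Because every Bayes factor is already a
likelihood ratio against the null, the per-gene likelihood relative to the
null model is

    L_g = pi0 + (1 - pi0) * (1/m_g) sum_j sum_gamma eta_gamma
                                     sum_l lambda_l BF_{g,j,gamma,l},

and the model likelihood is the product over genes.  (pi0, eta, lambda)
are estimated by EM: the E-step computes each gene's null responsibility
and, within the eQTL branch, the posterior over (SNP, configuration, grid
point); the M-step re-normalizes the summed responsibilities.  The
log-likelihood is non-decreasing across iterations — this is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .configs import ConfigWeights
from .priors import Grid

__all__ = [
    "GeneBFBundle",
    "HMParams",
    "hm_loglik",
    "em_fit",
    "hm_confidence_intervals",
    "default_init",
]

_NEG_INF = -np.inf


@dataclass
class GeneBFBundle:
    """Per-gene log Bayes factors: shape (m_g, configurations, grid points)."""

    gene_id: str
    log_bf: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.log_bf, dtype=float)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("log_bf must be (m_g >= 1, C, L)")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"gene {self.gene_id}: non-finite log BFs")
        self.log_bf = arr

    @property
    def m_g(self) -> int:
        return self.log_bf.shape[0]


@dataclass
class HMParams:
    """Hierarchical-model parameters and fit diagnostics."""

    pi0: float
    eta: ConfigWeights
    lam: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must lie in [0, 1]")
        lam = np.asarray(self.lam, dtype=float)
        if np.any(lam < 0) or not np.isclose(lam.sum(), 1.0):
            raise ValueError("lambda must be non-negative and sum to 1")
        self.lam = lam


def default_init(configs, n_grid: int, pi0: float = 0.9) -> HMParams:
    """Uniform-weight starting point away from the parameter boundary."""
    if isinstance(configs, ConfigWeights):
        configs = configs.configs
    eta = ConfigWeights(
        configs=list(configs), eta=np.full(len(configs), 1.0 / len(configs))
    )
    return HMParams(pi0=pi0, eta=eta, lam=np.full(n_grid, 1.0 / n_grid))


def _stack(bundles: list[GeneBFBundle]) -> tuple[np.ndarray, np.ndarray]:
    """Pad bundles to (G, max_m, C, L); padding slots get log BF = -inf."""
    if not bundles:
        raise ValueError("no gene bundles")
    C, L = bundles[0].log_bf.shape[1:]
    for b in bundles:
        if b.log_bf.shape[1:] != (C, L):
            raise ValueError("inconsistent (C, L) dimensions across genes")
    m = np.array([b.m_g for b in bundles])
    G, mmax = len(bundles), int(m.max())
    stacked = np.full((G, mmax, C, L), _NEG_INF)
    for i, b in enumerate(bundles):
        stacked[i, : b.m_g] = b.log_bf
    return stacked, m


def _log_alt(stacked: np.ndarray, m: np.ndarray, eta: np.ndarray, lam: np.ndarray):
    """Per-gene log of (1/m_g) sum_{j,gamma,l} eta lambda BF, plus the
    per-(j,gamma,l) log terms needed for responsibilities."""
    with np.errstate(divide="ignore"):
        logw = np.log(eta)[None, None, :, None] + np.log(lam)[None, None, None, :]
    terms = stacked + logw - np.log(m)[:, None, None, None]
    la = logsumexp(terms.reshape(terms.shape[0], -1), axis=1)
    return la, terms


def hm_loglik(params: HMParams, bundles: list[GeneBFBundle]) -> float:
    """Log-likelihood of the hierarchical model relative to the all-null model."""
    stacked, m = _stack(bundles)
    la, _ = _log_alt(stacked, m, params.eta.eta, params.lam)
    return float(_loglik_from_la(params.pi0, la))


def _loglik_from_la(pi0: float, la: np.ndarray) -> float:
    if pi0 >= 1.0:
        return 0.0
    if pi0 <= 0.0:
        return float(la.sum())
    return float(np.logaddexp(np.log(pi0), np.log1p(-pi0) + la).sum())


def em_fit(
    bundles: list[GeneBFBundle],
    init: HMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
    fixed: set[str] | None = None,
) -> HMParams:
    """Maximum-likelihood fit of (pi0, eta, lambda) by EM.

    Parameters
    ----------
    bundles
        Per-gene log-BF tables, all with the same (configurations, grid)
        axes; the configuration order must match ``init.eta.configs``.
    init
        Starting point; defaults to pi0 = 0.9 with uniform eta and lambda
        — impossible to build without a template, so pass it when the
        bundle axes are not self-describing.
    tol
        Relative log-likelihood convergence threshold.
    fixed
        Optional subset of {"pi0", "eta", "lambda"} held at their initial
        values (e.g. freeze lambda at uniform to mimic fixed grid weights).

    Returns fitted ``HMParams`` with ``loglik_trace`` (one entry per
    iteration, non-decreasing) and a ``converged`` flag.
    """
    if len(bundles) < 2:
        raise ValueError("need at least 2 genes to fit the hierarchical model")
    fixed = set(fixed or ())
    if not fixed <= {"pi0", "eta", "lambda"}:
        raise ValueError(f"unknown entries in fixed: {fixed}")
    stacked, m = _stack(bundles)
    G, _, C, L = stacked.shape
    if init is None:
        raise ValueError("an initial HMParams (see default_init) is required")
    if len(init.eta) != C or init.lam.size != L:
        raise ValueError("init dimensions do not match the bundles")

    pi0 = float(init.pi0)
    eta = init.eta.eta.copy()
    lam = init.lam.copy()
    trace: list[float] = []
    converged = False

    for _ in range(max_iter):
        la, terms = _log_alt(stacked, m, eta, lam)
        ll = _loglik_from_la(pi0, la)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite hierarchical-model likelihood")
        if trace and ll + 1e-9 < trace[-1]:
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        if trace and abs(ll - trace[-1]) <= tol * max(abs(trace[-1]), 1.0):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

        # E-step: null responsibility r0 and, within the alternative,
        # posterior mass over (j, gamma, l).
        if pi0 >= 1.0:
            r0 = np.ones(G)
        elif pi0 <= 0.0:
            r0 = np.zeros(G)
        else:
            log_num = np.full(G, np.log(pi0))
            log_den = np.logaddexp(log_num, np.log1p(-pi0) + la)
            r0 = np.exp(log_num - log_den)
        # normalized within-alternative posterior, (G, m, C, L)
        post = np.exp(terms - la[:, None, None, None])
        alt_w = (1.0 - r0)[:, None, None, None] * post

        # M-step
        if "pi0" not in fixed:
            pi0 = float(r0.mean())
        if "eta" not in fixed:
            eta_new = alt_w.sum(axis=(0, 1, 3))
            tot = eta_new.sum()
            if tot > 0:
                eta = eta_new / tot
        if "lambda" not in fixed:
            lam_new = alt_w.sum(axis=(0, 1, 2))
            tot = lam_new.sum()
            if tot > 0:
                lam = lam_new / tot
    else:
        converged = False

    return HMParams(
        pi0=pi0,
        eta=ConfigWeights(configs=list(init.eta.configs), eta=eta),
        lam=lam,
        loglik_trace=trace,
        converged=converged,
    )


def hm_confidence_intervals(
    params: HMParams,
    bundles: list[GeneBFBundle],
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
    max_iter: int = 100,
) -> dict[str, tuple[float, float]]:
    """Percentile-bootstrap intervals for the hierarchical-model parameters.

    Genes are resampled with replacement; each replicate is refit by EM
    starting from the point estimate.  Returns a dict with keys ``"pi0"``,
    ``"eta[<label>]"`` and ``"lambda[<index>]"``.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be at least 20 for percentile intervals")
    rng = np.random.default_rng(seed)
    G = len(bundles)
    draws: dict[str, list[float]] = {"pi0": []}
    labels = [c.label() for c in params.eta.configs]
    for lab in labels:
        draws[f"eta[{lab}]"] = []
    for li in range(params.lam.size):
        draws[f"lambda[{li}]"] = []

    for _ in range(n_boot):
        idx = rng.integers(0, G, size=G)
        fit = em_fit(
            [bundles[i] for i in idx], init=params, tol=1e-5, max_iter=max_iter
        )
        draws["pi0"].append(fit.pi0)
        for lab, e in zip(labels, fit.eta.eta):
            draws[f"eta[{lab}]"].append(float(e))
        for li, lv in enumerate(fit.lam):
            draws[f"lambda[{li}]"].append(float(lv))

    alpha = (1.0 - level) / 2.0
    return {
        k: (
            float(np.quantile(v, alpha)),
            float(np.quantile(v, 1.0 - alpha)),
        )
        for k, v in draws.items()
    }
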