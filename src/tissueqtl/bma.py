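"""Bayesian model averaging over configurations and grid points.

The SNP-level test statistic against the global null is the prior-weighted
average of configuration Bayes factors,

    BF_bma = sum_gamma eta_gamma sum_l lambda_l BF(gamma; phi_l, omega_l),

and under the at-most-one-eQTL assumption the gene-level statistic is the
plain average of BF_bma over the m_g candidate SNPs in the cis window.
Conditional on the SNP being an eQTL, the posterior over configurations is
proportional to eta_gamma * sum_l lambda_l BF(gamma; l), and the
probability that the eQTL is active in tissue s sums those posteriors over
configurations with gamma_s = 1.  Everything is accumulated in log space:
in strong-signal data single BFs overflow double precision long before the
averages do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .configs import ConfigWeights, Configuration
from .priors import Grid

__all__ = [
    "PosteriorSummary",
    "log_bf_bma",
    "bf_bma",
    "log_gene_bf",
    "gene_bf",
    "config_posterior",
]


def _check_shapes(log_bf: np.ndarray, eta: ConfigWeights, grid: Grid) -> np.ndarray:
    log_bf = np.asarray(log_bf, dtype=float)
    if log_bf.shape != (len(eta), len(grid)):
        raise ValueError(
            f"log BF table shape {log_bf.shape} does not match "
            f"({len(eta)} configurations, {len(grid)} grid points)"
        )
    return log_bf


def log_bf_bma(log_bf, eta: ConfigWeights, grid: Grid) -> float:
    """Log of the configuration- and grid-averaged Bayes factor.

    ``log_bf`` is a (configurations, grid points) table of natural-log BFs
    ordered like ``eta.configs`` and ``grid.points``.
    """
    log_bf = _check_shapes(log_bf, eta, grid)
    w = eta.eta[:, None] * grid.weights[None, :]
    return float(logsumexp(log_bf, b=w))


def bf_bma(log_bf, eta: ConfigWeights, grid: Grid) -> float:
    return float(np.exp(log_bf_bma(log_bf, eta, grid)))


def log_gene_bf(log_snp_bfs) -> float:
    """Log of the mean SNP-level BF over the cis candidate SNPs."""
    log_snp_bfs = np.asarray(log_snp_bfs, dtype=float)
    if log_snp_bfs.size == 0:
        raise ValueError("empty cis SNP set")
    return float(logsumexp(log_snp_bfs) - np.log(log_snp_bfs.size))


def gene_bf(snp_bma_bfs) -> float:
    """Arithmetic mean of SNP-level BMA Bayes factors (natural scale)."""
    bfs = np.asarray(snp_bma_bfs, dtype=float)
    if bfs.size == 0:
        raise ValueError("empty cis SNP set")
    return float(bfs.mean())


@dataclass
class PosteriorSummary:
    """Posterior over configurations and marginal tissue activity.

    ``config_probs[gamma]`` is P(gamma | data, eQTL present);
    ``tissue_probs[s]`` is P(gamma_s = 1 | data, eQTL present).
    """

    configs: list[Configuration]
    config_probs: np.ndarray
    tissue_probs: np.ndarray

    def prob(self, config: Configuration) -> float:
        return float(self.config_probs[self.configs.index(config)])


def config_posterior(log_bf, eta: ConfigWeights, grid: Grid) -> PosteriorSummary:
    """Posterior configuration probabilities, conditional on an eQTL.

    P(gamma) ∝ eta_gamma * sum_l lambda_l BF(gamma; l), normalized over
    the nonzero configurations; tissue-activity probabilities are sums of
    configuration posteriors over configurations active in that tissue.
    """
    log_bf = _check_shapes(log_bf, eta, grid)
    with np.errstate(divide="ignore"):
        log_num = np.log(eta.eta) + logsumexp(log_bf, b=grid.weights[None, :], axis=1)
    if np.all(np.isneginf(log_num)):
        raise ValueError("all posterior numerators are zero")
    log_norm = logsumexp(log_num)
    probs = np.exp(log_num - log_norm)
    S = eta.configs[0].S
    tissue = np.zeros(S)
    for p, cfg in zip(probs, eta.configs):
        for s in cfg.active:
            tissue[s] += p
    return PosteriorSummary(
        configs=list(eta.configs), config_probs=probs, tissue_probs=tissue
    )
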