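"""Per-gene analysis units and the orchestration layer.

A :class:`GenePair` bundles, for one gene, the expression vector in each
tissue and the dosage matrix of its cis candidate SNPs.  Everything
downstream — Bayes-factor tables, BMA statistics, permutation p-values,
hierarchical-model bundles, and the relaxation of the one-eQTL-per-gene
assumption — operates on lists of these units, whether they come from the
synthetic generator or from files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .bf import log_bf_table
from .bma import log_bf_bma, log_gene_bf
from .configs import ConfigWeights
from .hm import GeneBFBundle, HMParams
from .priors import Grid
from .regression import ResidualCorr, batch_regression, laplace_summaries
from .significance import _regression_pvalues, gene_seed

__all__ = [
    "GenePair",
    "pairs_from_study",
    "pair_summaries",
    "gene_log_bf",
    "bundles_from_pairs",
    "gene_bma_stat",
    "gene_tbt_stat",
    "bma_permutation_pvalue",
    "tbt_permutation_pvalue",
    "per_tissue_permutation_pvalues",
    "top_snp_index",
    "relax_single_eqtl",
]


@dataclass
class GenePair:
    """One gene's expression and cis dosages across tissues.

    ``ys[s]`` is the expression vector in tissue s; ``gs[s]`` is the
    (m_g, n_s) dosage matrix over the same individuals, in the same
    order.  ``shared_individuals`` marks designs where all tissues sample
    the same individuals in the same order, which is what permits both the
    correlated-errors Bayes factors and label permutations that are
    synchronized across tissues.
    """

    gene_id: str
    snp_ids: list[str]
    ys: list[np.ndarray]
    gs: list[np.ndarray]
    shared_individuals: bool = False

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        for y, G in zip(self.ys, self.gs):
            if G.shape != (m, y.size):
                raise ValueError(
                    f"gene {self.gene_id}: dosage matrix shape {G.shape} does not "
                    f"match {m} SNPs x {y.size} individuals"
                )
        if self.shared_individuals:
            sizes = {y.size for y in self.ys}
            if len(sizes) != 1:
                raise ValueError("shared individuals require equal sample sizes")

    @property
    def m_g(self) -> int:
        return len(self.snp_ids)

    @property
    def S(self) -> int:
        return len(self.ys)


def pairs_from_study(study) -> list[GenePair]:
    """Wrap a :class:`~tissueqtl.simulate.SimStudy` (one SNP per gene)."""
    pairs = []
    shared = study.scenario.shared_individuals
    for i, gene in enumerate(study.gene_ids):
        ys = [study.expression[s][i] for s in range(study.scenario.S)]
        gs = [study.genotypes[s][i][None, :] for s in range(study.scenario.S)]
        pairs.append(
            GenePair(gene, [f"snp_{gene}"], ys, gs, shared_individuals=shared)
        )
    return pairs


def pair_summaries(
    pair: GenePair, perm: np.ndarray | None = None, method: str = "fast"
):
    """Standardized slopes and SEs, (m_g, S) each.

    ``method="fast"`` uses the quantile-normalized-t standardization
    (cheap; the permutation statistics use it).  ``method="laplace"``
    anchors each summary at the mode of the exact per-tissue likelihood
    (the high-accuracy path used for hierarchical-model bundles and
    posterior reporting).  ``perm`` optionally permutes individual labels
    (same permutation in every tissue).
    """
    m, S = pair.m_g, pair.S
    bhat = np.empty((m, S))
    se = np.empty((m, S))
    for s in range(S):
        y = pair.ys[s] if perm is None else pair.ys[s][perm]
        if method == "laplace":
            Y = np.broadcast_to(y, (m, y.size))
            bhat[:, s], se[:, s] = laplace_summaries(Y, pair.gs[s])
        elif method == "fast":
            for j in range(m):
                b, e = batch_regression(y[None, :], pair.gs[s][j])
                bhat[j, s], se[j, s] = b[0], e[0]
        else:
            raise ValueError(f"unknown summary method {method!r}")
    return bhat, se


def gene_log_bf(
    pair: GenePair,
    configs,
    grid: Grid,
    rcorr: ResidualCorr | None = None,
    method: str = "laplace",
) -> np.ndarray:
    """(m_g, C, L) log Bayes factors for one gene."""
    if rcorr is not None and not pair.shared_individuals:
        raise ValueError(
            "correlated-errors Bayes factors require tissues sampled from the "
            "same individuals"
        )
    bhat, se = pair_summaries(pair, method=method)
    return log_bf_table(bhat, se, configs, grid, rcorr=rcorr)


def bundles_from_pairs(
    pairs: list[GenePair],
    configs,
    grid: Grid,
    rcorrs: dict[str, ResidualCorr] | None = None,
) -> list[GeneBFBundle]:
    """Hierarchical-model input: one log-BF bundle per gene with m_g >= 1."""
    out = []
    for pair in pairs:
        if pair.m_g == 0:
            continue
        rc = rcorrs.get(pair.gene_id) if rcorrs else None
        out.append(GeneBFBundle(pair.gene_id, gene_log_bf(pair, configs, grid, rc)))
    return out


def gene_bma_stat(
    pair: GenePair, eta: ConfigWeights, grid: Grid,
    log_bf: np.ndarray | None = None, method: str = "fast",
) -> float:
    """Gene-level log BMA Bayes factor (mean over cis SNPs).

    The default "fast" summaries keep the statistic consistent with the
    permutation path; pass method="laplace" for reporting-grade values.
    """
    if log_bf is None:
        log_bf = gene_log_bf(pair, eta.configs, grid, method=method)
    per_snp = np.array([log_bf_bma(log_bf[j], eta, grid) for j in range(pair.m_g)])
    return log_gene_bf(per_snp)


def gene_tbt_stat(pair: GenePair) -> float:
    """Minimum regression p-value over all cis SNPs and tissues."""
    best = np.inf
    for s in range(pair.S):
        for j in range(pair.m_g):
            best = min(
                best, float(_regression_pvalues(pair.ys[s][None, :], pair.gs[s][j])[0])
            )
    return best


def _perm_matrix(n: int, n_perm: int, rng) -> np.ndarray:
    return np.vstack([rng.permutation(n) for _ in range(n_perm)])


def _tissue_perms(pair: GenePair, n_perm: int, rng) -> list[np.ndarray]:
    """One (n_perm, n_s) permutation matrix per tissue, identical across
    tissues when individuals are shared (preserving intra-individual
    correlation under the null) and independent otherwise."""
    if pair.shared_individuals:
        shared = _perm_matrix(pair.ys[0].size, n_perm, rng)
        return [shared] * pair.S
    return [_perm_matrix(y.size, n_perm, rng) for y in pair.ys]


def bma_permutation_pvalue(
    pair: GenePair,
    eta: ConfigWeights,
    grid: Grid,
    n_perm: int,
    seed: int,
) -> float:
    """Gene-level permutation p-value for the BMA statistic.

    The same label permutation is applied in every tissue (valid for
    shared-individual designs and for independent designs alike, since
    independent tissues have nothing to preserve).  Fully vectorized over
    permutations; ties count as at least as extreme.
    """
    rng = np.random.default_rng(gene_seed(seed, pair.gene_id))
    perms = _tissue_perms(pair, n_perm, rng)
    observed = gene_bma_stat(pair, eta, grid)

    # (n_perm, m_g) per-SNP log BMA for permuted labels
    log_snp = np.empty((n_perm, pair.m_g))
    w = eta.eta[:, None] * grid.weights[None, :]
    for j in range(pair.m_g):
        bhat = np.empty((n_perm, pair.S))
        se = np.empty((n_perm, pair.S))
        for s in range(pair.S):
            Yp = pair.ys[s][perms[s]]
            bhat[:, s], se[:, s] = batch_regression(Yp, pair.gs[s][j])
        lb = log_bf_table(bhat, se, eta.configs, grid)  # (n_perm, C, L)
        log_snp[:, j] = logsumexp(lb.reshape(n_perm, -1), b=w.ravel()[None, :], axis=1)
    stats = logsumexp(log_snp, axis=1) - np.log(pair.m_g)
    return (1.0 + np.sum(stats >= observed)) / (n_perm + 1.0)


def tbt_permutation_pvalue(pair: GenePair, n_perm: int, seed: int) -> float:
    """Gene-level permutation p-value for the min-p statistic (smaller is
    more extreme), permuting labels jointly across tissues."""
    rng = np.random.default_rng(gene_seed(seed, pair.gene_id))
    perms = _tissue_perms(pair, n_perm, rng)
    observed = gene_tbt_stat(pair)
    minp = np.full(n_perm, np.inf)
    for s in range(pair.S):
        Yp = pair.ys[s][perms[s]]
        for j in range(pair.m_g):
            minp = np.minimum(minp, _regression_pvalues(Yp, pair.gs[s][j]))
    return (1.0 + np.sum(minp <= observed)) / (n_perm + 1.0)


def per_tissue_permutation_pvalues(
    pair: GenePair, n_perm: int, seed: int
) -> np.ndarray:
    """Per-tissue gene-level permutation p-values for the min-p statistic,
    with permutations performed in each tissue separately."""
    out = np.empty(pair.S)
    for s in range(pair.S):
        rng = np.random.default_rng(gene_seed(seed, f"{pair.gene_id}:t{s}"))
        y = pair.ys[s]
        perms = _perm_matrix(y.size, n_perm, rng)
        obs = np.inf
        minp = np.full(n_perm, np.inf)
        for j in range(pair.m_g):
            obs = min(obs, float(_regression_pvalues(y[None, :], pair.gs[s][j])[0]))
            minp = np.minimum(minp, _regression_pvalues(y[perms], pair.gs[s][j]))
        out[s] = (1.0 + np.sum(minp <= obs)) / (n_perm + 1.0)
    return out


def top_snp_index(bundle: GeneBFBundle, params: HMParams) -> int:
    """SNP with the largest posterior probability of being the gene's eQTL."""
    with np.errstate(divide="ignore"):
        logw = (
            np.log(params.eta.eta)[None, :, None]
            + np.log(params.lam)[None, None, :]
        )
    per_snp = logsumexp(
        (bundle.log_bf + logw).reshape(bundle.m_g, -1), axis=1
    )
    return int(np.argmax(per_snp))


def relax_single_eqtl(
    pairs: list[GenePair],
    bundles: list[GeneBFBundle],
    params: HMParams,
    grid: Grid,
) -> tuple[list[GenePair], list[GeneBFBundle]]:
    """Relax the one-eQTL-per-gene assumption via residual "artificial" genes.

    For each gene, the top SNP (largest posterior probability of being the
    eQTL under the round-1 fit) is regressed out of each tissue's
    expression; the residuals define an artificial gene whose Bayes
    factors capture any *second* independent signal.  Returns the combined
    (original + artificial) pairs and bundles for a joint refit.
    """
    by_id = {b.gene_id: b for b in bundles}
    new_pairs: list[GenePair] = list(pairs)
    new_bundles: list[GeneBFBundle] = list(bundles)
    import warnings

    for pair in pairs:
        if pair.m_g == 0 or pair.gene_id not in by_id:
            warnings.warn(f"gene {pair.gene_id}: no SNPs; skipped in relaxation")
            continue
        j = top_snp_index(by_id[pair.gene_id], params)
        resid_ys = []
        for s in range(pair.S):
            y, g = pair.ys[s], pair.gs[s][j]
            gc = g - g.mean()
            ss = float(gc @ gc)
            yc = y - y.mean()
            beta = float(gc @ yc) / ss if ss > 0 else 0.0
            resid_ys.append(yc - beta * gc)
        art = replace(
            pair, gene_id=f"{pair.gene_id}::resid", ys=resid_ys
        )
        new_pairs.append(art)
        new_bundles.append(
            GeneBFBundle(art.gene_id, gene_log_bf(art, params.eta.configs, grid))
        )
    return new_pairs, new_bundles
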