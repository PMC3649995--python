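"""Gene-level significance: permutation p-values, Storey q-values, and the
tissue-by-tissue and ANOVA baselines.

The Bayes-factor statistics are calibrated by permutation of individual
labels.  When tissues share individuals the *same* permutation is applied
to every tissue, preserving intra-individual correlation under the null.
Gene-level p-values use the add-one estimator
p = (1 + #{permuted >= observed}) / (n_perm + 1), which is valid for any
number of permutations; ties count as "at least as extreme".  FDR control
across genes follows Storey's q-value procedure with the smoother-based
pi0 estimate.
"""

from __future__ import annotations

import warnings
import zlib
from itertools import product

import numpy as np
from scipy import stats

__all__ = [
    "gene_seed",
    "permutation_pvalue",
    "storey_pi0",
    "storey_qvalues",
    "call_egenes",
    "tbt_min_p",
    "anova_lr_test",
    "overlap_table",
    "pairwise_pi1",
]


def gene_seed(global_seed: int, gene_id: str) -> int:
    """Deterministic per-gene seed (stable across runs and parallel workers)."""
    h = zlib.crc32(f"{global_seed}:{gene_id}".encode())
    return int(h % (2**31 - 1))


def permutation_pvalue(
    stat_fn,
    n_individuals: int,
    n_perm: int,
    seed: int,
    larger_is_extreme: bool = True,
) -> float:
    """Permutation p-value for one gene.

    ``stat_fn`` maps an index array (a permutation of individual labels)
    to the test statistic; it must apply the same permutation to every
    tissue.  The observed statistic is ``stat_fn(identity)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    identity = np.arange(n_individuals)
    observed = float(stat_fn(identity))
    if not np.isfinite(observed):
        raise ValueError("non-finite observed statistic")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_individuals)
        s = float(stat_fn(perm))
        if not np.isfinite(s):
            raise ValueError("non-finite statistic on permuted data")
        if (s >= observed) if larger_is_extreme else (s <= observed):
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


_LAMBDA_GRID = np.arange(0.0, 0.951, 0.05)


def storey_pi0(pvalues: np.ndarray) -> float:
    """Smoother-based estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid
    lambda in {0, 0.05, ..., 0.95}; a cubic polynomial smoother is
    evaluated at the largest lambda and the result clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    pi0_lam = np.array(
        [np.sum(p > lam) / (m * (1.0 - lam)) for lam in _LAMBDA_GRID]
    )
    coef = np.polyfit(_LAMBDA_GRID, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, _LAMBDA_GRID[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(pvalues) -> tuple[np.ndarray, float]:
    """Storey q-values and the pi0 estimate.

    With fewer than 20 p-values the smoother is unreliable, so pi0 falls
    back to 1 (Benjamini-Hochberg) with a warning.  q-values are monotone
    non-decreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m < 20:
        warnings.warn("fewer than 20 p-values; using pi0 = 1 (BH)")
        pi0 = 1.0
    else:
        pi0 = storey_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out, pi0


def call_egenes(qvalues, fdr: float = 0.05) -> np.ndarray:
    """Boolean mask of genes called at q <= fdr."""
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must be in (0, 1)")
    q = np.asarray(qvalues, dtype=float)
    return q <= fdr


def _regression_pvalues(Y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Two-sided simple-regression p-values for rows of Y against g."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    g = np.asarray(g, dtype=float)
    n = g.size
    if n < 3:
        raise ValueError("need at least 3 individuals")
    gc = g - g.mean()
    ss_g = float(gc @ gc)
    if ss_g <= 0:
        raise ValueError("zero genotype variance (monomorphic SNP)")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ss_y = np.einsum("ij,ij->i", Yc, Yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (Yc @ gc) ** 2 / (ss_g * ss_y)
        r2 = np.clip(r2, 0.0, 1.0)
        f = r2 * (n - 2) / (1.0 - r2)
    return stats.f.sf(f, 1, n - 2)


def tbt_min_p(ys: list[np.ndarray], genotypes: np.ndarray) -> float:
    """Tissue-by-tissue statistic: minimum regression p over SNPs and tissues.

    ``ys`` holds one expression vector per tissue; ``genotypes`` is an
    (m_snps, n) dosage matrix (shared across tissues) or a list of such
    matrices, one per tissue.
    """
    per_tissue = (
        genotypes if isinstance(genotypes, (list, tuple)) else [genotypes] * len(ys)
    )
    best = np.inf
    for y, G in zip(ys, per_tissue):
        G = np.atleast_2d(np.asarray(G, dtype=float))
        for g in G:
            best = min(best, float(_regression_pvalues(y[None, :], g)[0]))
    if not np.isfinite(best):
        raise ValueError("no valid SNP-tissue pair")
    return best


def anova_lr_test(ys: list[np.ndarray], gs) -> tuple[float, float]:
    """F test of any genotype effect, pooling residual variance over tissues.

    The alternative allows a separate slope and intercept per tissue but a
    single error variance; the null keeps only the intercepts.  Returns
    (F, p) with S and (N - 2S) degrees of freedom.  With one tissue this
    is the usual squared-t test of the regression slope.
    """
    S = len(ys)
    if S < 1:
        raise ValueError("need at least one tissue")
    per_tissue = gs if isinstance(gs, (list, tuple)) else [gs] * S
    rss0 = rss1 = 0.0
    n_total = 0
    for y, g in zip(ys, per_tissue):
        y = np.asarray(y, dtype=float)
        g = np.asarray(g, dtype=float)
        n = y.size
        n_total += n
        gc = g - g.mean()
        ss_g = float(gc @ gc)
        if ss_g <= 0:
            raise ValueError("singular design: monomorphic SNP in a tissue")
        yc = y - y.mean()
        beta = float(gc @ yc) / ss_g
        rss0 += float(yc @ yc)
        rss1 += float(yc @ yc) - beta**2 * ss_g
    df2 = n_total - 2 * S
    if df2 <= 0 or rss1 <= 0:
        raise ValueError("singular design or saturated fit")
    F = ((rss0 - rss1) / S) / (rss1 / df2)
    return float(F), float(stats.f.sf(F, S, df2))


def overlap_table(calls: dict[str, set]) -> dict[tuple[int, ...], float]:
    """Presence/absence-pattern proportions among genes called anywhere.

    ``calls`` maps tissue -> set of called genes.  Returns, for every
    nonzero pattern over the tissue order of ``calls``, the fraction of
    union genes showing that pattern (fractions sum to 1).
    """
    tissues = list(calls)
    if len(tissues) < 2:
        raise ValueError("need calls from at least 2 tissues")
    union = set().union(*calls.values())
    out: dict[tuple[int, ...], float] = {
        pat: 0.0 for pat in product((0, 1), repeat=len(tissues)) if any(pat)
    }
    if not union:
        return out
    for gene in union:
        pat = tuple(int(gene in calls[t]) for t in tissues)
        out[pat] += 1.0
    return {pat: v / len(union) for pat, v in out.items()}


def pairwise_pi1(pvalues_in_second_tissue) -> float:
    """Sharing estimate pi1 = 1 - pi0 for eQTLs discovered in one tissue.

    Given the nominal (uncorrected) p-values, in a second tissue, of the
    best per-gene SNPs discovered in a first tissue, pi1 estimates the
    fraction that are also eQTLs in the second tissue.
    """
    p = np.asarray(pvalues_in_second_tissue, dtype=float)
    if p.size < 20:
        raise ValueError("need at least 20 discovered genes for a pi1 estimate")
    return 1.0 - storey_pi0(p)
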