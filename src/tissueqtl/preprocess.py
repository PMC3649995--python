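"""Expression preprocessing: robust-gene filtering, PC-based confounder
removal and rank-based inverse-normal transformation.

These steps mirror standard practice in cis-eQTL mapping of array data:
restrict to genes robustly expressed in every tissue, regress out leading
expression principal components to absorb unmeasured confounders, then map
each gene's values onto standard-normal quantiles so that downstream
normal-theory inference is insensitive to the measurement scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import TissueDataset

__all__ = [
    "filter_robust_genes",
    "remove_pcs",
    "quantile_normal_transform",
    "transform_dataset",
]

#: Default increment-of-variance threshold for PC selection: a principal
#: component is removed only if it explains at least this fraction of the
#: total expression variance (0.0025% = 2.5e-5).
PC_INCREMENT_THRESHOLD = 0.0025 / 100


def filter_robust_genes(datasets: list[TissueDataset]) -> set[str]:
    """Genes robustly expressed in *every* tissue.

    A gene is robustly expressed in a tissue when its mean expression
    across individuals is >= the median of all expression values (all
    genes, all individuals) in that tissue.  The returned set is the
    intersection over tissues.
    """
    if not datasets:
        raise ValueError("need at least one tissue dataset")
    universe = set(datasets[0].genes)
    for ds in datasets[1:]:
        universe &= set(ds.genes)
    if not universe:
        raise ValueError("empty intersection of gene universes across tissues")

    passing = universe
    for ds in datasets:
        values = ds.expr.to_numpy(dtype=float)
        global_median = float(np.median(values))
        means = ds.expr.mean(axis=1)
        ok = set(means.index[means >= global_median])
        passing = passing & ok
    return passing


def remove_pcs(
    dataset: TissueDataset,
    increment_threshold: float = PC_INCREMENT_THRESHOLD,
) -> tuple[TissueDataset, int]:
    """Regress leading expression PCs out of every gene.

    PCA is run on the gene x individual matrix of one tissue (genes as
    variables, individuals as the component space).  Components are kept,
    in decreasing order of explained variance, for as long as the next one
    still explains at least ``increment_threshold`` of the total variance;
    the selected components are then regressed out of each gene's
    expression and the residuals returned.

    Returns the residual dataset and the number of PCs removed.
    """
    if not (0 < increment_threshold <= 1):
        raise ValueError("increment_threshold must be in (0, 1]")
    X = dataset.expr.to_numpy(dtype=float)
    n_ind = X.shape[1]
    if n_ind < 2:
        raise ValueError("need more than one individual")

    Xc = X - X.mean(axis=1, keepdims=True)
    # Right singular vectors live in individual space; squared singular
    # values give the variance decomposition.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        return TissueDataset(dataset.tissue_id, dataset.expr * 0.0), 0
    props = s**2 / total
    k = int(np.sum(props >= increment_threshold))
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(k, rank)
    if k == 0:
        return TissueDataset(dataset.tissue_id, dataset.expr.copy()), 0

    pcs = vt[:k]  # (k, individuals), orthonormal
    resid = Xc - (Xc @ pcs.T) @ pcs
    resid += X.mean(axis=1, keepdims=True)
    out = pd.DataFrame(resid, index=dataset.expr.index, columns=dataset.expr.columns)
    return TissueDataset(dataset.tissue_id, out), k


def quantile_normal_transform(values) -> np.ndarray:
    """Map values onto standard-normal quantiles by rank.

    Uses the offset-by-half grid Phi^-1((rank - 0.5)/n) with average ranks
    for ties.  The output is strictly monotone in the input for untied
    values and symmetric about zero.  An all-equal input degenerates to
    all zeros (with a warning).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    if np.ptp(x) == 0:
        warnings.warn("all values equal; rank-normal transform degenerates to zeros")
        return np.zeros(n)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def transform_dataset(dataset: TissueDataset) -> TissueDataset:
    """Apply the rank-normal transform to every gene of a tissue."""
    out = np.vstack(
        [quantile_normal_transform(row) for row in dataset.expr.to_numpy(dtype=float)]
    )
    return TissueDataset(
        dataset.tissue_id,
        pd.DataFrame(out, index=dataset.expr.index, columns=dataset.expr.columns),
    )
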