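"""Expression preprocessing and the file-based cis mapping workflow.

Builds a small expression matrix with a confounding component, applies
the robust-gene filter, principal-component removal and the rank-based
inverse-normal transform, then pairs genes with cis SNPs from a dosage
table via the 1 Mb window.
"""

import numpy as np
import pandas as pd

from tissueqtl import (
    TissueDataset,
    GenotypeTable,
    build_cismap,
    filter_robust_genes,
    quantile_normal_transform,
    remove_pcs,
)
from tissueqtl.data import SnpRecord

rng = np.random.default_rng(0)
n_genes, n_ind = 40, 30
batch = rng.normal(size=n_ind)  # unmeasured confounder shared by genes
expr = (
    rng.normal(size=(n_genes, n_ind))
    + 2.0 * np.outer(rng.normal(size=n_genes), batch)
    + np.linspace(0, 4, n_genes)[:, None]  # expression-level gradient
)
ds = TissueDataset(
    "LCL",
    pd.DataFrame(expr, index=[f"g{i}" for i in range(n_genes)],
                 columns=[f"ind{j}" for j in range(n_ind)]),
)

robust = filter_robust_genes([ds])
print(f"robust genes (mean >= global median): {len(robust)} of {n_genes}")

resid, k = remove_pcs(ds.subset_genes(sorted(robust)), increment_threshold=0.01)
print(f"principal components removed at a 1% increment threshold: {k}")

y = resid.expr.iloc[0].to_numpy()
z = quantile_normal_transform(y)
print(f"rank-normalized gene 1: mean {z.mean():.2e}, sd {z.std():.3f}")

snps = [SnpRecord(f"rs{i}", "chr1", 1_000_000 * (i + 1)) for i in range(5)]
dos = pd.DataFrame(rng.binomial(2, 0.3, size=(5, n_ind)).astype(float),
                   index=[s.id for s in snps], columns=resid.expr.columns)
coords = pd.DataFrame(
    {"chrom": "chr1", "tss": [1_500_000] * len(resid.expr)},
    index=resid.expr.index,
)
cis = build_cismap(coords, GenotypeTable(snps=snps, dosages=dos))
print(f"cis SNPs within 1 Mb of the shared TSS: {cis.snps[resid.expr.index[0]]}")
print("(each gene is then tested against exactly these candidate SNPs)")
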