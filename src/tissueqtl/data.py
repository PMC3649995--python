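"""Core in-memory containers for multi-tissue eQTL analysis.

A *tissue dataset* is a gene x individual expression matrix for one tissue.
A *genotype table* is a SNP x individual dosage matrix (0..2 copies of the
reference allele) with genomic coordinates.  Both are thin, validated
wrappers around pandas DataFrames so that downstream code can rely on
aligned, unique labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TissueDataset", "GenotypeTable", "SnpRecord"]


@dataclass
class TissueDataset:
    """Expression levels for one tissue.

    Parameters
    ----------
    tissue_id
        Label for the tissue (e.g. ``"LCL"``).
    expr
        DataFrame of shape (genes, individuals); index = gene IDs,
        columns = individual IDs.  All values must be finite.
    """

    tissue_id: str
    expr: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.expr, pd.DataFrame):
            self.expr = pd.DataFrame(self.expr)
        if self.expr.shape[1] < 3:
            raise ValueError(
                f"tissue {self.tissue_id!r}: need at least 3 individuals, "
                f"got {self.expr.shape[1]}"
            )
        if not self.expr.index.is_unique:
            raise ValueError(f"tissue {self.tissue_id!r}: duplicate gene IDs")
        if not self.expr.columns.is_unique:
            raise ValueError(f"tissue {self.tissue_id!r}: duplicate sample IDs")
        values = self.expr.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"tissue {self.tissue_id!r}: non-finite expression values")

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def n_individuals(self) -> int:
        return self.expr.shape[1]

    def subset_genes(self, genes) -> "TissueDataset":
        return TissueDataset(self.tissue_id, self.expr.loc[list(genes)])


@dataclass(frozen=True)
class SnpRecord:
    id: str
    chrom: str
    pos: int  # 1-based

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: position must be a positive integer")


@dataclass
class GenotypeTable:
    """Dosage matrix for a set of SNPs.

    ``dosages`` has SNP IDs as index and individual IDs as columns; values
    lie in [0, 2] (allele counts or imputed dosages).  Missing genotypes are
    NaN and are dropped pairwise by the regression layer.
    """

    snps: list[SnpRecord]
    dosages: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.dosages, pd.DataFrame):
            self.dosages = pd.DataFrame(self.dosages)
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP IDs")
        if list(self.dosages.index) != ids:
            raise ValueError("dosage rows must match SNP records in order")
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def samples(self) -> pd.Index:
        return self.dosages.columns

    def dosage(self, snp_id: str) -> pd.Series:
        return self.dosages.loc[snp_id]
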