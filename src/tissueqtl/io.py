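"""Readers and writers for the standard formats, and cis-window pairing.

Genotypes come from VCF (dosages from the DS FORMAT field when present,
otherwise counted from GT) or from a plain dosage TSV; expression matrices
are gene x sample TSVs paired with a BED file of gene coordinates.  All
genomic positions are normalized internally to 0-based (VCF POS is 1-based
on disk, BED is already 0-based half-open).  The cis candidate region of a
gene is every SNP within ``window`` bases of its transcription start site,
boundary inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeTable, SnpRecord, TissueDataset

__all__ = [
    "CisMap",
    "read_genotypes",
    "read_expression",
    "build_cismap",
    "write_dosage_tsv",
    "write_hm_params",
    "read_hm_params",
]

CIS_WINDOW = 1_000_000


@dataclass
class CisMap:
    """Gene -> cis candidate SNPs within ``window`` bases of the TSS.

    ``tss`` maps gene -> (chrom, 0-based TSS position); ``snps`` maps
    gene -> list of SNP IDs (possibly empty).
    """

    tss: dict[str, tuple[str, int]]
    snps: dict[str, list[str]]
    window: int = CIS_WINDOW

    def m_g(self, gene: str) -> int:
        return len(self.snps.get(gene, []))


def _vcf_genotypes(path: str) -> tuple[list[SnpRecord], pd.DataFrame]:
    import pysam

    records: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(
                    f"skipping multi-allelic or ALT-less site at "
                    f"{rec.chrom}:{rec.pos}"
                )
                continue
            dos = np.full(len(samples), np.nan)
            for i, sample in enumerate(samples):
                call = rec.samples[sample]
                if "DS" in call and call["DS"] is not None:
                    dos[i] = float(call["DS"])
                else:
                    gt = call.get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    dos[i] = float(sum(gt))
            rid = rec.id or f"{rec.chrom}:{rec.pos}"
            records.append(SnpRecord(id=rid, chrom=rec.chrom, pos=rec.pos))
            rows.append(dos)
    dosages = pd.DataFrame(
        rows, index=[r.id for r in records], columns=samples, dtype=float
    )
    return records, dosages


def _tsv_genotypes(path: str) -> tuple[list[SnpRecord], pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    required = {"id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"dosage TSV must have columns {sorted(required)} + samples")
    records = [
        SnpRecord(id=str(r.id), chrom=str(r.chrom), pos=int(r.pos))
        for r in df.itertuples()
    ]
    sample_cols = [c for c in df.columns if c not in required]
    dosages = df.set_index("id")[sample_cols].astype(float)
    return records, dosages


def read_genotypes(path: str, format: str = "vcf") -> GenotypeTable:
    """Load a genotype table from a VCF or a dosage TSV.

    The dosage TSV layout is ``id  chrom  pos  <sample1> <sample2> ...``
    with 1-based positions, matching :func:`write_dosage_tsv`.
    """
    if format == "vcf":
        records, dosages = _vcf_genotypes(path)
    elif format == "dosage_tsv":
        records, dosages = _tsv_genotypes(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return GenotypeTable(snps=records, dosages=dosages)


def write_dosage_tsv(table: GenotypeTable, path: str) -> None:
    df = table.dosages.copy()
    df.insert(0, "pos", [s.pos for s in table.snps])
    df.insert(0, "chrom", [s.chrom for s in table.snps])
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression(
    expr_path: str, bed_path: str, tissue_id: str | None = None
) -> tuple[TissueDataset, pd.DataFrame]:
    """Load a gene x sample expression TSV plus gene coordinates from BED.

    The BED file is 0-based half-open with columns
    chrom, start, end, name[, score, strand]; the TSS is the start
    coordinate for + strand genes and the end coordinate for - strand
    genes.  Genes present in the expression matrix must appear in the BED.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    if not expr.index.is_unique:
        raise ValueError(f"{expr_path}: duplicated gene IDs")
    bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = bed.shape[1]
    names = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
    bed.columns = names
    if "name" not in bed.columns:
        raise ValueError(f"{bed_path}: BED must have at least 4 columns")
    if "strand" not in bed.columns:
        bed["strand"] = "+"
    bed = bed.set_index("name")
    missing = set(expr.index) - set(bed.index)
    if missing:
        raise ValueError(f"genes missing from BED: {sorted(missing)[:5]} ...")
    coords = bed.loc[list(expr.index)]
    tss = np.where(coords["strand"] == "-", coords["end"], coords["start"])
    gene_coords = pd.DataFrame(
        {"chrom": coords["chrom"], "tss": tss.astype(int), "strand": coords["strand"]},
        index=expr.index,
    )
    if tissue_id is None:
        tissue_id = expr_path
    return TissueDataset(tissue_id, expr), gene_coords


def build_cismap(
    gene_coords: pd.DataFrame,
    genotypes: GenotypeTable,
    window: int = CIS_WINDOW,
) -> CisMap:
    """Pair each gene with the SNPs within ``window`` bases of its TSS.

    Boundary inclusive: a SNP at exactly ``window`` bases is a candidate.
    ``gene_coords`` needs columns chrom and tss (0-based, as produced by
    :func:`read_expression`).
    """
    tmp: dict[str, list] = {}
    for s in genotypes.snps:
        chrom = tmp.setdefault(s.chrom, [[], []])
        chrom[0].append(s.pos - 1)  # 1-based VCF -> 0-based internal
        chrom[1].append(s.id)
    sorted_chrom = {}
    for c, (pos, ids) in tmp.items():
        pos = np.asarray(pos)
        order = np.argsort(pos, kind="stable")
        sorted_chrom[c] = (pos[order], [ids[i] for i in order])

    tss_map: dict[str, tuple[str, int]] = {}
    snp_map: dict[str, list[str]] = {}
    for gene, row in gene_coords.iterrows():
        chrom, tss = str(row["chrom"]), int(row["tss"])
        tss_map[gene] = (chrom, tss)
        if chrom not in sorted_chrom:
            snp_map[gene] = []
            continue
        pos, ids = sorted_chrom[chrom]
        lo = np.searchsorted(pos, tss - window, side="left")
        hi = np.searchsorted(pos, tss + window, side="right")
        snp_map[gene] = ids[lo:hi]
    return CisMap(tss=tss_map, snps=snp_map, window=window)


def write_hm_params(params, path: str) -> None:
    """Serialize fitted hierarchical-model parameters as key: value lines."""
    lines = [f"pi0: {params.pi0:.10g}"]
    for cfg, e in zip(params.eta.configs, params.eta.eta):
        lines.append(f"eta[{cfg.label()}]: {e:.10g}")
    for i, lv in enumerate(params.lam):
        lines.append(f"lambda[{i}]: {lv:.10g}")
    lines.append(f"converged: {params.converged}")
    lines.append(f"n_iterations: {len(params.loglik_trace)}")
    if params.loglik_trace:
        lines.append(f"loglik: {params.loglik_trace[-1]:.10g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_hm_params(path: str) -> dict[str, float | bool | int]:
    out: dict[str, float | bool | int] = {}
    with open(path) as fh:
        for line in fh:
            key, _, val = line.strip().partition(": ")
            if not key:
                continue
            if val in ("True", "False"):
                out[key] = val == "True"
            else:
                out[key] = float(val)
    return out
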