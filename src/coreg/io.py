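"""Readers and writers for the pipeline's on-disk formats.

VCF (genotypes, via cyvcf2 on read), GTEx-style expression BED, a
covariate-by-sample TSV and the truth-table JSON.  Internal coordinates are
0-based half-open; VCF positions convert on read/write.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panels import CovariateMatrix, ExpressionPanel, GenotypePanel

logger = logging.getLogger(__name__)

_BED_FIXED = ["#chr", "start", "end", "gene_id"]


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal diploid hard-call VCF (CHROM/POS/ID/REF/ALT + GT)."""
    dos = panel.dosages
    if not np.all(np.isin(dos, (0.0, 1.0, 2.0))):
        raise ValueError("write_vcf requires hard-call dosages in {0, 1, 2}")
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for j, v in panel.variants.iterrows():
            calls = "\t".join(gt[d] for d in dos[:, j])
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\t.\t.\tGT\t{calls}\n")


def read_vcf(path, maf_min: float = 0.01) -> GenotypePanel:
    """Parse GT fields into an additive dosage matrix.

    Multi-allelic records are split into one biallelic row per ALT allele;
    variants below ``maf_min`` are dropped (counted in the log); missing
    genotypes are mean-imputed per variant with missingness logged.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns, rows = [], []
    n_dropped = n_missing = 0
    for var in vcf:
        gts = np.array([g[:2] for g in var.genotypes], dtype=np.int32)
        for k, alt in enumerate(var.ALT, start=1):
            missing = (gts < 0).any(axis=1)
            dos = (gts == k).sum(axis=1).astype(np.float64)
            if missing.any():
                n_missing += int(missing.sum())
                known = dos[~missing]
                dos[missing] = known.mean() if known.size else 0.0
            af = dos.mean() / 2.0
            maf = min(af, 1.0 - af)
            if maf < maf_min:
                n_dropped += 1
                continue
            vid = var.ID if var.ID and len(var.ALT) == 1 else f"{var.CHROM}_{var.POS}_{var.REF}_{alt}"
            rows.append(
                {"chrom": var.CHROM, "pos": var.POS, "id": vid,
                 "ref": var.REF, "alt": alt, "maf": float(maf)}
            )
            columns.append(dos)
    if n_dropped:
        logger.info("read_vcf: dropped %d variants below MAF %.3g", n_dropped, maf_min)
    if n_missing:
        logger.info("read_vcf: mean-imputed %d missing genotype calls", n_missing)
    dosages = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypePanel(samples=samples, dosages=dosages, variants=pd.DataFrame(rows))


def write_expression_bed(panel: ExpressionPanel, path) -> None:
    """GTEx-style BED: #chr, start, end, gene_id, strand, then sample columns."""
    df = pd.DataFrame(
        {
            "#chr": panel.genes["chrom"],
            "start": panel.genes["start"],
            "end": panel.genes["end"],
            "gene_id": panel.genes["gene_id"],
            "strand": panel.genes["strand"],
        }
    )
    values = pd.DataFrame(panel.values.T, columns=panel.samples)
    out = pd.concat([df.reset_index(drop=True), values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_expression_bed(path) -> ExpressionPanel:
    """Read a GTEx-style expression BED (optional strand column).

    Coordinates are 0-based half-open.  With a strand column the TSS is
    start for '+' and end for '-'; without one the TSS falls back to start
    (with a warning), the GTEx convention of TSS-encoded starts.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if cols[:4] != _BED_FIXED:
        raise ValueError(f"expression BED must start with columns {_BED_FIXED}, got {cols[:4]}")
    has_strand = len(cols) > 4 and cols[4] == "strand"
    sample_cols = cols[5:] if has_strand else cols[4:]
    if has_strand:
        strand = df["strand"].astype(str)
    else:
        logger.warning("expression BED has no strand column; using TSS = start")
        strand = pd.Series(["+"] * len(df))
    tss = np.where(strand.to_numpy() == "-", df["end"].to_numpy(), df["start"].to_numpy())
    genes = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["#chr"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": strand,
            "tss": tss.astype(int),
        }
    )
    values = df[sample_cols].to_numpy(dtype=np.float64).T
    return ExpressionPanel(samples=list(sample_cols), values=values, genes=genes)


def write_covariates_tsv(cov: CovariateMatrix, path) -> None:
    """Covariate x sample TSV (first column 'id' holds covariate names)."""
    df = pd.DataFrame(cov.values.T, index=pd.Index(cov.names, name="id"), columns=cov.samples)
    df.to_csv(path, sep="\t")


def read_covariates_tsv(path) -> CovariateMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CovariateMatrix(
        samples=list(df.columns),
        names=list(df.index),
        values=df.to_numpy(dtype=np.float64).T,
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
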