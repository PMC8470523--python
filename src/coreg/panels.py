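"""Core in-memory containers shared by every pipeline stage.

Coordinates are 0-based half-open internally; the ``pos`` column of a
:class:`GenotypePanel` variant table is the 1-based VCF position (converted
on read/write by :mod:`coreg.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "maf"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


@dataclass
class GenotypePanel:
    """Sample x variant dosage matrix with variant coordinates and MAF.

    dosages are additive alt-allele counts in {0, 1, 2} (float after
    mean-imputation of missing calls).  ``variants`` has columns
    chrom, pos (1-based), id, ref, alt, maf.
    """

    samples: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        dup = self.variants.duplicated(subset=["chrom", "pos", "alt"])
        if dup.any():
            raise ValueError(
                "duplicate (chrom, pos, alt) variants: "
                + ", ".join(self.variants.loc[dup, "id"].astype(str).head(5))
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_samples(self, indices: np.ndarray | list[int]) -> "GenotypePanel":
        """Panel restricted to ``indices`` (emulates per-tissue donor subsets)."""
        indices = np.asarray(indices)
        return GenotypePanel(
            samples=[self.samples[i] for i in indices],
            dosages=self.dosages[indices],
            variants=self.variants.copy(),
        )


@dataclass
class ExpressionPanel:
    """Sample x gene expression matrix with gene coordinates.

    ``genes`` has columns gene_id, chrom, start, end, strand, tss with
    tss = start for '+' strand genes and end for '-' strand genes
    (0-based body interval [start, end)).
    """

    samples: list[str]
    values: np.ndarray
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"expression matrix {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def subset_samples(self, indices: np.ndarray | list[int]) -> "ExpressionPanel":
        indices = np.asarray(indices)
        return ExpressionPanel(
            samples=[self.samples[i] for i in indices],
            values=self.values[indices],
            genes=self.genes.copy(),
        )


@dataclass
class CovariateMatrix:
    """Known covariates (sex, platform, expression factors, ...).

    Stored sample-major for regression convenience; serialized
    covariate x sample, the GTEx covariate-file orientation.
    """

    samples: list[str]
    names: list[str]
    values: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.samples), len(self.names)):
            raise ValueError(
                f"covariate matrix {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.names)} covariates"
            )

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def subset_samples(self, indices: np.ndarray | list[int]) -> "CovariateMatrix":
        indices = np.asarray(indices)
        return CovariateMatrix(
            samples=[self.samples[i] for i in indices],
            names=list(self.names),
            values=self.values[indices],
        )


def align_samples(
    genotypes: GenotypePanel,
    expression: ExpressionPanel,
    covariates: CovariateMatrix | None = None,
):
    """Intersect sample ids and return panels in a common sample order.

    Order follows the genotype panel.  Raises ``ValueError`` when the
    intersection is empty.
    """
    expr_index = {s: i for i, s in enumerate(expression.samples)}
    cov_index = {s: i for i, s in enumerate(covariates.samples)} if covariates else None
    keep: list[int] = []
    for i, s in enumerate(genotypes.samples):
        if s in expr_index and (cov_index is None or s in cov_index):
            keep.append(i)
    if not keep:
        raise ValueError("no overlapping samples between genotype and expression panels")
    geno = genotypes.subset_samples(keep)
    expr = expression.subset_samples([expr_index[genotypes.samples[i]] for i in keep])
    cov = (
        covariates.subset_samples([cov_index[genotypes.samples[i]] for i in keep])
        if covariates is not None
        else None
    )
    return geno, expr, cov
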