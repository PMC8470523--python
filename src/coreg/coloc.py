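"""Pairwise approximate-Bayes-factor colocalization of two cis-eQTL signals.

For each variant shared by two genes' cis windows, a Wakefield approximate
Bayes factor is computed from the regression slope, its variance and the
phenotype SD (quantitative-trait prior SD = 0.15 * sdY).  Per-hypothesis
evidence is accumulated in log space:

  H0 no association, H1/H2 one gene only, H3 two distinct causal variants,
  H4 one shared causal variant.

Priors: p1 and p2 are the two genes' own nominal significance thresholds;
p12 = min(5e-6, p1, p2).  A pair with no shared variants gets H4 := 0
(reported as PP0 = 1 with an explicit no-overlap flag so "not testable" is
never confused with "tested and rejected").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

P12_DEFAULT = 5e-6
WAKEFIELD_SD_FRACTION = 0.15


@dataclass
class ColocInput:
    """One gene's side of a colocalization test."""

    gene_id: str
    variant_ids: np.ndarray
    slope: np.ndarray
    varbeta: np.ndarray
    sdY: float
    nominal_threshold: float

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids)
        self.slope = np.asarray(self.slope, dtype=np.float64)
        self.varbeta = np.asarray(self.varbeta, dtype=np.float64)
        if np.any(self.varbeta <= 0):
            raise ValueError(f"{self.gene_id}: slope variances must be positive")
        if not self.sdY > 0:
            raise ValueError(f"{self.gene_id}: sdY must be positive")

    @classmethod
    def from_associations(
        cls, gene_id: str, assoc: pd.DataFrame, sdY: float, nominal_threshold: float
    ) -> "ColocInput":
        sub = assoc[assoc["gene_id"] == gene_id]
        return cls(
            gene_id=gene_id,
            variant_ids=sub["variant_id"].to_numpy(),
            slope=sub["slope"].to_numpy(),
            varbeta=sub["slope_se"].to_numpy() ** 2,
            sdY=sdY,
            nominal_threshold=nominal_threshold,
        )


@dataclass
class ColocRecord:
    gene_a: str
    gene_b: str
    tissue: str | int = ""
    region_id: str = ""
    n_overlap_variants: int = 0
    p1: float = np.nan
    p2: float = np.nan
    p12: float = np.nan
    pp0: float = np.nan
    pp1: float = np.nan
    pp2: float = np.nan
    pp3: float = np.nan
    pp4: float = np.nan
    no_overlap: bool = False
    lead_variant_id: str | None = None
    lead_slope_a: float = np.nan
    lead_slope_b: float = np.nan
    extra: dict = field(default_factory=dict)

    @property
    def h4(self) -> float:
        return self.pp4

    def to_row(self) -> dict:
        return {
            "gene_a": self.gene_a,
            "gene_b": self.gene_b,
            "tissue": self.tissue,
            "region_id": self.region_id,
            "n_overlap_variants": self.n_overlap_variants,
            "p1": self.p1,
            "p2": self.p2,
            "p12": self.p12,
            "pp0": self.pp0,
            "pp1": self.pp1,
            "pp2": self.pp2,
            "pp3": self.pp3,
            "pp4": self.pp4,
            "no_overlap": self.no_overlap,
            "lead_variant_id": self.lead_variant_id,
            "lead_slope_a": self.lead_slope_a,
            "lead_slope_b": self.lead_slope_b,
        }


def compute_labf(slope, varbeta, sdY: float) -> np.ndarray:
    """Log Wakefield approximate Bayes factor for a quantitative trait.

    With z^2 = slope^2 / varbeta, prior effect variance W = (0.15 * sdY)^2
    and shrinkage r = W / (W + varbeta):  labf = 0.5 * (log(1 - r) + r z^2).
    """
    slope = np.asarray(slope, dtype=np.float64)
    varbeta = np.asarray(varbeta, dtype=np.float64)
    if np.any(varbeta <= 0):
        raise ValueError("varbeta must be positive")
    if not sdY > 0:
        raise ValueError("sdY must be positive")
    w = (WAKEFIELD_SD_FRACTION * sdY) ** 2
    r = w / (w + varbeta)
    z2 = slope * slope / varbeta
    return 0.5 * (np.log1p(-r) + r * z2)


def choose_priors(
    threshold_a: float, threshold_b: float, p12_default: float = P12_DEFAULT
) -> tuple[float, float, float]:
    """Gene-specific priors: p1/p2 are the genes' own nominal thresholds,
    p12 the default lowered to min(p1, p2) when either is smaller."""
    p1, p2 = float(threshold_a), float(threshold_b)
    if not (p1 > 0 and p2 > 0):
        raise ValueError("nominal thresholds must be positive to serve as priors")
    return p1, p2, min(p12_default, p1, p2)


def coloc_abf(
    input_a: ColocInput,
    input_b: ColocInput,
    priors: tuple[float, float, float] | None = None,
    tissue: str | int = "",
    region_id: str = "",
) -> ColocRecord:
    """Posterior probabilities PP0-PP4 for one gene pair over shared variants.

    All per-hypothesis sums are evaluated with log-sum-exp; H3's
    sum-over-distinct-pairs is exp(L1 + L2) - exp(L12) computed stably.
    """
    if priors is None:
        priors = choose_priors(input_a.nominal_threshold, input_b.nominal_threshold)
    p1, p2, p12 = priors
    rec = ColocRecord(
        gene_a=input_a.gene_id, gene_b=input_b.gene_id, tissue=tissue,
        region_id=region_id, p1=p1, p2=p2, p12=p12,
    )
    ids_a = {v: i for i, v in enumerate(input_a.variant_ids)}
    shared = [(ids_a[v], j) for j, v in enumerate(input_b.variant_ids) if v in ids_a]
    rec.n_overlap_variants = len(shared)
    if not shared:
        rec.no_overlap = True
        rec.pp0, rec.pp1, rec.pp2, rec.pp3, rec.pp4 = 1.0, 0.0, 0.0, 0.0, 0.0
        return rec
    ia = np.array([i for i, _ in shared])
    ib = np.array([j for _, j in shared])
    labf1 = compute_labf(input_a.slope[ia], input_a.varbeta[ia], input_a.sdY)
    labf2 = compute_labf(input_b.slope[ib], input_b.varbeta[ib], input_b.sdY)
    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    l12 = logsumexp(labf1 + labf2)
    diff = l12 - (l1 + l2)
    if diff >= 0:
        if diff > 1e-9:
            logger.warning("numerically impossible L12 > L1 + L2 (diff=%.3g); clamping H3", diff)
        l3 = -np.inf
    else:
        l3 = l1 + l2 + np.log1p(-np.exp(diff))
    logw = np.array(
        [
            0.0,
            np.log(p1) + l1,
            np.log(p2) + l2,
            np.log(p1) + np.log(p2) + l3,
            np.log(p12) + l12,
        ]
    )
    pp = np.exp(logw - logsumexp(logw))
    rec.pp0, rec.pp1, rec.pp2, rec.pp3, rec.pp4 = (float(v) for v in pp)
    lead = int(np.argmax(labf1 + labf2))
    # tie-break at the lower genomic position == lower index (variants are
    # position-sorted within a region); np.argmax already takes the first.
    rec.lead_variant_id = str(input_a.variant_ids[ia[lead]])
    rec.lead_slope_a = float(input_a.slope[ia[lead]])
    rec.lead_slope_b = float(input_b.slope[ib[lead]])
    return rec


def coloc_all_pairs(
    inputs: dict[str, ColocInput],
    genes: list[str] | None = None,
    p12_default: float = P12_DEFAULT,
    tissue: str | int = "",
    region_id: str = "",
) -> list[ColocRecord]:
    """Colocalize every unordered gene pair of a candidate region."""
    genes = sorted(inputs) if genes is None else sorted(genes)
    records = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            a, b = inputs[ga], inputs[gb]
            priors = choose_priors(a.nominal_threshold, b.nominal_threshold, p12_default)
            records.append(coloc_abf(a, b, priors, tissue=tissue, region_id=region_id))
    return records
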