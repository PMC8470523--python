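"""Characterization of co-regulated pairs and clusters.

Covers: gene-body overlap classes and distances, effect-direction
concordance at the jointly best shared variant, cross-tissue pair sharing,
haploinsufficiency-list overlap with off-target enumeration, and the
sample-size regression report statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def classify_overlap(
    body_a: tuple[int, int], body_b: tuple[int, int]
) -> tuple[str, int | None]:
    """Overlap class of two half-open gene-body intervals.

    'full' when one interval contains the other, 'partial' when they
    intersect without containment, else 'non_overlapping' with the gap
    between the nearest body ends (touching intervals have distance 0).
    """
    (s1, e1), (s2, e2) = body_a, body_b
    if e1 <= s1 or e2 <= s2:
        raise ValueError("gene bodies must be non-empty half-open intervals")
    if (s1 <= s2 and e2 <= e1) or (s2 <= s1 and e1 <= e2):
        return "full", None
    if s1 < e2 and s2 < e1:
        return "partial", None
    return "non_overlapping", max(s1 - e2, s2 - e1)


def direction_concordance(lead_slope_a: float, lead_slope_b: float) -> str:
    """'same' iff the two slopes at the shared lead variant have equal sign."""
    return "same" if np.sign(lead_slope_a) == np.sign(lead_slope_b) else "opposite"


def tss_distance(tss_a: int, tss_b: int) -> int:
    return abs(tss_a - tss_b)


def annotate_pairs(
    coloc_df: pd.DataFrame,
    genes: pd.DataFrame,
    h4_cut: float = 0.8,
    distance_mode: str = "body_gap",
) -> pd.DataFrame:
    """One annotation row per co-regulated pair per tissue.

    ``coloc_df`` is the record table from the colocalization stage (rows
    with pp4 >= h4_cut are kept); ``genes`` supplies bodies and TSS.
    ``distance_mode`` 'body_gap' (default) or 'tss' switches the distance
    definition for non-overlapping pairs.
    """
    gene_info = genes.set_index("gene_id")
    rows = []
    sig = coloc_df[coloc_df["pp4"] >= h4_cut]
    for row in sig.itertuples(index=False):
        ga, gb = sorted((row.gene_a, row.gene_b))
        a, b = gene_info.loc[ga], gene_info.loc[gb]
        overlap, dist = classify_overlap(
            (int(a["start"]), int(a["end"])), (int(b["start"]), int(b["end"]))
        )
        if distance_mode == "tss" and overlap == "non_overlapping":
            dist = tss_distance(int(a["tss"]), int(b["tss"]))
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "tissue": row.tissue,
                "h4": row.pp4,
                "overlap_class": overlap,
                "distance_bp": dist,
                "direction": direction_concordance(row.lead_slope_a, row.lead_slope_b),
                "lead_variant_id": row.lead_variant_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "tissue", "h4", "overlap_class",
            "distance_bp", "direction", "lead_variant_id",
        ],
    )


def pair_catalog(annotations: pd.DataFrame) -> pd.DataFrame:
    """Unique pairs across tissues with tissue lists and per-class stats."""
    if annotations.empty:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "n_tissues", "tissues", "overlap_class", "distance_bp"]
        )
    grouped = annotations.groupby(["gene_a", "gene_b"], as_index=False).agg(
        n_tissues=("tissue", "nunique"),
        tissues=("tissue", lambda s: ",".join(str(t) for t in sorted(set(s)))),
        overlap_class=("overlap_class", "first"),
        distance_bp=("distance_bp", "first"),
    )
    return grouped


@dataclass
class HaploinsufficiencyReport:
    hi_genes_in_clusters: set = field(default_factory=set)
    clusters_affected: set = field(default_factory=set)  # frozensets of gene ids
    off_target_genes: dict = field(default_factory=dict)  # cluster -> set of non-HI genes
    unmatched_symbols: set = field(default_factory=set)

    @property
    def n_off_target(self) -> int:
        return len(set().union(*self.off_target_genes.values())) if self.off_target_genes else 0

    def summary(self, hi_list_size: int | None = None) -> dict:
        return {
            "n_hi_genes_in_clusters": len(self.hi_genes_in_clusters),
            "n_hi_list": hi_list_size,
            "n_clusters_affected": len(self.clusters_affected),
            "n_off_target_genes": self.n_off_target,
        }


def load_hi_list(paths, alias_map: dict[str, str] | None = None) -> set[str]:
    """Union of one-symbol-per-line gene lists, deduplicated, aliases applied."""
    genes: set[str] = set()
    for path in paths:
        with open(path) as fh:
            for line in fh:
                sym = line.strip()
                if sym and not sym.startswith("#"):
                    genes.add((alias_map or {}).get(sym, sym))
    return genes


def haploinsufficiency_overlap(
    cluster_gene_sets, hi_list: set[str], known_genes: set[str] | None = None
) -> HaploinsufficiencyReport:
    """Which haploinsufficiency genes sit in clusters, and their off-targets.

    ``cluster_gene_sets`` is any iterable of gene-id sets (typically the
    catalog's unique gene sets).  Symbols absent from ``known_genes`` (when
    given) are reported as unmatched, never silently dropped.
    """
    report = HaploinsufficiencyReport()
    if known_genes is not None:
        report.unmatched_symbols = set(hi_list) - known_genes
        if report.unmatched_symbols:
            logger.info(
                "%d haploinsufficiency symbols not present in the expression annotation",
                len(report.unmatched_symbols),
            )
    for cluster in {frozenset(c) for c in cluster_gene_sets}:
        hit = cluster & hi_list
        if hit:
            report.hi_genes_in_clusters |= hit
            report.clusters_affected.add(cluster)
            report.off_target_genes[cluster] = set(cluster - hi_list)
    return report


def sample_size_regression(
    n_samples, counts, split_n: int | None = None
) -> pd.DataFrame:
    """OLS of a per-tissue count on tissue sample size.

    Returns one row per stratum ('all', and '< split' / '>= split' when a
    split point is given) with slope, intercept, r2 and the two-sided p.
    """
    n_samples = np.asarray(n_samples, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if n_samples.size != counts.size or n_samples.size < 2:
        raise ValueError("need >= 2 matched (sample size, count) points")
    strata = {"all": np.ones_like(n_samples, dtype=bool)}
    if split_n is not None:
        strata[f"<{split_n}"] = n_samples < split_n
        strata[f">={split_n}"] = n_samples >= split_n
    rows = []
    for name, mask in strata.items():
        if mask.sum() < 2:
            continue
        x, y = n_samples[mask], counts[mask]
        if np.allclose(y, y[0]) or np.allclose(x, x[0]):
            slope, intercept, r2, p = 0.0, float(y.mean()), 0.0, 1.0
        else:
            fit = stats.linregress(x, y)
            slope, intercept, r2, p = fit.slope, fit.intercept, fit.rvalue**2, fit.pvalue
        rows.append(
            {"stratum": name, "n_points": int(mask.sum()), "slope": slope,
             "intercept": intercept, "r2": r2, "p_value": p}
        )
    return pd.DataFrame(rows, columns=["stratum", "n_points", "slope", "intercept", "r2", "p_value"])
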