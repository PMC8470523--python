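"""End-to-end pipeline: eqtl -> regions -> coloc -> clusters -> annotate -> report.

Each stage writes a TSV plus a JSON provenance sidecar (parameters, seed,
counts).  The ``simulate`` entry point emits a full synthetic study with a
truth table; ``verify`` scores recovered pairs and clusters against it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import clusters as cl
from . import coloc as co
from . import eqtl
from . import io as cio
from .panels import align_samples
from .simulate import TruthTable, default_study_config, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    beds: list[str] = field(default_factory=list)
    covs: list[str] = field(default_factory=list)
    tissue_labels: list[str] = field(default_factory=list)
    hi_list: str | None = None
    outdir: str = "coreg_out"
    window_bp: int = 1_000_000
    maf_min: float = 0.01
    n_perm_min: int = 1000
    n_perm_max: int = 10000
    lambda_: float = 0.85
    q_cut: float = 0.05
    merge_bp: int = 2_000_000
    p12: float = 5e-6
    h4_cut: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_bp", "maf_min", "n_perm_min", "n_perm_max",
                     "lambda_", "q_cut", "merge_bp", "p12", "h4_cut"):
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be positive")
        if not self.tissue_labels:
            self.tissue_labels = [f"tissue{i}" for i in range(len(self.beds))]
        if len(self.beds) != len(self.covs) or len(self.beds) != len(self.tissue_labels):
            raise ValueError("beds, covs and tissue_labels must have equal length")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_provenance(path: Path, stage: str, config: PipelineConfig, counts: dict) -> None:
    payload = {"stage": stage, "parameters": asdict(config), "counts": counts}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def simulate_to_dir(outdir, seed: int = 0, n_samples: int = 300, n_tissues: int = 2) -> Path:
    """Write the stock synthetic study (VCF, BEDs, covariates, truth JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = default_study_config(seed=seed, n_samples=n_samples, n_tissues=n_tissues)
    geno, tissues, truth = simulate_study(config)
    cio.write_vcf(geno, out / "genotypes.vcf")
    for t, (expr, cov) in enumerate(tissues):
        cio.write_expression_bed(expr, out / f"expression_tissue{t}.bed")
        cio.write_covariates_tsv(cov, out / f"covariates_tissue{t}.tsv")
    truth.to_json(out / "truth.json")
    (out / "sim_provenance.json").write_text(
        json.dumps({"seed": seed, "n_samples": n_samples, "n_tissues": n_tissues}, indent=1)
    )
    return out


def run_tissue(genotypes, expression, covariates, config: PipelineConfig, tissue, seed: int):
    """All per-tissue stages; returns a dict of result tables/records."""
    geno, expr, cov = align_samples(genotypes, expression, covariates)
    summaries, nominal, evariants = eqtl.map_tissue(
        geno, expr, cov,
        window_bp=config.window_bp,
        n_perm_min=config.n_perm_min,
        n_perm_max=config.n_perm_max,
        q_cut=config.q_cut,
        lambda_=config.lambda_,
        seed=seed,
    )
    regions = cl.find_candidate_regions(evariants, geno.variants, merge_bp=config.merge_bp)
    # residualized expression SD per gene feeds the coloc sdY
    yr = eqtl.residualize(expr.values, cov)
    sdy = {g: float(yr[:, i].std(ddof=1)) for i, g in enumerate(expr.genes["gene_id"])}
    thresholds = summaries.set_index("gene_id")["nominal_threshold"] if not summaries.empty else pd.Series(dtype=float)
    records: list[co.ColocRecord] = []
    clusters: list[cl.RegulatoryCluster] = []
    for region in regions:
        inputs = {}
        for gid in sorted(region.member_genes):
            thr = float(thresholds.get(gid, np.nan))
            if not np.isfinite(thr) or thr <= 0:
                logger.info("skipping %s in %s: no usable nominal threshold", gid, region.region_id)
                continue
            inputs[gid] = co.ColocInput.from_associations(gid, nominal, sdy[gid], thr)
        if len(inputs) < 2:
            continue
        recs = co.coloc_all_pairs(
            inputs, p12_default=config.p12, tissue=tissue, region_id=region.region_id
        )
        records.extend(recs)
        clusters.extend(
            cl.clusters_from_records(recs, tissue=tissue, region_id=region.region_id, h4_cut=config.h4_cut)
        )
    return {
        "summaries": summaries,
        "nominal": nominal,
        "evariants": evariants,
        "regions": regions,
        "coloc": records,
        "clusters": clusters,
        "genes": expr.genes,
        "n_samples": geno.n_samples,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage for every tissue and write the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes = cio.read_vcf(config.vcf, maf_min=config.maf_min)
    tissue_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                    np.random.SeedSequence(config.seed).spawn(len(config.beds))]
    all_coloc_rows = []
    per_tissue_clusters: dict[str, list] = {}
    tissue_stats = []
    genes_frames = []
    for t, label in enumerate(config.tissue_labels):
        expression = cio.read_expression_bed(config.beds[t])
        covariates = cio.read_covariates_tsv(config.covs[t])
        res = run_tissue(genotypes, expression, covariates, config, label, tissue_seeds[t])
        tdir = out / label
        tdir.mkdir(exist_ok=True)
        cio.write_table(res["summaries"], tdir / "egenes.tsv")
        cio.write_table(res["evariants"], tdir / "evariants.tsv")
        region_df = pd.DataFrame(
            [
                {"region_id": r.region_id, "chrom": r.chrom, "start": r.start, "end": r.end,
                 "n_variants": len(r.member_variants), "genes": ",".join(sorted(r.member_genes))}
                for r in res["regions"]
            ],
            columns=["region_id", "chrom", "start", "end", "n_variants", "genes"],
        )
        cio.write_table(region_df, tdir / "regions.tsv")
        coloc_df = pd.DataFrame([r.to_row() for r in res["coloc"]],
                                columns=list(co.ColocRecord(gene_a="", gene_b="").to_row()))
        cio.write_table(coloc_df, tdir / "coloc.tsv")
        all_coloc_rows.append(coloc_df)
        per_tissue_clusters[label] = res["clusters"]
        genes_frames.append(res["genes"])
        n_egenes = int(res["summaries"]["is_egene"].sum()) if len(res["summaries"]) else 0
        tissue_stats.append(
            {"tissue": label, "n_samples": res["n_samples"], "n_genes": len(res["genes"]),
             "n_egenes": n_egenes, "n_evariants": len(res["evariants"]),
             "n_regions": len(res["regions"]), "n_clusters": len(res["clusters"])}
        )
        _write_provenance(tdir / "provenance.json", "per_tissue", config, tissue_stats[-1])

    catalog = cl.dedupe_and_compare(per_tissue_clusters)
    cio.write_table(catalog.to_frame(), out / "clusters.tsv")
    unique_df = pd.DataFrame(
        sorted({",".join(sorted(s)) for s in catalog.unique_gene_sets()}), columns=["genes"]
    )
    cio.write_table(unique_df, out / "unique_clusters.tsv")
    catalog.sharing_matrix().to_csv(out / "tissue_sharing.tsv", sep="\t")
    cio.write_table(catalog.size_histograms(), out / "cluster_sizes.tsv")

    coloc_all = (
        pd.concat(all_coloc_rows, ignore_index=True)
        if all_coloc_rows
        else pd.DataFrame(columns=list(co.ColocRecord(gene_a="", gene_b="").to_row()))
    )
    genes_all = pd.concat(genes_frames, ignore_index=True).drop_duplicates("gene_id")
    annotations = ann.annotate_pairs(coloc_all, genes_all, h4_cut=config.h4_cut)
    cio.write_table(annotations, out / "pairs.tsv")
    cio.write_table(ann.pair_catalog(annotations), out / "unique_pairs.tsv")

    summary: dict = {"tissues": tissue_stats,
                     "n_unique_clusters": len(catalog.unique_gene_sets()),
                     "n_unique_pairs": int(len(ann.pair_catalog(annotations)))}
    stats_df = pd.DataFrame(tissue_stats)
    if len(stats_df) >= 2:
        reg = ann.sample_size_regression(stats_df["n_samples"], stats_df["n_egenes"])
        summary["egene_sample_size_regression"] = reg.to_dict(orient="records")
    if config.hi_list:
        hi = ann.load_hi_list([config.hi_list])
        report = ann.haploinsufficiency_overlap(
            catalog.unique_gene_sets(), hi, known_genes=set(genes_all["gene_id"])
        )
        hi_rows = [
            {"cluster": ",".join(sorted(c)), "hi_genes": ",".join(sorted(c & hi)),
             "off_target_genes": ",".join(sorted(report.off_target_genes[c]))}
            for c in sorted(report.clusters_affected, key=lambda c: sorted(c))
        ]
        cio.write_table(pd.DataFrame(hi_rows, columns=["cluster", "hi_genes", "off_target_genes"]),
                        out / "hi_report.tsv")
        summary["haploinsufficiency"] = report.summary(hi_list_size=len(hi))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    _write_provenance(out / "provenance.json", "pipeline", config, {"n_tissues": len(config.beds)})
    return out


def verify(outdir, truth_path, tissue_labels: list[str] | None = None) -> dict:
    """Score recovered pairs and clusters against a simulation truth table.

    Pair calls are compared tissue-blind on unique gene pairs (a recovered
    pair is correct if planted in any tissue); clusters likewise on unique
    gene sets.  Directions are compared per planted pair where recovered.
    """
    out = Path(outdir)
    truth = TruthTable.from_json(truth_path)
    pairs_df = pd.read_csv(out / "pairs.tsv", sep="\t")
    found_pairs = (
        {frozenset((a, b)) for a, b in zip(pairs_df["gene_a"], pairs_df["gene_b"])}
        if len(pairs_df)
        else set()
    )
    true_pairs = truth.all_unique_pairs()
    tp = len(found_pairs & true_pairs)
    pair_precision = tp / len(found_pairs) if found_pairs else float("nan")
    pair_recall = tp / len(true_pairs) if true_pairs else float("nan")

    clusters_df = pd.read_csv(out / "unique_clusters.tsv", sep="\t")
    found_clusters = (
        {frozenset(g.split(",")) for g in clusters_df["genes"]} if len(clusters_df) else set()
    )
    true_clusters = truth.all_unique_clusters()
    ctp = len(found_clusters & true_clusters)
    cluster_precision = ctp / len(found_clusters) if found_clusters else float("nan")
    cluster_recall = ctp / len(true_clusters) if true_clusters else float("nan")

    # direction agreement on recovered true pairs (any tissue)
    truth_dir: dict[frozenset, str] = {}
    for d in truth.pairs.values():
        truth_dir.update(d)
    n_dir = n_dir_ok = 0
    for row in pairs_df.itertuples(index=False):
        key = frozenset((row.gene_a, row.gene_b))
        if key in truth_dir:
            n_dir += 1
            n_dir_ok += int(row.direction == truth_dir[key])
    result = {
        "pair_precision": pair_precision,
        "pair_recall": pair_recall,
        "cluster_precision": cluster_precision,
        "cluster_recall": cluster_recall,
        "direction_agreement": (n_dir_ok / n_dir) if n_dir else float("nan"),
        "n_found_pairs": len(found_pairs),
        "n_true_pairs": len(true_pairs),
        "n_found_clusters": len(found_clusters),
        "n_true_clusters": len(true_clusters),
    }
    (out / "verify.json").write_text(json.dumps(result, indent=1, sort_keys=True))
    return result


def run_synthetic_study(workdir, seed: int = 0, n_samples: int = 300, n_tissues: int = 2,
                        hi_list: str | None = None) -> tuple[Path, dict]:
    """Convenience: simulate, run the pipeline, verify. Returns (outdir, scores)."""
    workdir = Path(workdir)
    data = simulate_to_dir(workdir / "data", seed=seed, n_samples=n_samples, n_tissues=n_tissues)
    config = PipelineConfig(
        vcf=str(data / "genotypes.vcf"),
        beds=[str(data / f"expression_tissue{t}.bed") for t in range(n_tissues)],
        covs=[str(data / f"covariates_tissue{t}.tsv") for t in range(n_tissues)],
        tissue_labels=[f"tissue{t}" for t in range(n_tissues)],
        hi_list=hi_list,
        outdir=str(workdir / "results"),
        seed=seed,
    )
    out = run_pipeline(config)
    scores = verify(out, data / "truth.json")
    return out, scores
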