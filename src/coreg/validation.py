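"""Calibration and power experiments on planted synthetic data.

These routines quantify how well each stage behaves under known truth:
uniformity of permutation-calibrated empirical p-values on null genes,
realized false-discovery proportion and power of the eGene call,
colocalization discrimination between shared and distinct causal variants,
and exact recovery of planted clusters by the full per-tissue pipeline.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import eqtl
from .annotate import annotate_pairs
from .coloc import ColocInput, coloc_abf
from .pipeline import PipelineConfig, run_tissue
from .simulate import (
    PlantedGene,
    simulate_study,
    SimConfig,
    default_study_config,
    simulate_expression,
    simulate_genotypes,
)


def null_calibration(
    n_genes: int = 200,
    n_samples: int = 300,
    n_variants: int = 50,
    ld_rho: float = 0.9,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation calibration on null genes sharing one LD-structured region.

    Returns per-gene empirical_p_direct / empirical_p_beta plus the best
    nominal p; under the null the beta-extrapolated empirical p-values are
    Uniform(0, 1).
    """
    ss = np.random.SeedSequence(seed).spawn(n_genes + 2)
    config = SimConfig(n_samples=n_samples, n_variants_per_region=n_variants,
                       maf_range=(0.05, 0.5), ld_rho=ld_rho, seed=seed)
    geno = simulate_genotypes(config, rng=np.random.default_rng(ss[0]))
    x = geno.dosages - geno.dosages.mean(axis=0)
    dof = n_samples - 2
    ygen = np.random.default_rng(ss[1])
    rows = []
    for i in range(n_genes):
        y = ygen.standard_normal(n_samples)
        y -= y.mean()
        _, _, _, p, _ = eqtl._assoc_stats(x, y, dof)
        res = eqtl.permutation_pass(x, y, dof, float(p.min()),
                                    rng=np.random.default_rng(ss[2 + i]),
                                    n_perm_min=n_perm, n_perm_max=n_perm)
        rows.append({"gene": i, "best_nominal_p": float(p.min()),
                     "empirical_p_direct": res.empirical_p_direct,
                     "empirical_p_beta": res.empirical_p_beta})
    df = pd.DataFrame(rows)
    df.attrs["ks_uniform_p"] = float(stats.kstest(df["empirical_p_beta"], "uniform").pvalue)
    df.attrs["median_abs_diff"] = float(
        (df["empirical_p_beta"] - df["empirical_p_direct"]).abs().median()
    )
    return df


def _fdr_layout(n_true: int, n_null: int, effect: float, n_variants: int,
                spacing: int) -> tuple[PlantedGene, ...]:
    """True and null genes tiled over shared regions (10 true per region)."""
    per_region = 10
    n_regions = (n_true + per_region - 1) // per_region
    from .simulate import REGION_GAP_BP

    genes: list[PlantedGene] = []
    nulls_per_region = (n_null + n_regions - 1) // n_regions
    for r in range(n_regions):
        base = r * (n_variants * spacing + REGION_GAP_BP)
        for i in range(per_region):
            g = r * per_region + i
            if g >= n_true:
                break
            cv = (i * (n_variants // per_region) + 2) % n_variants
            tss = base + cv * spacing + 10_000 + i * 22_000
            genes.append(PlantedGene(gene_id=f"true_{g}", region_index=r, tss_bp=tss,
                                     body=(tss, tss + 20_000), causal_variant_index=cv,
                                     effect_size=effect))
        for i in range(nulls_per_region):
            g = r * nulls_per_region + i
            if g >= n_null:
                break
            tss = base + 1_000 + i * 22_000
            genes.append(PlantedGene(gene_id=f"null_{g}", region_index=r, tss_bp=tss,
                                     body=(tss, tss + 20_000)))
    return tuple(genes)


def fdr_experiment(
    n_tissues: int = 20,
    n_true: int = 100,
    n_null: int = 400,
    effect: float = 0.8,
    n_samples: int = 300,
    seed: int = 0,
) -> dict:
    """Realized false-eGene proportion and power of the Q < 0.05 call.

    Each "tissue" is an independent study of n_true planted and n_null null
    genes; thresholds additionally yield the lead-variant nominal pass rate.
    """
    layout = _fdr_layout(n_true, n_null, effect, n_variants=50, spacing=5_000)
    n_regions = max(g.region_index for g in layout) + 1
    fp = tp = calls = lead_pass = lead_total = 0
    for t in range(n_tissues):
        tissue_seed = int(np.random.SeedSequence([seed, t]).generate_state(1)[0] % 2**31)
        config = SimConfig(n_samples=n_samples, n_variants_per_region=50,
                           n_regions=n_regions, maf_range=(0.05, 0.5), ld_rho=0.9,
                           gene_layout=layout, n_covariates=3, seed=tissue_seed)
        geno = simulate_genotypes(config)
        expr, cov, truth = simulate_expression(geno, config, tissue=0)
        summaries, nominal, _ = eqtl.map_tissue(geno, expr, cov, seed=tissue_seed)
        egenes = set(summaries.loc[summaries["is_egene"], "gene_id"])
        true_set = truth.egenes[0]
        calls += len(egenes)
        fp += len(egenes - true_set)
        tp += len(egenes & true_set)
        # per-gene nominal threshold check on the true genes' lead variants
        sig = summaries[summaries["is_egene"] & summaries["gene_id"].isin(true_set)]
        lead_total += len(sig)
        lead_pass += int((sig["best_nominal_p"] < sig["nominal_threshold"]).sum())
    return {
        "fdp": fp / calls if calls else 0.0,
        "power": tp / (n_true * n_tissues),
        "lead_variant_pass_rate": lead_pass / lead_total if lead_total else float("nan"),
        "n_calls": calls,
        "n_tissues": n_tissues,
    }


def _pair_coloc(geno, config, priors=(1e-4, 1e-4, 5e-6)):
    expr, cov, _ = simulate_expression(geno, config, tissue=0)
    nominal = eqtl.nominal_pass(geno, expr, cov)
    yr = eqtl.residualize(expr.values, cov)
    inputs = {}
    for i, gid in enumerate(expr.genes["gene_id"]):
        inputs[gid] = ColocInput.from_associations(
            gid, nominal, sdY=float(yr[:, i].std(ddof=1)), nominal_threshold=priors[0]
        )
    gids = list(expr.genes["gene_id"])
    return coloc_abf(inputs[gids[0]], inputs[gids[1]], priors)


def _low_ld_pair(geno, r2_max: float = 0.2, min_sep: int = 10) -> tuple[int, int]:
    """A variant index pair with genotype LD r^2 below ``r2_max``."""
    m = geno.n_variants
    corr = np.corrcoef(geno.dosages.T)
    for sep in range(m - 1, min_sep - 1, -1):
        for i in range(m - sep):
            if corr[i, i + sep] ** 2 < r2_max:
                return i, i + sep
    raise RuntimeError(f"no variant pair with LD r^2 < {r2_max}")


def coloc_discrimination(
    n_reps: int = 50,
    effect: float = 0.8,
    n_samples: int = 300,
    n_variants: int = 50,
    ld_rho: float = 0.9,
    seed: int = 0,
) -> dict:
    """Shared- vs distinct-causal discrimination of the ABF colocalization.

    Shared pairs (one causal variant, both genes) should reach PP4 >= 0.8;
    distinct pairs with causal LD r^2 < 0.2 should favour PP3 over PP4.
    """
    shared_hits = distinct_hits = 0
    shared_pp4, distinct_pp3 = [], []
    for rep in range(n_reps):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31)
        base = SimConfig(n_samples=n_samples, n_variants_per_region=n_variants,
                         maf_range=(0.05, 0.5), ld_rho=ld_rho, seed=rep_seed)
        geno = simulate_genotypes(base)

        shared_layout = _two_gene_layout(n_variants, 25, 25, effect)
        rec = _pair_coloc(geno, replace(base, gene_layout=shared_layout))
        shared_pp4.append(rec.pp4)
        shared_hits += rec.pp4 >= 0.8

        ia, ib = _low_ld_pair(geno)
        distinct_layout = _two_gene_layout(n_variants, ia, ib, effect)
        rec = _pair_coloc(geno, replace(base, gene_layout=distinct_layout))
        distinct_pp3.append(rec.pp3)
        distinct_hits += rec.pp3 > rec.pp4
    return {
        "shared_pp4_rate": shared_hits / n_reps,
        "distinct_pp3_rate": distinct_hits / n_reps,
        "mean_shared_pp4": float(np.mean(shared_pp4)),
        "mean_distinct_pp3": float(np.mean(distinct_pp3)),
        "n_reps": n_reps,
    }


def _two_gene_layout(n_variants: int, cv_a: int, cv_b: int, effect: float):
    shared = cv_a == cv_b
    genes = []
    for i, cv in enumerate((cv_a, cv_b)):
        tss = cv * 5_000 + 20_000 + i * 25_000
        genes.append(PlantedGene(gene_id=f"g{i}", region_index=0, tss_bp=tss,
                                 body=(tss, tss + 20_000), causal_variant_index=cv,
                                 effect_size=effect,
                                 cluster_label="shared" if shared else None))
    return tuple(genes)


def cluster_recovery(n_reps: int = 50, n_samples: int = 300, seed: int = 0) -> dict:
    """Exact recovery of the stock study's planted clusters by the full pipeline.

    Runs both tissues of the default two-tissue study in memory per
    replicate and scores: exact gene-set recovery of each planted cluster,
    precision of pair calls, and the labelled direction of the planted
    opposite pair.
    """
    params = PipelineConfig()
    cluster_found: dict[frozenset, int] = {}
    pair_tp = pair_calls = 0
    oppo_seen = oppo_correct = 0
    for rep in range(n_reps):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31)
        config = default_study_config(seed=rep_seed, n_samples=n_samples)
        geno, tissues, truth = simulate_study(config)
        found_sets: set[frozenset] = set()
        found_pairs: set[frozenset] = set()
        for t, (expr, cov) in enumerate(tissues):
            res = run_tissue(geno, expr, cov, params, tissue=t, seed=rep_seed + t)
            for c in res["clusters"]:
                found_sets.add(c.gene_ids)
            coloc_df = pd.DataFrame([r.to_row() for r in res["coloc"]])
            if len(coloc_df):
                ann_df = annotate_pairs(coloc_df, res["genes"], h4_cut=params.h4_cut)
                for row in ann_df.itertuples(index=False):
                    found_pairs.add(frozenset((row.gene_a, row.gene_b)))
                    if {row.gene_a, row.gene_b} == {"oppo_g0", "oppo_g1"}:
                        oppo_seen += 1
                        oppo_correct += row.direction == "opposite"
        true_pairs = truth.all_unique_pairs()
        pair_calls += len(found_pairs)
        pair_tp += len(found_pairs & true_pairs)
        for c in truth.all_unique_clusters():
            cluster_found[c] = cluster_found.get(c, 0) + (c in found_sets)
    recovery = {",".join(sorted(c)): hits / n_reps for c, hits in cluster_found.items()}
    return {
        "cluster_recovery": recovery,
        "min_cluster_recovery": min(recovery.values()),
        "pair_precision": pair_tp / pair_calls if pair_calls else float("nan"),
        "opposite_label_rate": oppo_correct / oppo_seen if oppo_seen else float("nan"),
        "n_reps": n_reps,
    }
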