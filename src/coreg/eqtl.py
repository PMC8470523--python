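"""Per-tissue cis-eQTL mapping with permutation calibration.

Workflow (one tissue):

1. residualize expression and dosages on the covariates (projection is
   equivalent to including the covariates in the regression),
2. nominal pass — per gene, Pearson correlation of residualized expression
   against every variant within +/- 1 Mbp of the TSS, t-statistic with
   dof = n - 2 - n_covariates,
3. adaptive permutation pass ("permute 1000 10000") — the minimum nominal p
   over the cis window per permutation, a Beta(a, b) maximum-likelihood fit
   to those minima, and the beta-extrapolated empirical p-value
   BetaCDF(best nominal p; a, b),
4. Storey q-values (single lambda = 0.85) and the Q < 0.05 eGene call,
5. a tissue-wide empirical p-value threshold converted per gene through the
   inverse beta CDF into a nominal significance threshold; associations
   below their gene's threshold are the significant eVariants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # perfect-fit floor, avoids NaN propagation
SE_FLOOR = 1e-12


@dataclass
class PermutationResult:
    perm_count: int
    perm_hits: int
    beta_shape1: float
    beta_shape2: float
    empirical_p_direct: float
    empirical_p_beta: float
    beta_mle_converged: bool


def residualize(matrix: np.ndarray, covariates=None) -> np.ndarray:
    """Project sample x k columns onto the orthocomplement of [1, covariates].

    Raises ``ValueError`` naming collinear columns when the design is
    rank-deficient.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if covariates is None or covariates.n_covariates == 0:
        return matrix - matrix.mean(axis=0, keepdims=True)
    design = np.column_stack([np.ones(n), covariates.values])
    names = ["intercept", *covariates.names]
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        raise ValueError(
            "rank-deficient covariates; collinear columns: "
            + ", ".join(np.array(names)[bad])
        )
    return matrix - q @ (q.T @ matrix)


def cis_window(gene: pd.Series, variants: pd.DataFrame, window_bp: int = 1_000_000) -> np.ndarray:
    """Indices of variants on the gene's chromosome within +/- window_bp of the TSS.

    The boundary is closed (a variant exactly window_bp away is included);
    strand affects only which gene end is the TSS.
    """
    pos0 = variants["pos"].to_numpy() - 1  # 0-based
    mask = (variants["chrom"].to_numpy() == gene["chrom"]) & (
        np.abs(pos0 - gene["tss"]) <= window_bp
    )
    return np.flatnonzero(mask)


def _assoc_stats(xr: np.ndarray, yr: np.ndarray, dof: int):
    """Slope, SE, r and two-sided p for residualized dosages xr (n x m) vs yr (n,)."""
    sxx = np.einsum("ij,ij->j", xr, xr)
    syy = float(yr @ yr)
    sxy = xr.T @ yr
    valid = sxx > 0
    r = np.zeros_like(sxy)
    np.divide(sxy, np.sqrt(sxx * syy), out=r, where=valid & (syy > 0))
    r = np.clip(r, -1.0, 1.0)
    r2 = r * r
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(dof / np.maximum(1.0 - r2, 1e-32))
        slope = np.where(valid, sxy / np.where(valid, sxx, 1.0), 0.0)
        sigma2 = np.maximum(syy - slope * sxy, 0.0) / dof
        se = np.sqrt(np.where(valid, sigma2 / np.where(valid, sxx, 1.0), np.inf))
    se = np.maximum(se, SE_FLOOR)
    p = np.maximum(2.0 * stats.t.sf(np.abs(tstat), dof), P_FLOOR)
    return slope, se, r, p, valid


def nominal_pass(genotypes, expression, covariates=None, window_bp: int = 1_000_000) -> pd.DataFrame:
    """All local gene-variant association statistics for one tissue.

    Returns one row per (gene, cis variant): gene_id, variant_id, slope,
    slope_se, dof, nominal_p, maf.  Zero-variance residualized dosages are
    skipped and counted in the log.
    """
    n = genotypes.n_samples
    k = covariates.n_covariates if covariates is not None else 0
    dof = n - 2 - k
    if dof < 1:
        raise ValueError(f"not enough samples: n={n}, covariates={k} leaves dof={dof}")
    yr = residualize(expression.values, covariates)
    xr = residualize(genotypes.dosages, covariates)
    frames = []
    n_skipped = 0
    var_ids = genotypes.variants["id"].to_numpy()
    var_maf = genotypes.variants["maf"].to_numpy()
    for gi, gene in expression.genes.iterrows():
        idx = cis_window(gene, genotypes.variants, window_bp)
        if idx.size == 0:
            continue
        slope, se, r, p, valid = _assoc_stats(xr[:, idx], yr[:, gi], dof)
        n_skipped += int((~valid).sum())
        keep = valid
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene["gene_id"],
                    "variant_id": var_ids[idx][keep],
                    "slope": slope[keep],
                    "slope_se": se[keep],
                    "dof": dof,
                    "nominal_p": p[keep],
                    "maf": var_maf[idx][keep],
                }
            )
        )
    if n_skipped:
        logger.info("nominal pass: skipped %d zero-variance dosage columns", n_skipped)
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "variant_id", "slope", "slope_se", "dof", "nominal_p", "maf"]
        )
    return pd.concat(frames, ignore_index=True)


def _min_p_from_max_r2(max_r2: np.ndarray, dof: int) -> np.ndarray:
    t = np.sqrt(max_r2 * dof / np.maximum(1.0 - max_r2, 1e-32))
    return np.maximum(2.0 * stats.t.sf(t, dof), P_FLOOR)


def _fit_beta(minp: np.ndarray) -> tuple[float, float, bool]:
    """Beta(a, b) MLE on permutation minimum p-values, method-of-moments fallback."""
    x = np.clip(minp, 1e-300, 1.0 - 1e-16)
    mean, var = float(x.mean()), float(x.var())
    if var <= 0:
        return 1.0, 1.0, False
    common = mean * (1.0 - mean) / var - 1.0
    a_mom, b_mom = max(mean * common, 1e-6), max((1.0 - mean) * common, 1e-6)
    try:
        a, b, _, _ = stats.beta.fit(x, a_mom, b_mom, floc=0.0, fscale=1.0)
        if np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0:
            return float(a), float(b), True
    except Exception:  # noqa: BLE001 - any MLE failure falls back to moments
        pass
    logger.warning("beta MLE failed to converge; using method-of-moments estimates")
    return a_mom, b_mom, False


def permutation_pass(
    xr_cis: np.ndarray,
    yr: np.ndarray,
    dof: int,
    best_nominal_p: float,
    rng: np.random.Generator,
    n_perm_min: int = 1000,
    n_perm_max: int = 10000,
    batch: int = 500,
) -> PermutationResult:
    """Adaptive permutation calibration for one gene.

    Permutes the residualized phenotype (covariate structure is then
    exchangeable under the null), records the minimum nominal p over the
    gene's cis variants per permutation, and stops early once at least
    ``n_perm_min`` permutations have produced >= 100 hits (permutation
    minima at or below the observed best p); otherwise runs to
    ``n_perm_max``.  A Beta(a, b) fit to the minima yields the
    beta-extrapolated empirical p-value.
    """
    sxx = np.einsum("ij,ij->j", xr_cis, xr_cis)
    valid = sxx > 0
    if not valid.any():
        raise ValueError("no polymorphic cis variants for permutation pass")
    x = xr_cis[:, valid]
    denom = np.sqrt(sxx[valid])
    syy = float(yr @ yr)
    minp_all = []
    hits = 0
    count = 0
    while count < n_perm_max:
        size = min(batch, n_perm_max - count)
        yperm = np.tile(yr, (size, 1))
        rng.permuted(yperm, axis=1, out=yperm)
        # r^2 per (perm, variant); max over variants <=> min nominal p
        num = yperm @ x
        r2 = (num / denom) ** 2 / syy
        minp = _min_p_from_max_r2(np.clip(r2.max(axis=1), 0.0, 1.0), dof)
        minp_all.append(minp)
        hits += int((minp <= best_nominal_p).sum())
        count += size
        if count >= n_perm_min and hits >= 100:
            break
    minp_sample = np.concatenate(minp_all)
    a, b, converged = _fit_beta(minp_sample)
    emp_beta = float(np.clip(stats.beta.cdf(best_nominal_p, a, b), P_FLOOR, 1.0 - 1e-16))
    return PermutationResult(
        perm_count=count,
        perm_hits=hits,
        beta_shape1=a,
        beta_shape2=b,
        empirical_p_direct=(hits + 1) / (count + 1),
        empirical_p_beta=emp_beta,
        beta_mle_converged=converged,
    )


def qvalues(pvals, lambda_: float = 0.85) -> tuple[np.ndarray, float]:
    """Storey q-values with a single lambda for the pi0 estimate.

    pi0 = #{p > lambda} / (m * (1 - lambda)) capped at 1; a zero count is
    guarded by the 1/(m * (1 - lambda)) floor.  Returns q-values in the
    input order plus pi0.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        raise ValueError("qvalues requires at least one p-value")
    m = p.size
    n_above = int((p > lambda_).sum())
    if n_above == 0:
        logger.warning("no p-values above lambda=%.2f; treating the count as 1", lambda_)
    pi0 = min(1.0, max(n_above, 1) / (m * (1.0 - lambda_)))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def permutation_summaries(
    genotypes,
    expression,
    covariates=None,
    window_bp: int = 1_000_000,
    n_perm_min: int = 1000,
    n_perm_max: int = 10000,
    seed: int = 0,
    nominal: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Nominal + permutation pass for every gene; one summary row per gene.

    Per-gene RNG streams are spawned from ``seed`` in gene order, so
    results do not depend on the adaptive stopping of other genes.
    """
    if nominal is None:
        nominal = nominal_pass(genotypes, expression, covariates, window_bp)
    n = genotypes.n_samples
    k = covariates.n_covariates if covariates is not None else 0
    dof = n - 2 - k
    yr = residualize(expression.values, covariates)
    xr = residualize(genotypes.dosages, covariates)
    best = (
        nominal.loc[nominal.groupby("gene_id")["nominal_p"].idxmin()]
        .set_index("gene_id")
        if len(nominal)
        else pd.DataFrame()
    )
    children = np.random.SeedSequence(seed).spawn(expression.n_genes)
    rows = []
    for gi, gene in expression.genes.iterrows():
        gid = gene["gene_id"]
        if gid not in best.index:
            continue
        idx = cis_window(gene, genotypes.variants, window_bp)
        res = permutation_pass(
            xr[:, idx],
            yr[:, gi],
            dof,
            float(best.loc[gid, "nominal_p"]),
            rng=np.random.default_rng(children[gi]),
            n_perm_min=n_perm_min,
            n_perm_max=n_perm_max,
        )
        rows.append(
            {
                "gene_id": gid,
                "n_cis_variants": int(idx.size),
                "best_variant_id": best.loc[gid, "variant_id"],
                "best_nominal_p": float(best.loc[gid, "nominal_p"]),
                "perm_count": res.perm_count,
                "perm_hits": res.perm_hits,
                "beta_shape1": res.beta_shape1,
                "beta_shape2": res.beta_shape2,
                "empirical_p_direct": res.empirical_p_direct,
                "empirical_p_beta": res.empirical_p_beta,
                "beta_mle_converged": res.beta_mle_converged,
            }
        )
    return pd.DataFrame(rows)


def significance_thresholds(
    summaries: pd.DataFrame, q_cut: float = 0.05, lambda_: float = 0.85
) -> pd.DataFrame:
    """q-values, eGene calls and per-gene nominal significance thresholds.

    The tissue-wide empirical threshold is the mean of the largest
    beta-extrapolated empirical p among significant genes and the smallest
    among non-significant genes (one-sided boundary when either side is
    empty); each gene then maps it back through its inverse beta CDF.
    """
    out = summaries.copy()
    if out.empty:
        for col in ("q_value", "is_egene", "nominal_threshold"):
            out[col] = []
        out.attrs["pi0"] = np.nan
        out.attrs["empirical_threshold"] = np.nan
        return out
    q, pi0 = qvalues(out["empirical_p_beta"].to_numpy(), lambda_)
    out["q_value"] = q
    out["is_egene"] = out["q_value"] < q_cut
    sig = out.loc[out["is_egene"], "empirical_p_beta"]
    non = out.loc[~out["is_egene"], "empirical_p_beta"]
    if len(sig) == 0:
        pt = np.nan
        logger.info("no significant eGenes at q < %.3g; eVariant set will be empty", q_cut)
    elif len(non) == 0:
        pt = float(sig.max())
    else:
        pt = float((sig.max() + non.min()) / 2.0)
    out.attrs["pi0"] = pi0
    out.attrs["empirical_threshold"] = pt
    if np.isnan(pt):
        out["nominal_threshold"] = np.nan
    else:
        out["nominal_threshold"] = stats.beta.ppf(
            pt, out["beta_shape1"].to_numpy(), out["beta_shape2"].to_numpy()
        )
    return out


def call_evariants(nominal: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Significant eVariants: associations of eGenes below the gene's threshold."""
    eg = summaries.loc[summaries["is_egene"], ["gene_id", "nominal_threshold"]]
    merged = nominal.merge(eg, on="gene_id", how="inner")
    out = merged[merged["nominal_p"] < merged["nominal_threshold"]].reset_index(drop=True)
    return out


def map_tissue(
    genotypes,
    expression,
    covariates=None,
    window_bp: int = 1_000_000,
    n_perm_min: int = 1000,
    n_perm_max: int = 10000,
    q_cut: float = 0.05,
    lambda_: float = 0.85,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Complete single-tissue cis-eQTL scan.

    Returns (gene summaries incl. q-values and thresholds, all nominal
    associations, significant eVariant associations).
    """
    nominal = nominal_pass(genotypes, expression, covariates, window_bp)
    summaries = permutation_summaries(
        genotypes,
        expression,
        covariates,
        window_bp=window_bp,
        n_perm_min=n_perm_min,
        n_perm_max=n_perm_max,
        seed=seed,
        nominal=nominal,
    )
    summaries = significance_thresholds(summaries, q_cut=q_cut, lambda_=lambda_)
    evariants = call_evariants(nominal, summaries) if not summaries.empty else nominal.iloc[0:0]
    return summaries, nominal, evariants
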