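"""cis-eQTL mapping: residualization, nominal stats, permutations, q-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coreg.eqtl import (
    P_FLOOR,
    cis_window,
    nominal_pass,
    permutation_pass,
    qvalues,
    residualize,
    significance_thresholds,
)
from coreg.panels import CovariateMatrix, ExpressionPanel
from coreg.simulate import SimConfig, simulate_expression

from conftest import make_planted_pair


class TestResidualize:
    def test_intercept_only_mean_centers(self, rng):
        x = rng.standard_normal((30, 4))
        out = residualize(x, None)
        assert np.allclose(out, x - x.mean(axis=0), atol=1e-12)

    def test_covariate_column_is_annihilated(self, covariates):
        cov = covariates(40, 2)
        x = np.column_stack([cov.values[:, 0], np.random.default_rng(0).standard_normal(40)])
        out = residualize(x, cov)
        assert np.linalg.norm(out[:, 0]) < 1e-10

    def test_matches_per_column_ols_residuals(self, rng, covariates):
        # independent normal-equations solve as the oracle
        cov = covariates(50, 2)
        x = rng.standard_normal((50, 3))
        out = residualize(x, cov)
        design = np.column_stack([np.ones(50), cov.values])
        for j in range(3):
            beta = np.linalg.solve(design.T @ design, design.T @ x[:, j])
            assert np.allclose(out[:, j], x[:, j] - design @ beta, atol=1e-10)

    def test_orthogonal_to_design(self, rng, covariates):
        cov = covariates(60, 2)
        out = residualize(rng.standard_normal((60, 5)), cov)
        design = np.column_stack([np.ones(60), cov.values])
        dots = np.abs(design.T @ out)
        scale = np.outer(np.linalg.norm(design, axis=0), np.maximum(np.linalg.norm(out, axis=0), 1.0))
        assert (dots / scale).max() < 1e-8

    def test_collinear_covariates_named_in_error(self):
        values = np.column_stack([np.ones(20), np.ones(20) * 2.0])
        cov = CovariateMatrix(samples=[str(i) for i in range(20)],
                              names=["dup1", "dup2"], values=values)
        with pytest.raises(ValueError, match="collinear"):
            residualize(np.random.default_rng(1).standard_normal((20, 2)), cov)


class TestCisWindow:
    variants = pd.DataFrame({
        "chrom": ["chr1"] * 4 + ["chr2"],
        "pos": [1, 500_001, 1_000_001, 1_000_002, 500_001],  # 1-based
        "id": list("abcde"), "ref": "A", "alt": "G", "maf": 0.2,
    })

    def test_closed_boundary_at_one_megabase(self):
        gene = pd.Series({"chrom": "chr1", "tss": 0, "strand": "+"})
        idx = cis_window(gene, self.variants, window_bp=1_000_000)
        # variant at tss, at tss+500kb and at exactly tss+1Mb included; +1Mb+1 excluded
        assert list(self.variants["id"].iloc[idx]) == ["a", "b", "c"]

    def test_other_chromosome_excluded(self):
        gene = pd.Series({"chrom": "chr2", "tss": 500_000, "strand": "+"})
        idx = cis_window(gene, self.variants, window_bp=1_000_000)
        assert list(self.variants["id"].iloc[idx]) == ["e"]

    def test_minus_strand_window_centred_on_body_end(self):
        gene = pd.Series({"chrom": "chr1", "tss": 1_000_001, "strand": "-"})
        idx = cis_window(gene, self.variants, window_bp=1_000)
        assert list(self.variants["id"].iloc[idx]) == ["c", "d"]


def _expr_panel(y: np.ndarray, tss: int = 0) -> ExpressionPanel:
    n = y.shape[0]
    return ExpressionPanel(
        samples=[f"sample_{i:04d}" for i in range(n)],
        values=y.reshape(n, -1),
        genes=pd.DataFrame({"gene_id": [f"g{j}" for j in range(y.reshape(n, -1).shape[1])],
                            "chrom": "chr1", "start": tss, "end": tss + 1000,
                            "strand": "+", "tss": tss}),
    )


class TestNominalPass:
    def test_hand_computed_six_sample_association(self, small_panel):
        # textbook simple-regression oracle on one variant
        y = np.array([1.2, -0.3, 0.7, 2.1, -1.0, 0.4])
        x = small_panel.dosages[:6, 0]
        geno = small_panel.subset_samples(np.arange(6))
        res = nominal_pass(geno, _expr_panel(y), None, window_bp=10**9)
        row = res[res["variant_id"] == small_panel.variants["id"].iloc[0]].iloc[0]
        fit = stats.linregress(x - x.mean(), y - y.mean())
        assert row["slope"] == pytest.approx(fit.slope, abs=1e-12)
        assert row["nominal_p"] == pytest.approx(fit.pvalue, abs=1e-12)
        assert row["slope_se"] == pytest.approx(fit.stderr, rel=1e-6)

    def test_perfect_fit_hits_floor_not_nan(self, small_panel):
        y = small_panel.dosages[:, 0].copy()
        res = nominal_pass(small_panel, _expr_panel(y), None, window_bp=10**9)
        row = res[res["variant_id"] == small_panel.variants["id"].iloc[0]].iloc[0]
        assert row["nominal_p"] == P_FLOOR
        assert row["slope"] == pytest.approx(1.0, abs=1e-10)
        assert np.isfinite(res["nominal_p"]).all()

    def test_null_p_values_are_uniform(self, small_panel):
        rng = np.random.default_rng(42)
        y = rng.standard_normal((small_panel.n_samples, 10))
        res = nominal_pass(small_panel, _expr_panel(y), None, window_bp=10**9)
        # one variant per gene to dodge LD dependence
        sub = res.groupby("gene_id").nth(0)
        more = res[res["variant_id"] == small_panel.variants["id"].iloc[25]]
        ks = stats.kstest(np.concatenate([sub["nominal_p"], more["nominal_p"]]), "uniform")
        assert ks.pvalue > 0.01

    def test_sample_shuffle_leaves_statistics_unchanged(self, small_panel, covariates):
        cov = covariates(small_panel.n_samples, 2)
        y = np.random.default_rng(3).standard_normal((small_panel.n_samples, 3))
        base = nominal_pass(small_panel, _expr_panel(y), cov, window_bp=10**9)
        perm = np.random.default_rng(4).permutation(small_panel.n_samples)
        shuffled = nominal_pass(
            small_panel.subset_samples(perm), _expr_panel(y[perm]),
            cov.subset_samples(perm), window_bp=10**9,
        )
        for col in ("slope", "slope_se", "nominal_p"):
            assert np.allclose(base[col], shuffled[col], atol=1e-10)


class TestPermutationPass:
    def test_perfect_association_gives_minimum_empirical_p(self, small_panel):
        y = small_panel.dosages[:, 10] - small_panel.dosages[:, 10].mean()
        res = permutation_pass(
            small_panel.dosages - small_panel.dosages.mean(axis=0), y,
            dof=small_panel.n_samples - 2, best_nominal_p=P_FLOOR,
            rng=np.random.default_rng(0), n_perm_min=100, n_perm_max=500,
        )
        assert res.perm_hits == 0
        assert res.perm_count == 500
        assert res.empirical_p_direct == pytest.approx(1.0 / 501)

    def test_single_null_variant_beta_fit_near_uniform(self, small_panel):
        # with one cis variant the permutation minimum p IS a uniform draw,
        # so the fitted beta should be close to Beta(1, 1)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(small_panel.n_samples)
        y -= y.mean()
        x = (small_panel.dosages[:, [0]] - small_panel.dosages[:, [0]].mean(axis=0))
        res = permutation_pass(x, y, dof=small_panel.n_samples - 2,
                               best_nominal_p=0.5, rng=rng,
                               n_perm_min=5000, n_perm_max=5000)
        assert 0.7 <= res.beta_shape1 <= 1.4
        assert 0.7 <= res.beta_shape2 <= 1.4

    def test_adaptive_stop_under_the_null(self, small_panel):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(small_panel.n_samples)
        y -= y.mean()
        x = small_panel.dosages - small_panel.dosages.mean(axis=0)
        res = permutation_pass(x, y, dof=small_panel.n_samples - 2,
                               best_nominal_p=0.2, rng=rng,
                               n_perm_min=1000, n_perm_max=10000)
        # a mid-range observed p accumulates 100 hits fast: stops at the floor
        assert res.perm_count == 1000
        assert res.perm_hits >= 100


class TestQvalues:
    def test_uniform_null_pi0_near_one(self):
        p = np.random.default_rng(8).uniform(size=20000)
        _, pi0 = qvalues(p)
        assert 0.9 <= pi0 <= 1.0

    def test_single_p_value(self):
        q, pi0 = qvalues([0.5])
        assert q[0] == pytest.approx(pi0 * 0.5)

    def test_matches_naive_step_down_oracle(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(size=50) * 1e-3, rng.uniform(size=150)])
        q, pi0 = qvalues(p)
        m = p.size
        order = np.argsort(p)
        expected = np.empty(m)
        for rank, i in enumerate(order, start=1):
            expected[i] = min(
                pi0 * m * p[j] / (list(order).index(j) + 1) for j in order[rank - 1:]
            )
        assert np.allclose(q, np.minimum(expected, 1.0), atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2, max_size=60))
    def test_qvalues_monotone_in_p(self, pvals):
        q, _ = qvalues(pvals)
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qvalues([])


class TestSignificanceThresholds:
    @staticmethod
    def _summaries(emp_p, a=1.0, b=1.0):
        n = len(emp_p)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "n_cis_variants": 10, "best_variant_id": "v",
            "best_nominal_p": emp_p, "perm_count": 1000, "perm_hits": 10,
            "beta_shape1": a, "beta_shape2": b,
            "empirical_p_direct": emp_p, "empirical_p_beta": emp_p,
            "beta_mle_converged": True,
        })

    def test_uniform_beta_threshold_equals_empirical_threshold(self):
        emp = [1e-6, 2e-6, 0.4, 0.5, 0.6, 0.7, 0.8, 0.86, 0.9, 0.95]
        out = significance_thresholds(self._summaries(emp))
        pt = out.attrs["empirical_threshold"]
        sig = out[out["is_egene"]]
        non = out[~out["is_egene"]]
        assert pt == pytest.approx((sig["empirical_p_beta"].max() + non["empirical_p_beta"].min()) / 2)
        # Beta(1,1): the inverse CDF is the identity
        assert np.allclose(out["nominal_threshold"], pt)

    def test_all_genes_significant_uses_one_sided_boundary(self):
        emp = [1e-8, 1e-7, 1e-6]
        out = significance_thresholds(self._summaries(emp))
        assert out["is_egene"].all()
        assert out.attrs["empirical_threshold"] == pytest.approx(max(emp))

    def test_no_significant_genes_leaves_thresholds_undefined(self):
        emp = [0.9, 0.92, 0.95, 0.99]
        out = significance_thresholds(self._summaries(emp))
        assert not out["is_egene"].any()
        assert np.isnan(out["nominal_threshold"]).all()


def test_direct_and_beta_empirical_p_agree_on_null_genes(small_panel):
    """Beta extrapolation vs direct permutation count on 30 null genes."""
    rng = np.random.default_rng(77)
    x = small_panel.dosages - small_panel.dosages.mean(axis=0)
    diffs = []
    for i in range(30):
        y = rng.standard_normal(small_panel.n_samples)
        y -= y.mean()
        from coreg.eqtl import _assoc_stats

        _, _, _, p, _ = _assoc_stats(x, y, small_panel.n_samples - 2)
        res = permutation_pass(x, y, small_panel.n_samples - 2, float(p.min()),
                               rng=np.random.default_rng(1000 + i),
                               n_perm_min=2000, n_perm_max=2000)
        diffs.append(abs(res.empirical_p_beta - res.empirical_p_direct))
    assert np.median(diffs) < 0.01
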