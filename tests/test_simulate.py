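"""Synthetic-data generator: LD structure, planted truth, reproducibility."""

import numpy as np
import pytest

from coreg.simulate import (
    PlantedGene,
    SimConfig,
    default_study_config,
    simulate_expression,
    simulate_genotypes,
    simulate_study,
    truth_for_tissue,
)

from conftest import make_planted_pair


def _gene(gene_id="g0", causal=None, effect=0.0, direction=1, label=None, tissues=(0,)):
    tss = 100_000
    return PlantedGene(gene_id=gene_id, region_index=0, tss_bp=tss, body=(tss, tss + 20_000),
                       causal_variant_index=causal, effect_size=effect, direction=direction,
                       cluster_label=label, active_tissues=frozenset(tissues))


class TestConfigValidation:
    def test_effect_without_causal_variant_rejected(self):
        with pytest.raises(ValueError, match="effect_size must be 0 iff"):
            _gene(causal=None, effect=0.5)

    def test_coactive_cluster_members_must_share_causal_variant(self):
        genes = (_gene("a", causal=3, effect=0.5, label="c"),
                 _gene("b", causal=7, effect=0.5, label="c"))
        with pytest.raises(ValueError, match="do not share a causal variant"):
            SimConfig(gene_layout=genes)

    @pytest.mark.parametrize("kwargs", [
        {"n_samples": 1},
        {"ld_rho": 1.0},
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.3, 0.6)},
    ])
    def test_invalid_scalar_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenotypes:
    def test_seeded_runs_are_bit_identical(self):
        config = SimConfig(n_samples=100, n_variants_per_region=20, seed=5)
        a = simulate_genotypes(config)
        b = simulate_genotypes(config)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)

    def test_dosages_are_hard_calls_with_bounded_maf(self):
        config = SimConfig(n_samples=1000, n_variants_per_region=100,
                           maf_range=(0.01, 0.5), seed=3)
        panel = simulate_genotypes(config)
        assert set(np.unique(panel.dosages)) <= {0.0, 1.0, 2.0}
        maf = panel.variants["maf"].to_numpy()
        assert (maf > 0).all() and (maf <= 0.55).all()
        # no monomorphic variant survives the redraw loop
        assert (panel.dosages.min(axis=0) < panel.dosages.max(axis=0)).all()

    def test_independent_variants_without_ld(self):
        config = SimConfig(n_samples=200, n_variants_per_region=30,
                           maf_range=(0.2, 0.5), ld_rho=0.0, seed=9)
        panel = simulate_genotypes(config)
        corr = np.corrcoef(panel.dosages.T)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.mean(np.abs(off)) < 3.0 / np.sqrt(config.n_samples)

    def test_strong_ld_between_adjacent_variants(self):
        # Monte-Carlo oracle under the latent AR(1) threshold model: with
        # rho = 0.95 and common alleles, the induced genotype correlation of
        # adjacent variants comfortably exceeds 0.5.
        config = SimConfig(n_samples=500, n_variants_per_region=40,
                           maf_range=(0.25, 0.35), ld_rho=0.95, seed=21)
        panel = simulate_genotypes(config)
        adjacent = [np.corrcoef(panel.dosages[:, j], panel.dosages[:, j + 1])[0, 1]
                    for j in range(panel.n_variants - 1)]
        assert np.median(adjacent) > 0.5

    def test_variant_positions_follow_spacing(self):
        config = SimConfig(n_samples=50, n_variants_per_region=5, n_regions=2,
                           variant_spacing_bp=1000, seed=1)
        panel = simulate_genotypes(config)
        pos = panel.variants["pos"].to_numpy()
        assert list(np.diff(pos[:5])) == [1000] * 4
        assert pos[5] - pos[4] > 2_000_000  # regions never merge


class TestExpression:
    def test_zero_effects_give_empty_truth(self):
        config = SimConfig(n_samples=100, gene_layout=(_gene("a"), _gene("b")), seed=2)
        geno = simulate_genotypes(config)
        _, _, truth = simulate_expression(geno, config, tissue=0)
        assert truth.egenes[0] == set()
        assert truth.pairs[0] == {}

    def test_opposite_direction_pair_marked_opposite(self):
        layout = make_planted_pair(dir_a=1, dir_b=-1)
        config = SimConfig(n_samples=100, gene_layout=layout, seed=2)
        truth = truth_for_tissue(config, 0)
        assert list(truth.pairs[0].values()) == ["opposite"]

    def test_variance_decomposition_of_planted_effect(self):
        # closed form: with y = es * z + noise(1), var(z) = 1 =>
        # r^2 -> es^2 / (es^2 + 1); Monte-Carlo check at n = 300
        es = 0.8
        layout = (_gene("g", causal=25, effect=es),)
        config = SimConfig(n_samples=300, gene_layout=layout,
                           n_covariates=0, noise_sd=1.0, seed=17)
        geno = simulate_genotypes(config)
        expr, _, _ = simulate_expression(geno, config, tissue=0)
        dos = geno.dosages[:, 25]
        r2 = np.corrcoef(dos, expr.values[:, 0])[0, 1] ** 2
        expected = es**2 / (es**2 + 1.0)
        assert abs(r2 - expected) < 0.1

    def test_inactive_tissue_gene_has_no_genetic_effect(self):
        layout = (_gene("g", causal=25, effect=2.0, tissues=(0,)),)
        config = SimConfig(n_samples=400, gene_layout=layout, n_covariates=0, seed=8)
        geno = simulate_genotypes(config)
        expr1, _, truth1 = simulate_expression(geno, config, tissue=1)
        assert truth1.egenes[1] == set()
        r2 = np.corrcoef(geno.dosages[:, 25], expr1.values[:, 0])[0, 1] ** 2
        assert r2 < 0.05

    def test_causal_variant_outside_region_fails(self):
        with pytest.raises(ValueError, match="outside region"):
            SimConfig(n_variants_per_region=10, gene_layout=(_gene("g", causal=10, effect=0.5),))

    def test_truth_cluster_of_size_k_has_k_choose_2_pairs(self):
        config = default_study_config(seed=0)
        truth = truth_for_tissue(config, 0)
        n_pairs = sum(len(c) * (len(c) - 1) // 2 for c in truth.clusters[0])
        assert len(truth.pairs[0]) == n_pairs

    def test_sample_subsetting_restricts_panel(self, small_panel):
        config = SimConfig(n_samples=200, n_variants_per_region=50, maf_range=(0.1, 0.5),
                           ld_rho=0.9, seed=11, gene_layout=(_gene("g", causal=5, effect=0.5),))
        expr, cov, _ = simulate_expression(small_panel, config, tissue=0,
                                           sample_indices=np.arange(80))
        assert expr.n_samples == 80 and cov.values.shape == (80, 3)


def test_study_truth_roundtrips_through_json(tmp_path):
    config = default_study_config(seed=4, n_samples=60)
    _, _, truth = simulate_study(config)
    truth.to_json(tmp_path / "truth.json")
    from coreg.simulate import TruthTable

    loaded = TruthTable.from_json(tmp_path / "truth.json")
    assert loaded.egenes == truth.egenes
    assert loaded.pairs == truth.pairs
    assert loaded.clusters == truth.clusters
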