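"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from coreg.panels import CovariateMatrix
from coreg.simulate import PlantedGene, SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211001)


@pytest.fixture(scope="session")
def small_panel():
    """50-variant LD-structured panel, 200 samples, one region."""
    config = SimConfig(n_samples=200, n_variants_per_region=50, n_regions=1,
                       maf_range=(0.1, 0.5), ld_rho=0.9, seed=11)
    return simulate_genotypes(config)


@pytest.fixture
def covariates(rng):
    def make(n_samples: int, k: int = 2) -> CovariateMatrix:
        return CovariateMatrix(
            samples=[f"sample_{i:04d}" for i in range(n_samples)],
            names=[f"cov{i}" for i in range(k)],
            values=np.random.default_rng(7).standard_normal((n_samples, k)),
        )

    return make


def brute_force_maximal_cliques(nodes, edges) -> set[frozenset]:
    """Oracle: maximal cliques of size >= 2 by exhaustive subset enumeration."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}
    cliques = []
    for r in range(2, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all(frozenset((a, b)) in edge_set for a, b in combinations(subset, 2)):
                cliques.append(frozenset(subset))
    return {c for c in cliques if not any(c < other for other in cliques)}


def direct_coloc_enumeration(labf1, labf2, p1, p2, p12):
    """Oracle: PP0-PP4 by raw (non-log) per-hypothesis summation.

    Extended precision keeps the raw Bayes factors representable for
    strong-but-realistic signals.
    """
    bf1 = np.exp(np.asarray(labf1, dtype=np.longdouble))
    bf2 = np.exp(np.asarray(labf2, dtype=np.longdouble))
    s1 = bf1.sum()
    s2 = bf2.sum()
    s12 = bf1 @ bf2
    s3 = sum(bf1[i] * bf2[j] for i in range(len(bf1)) for j in range(len(bf2)) if i != j)
    weights = np.array([np.longdouble(1.0), p1 * s1, p2 * s2, p1 * p2 * s3, p12 * s12])
    return (weights / weights.sum()).astype(np.float64)


def make_planted_pair(effect_a=0.8, effect_b=0.8, dir_a=1, dir_b=1,
                      causal_a=25, causal_b=25, label="pair",
                      n_null=0) -> tuple[PlantedGene, ...]:
    """Two planted genes in region 0, optionally sharing the causal variant."""
    shared = causal_a == causal_b and dir_a * dir_b != 0
    genes = []
    for i, (cv, es, d) in enumerate(((causal_a, effect_a, dir_a), (causal_b, effect_b, dir_b))):
        tss = cv * 5_000 + 30_000 + i * 25_000
        genes.append(
            PlantedGene(gene_id=f"{label}_g{i}", region_index=0, tss_bp=tss,
                        body=(tss, tss + 20_000), causal_variant_index=cv,
                        effect_size=es, direction=d,
                        cluster_label=label if shared else None)
        )
    for i in range(n_null):
        tss = 1_000 + i * 25_000
        genes.append(PlantedGene(gene_id=f"{label}_null{i}", region_index=0,
                                 tss_bp=tss, body=(tss, tss + 20_000)))
    return tuple(genes)
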