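"""Synthetic genotype/expression study with a planted regulatory architecture.

The generator emulates the inputs of a multi-tissue cis-eQTL study: one
genotype panel shared by all tissues (same donors), per-tissue expression
with known causal structure, and generic covariates standing in for
technical/expression factors.  Because the architecture is planted, every
downstream stage (eGene calls, colocalization edges, cliques) has an exact
ground truth to score against.

LD model: each haplotype is a latent Gaussian AR(1) process across variants
(parameter ``ld_rho``) thresholded at the quantile of the variant's drawn
allele frequency; the genotype is the sum of two independent haplotypes.
This gives smooth, single-parameter LD decay without modelling real human
haplotype structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .panels import CovariateMatrix, ExpressionPanel, GenotypePanel

# Regions are laid far enough apart that a 1 Mbp cis window and the 2 Mbp
# region-merge rule can never bridge two simulated regions.
REGION_GAP_BP = 10_000_000
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class PlantedGene:
    """Ground-truth description of one simulated gene.

    effect_size is the per-allele slope in units of expression SD applied to
    the standardized dosage of the causal variant; genes sharing a
    ``cluster_label`` share that causal variant (the planted co-regulation).
    """

    gene_id: str
    region_index: int
    tss_bp: int
    body: tuple[int, int]
    causal_variant_index: int | None = None
    effect_size: float = 0.0
    direction: int = 1
    cluster_label: str | None = None
    active_tissues: frozenset[int] = frozenset({0})

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if (self.causal_variant_index is None) != (self.effect_size == 0.0):
            raise ValueError(
                f"{self.gene_id}: effect_size must be 0 iff causal_variant_index is None"
            )
        if self.body[1] <= self.body[0]:
            raise ValueError(f"{self.gene_id}: empty body interval {self.body}")


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 300
    n_variants_per_region: int = 50
    n_regions: int = 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.9
    variant_spacing_bp: int = 5_000
    gene_layout: tuple[PlantedGene, ...] = ()
    n_tissues: int = 1
    n_covariates: int = 3
    covariate_effect_sd: float = 0.3
    noise_sd: float | tuple[float, ...] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_layout", tuple(self.gene_layout))
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        for g in self.gene_layout:
            if g.region_index >= self.n_regions:
                raise ValueError(f"{g.gene_id}: region_index {g.region_index} out of range")
            if g.causal_variant_index is not None and not (
                0 <= g.causal_variant_index < self.n_variants_per_region
            ):
                raise ValueError(
                    f"{g.gene_id}: causal_variant_index {g.causal_variant_index} "
                    f"outside region of {self.n_variants_per_region} variants"
                )
        # genes sharing a cluster label in overlapping tissues must share the signal
        by_label: dict[str, list[PlantedGene]] = {}
        for g in self.gene_layout:
            if g.cluster_label is not None:
                by_label.setdefault(g.cluster_label, []).append(g)
        for label, members in by_label.items():
            for a, b in combinations(members, 2):
                if a.active_tissues & b.active_tissues and (
                    a.causal_variant_index != b.causal_variant_index
                    or a.region_index != b.region_index
                ):
                    raise ValueError(
                        f"cluster '{label}': {a.gene_id} and {b.gene_id} are co-active "
                        "but do not share a causal variant"
                    )

    def noise_sd_for(self, tissue: int) -> float:
        if isinstance(self.noise_sd, (int, float)):
            return float(self.noise_sd)
        return float(self.noise_sd[tissue])


@dataclass
class TruthTable:
    """Planted truth per tissue: eGenes, co-regulated pairs, clusters.

    ``pairs`` maps a tissue to {frozenset({a, b}): "same" | "opposite"}.
    """

    egenes: dict[int, set[str]] = field(default_factory=dict)
    pairs: dict[int, dict[frozenset, str]] = field(default_factory=dict)
    clusters: dict[int, set[frozenset]] = field(default_factory=dict)

    def all_unique_pairs(self) -> set[frozenset]:
        out: set[frozenset] = set()
        for d in self.pairs.values():
            out.update(d.keys())
        return out

    def all_unique_clusters(self) -> set[frozenset]:
        out: set[frozenset] = set()
        for s in self.clusters.values():
            out.update(s)
        return out

    def to_json(self, path) -> None:
        payload = {
            "egenes": {str(t): sorted(v) for t, v in self.egenes.items()},
            "pairs": {
                str(t): [[sorted(p), d] for p, d in sorted(v.items(), key=lambda kv: sorted(kv[0]))]
                for t, v in self.pairs.items()
            },
            "clusters": {
                str(t): sorted([sorted(c) for c in v]) for t, v in self.clusters.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            egenes={int(t): set(v) for t, v in payload["egenes"].items()},
            pairs={
                int(t): {frozenset(p): d for p, d in v} for t, v in payload["pairs"].items()
            },
            clusters={
                int(t): {frozenset(c) for c in v} for t, v in payload["clusters"].items()
            },
        )


def region_offset(region_index: int, config: SimConfig) -> int:
    """0-based genomic offset of a simulated region (all regions on chr1)."""
    span = config.n_variants_per_region * config.variant_spacing_bp
    return region_index * (span + REGION_GAP_BP)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw LD-structured biallelic genotypes for every region.

    Monomorphic variants are redrawn (latent value refreshed conditional on
    the left neighbour, preserving local LD) up to a bounded number of
    times; a variant still monomorphic afterwards raises ``RuntimeError``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n, m = config.n_samples, config.n_variants_per_region
    rho = config.ld_rho
    blocks, rows = [], []
    for r in range(config.n_regions):
        freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
        thresh = stats.norm.ppf(freqs)
        # two independent haplotypes per sample, AR(1) across variants
        z = np.empty((n, 2, m))
        z[:, :, 0] = rng.standard_normal((n, 2))
        innov = rng.standard_normal((n, 2, m - 1)) if m > 1 else None
        for j in range(1, m):
            z[:, :, j] = rho * z[:, :, j - 1] + np.sqrt(1 - rho * rho) * innov[:, :, j - 1]
        dos = (z < thresh).sum(axis=1).astype(np.float64)
        for j in range(m):
            redraws = 0
            while dos[:, j].min() == dos[:, j].max():
                if redraws >= _MAX_REDRAWS:
                    raise RuntimeError(
                        f"variant {j} of region {r} monomorphic after {_MAX_REDRAWS} "
                        f"redraws (allele frequency {freqs[j]:.4g}, n={n}); "
                        "increase n_samples or the lower MAF bound"
                    )
                base = rho * z[:, :, j - 1] if j > 0 else 0.0
                z[:, :, j] = base + np.sqrt(1 - rho * rho if j > 0 else 1.0) * rng.standard_normal((n, 2))
                dos[:, j] = (z[:, :, j] < thresh[j]).sum(axis=1)
                redraws += 1
        offset = region_offset(r, config)
        af = dos.sum(axis=0) / (2 * n)
        for j in range(m):
            pos1 = offset + j * config.variant_spacing_bp + 1
            rows.append(
                {
                    "chrom": "chr1",
                    "pos": pos1,
                    "id": f"var_r{r}_{j}",
                    "ref": "A",
                    "alt": "G",
                    "maf": float(min(af[j], 1 - af[j])),
                }
            )
        blocks.append(dos)
    samples = [f"sample_{i:04d}" for i in range(n)]
    return GenotypePanel(samples=samples, dosages=np.hstack(blocks), variants=pd.DataFrame(rows))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant dosage vector")
    return (x - x.mean()) / sd


def simulate_expression(
    genotypes: GenotypePanel,
    config: SimConfig,
    tissue: int = 0,
    rng: np.random.Generator | None = None,
    sample_indices: np.ndarray | list[int] | None = None,
) -> tuple[ExpressionPanel, CovariateMatrix, TruthTable]:
    """Simulate one tissue's expression panel from the planted layout.

    Active planted genes get ``direction * effect_size * standardized
    dosage`` of their causal variant plus a shared-covariate term and
    Gaussian noise; inactive and null genes get covariate + noise only.
    ``sample_indices`` restricts to a donor subset (varying tissue sample
    sizes); the truth table for this tissue is returned alongside.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2 + tissue)[-1])
    geno = genotypes if sample_indices is None else genotypes.subset_samples(sample_indices)
    n = geno.n_samples
    k = config.n_covariates
    cov_values = rng.standard_normal((n, k))
    var_index = {v: i for i, v in enumerate(geno.variants["id"])}
    noise_sd = config.noise_sd_for(tissue)

    cols, gene_rows = [], []
    for g in config.gene_layout:
        loadings = rng.normal(0.0, config.covariate_effect_sd, size=k)
        y = cov_values @ loadings + rng.normal(0.0, noise_sd, size=n)
        active = tissue in g.active_tissues
        if active and g.causal_variant_index is not None:
            vid = f"var_r{g.region_index}_{g.causal_variant_index}"
            if vid not in var_index:
                raise ValueError(f"{g.gene_id}: causal variant {vid} not in genotype panel")
            y = y + g.direction * g.effect_size * _standardize(geno.dosages[:, var_index[vid]])
        cols.append(y)
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": "chr1",
                "start": g.body[0],
                "end": g.body[1],
                "strand": "+",
                "tss": g.tss_bp,
            }
        )
    expr = ExpressionPanel(
        samples=list(geno.samples),
        values=np.column_stack(cols) if cols else np.empty((n, 0)),
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]),
    )
    cov = CovariateMatrix(
        samples=list(geno.samples),
        names=[f"cov{i + 1}" for i in range(k)],
        values=cov_values,
    )
    return expr, cov, truth_for_tissue(config, tissue)


def truth_for_tissue(config: SimConfig, tissue: int) -> TruthTable:
    """Derive the single-tissue truth table from the planted layout."""
    active = [
        g
        for g in config.gene_layout
        if tissue in g.active_tissues and g.causal_variant_index is not None and g.effect_size != 0
    ]
    egenes = {g.gene_id for g in active}
    by_label: dict[str, list[PlantedGene]] = {}
    for g in active:
        if g.cluster_label is not None:
            by_label.setdefault(g.cluster_label, []).append(g)
    pairs: dict[frozenset, str] = {}
    clusters: set[frozenset] = set()
    for members in by_label.values():
        if len(members) < 2:
            continue
        clusters.add(frozenset(g.gene_id for g in members))
        for a, b in combinations(members, 2):
            pairs[frozenset({a.gene_id, b.gene_id})] = (
                "same" if a.direction == b.direction else "opposite"
            )
    return TruthTable(egenes={tissue: egenes}, pairs={tissue: pairs}, clusters={tissue: clusters})


def merge_truth(tables: list[TruthTable]) -> TruthTable:
    merged = TruthTable()
    for t in tables:
        merged.egenes.update(t.egenes)
        merged.pairs.update(t.pairs)
        merged.clusters.update(t.clusters)
    return merged


def simulate_study(
    config: SimConfig,
) -> tuple[GenotypePanel, list[tuple[ExpressionPanel, CovariateMatrix]], TruthTable]:
    """Full study: one genotype panel plus per-tissue expression/covariates."""
    ss = np.random.SeedSequence(config.seed).spawn(1 + config.n_tissues)
    geno = simulate_genotypes(config, rng=np.random.default_rng(ss[0]))
    tissues, truths = [], []
    for t in range(config.n_tissues):
        expr, cov, truth = simulate_expression(
            geno, config, tissue=t, rng=np.random.default_rng(ss[1 + t])
        )
        tissues.append((expr, cov))
        truths.append(truth)
    return geno, tissues, merge_truth(truths)


def cluster_layout(
    cluster_sizes: dict[str, int] | None = None,
    n_variants_per_region: int = 50,
    variant_spacing_bp: int = 5_000,
    effect_size: float = 0.8,
    directions: dict[str, list[int]] | None = None,
    n_null_per_region: int = 2,
    active_tissues: frozenset[int] = frozenset({0}),
    causal_index: int = 25,
) -> tuple[PlantedGene, ...]:
    """Convenience layout builder: one planted cluster per region plus nulls.

    ``cluster_sizes`` maps a cluster label to its gene count; genes of a
    cluster share the region's ``causal_index`` variant.  Gene bodies are
    disjoint 20 kb intervals tiled downstream of the causal variant.
    """
    cluster_sizes = cluster_sizes or {"clusterA": 2}
    labels = list(cluster_sizes)
    genes: list[PlantedGene] = []
    for r, label in enumerate(labels):
        size = cluster_sizes[label]
        dirs = (directions or {}).get(label, [1] * size)
        base = r * (n_variants_per_region * variant_spacing_bp + REGION_GAP_BP)
        for i in range(size):
            tss = base + causal_index * variant_spacing_bp + 30_000 + i * 25_000
            genes.append(
                PlantedGene(
                    gene_id=f"{label}_g{i}",
                    region_index=r,
                    tss_bp=tss,
                    body=(tss, tss + 20_000),
                    causal_variant_index=causal_index,
                    effect_size=effect_size,
                    direction=dirs[i],
                    cluster_label=label,
                    active_tissues=active_tissues,
                )
            )
        for i in range(n_null_per_region):
            tss = base + 5_000 + i * 25_000
            genes.append(
                PlantedGene(
                    gene_id=f"null_r{r}_g{i}",
                    region_index=r,
                    tss_bp=tss,
                    body=(tss, tss + 20_000),
                    active_tissues=active_tissues,
                )
            )
    return tuple(genes)


def default_study_config(seed: int = 0, n_samples: int = 300, n_tissues: int = 2) -> SimConfig:
    """The stock two-tissue synthetic study used by the ``simulate`` command.

    Regions carry, in order: a same-direction pair, a mixed-direction
    triplet, a five-gene cluster, two independently regulated genes, and an
    opposite-direction pair active in tissue 0 only; each region also holds
    two null genes.  Effects are 0.8 SD per allele at common variants.
    """
    both = frozenset(range(n_tissues))
    layout = list(
        cluster_layout(
            cluster_sizes={"pairAB": 2, "trio": 3, "quint": 5},
            directions={"trio": [1, 1, -1]},
            active_tissues=both,
        )
    )
    # region 3: two genes with distinct, well-separated causal variants
    base3 = 3 * (50 * 5_000 + REGION_GAP_BP)
    for i, cv in enumerate((5, 45)):
        tss = base3 + cv * 5_000 + 30_000
        layout.append(
            PlantedGene(
                gene_id=f"indep_g{i}",
                region_index=3,
                tss_bp=tss,
                body=(tss, tss + 20_000),
                causal_variant_index=cv,
                effect_size=0.8,
                direction=1,
                active_tissues=both,
            )
        )
    # region 4: opposite-direction pair, tissue 0 only
    base4 = 4 * (50 * 5_000 + REGION_GAP_BP)
    for i, d in enumerate((1, -1)):
        tss = base4 + 25 * 5_000 + 30_000 + i * 25_000
        layout.append(
            PlantedGene(
                gene_id=f"oppo_g{i}",
                region_index=4,
                tss_bp=tss,
                body=(tss, tss + 20_000),
                causal_variant_index=25,
                effect_size=0.8,
                direction=d,
                cluster_label="oppo",
                active_tissues=frozenset({0}),
            )
        )
    return SimConfig(
        n_samples=n_samples,
        n_variants_per_region=50,
        n_regions=5,
        maf_range=(0.05, 0.5),
        ld_rho=0.9,
        variant_spacing_bp=5_000,
        gene_layout=tuple(layout),
        n_tissues=n_tissues,
        n_covariates=3,
        covariate_effect_sd=0.3,
        noise_sd=1.0,
        seed=seed,
    )
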