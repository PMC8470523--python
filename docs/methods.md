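# Methods

## Model and procedure

`coreg` identifies genes whose expression is driven by one shared genetic
signal. The statistical chain is: per-tissue cis-eQTL mapping with
permutation-based gene-level calibration → false-discovery-rate control on
gene-level empirical p-values → per-gene nominal significance thresholds →
candidate regions of multi-gene eVariants → pairwise approximate-Bayes-factor
colocalization → maximal-clique cluster assembly → pair/cluster
characterization. Only the most prominent signal per gene is modelled; genes
with several independent cis signals contribute their strongest one. This
keeps pairs comparable across tissues of very different sample sizes but
misses secondary-signal co-regulation.

### cis-eQTL mapping

Associations are simple linear regressions of residualized expression on
residualized dosage. Covariates are removed once by orthogonal projection
(QR of `[1 | C]`), which is numerically identical to including them in
every per-variant regression but costs one pass. The cis window is ±1 Mbp
around the TSS with a closed boundary (a variant exactly 1 Mbp away is
tested); strand changes only which gene end is the TSS.

The gene-level null distribution of the best cis p-value is estimated by
permuting the residualized phenotype — under the null the residuals are
exchangeable, so covariate structure is preserved. Permutations run
adaptively: at least 1000, stopping once 100 permutation minima beat the
observed best p, else continuing to 10000. A Beta(a, b) is fitted to the
permutation minima by maximum likelihood (method-of-moments fallback,
flagged in the output) and the gene-level empirical p-value is
`BetaCDF(best nominal p; a, b)`. With a single cis variant this reduces to
the uniform order-statistic case and the fit approaches Beta(1, 1).

eGenes are called at Storey q < 0.05 with a single-λ pi0 estimate
(λ = 0.85); when no p-value exceeds λ the count is floored at one and pi0
capped at 1. The tissue-wide empirical threshold is the mean of the largest
empirical p among significant genes and the smallest among non-significant
ones (one-sided boundary when either set is empty); each gene converts it
into a nominal threshold through its own inverse beta CDF. eVariants are
called only for eGenes.

### Colocalization

For each gene pair within a candidate region, every shared variant
contributes Wakefield log approximate Bayes factors computed from the
regression slope, its variance and the SD of the (residualized)
expression, with prior effect SD 0.15·sdY — the quantitative-trait default.
The slope and SE passed to colocalization are those of the
residualized-scale regression, consistent with sdY measured on the same
scale. All five hypothesis sums are accumulated in log space
(log-sum-exp); the two-distinct-variants sum is
`exp(L1 + L2) − exp(L12)` evaluated via `log1p(−exp(Δ))` and clamped at
−∞ if Δ ≥ 0 within rounding. All cis variants with nominal statistics
enter — not only significant ones — because the evidence model needs the
full local signal shape.

Priors follow the gene-specific rule: p1 and p2 are the two genes' own
nominal thresholds; p12 = min(5 × 10⁻⁶, p1, p2). Thresholds are used
verbatim, without an additional floor or cap; a threshold above the common
1 × 10⁻⁴ default is unusual but applied as-is. Pairs with zero shared
variants are reported with PP0 = 1, PP1–PP4 = 0 and an explicit
`no_overlap` flag so "not testable" is never confused with "tested and
rejected".

### Regions, cliques, catalog

Significant eVariants regulating ≥ 2 eGenes are sorted by position and
merged while consecutive variants are strictly less than 2 Mbp apart (a
gap of exactly 2 Mbp starts a new region). The co-regulation graph has an
edge for every pair with H4 ≥ 0.8 (boundary inclusive). Clusters are
*maximal* cliques of size ≥ 2 — reporting all sub-cliques would multiply
counts; the characteristic pattern of two large clusters differing in a
single member arises exactly from a near-complete graph missing one edge.
Cluster identity for cross-tissue deduplication is the gene set alone;
tissue sharing counts a cluster of tissue A as shared with B when some
B-cluster is a superset or subset of it, each A-cluster at most once (the
matrix is therefore not symmetric when catalog sizes differ).

### Pair annotation

Overlap classes compare gene bodies: full containment, partial
intersection, or non-overlapping with distance = gap between the nearest
body ends (touching bodies have distance 0). Distance is defined only for
non-overlapping pairs; a TSS-distance mode is available behind a flag.
Direction concordance is read at the single variant maximizing the sum of
the two genes' log Bayes factors (ties broken by lower position via
first-match argmax over position-sorted variants), so both slopes are
compared at one locus. Haploinsufficiency lists are unions of
one-symbol-per-line files; symbols absent from the expression annotation
are reported as unmatched, never dropped silently.

## Synthetic data

The generator emulates a multi-tissue eQTL study with a known answer. One
genotype panel serves all tissues (same donors; per-tissue donor subsets
are supported through index lists). Haplotypes are latent Gaussian AR(1)
processes across variants thresholded at each variant's allele-frequency
quantile; genotype = sum of two independent haplotypes. This yields smooth
single-parameter LD decay (`ld_rho`) but none of the block structure,
recombination hotspots or allele-frequency spectrum of real human
haplotypes. Monomorphic variants are redrawn conditional on their left
neighbour (bounded retries, then an error). Covariates are standard normal
with per-gene Gaussian loadings — a stand-in for technical/expression
factors, not an inference of them.

Planted genes get `direction × effect × standardized causal dosage +
covariates·loadings + N(0, noise_sd)`; genes sharing a `cluster_label`
share the causal variant, which is exactly the "one shared signal"
hypothesis H4 tests. The stock study (`default_study_config`) uses 300
samples, 5 regions × 50 variants at 5 kb spacing, MAF drawn from
[0.05, 0.5], ld_rho 0.9, per-allele effects of 0.8 expression SD, 3
covariates and unit noise — common variants with strong-but-realistic
effects, sized so pairwise colocalization is well powered, which is the
regime the cluster-assembly logic is meant to be tested in. Regions are
placed 10 Mbp apart so cis windows and region merging never bridge them.

Because LD is simplified and effects are homogeneous, passing tests show
the *procedure* is correct and calibrated under its assumptions; they do
not certify performance on real cohorts with complex LD, allelic
heterogeneity, or expression outliers.

## Numerical choices

- Perfect-fit nominal p-values are floored at 1e-300 and slope SEs at
  1e-12 to avoid NaN propagation.
- Beta MLE failures fall back to method-of-moments, flagged per gene.
- Rank-deficient covariate designs fail loudly, naming collinear columns.
- Missing genotypes are mean-imputed per variant (standard eQTL practice);
  multi-allelic VCF records are split per ALT allele keyed by
  (chrom, pos, alt).
- Expression BEDs without a strand column fall back to TSS = start with a
  warning (the GTEx convention encodes the TSS in `start`).
- All RNG streams descend from one `SeedSequence`; per-gene permutation
  streams are spawned in gene order, so one gene's adaptive stopping never
  shifts another gene's stream, and a fixed seed reproduces every output
  byte-for-byte. Permutation-based quantities are reproducible for a fixed
  seed and sample order; nominal statistics are additionally invariant
  under any consistent sample reordering.
- Clique enumeration (Bron–Kerbosch with pivoting) is capped at 100 nodes
  per region graph; real candidate regions contain a handful of genes.

## Validation experiment sizes

`scripts/acceptance.py` and the statistical tests use: 200 null genes ×
5000 permutations for calibration; five (script) or twenty (test suite)
independent 100-true/400-null gene studies for FDR and power; 50
replicates for colocalization discrimination; 20–50 replicates of the
stock study for cluster recovery. These sizes give Monte-Carlo standard
errors comfortably below the decision margins being checked.

## Known limitations

- Single causal signal per gene; no conditional/secondary eQTLs, no
  trans-eQTLs, no interaction models.
- No PEER/factor inference — covariates are consumed as given.
- The LD model is AR(1)-like; results on real haplotype structure may
  differ, particularly PP3/PP4 separation at high LD between distinct
  causal variants.
- Case-control traits and fine-mapping-based colocalization are out of
  scope.
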