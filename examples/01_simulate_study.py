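"""Simulate a two-tissue study with planted co-regulation and inspect its truth.

The generator plants clusters of genes that share a causal variant (the
ground truth for co-regulation), independent eQTL genes and null genes, on
an LD-structured genotype panel shared by all tissues.
"""

from coreg.simulate import default_study_config, simulate_study

config = default_study_config(seed=42, n_samples=300, n_tissues=2)
genotypes, tissues, truth = simulate_study(config)

print(f"genotypes: {genotypes.n_samples} samples x {genotypes.n_variants} variants")
print(f"MAF range: {genotypes.variants['maf'].min():.3f}-{genotypes.variants['maf'].max():.3f}")
for t, (expr, cov) in enumerate(tissues):
    print(f"tissue {t}: {expr.n_genes} genes, {cov.n_covariates} covariates, "
          f"{len(truth.egenes[t])} true eGenes, {len(truth.pairs[t])} true co-regulated pairs")
print("planted clusters (tissue 0):")
for cluster in sorted(truth.clusters[0], key=sorted):
    print("  ", ", ".join(sorted(cluster)))
# Genes listed together share one causal variant, so a correct pipeline
# should rediscover exactly these gene sets as regulatory clusters.
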