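# bridgeprs

Cross-ancestry polygenic risk scores by two-stage Bayesian ridge regression.

Polygenic risk scores (PRS) trained on one ancestry lose much of their
accuracy when applied to another: linkage disequilibrium (LD) and allele
frequencies differ between populations, and the GWAS available for most
non-European ancestries are comparatively underpowered. `bridgeprs`
addresses this by *bridging*: the SNP-effect posterior learned from a
well-powered discovery-population GWAS becomes the prior for the target
population, whose own GWAS then updates it. It is aimed at statistical
geneticists building PRS for under-represented ancestries from GWAS summary
statistics plus modest individual-level test/validation data.

## The model

All modelling is per locus, with loci defined by LD clumping
(`--clump-p1 0.01 --clump-p2 0.01 --clump-kb 1000 --clump-r2 0.01`
semantics) and treated as independent.

**Stage 1 (single population).** With marginal GWAS effects β̂, allele
frequencies θ and per-locus genotypic covariance Φ estimated from a
reference panel, a zero-centred conjugate Gaussian prior with SNP-specific
precision λ_k = λ⁽⁰⁾(θ_k(1−θ_k))^α gives the closed-form posterior

    β ~ N(β̃₁, ψ Ω₁⁻¹),   Ω₁ = diag(λ) + Φ,   β̃₁ = Ω₁⁻¹ diag(Φ) β̂

(ψ, the residual variance, cancels from every score). Models are fitted on
a grid α ∈ {0, 0.25, 0.5, 0.75, 1}, λ⁽⁰⁾ ∈ {0.05, 0.1, 0.2, 0.5, 1, 2, 5};
loci are thresholded into nested subsets S_k by top-SNP p < 10⁻ᵏ
(k = 1..8); the 280 resulting genome-wide scores are combined by ridge
regression on held-out test individuals with the penalty chosen by
closed-form leave-one-out cross-validation.

**Stage 2 (bridging).** The best-fitting stage-1 posterior becomes the
target-population prior, β₂ ~ N(β̃₁, ψ(τΩ₁)⁻¹), with τ controlling how much
the discovery population is trusted (τ→∞ copies its effects). The conjugate
update with target summary statistics gives Ω₂ = τΩ₁ + Φ₂ and
β̃₂ = Ω₂⁻¹(τΩ₁β̃₁ + diag(Φ₂)β̂₂), fitted over
τ ∈ {1, 2, 5, 10, 15, 20, 50, 100, 200, 500}. Variants missing from the
target data are handled by Gaussian conditioning of the prior on their
effects being zero. Because single-SNP p-values rank loci poorly across
LD structures, loci are ranked by a pseudo-F statistic,
F = (n_eff − k)/(kσ²) · β̃₂ᵀΩ₂β̃₂ with n_eff = n(1+τ), quantile-matched so
each S_k keeps as many loci as the p-value ranking would.

**Combining.** Three candidate models — M1 (two-stage), M2 (target-only
stage 1) and M3 (ridge stack over the union of both score grids) — are
weighted by their approximate evidence, w_i ∝ σ_i^(−n) with σ_i² each
model's cross-validated residual variance. The final PRS is the weighted
sum, exportable as a flat per-SNP weight file.

The package also ships a two-population synthetic-data generator
(Balding–Nichols frequency divergence, population-specific block LD via
thresholded AR(1) Gaussians, causal effects correlated 0.9 across
populations, marginal-regression GWAS), so the entire pipeline runs and is
tested without any external data.

## Worked example

```python
import bridgeprs as bp

# a two-population world: 8000/2000/2000 discovery train/test/validation,
# 2000/2000/2000 target; 1000 variants in 50 LD blocks; 5% causal;
# h2 = 0.5; cross-population effect correlation 0.9; FST = 0.12
world = bp.make_world(bp.default_small_world(seed=1))
result = bp.run_pipeline(world)
print({k: round(v, 4) for k, v in result.r2.items()})
```

prints (seed 1):

```
{'final': 0.4351, 'M1': 0.3924, 'M2': 0.4196, 'M3': 0.4351}
```

i.e. on the target population's untouched validation split, the bridged and
model-averaged score (`final`) explains 43.5% of trait variance versus
42.0% for the target-only model (`M2`) — the discovery GWAS's extra power
carries over. `M1` is the two-stage score alone and `M3` the merged stack.

The same pipeline is available from the shell:

```sh
bridgeprs run-all --seed 1 --out results/demo
bridgeprs simulate --seed 1 --out world/    # PLINK + phenotype + GWAS files
bridgeprs stage1 --sumstats world/pop1.sumstats.tsv --ld-panel world/pop1 \
    --test-geno world/pop1 --test-pheno world/pop1.pheno.tsv \
    --splits world/pop1.splits.json --out s1.json
```

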