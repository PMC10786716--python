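# Methods

## Model and assumptions

Trait values at a locus are modelled as y ~ N(Xβ, ψI) with X the 0–2
effect-allele dosage matrix and ψ the residual precision-scale; the
Gaussian is parameterized by mean and precision throughout. Loci are
assumed independent, which clumping (disjoint assignment of every variant
to at most one lead) enforces structurally. Within a locus, the conjugate
Gaussian prior/posterior pair keeps every update closed-form; no sampling
is involved anywhere in the pipeline.

Summary statistics enter through two reconstructions:

* X̃ᵀỹ/n is recovered per SNP as Var(x_k)·β̂_k, where Var(x_k) is the
  diagonal of the panel-estimated genotypic covariance Φ. Under
  Hardy–Weinberg equilibrium Var(x_k) = 2θ_k(1−θ_k), so this is the usual
  frequency formula evaluated on the panel's own scale. The choice makes
  two identities exact rather than approximate: with in-sample Φ the
  summary-statistic posterior mean equals penalized least squares on the
  individual-level data, and the one-SNP flat-prior limit returns β̂ for
  any panel. Both are asserted in the test suite at 1e-6 relative error or
  better.
* X̃ᵀX̃ = nΦ, with Φ the ddof = 0 sample covariance of mean-centred panel
  dosages (so the identity is exact, not up to n/(n−1)).

ψ cancels from every posterior mean and score and is never assigned a
value. The only place a phenotypic variance is needed is the pseudo-F
statistic; there σ² is estimated from the target summary statistics as the
median over variants of 2θ(1−θ)(n·se² + β̂²), whose two terms recover the
residual and explained variance contributions per SNP. The median makes
the estimate robust to the few large-effect variants.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| λ⁽⁰⁾ grid | 0.05–5 (7 values) | base prior precision; n-rescaled, so λ⁽⁰⁾ = 0.05 at n = 2000 means a penalty of 100 trait-variance units |
| α grid | 0–1 (5 values) | frequency-dependence of the prior; α = 1 assumes larger effects at rarer alleles |
| k grid | 1–8 | locus subsets by top-SNP p < 10⁻ᵏ (strict inequality) |
| τ grid | 1–500 (10 values) | trust in the discovery posterior; τ→∞ copies population-1 effects |
| clump p1, p2, kb, r² | 0.01, 0.01, 1000, 0.01 | locus definition; windows are lead-centred, ±kb, 1-based inclusive |
| ranking | `fstat` | stage-2 locus ranking; `pval` switches to discovery top-SNP p |

Grid-search selection notes: the best stage-1 prior is the single grid
column maximizing test-set R² (ties broken toward the smallest
(λ⁽⁰⁾, α, k) lexicographically, for determinism). α is only weakly
identified by this criterion — its signature concentrates at rare,
low-variance SNPs that contribute little to a score's R², and the λ⁽⁰⁾
grid absorbs most of its overall-shrinkage effect — so no particular
selected α should be expected even when the generative architecture is
frequency-independent. The stacked score, which weights all grid columns,
is insensitive to this.

## Ridge stacking

Score-grid columns are centred and scaled to unit variance (zero-variance
columns are frozen at weight 0), the trait is residualized on covariates
first, and the ridge penalty is selected from 50 log-spaced values spanning
[10⁻⁴, 10⁴]·n — from near-OLS to near-total shrinkage at any test-set size
— by exact leave-one-out error computed from the hat-matrix diagonal of a
single SVD. The same LOO residual variance at the selected penalty serves
as each candidate model's σ_i² in the evidence weights
w_i ∝ exp(−(n/2)·log σ_i²); lower cross-validated residual variance yields
higher weight, computed in log space with max-subtraction. LOO is used as
the common "fold" scheme for all models so the weights are comparable and
the whole pipeline is deterministic.

## Incomplete overlap and orientation

Stage 2 intersects each discovery locus with the variants present in the
target summary statistics and conditions the prior on the missing effects
being zero (precision-form Gaussian conditioning: mean
β̃₁⁽ᵃ⁾ + (Ω₁⁽ᵃᵃ⁾)⁻¹Ω₁⁽ᵃᵇ⁾β̃₁⁽ᵇ⁾, precision Ω₁⁽ᵃᵃ⁾). Loci with no overlap
are dropped with a log entry. Harmonization matches variants by
(chrom, pos, unordered allele pair) — not rsid — flips effect signs,
frequencies and dosage orientation where effect alleles are swapped, and
drops strand-ambiguous A/T and C/G variants by default (configurable);
frequency-based disambiguation is unreliable near θ = 0.5, so it is not
attempted. Matched variants inherit the left-hand dataset's ids so
downstream id-joins are consistent.

## Synthetic-data generator

The generator emulates exactly the features the method exploits, at desk
scale:

* **Frequency divergence** — Balding–Nichols: ancestral θ ~ U(0.05, 0.95),
  population frequencies Beta(θ(1−F)/F, (1−θ)(1−F)/F) with F the target
  FST. Within a block, ancestral and population draws are coupled through
  Gaussian copulas (AR(1), coherence 0.9) with marginals unchanged:
  variants in tight LD have similar frequencies, as in real data, and the
  Hudson-estimator FST still matches the target (verified at ±0.03).
* **Population-specific LD** — two latent AR(1) Gaussian haplotype draws
  per individual, thresholded at the frequency-matched quantile. The
  latent correlation is tetrachoric-corrected (sin(πr/2)) so the config
  parameter tracks the realized mean adjacent dosage correlation; per-pair
  correlations remain bounded by the frequency margins, which is a real
  property of binary data, not an artefact. Defaults 0.85 (discovery,
  European-like) and 0.5 (target, African-like). Blocks are placed 3 Mb
  apart so no clumping window spans two blocks.
* **Architecture** — round(causal_fraction·m) causal variants, effects
  drawn bivariate-Gaussian with cross-population correlation 0.9
  (exactly shared when ρ = 1); phenotype noise is scaled to hit the target
  SNP heritability (realized h² verified at ±0.05 for n = 5000).
* **GWAS** — per-variant marginal least squares with two-sided t p-values;
  zero-variance variants are dropped with a log entry.

Canonical study design (`default_small_world`): discovery population of
12,000 (8,000 GWAS / 2,000 test / 2,000 validation), target of 6,000
(2,000 / 2,000 / 2,000), 50 blocks × 20 variants, 5% causal, h² = 0.5,
ρ_β = 0.9, FST = 0.12. These sizes keep a full ten-replicate pipeline
comparison under a minute per replicate on one CPU while leaving the
bridging signal detectable. For file-based runs the default split is
(2/3, 1/6, 1/6), the scheme typical of biobank analyses; the canonical
design overrides the target's splits to equal thirds so its GWAS is
genuinely underpowered relative to the discovery GWAS.

What the generator does **not** emulate: recombination-map-driven LD decay
and haplotype mosaics, allele-frequency-dependent architectures (effect
variance is frequency-independent, i.e. generative α = 0), selection,
binary traits, covariate structure, and cryptic relatedness. Passing tests
therefore demonstrate the estimator's internal correctness and the
direction of its comparative advantages, not absolute real-data accuracy.

## Numerical choices and degenerate inputs

* Posterior solves use `np.linalg.solve` on diag(λ)+Φ, which is positive
  definite for any λ > 0 even when Φ is rank-deficient (duplicate
  variants); no jitter is added by default, but `jitter` is exposed.
* Clump tie-breaks: equal p-values resolve toward the smaller
  (chrom, pos); quantile-matching ties at the F cut are included
  (erring toward inclusion, logged).
* Missing dosages are mean-filled per variant; monomorphic variants are
  dropped (or rejected, per flag) on read.
* The pseudo-F requires n_eff = n(1+τ) > locus dimension; violations raise.
* Bootstrap confidence intervals are percentile-based; adjusted R² is
  reported as computed, including negative values, to preserve small
  differences between methods.
* All randomness flows through `numpy` Generators seeded from one
  SeedSequence with one sub-stream per generative step; identical configs
  give bit-identical worlds, and the CLI manifest hashes reproduce.

## Known limitations

Binary traits are not modelled (no liability-scale R²). The evidence
approximation ignores model complexity beyond the residual variance, so
with many test samples the merged model M3, which nests the others, tends
to take most of the weight. Stage 2 re-uses discovery-defined loci for the
two-stage model by design; target-specific signal outside those loci is
captured only through the target-only model M2. LD is estimated from
user-supplied genotype panels; a badly mismatched panel degrades the
posterior like any LD-aware summary-statistic method.
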