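"""Two-population synthetic genotype/phenotype worlds for end-to-end testing.

The generator reproduces the statistical structure that cross-ancestry PRS
methods actually exploit, with no external data:

* allele-frequency divergence between populations, via the Balding-Nichols
  construction — each population's frequency is Beta-distributed around a
  shared ancestral frequency with spread set by FST;
* population-specific block LD — within a block, genotypes are built from
  two latent AR(1) Gaussian haplotype draws thresholded at the frequency-
  matched quantile, so adjacent-variant correlation is tunable per
  population and blocks are independent (they are placed megabases apart);
* correlated causal architecture — a configurable fraction of variants is
  causal, with per-population effect sizes drawn from a bivariate Gaussian
  with correlation rho_beta (0.9 by default);
* additive phenotypes at a target SNP heritability, and per-SNP marginal
  least-squares GWAS summary statistics.

Defaults mirror the desk-scale study design used throughout the tests: a
well-powered discovery population (8,000 GWAS individuals) and an
underpowered target population (2,000), 50 blocks of 20 variants, 5% causal
variants, h2 = 0.5, effect correlation 0.9 and FST = 0.12, with stronger
LD in the discovery population than the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import GenotypePanel, PhenotypeTable, SumStats

logger = logging.getLogger("bridgeprs")

#: physical layout of simulated blocks: far enough apart that no clumping
#: window can join variants from different blocks
_BLOCK_SPACING_BP = 3_000_000
_VARIANT_SPACING_BP = 1_000


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the two-population synthetic world."""

    n_pop1: int = 12_000
    n_pop2: int = 6_000
    n_blocks: int = 50
    block_size: int = 20
    fst: float = 0.12
    rho_ld_1: float = 0.85
    rho_ld_2: float = 0.5
    causal_fraction: float = 0.05
    h2: float = 0.5
    rho_beta: float = 0.9
    seed: int = 0
    split_fracs: tuple = (2 / 3, 1 / 6, 1 / 6)
    splits_pop1: tuple | None = None     # absolute (train, test, validation)
    splits_pop2: tuple | None = None

    def __post_init__(self):
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        for r in (self.rho_ld_1, self.rho_ld_2):
            if not 0 <= r < 1:
                raise ValueError("LD correlations must lie in [0, 1)")
        if not 0 < self.causal_fraction <= 1:
            raise ValueError("causal_fraction must lie in (0, 1]")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0 <= self.rho_beta <= 1:
            raise ValueError("rho_beta must lie in [0, 1]")
        if self.block_size < 1 or self.n_blocks < 1:
            raise ValueError("need at least one block of at least one variant")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size


def default_small_world(seed: int = 0) -> SimConfig:
    """The canonical desk-scale study design (see module docstring)."""
    return SimConfig(seed=seed, splits_pop1=(8_000, 2_000, 2_000),
                     splits_pop2=(2_000, 2_000, 2_000))


@dataclass
class SimWorld:
    config: SimConfig
    panels: dict               # population (1|2) -> GenotypePanel
    phenos: dict               # population -> PhenotypeTable
    causal_idx: np.ndarray
    effects: dict              # population -> per-variant true effects
    splits: dict               # population -> {"train"/"test"/"validation": ids}


# ---------------------------------------------------------------------------
# generative steps
# ---------------------------------------------------------------------------

#: within-block coherence of allele frequencies (Gaussian-copula AR(1)
#: parameter): variants in tight LD have similar frequencies, as in real data
_FREQ_COHERENCE = 0.9


def _block_copula_uniforms(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-variant U(0,1) draws, AR(1)-correlated within each block."""
    bs = cfg.block_size
    C = _FREQ_COHERENCE ** np.abs(np.subtract.outer(np.arange(bs),
                                                    np.arange(bs)))
    L = np.linalg.cholesky(C + 1e-12 * np.eye(bs))
    z = rng.standard_normal((cfg.n_blocks, bs)) @ L.T
    return stats.norm.cdf(z).ravel()


def draw_frequencies(cfg: SimConfig, rng: np.random.Generator):
    """Ancestral and per-population allele frequencies (Balding-Nichols).

    Ancestral theta ~ U(0.05, 0.95) per variant; each population draws
    Beta(theta(1-F)/F, (1-theta)(1-F)/F), which has mean theta and variance
    F * theta(1-theta) — F = 0 copies the ancestral frequencies exactly.
    Within a block the draws are coupled by a Gaussian copula (marginals
    unchanged), so frequencies vary smoothly across variants in LD as they
    do in real data.
    """
    theta = 0.05 + 0.9 * _block_copula_uniforms(cfg, rng)
    if cfg.fst == 0:
        return theta, theta.copy(), theta.copy()
    scale = (1.0 - cfg.fst) / cfg.fst
    pops = []
    for _ in range(2):
        u = _block_copula_uniforms(cfg, rng)
        draw = stats.beta.ppf(u, theta * scale, (1.0 - theta) * scale)
        pops.append(np.clip(draw, 1e-6, 1 - 1e-6))
    return theta, pops[0], pops[1]


def _variant_table(cfg: SimConfig) -> pd.DataFrame:
    pos, ids = [], []
    for b in range(cfg.n_blocks):
        start = 1 + b * _BLOCK_SPACING_BP
        for j in range(cfg.block_size):
            pos.append(start + j * _VARIANT_SPACING_BP)
            ids.append(f"rs{b * cfg.block_size + j + 1}")
    return pd.DataFrame({"id": ids, "chrom": "1", "pos": pos,
                         "effect_allele": "A", "other_allele": "G"})


def draw_genotypes(freqs: np.ndarray, cfg: SimConfig, rho_ld: float,
                   n: int, rng: np.random.Generator,
                   sample_prefix: str) -> GenotypePanel:
    """Blockwise thresholded-Gaussian genotypes.

    Two latent haplotype draws per individual follow an AR(1) Gaussian within
    each block; a haplotype carries the effect allele when its latent value
    exceeds the frequency-matched normal quantile, so marginal frequencies
    match ``freqs`` in expectation and adjacent-variant dosage correlation
    rises with ``rho_ld``.
    """
    bs = cfg.block_size
    # thresholding a Gaussian attenuates correlation; the tetrachoric-style
    # inverse sin(pi r / 2) makes the realized adjacent dosage correlation
    # track rho_ld (exact at threshold zero, approximate elsewhere)
    rho_latent = np.sin(np.pi * rho_ld / 2.0)
    C = rho_latent ** np.abs(np.subtract.outer(np.arange(bs), np.arange(bs)))
    L = np.linalg.cholesky(C + 1e-12 * np.eye(bs))
    thresholds = stats.norm.ppf(1.0 - freqs)
    dosages = np.empty((n, cfg.n_variants), dtype=float)
    for b in range(cfg.n_blocks):
        sl = slice(b * bs, (b + 1) * bs)
        t = thresholds[sl]
        hap1 = rng.standard_normal((n, bs)) @ L.T > t
        hap2 = rng.standard_normal((n, bs)) @ L.T > t
        dosages[:, sl] = hap1.astype(float) + hap2.astype(float)
    sample_ids = np.array([f"{sample_prefix}_{i:05d}" for i in range(n)],
                          dtype=object)
    return GenotypePanel(sample_ids, _variant_table(cfg), dosages)


def draw_effects(cfg: SimConfig, rng: np.random.Generator):
    """Causal set and correlated per-population true effects.

    round(causal_fraction * m) variants (at least one) are causal, sampled
    uniformly; their (beta1, beta2) pairs come from a bivariate standard
    Gaussian with correlation rho_beta. Non-causal effects are exactly zero.
    """
    m = cfg.n_variants
    n_causal = max(1, round(cfg.causal_fraction * m))
    causal_idx = np.sort(rng.choice(m, size=n_causal, replace=False))
    if cfg.rho_beta == 1.0:
        shared = rng.standard_normal(n_causal)
        draws = np.column_stack([shared, shared])
    else:
        cov = np.array([[1.0, cfg.rho_beta], [cfg.rho_beta, 1.0]])
        draws = rng.multivariate_normal(np.zeros(2), cov, size=n_causal)
    beta1, beta2 = np.zeros(m), np.zeros(m)
    beta1[causal_idx] = draws[:, 0]
    beta2[causal_idx] = draws[:, 1]
    return causal_idx, beta1, beta2


def make_phenotypes(panel: GenotypePanel, effects: np.ndarray, h2: float,
                    rng: np.random.Generator) -> PhenotypeTable:
    """Additive phenotype with Gaussian noise set to hit heritability h2.

    y = g + e with g = X beta and Var(e) = Var(g)(1 - h2)/h2, so the realized
    Var(g)/Var(y) concentrates on h2.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1)")
    g = panel.dosages @ effects
    var_g = float(g.var())
    if var_g == 0:
        raise ValueError("no causal genetic variation in this panel")
    noise = rng.standard_normal(len(g)) * np.sqrt(var_g * (1 - h2) / h2)
    return PhenotypeTable(panel.sample_ids, g + noise)


def run_gwas(panel: GenotypePanel, pheno: PhenotypeTable) -> SumStats:
    """Per-variant marginal least-squares GWAS (two-sided t p-values)."""
    if list(panel.sample_ids) != list(pheno.sample_ids):
        raise ValueError("panel and phenotype samples differ")
    n = panel.n_samples
    if n < 30:
        raise ValueError("need at least 30 samples for a GWAS")
    X = panel.dosages
    y = pheno.y - pheno.y.mean()
    Xc = X - X.mean(axis=0)
    sxx = (Xc ** 2).sum(axis=0)
    keep = sxx > 0
    if (~keep).any():
        logger.warning("run_gwas: dropped %d zero-variance variant(s)",
                       int((~keep).sum()))
    Xc, sxx = Xc[:, keep], sxx[keep]
    sxy = Xc.T @ y
    beta = sxy / sxx
    rss = float(y @ y) - beta * sxy
    df = n - 2
    se = np.sqrt(np.maximum(rss, 0.0) / (df * sxx))
    with np.errstate(divide="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    table = panel.variants.loc[keep].reset_index(drop=True).copy()
    table["beta"] = beta
    table["se"] = se
    table["freq"] = X[:, keep].mean(axis=0) / 2.0
    table["pval"] = pval
    return SumStats(table, n)


def theoretical_portability(n: int, h2: float, m: int) -> float:
    """Expected r^2/h2 of a clump-and-threshold score, (1 + m/(n h2))^-1.

    Under independent causal variants, prediction accuracy depends on the
    study only through n h2 / m — doubling heritability buys as much power
    as doubling the GWAS sample size.
    """
    if n < 1 or m < 1 or not 0 < h2 <= 1:
        raise ValueError("need n, m >= 1 and h2 in (0, 1]")
    return 1.0 / (1.0 + m / (n * h2))


# ---------------------------------------------------------------------------
# world assembly
# ---------------------------------------------------------------------------

def _split_ids(sample_ids: np.ndarray, cfg: SimConfig,
               explicit: tuple | None) -> dict:
    n = len(sample_ids)
    if explicit is not None:
        if sum(explicit) != n:
            raise ValueError(f"explicit splits {explicit} must sum to {n}")
        n_train, n_test, _ = explicit
    else:
        n_train = int(n * cfg.split_fracs[0])
        n_test = int(n * cfg.split_fracs[1])
    return {"train": sample_ids[:n_train],
            "test": sample_ids[n_train:n_train + n_test],
            "validation": sample_ids[n_train + n_test:]}


def make_world(cfg: SimConfig) -> SimWorld:
    """Deterministically generate the full two-population world from cfg.seed.

    Randomness is funneled through one seed sequence with an independent
    sub-stream per generative step, so identical configs give bit-identical
    worlds.
    """
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(cfg.seed).spawn(6)]
    rng_freq, rng_g1, rng_g2, rng_eff, rng_p1, rng_p2 = streams
    _, theta1, theta2 = draw_frequencies(cfg, rng_freq)
    panel1 = draw_genotypes(theta1, cfg, cfg.rho_ld_1, cfg.n_pop1, rng_g1, "p1")
    panel2 = draw_genotypes(theta2, cfg, cfg.rho_ld_2, cfg.n_pop2, rng_g2, "p2")
    causal_idx, beta1, beta2 = draw_effects(cfg, rng_eff)
    pheno1 = make_phenotypes(panel1, beta1, cfg.h2, rng_p1)
    pheno2 = make_phenotypes(panel2, beta2, cfg.h2, rng_p2)
    splits = {1: _split_ids(panel1.sample_ids, cfg, cfg.splits_pop1),
              2: _split_ids(panel2.sample_ids, cfg, cfg.splits_pop2)}
    return SimWorld(cfg, {1: panel1, 2: panel2}, {1: pheno1, 2: pheno2},
                    causal_idx, {1: beta1, 2: beta2}, splits)


def gwas_for(world: SimWorld, pop: int) -> SumStats:
    """GWAS summary statistics on a population's training split."""
    ids = world.splits[pop]["train"]
    return run_gwas(world.panels[pop].subset_samples(ids),
                    world.phenos[pop].subset(ids))


def split_panel(world: SimWorld, pop: int, which: str) -> GenotypePanel:
    return world.panels[pop].subset_samples(world.splits[pop][which])


def split_pheno(world: SimWorld, pop: int, which: str) -> PhenotypeTable:
    return world.phenos[pop].subset(world.splits[pop][which])


def drop_causal(world: SimWorld) -> SimWorld:
    """The same world with causal variants removed from the analyzable set.

    Emulates analyses where the causal variants are absent from the data and
    only LD partners tag them.
    """
    keep = np.setdiff1d(np.arange(world.config.n_variants), world.causal_idx)
    panels = {p: world.panels[p].subset_variants(keep) for p in world.panels}
    effects = {p: world.effects[p][keep] for p in world.effects}
    return SimWorld(replace(world.config), panels, world.phenos,
                    np.array([], dtype=int), effects, world.splits)
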