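"""Bridge discovery-population posteriors to a target population.

The stage-1 posterior for the discovery population, N(beta_tilde_1,
psi Omega_1^-1), becomes the prior for the target population's SNP effects,
with a bridging parameter tau scaling its precision:

    beta_2 ~ N(beta_tilde_1, psi (tau Omega_1)^-1)   a priori
    beta_2 ~ N(beta_tilde_2, psi Omega_2^-1)         a posteriori, where
    Omega_2 = tau Omega_1 + Phi_2
    beta_tilde_2 = Omega_2^-1 (tau Omega_1 beta_tilde_1 + diag(Phi_2) beta_hat_2)

Small tau discounts the discovery information (the target-population data
dominate); as tau grows the posterior mean is pulled to beta_tilde_1.
Variants absent from the target data are handled by Gaussian conditioning of
the prior on their effects being zero.

Because single-SNP p-values rank loci poorly when LD differs between
populations, loci are ranked by a pseudo-F statistic — the classical
multivariate F with the maximum-likelihood quantities replaced by posterior
ones and the sample size by n_eff = n (1 + tau) — and thresholded so each
subset S_k keeps exactly as many loci as the top-SNP p-value ranking would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import GenotypePanel, PhenotypeTable, SumStats, harmonize
from .loci import LDBlock, Locus, compute_phi
from .stage1 import (PosteriorBlock, PRSGrid, StackedPRS, Stage1Model,
                     _locus_scores, stack_ridge)

logger = logging.getLogger("bridgeprs")

#: bridging-parameter grid explored in stage 2
DEFAULT_TAUS = (1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 50.0, 100.0, 200.0, 500.0)


@dataclass(frozen=True)
class PriorSpec2:
    """Stage-2 prior: precision multiplier tau > 0 on the stage-1 posterior."""

    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class PseudoF:
    locus_id: str
    f_bayes: float
    n_eff: float
    k: int                      # locus dimension


def conditional_prior(post1: PosteriorBlock, overlap: np.ndarray,
                      missing: np.ndarray) -> PosteriorBlock | None:
    """Condition a stage-1 posterior on absent variants having zero effect.

    ``overlap`` and ``missing`` are disjoint index arrays partitioning the
    members. Gaussian conditioning in precision form gives mean
    beta_a + Omega_aa^-1 Omega_ab beta_b and precision Omega_aa. Returns
    None (locus dropped) when no member overlaps.
    """
    overlap = np.asarray(overlap, dtype=int)
    missing = np.asarray(missing, dtype=int)
    m = len(post1.member_ids)
    if sorted(np.concatenate([overlap, missing]).tolist()) != list(range(m)):
        raise ValueError("overlap and missing must partition the members")
    if len(overlap) == 0:
        logger.info("locus %s: no variants shared with population 2, dropped",
                    post1.locus_id)
        return None
    if len(missing) == 0:
        return post1
    O = post1.omega
    O_aa = O[np.ix_(overlap, overlap)]
    O_ab = O[np.ix_(overlap, missing)]
    mean = post1.beta_tilde[overlap] + np.linalg.solve(
        O_aa, O_ab @ post1.beta_tilde[missing])
    return PosteriorBlock(post1.locus_id,
                          [post1.member_ids[i] for i in overlap],
                          mean, O_aa, post1.prior)


def posterior_update2(block2: LDBlock, s2: SumStats, tau: float,
                      prior: PosteriorBlock) -> PosteriorBlock:
    """Conjugate target-population update of the (conditioned) stage-1 prior."""
    members = block2.locus.members
    if list(s2.table["id"]) != list(members) or prior.member_ids != list(members):
        raise ValueError("population-2 statistics, LD block and prior must "
                         "cover the same variants in the same order")
    omega2 = tau * prior.omega + block2.phi
    rhs = tau * (prior.omega @ prior.beta_tilde) + np.diag(block2.phi) * s2.beta
    beta2 = np.linalg.solve(omega2, rhs)
    return PosteriorBlock(prior.locus_id, list(members), beta2, omega2,
                          PriorSpec2(tau=tau))


def estimate_sigma2(s2: SumStats) -> float:
    """Phenotypic variance implied by the summary statistics.

    Per variant, n * se^2 * Var(x) recovers the residual variance and
    beta_hat^2 * Var(x) the variance explained, with Var(x) = 2 theta(1-theta)
    under HWE; their sum approximates Var(y). The median over variants is
    robust to the handful of large-effect variants.
    """
    if len(s2) == 0:
        raise ValueError("empty summary statistics")
    v = 2.0 * s2.freq * (1.0 - s2.freq) * (s2.n * s2.se ** 2 + s2.beta ** 2)
    return float(np.median(v))


def pseudo_f(post2: PosteriorBlock, n: int, tau: float, sigma2: float) -> PseudoF:
    """Locus association strength from posterior quantities.

    F_Bayes = (n_eff - k) / (k sigma2) * beta_tilde_2' Omega_2 beta_tilde_2
    with n_eff = n (1 + tau) the effective observation count including the
    prior. In the flat-prior limit this is the first-order approximation of
    the classical F statistic, accurate when the locus explains little trait
    variance.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    k = len(post2.beta_tilde)
    n_eff = n * (1.0 + tau)
    if n_eff <= k:
        raise ValueError(f"effective sample size {n_eff} <= locus dimension {k}")
    quad = float(post2.beta_tilde @ post2.omega @ post2.beta_tilde)
    return PseudoF(post2.locus_id, (n_eff - k) / (k * sigma2) * quad, n_eff, k)


def match_quantiles(fstats: dict[str, float], top_pvals: dict[str, float],
                    k_grid) -> dict[int, set]:
    """Threshold F so each S_k matches the p-value ranking's cardinality.

    For each k, as many loci pass the F cut as satisfy p < 10^-k; ties in F
    at the cut are included (logged when the subset therefore exceeds the
    matched count).
    """
    if set(fstats) != set(top_pvals):
        raise ValueError("fstats and top_pvals must cover the same loci")
    locus_ids = list(fstats)
    f = np.array([fstats[l] for l in locus_ids])
    p = np.array([top_pvals[l] for l in locus_ids])
    out: dict[int, set] = {}
    for k in k_grid:
        count = int((p < 10.0 ** -k).sum())
        if count == 0:
            out[int(k)] = set()
            continue
        cut = np.sort(f)[::-1][count - 1]
        chosen = {locus_ids[i] for i in np.nonzero(f >= cut)[0]}
        if len(chosen) > count:
            logger.info("match_quantiles: k=%d ties at the cut, %d loci kept "
                        "for a matched count of %d", k, len(chosen), count)
        out[int(k)] = chosen
    return out


def score_grid2(posteriors: dict[float, dict], subsets_by_tau: dict[float, dict],
                geno: GenotypePanel) -> PRSGrid:
    """Genome-wide PRS per (tau, k); subsets may differ across tau because
    the pseudo-F ranking depends on tau."""
    columns, cols = [], []
    for tau, posterior_set in posteriors.items():
        per_locus = _locus_scores(posterior_set, geno)
        for k, subset in subsets_by_tau[tau].items():
            col = np.zeros(geno.n_samples)
            for locus_id in subset:
                if locus_id in per_locus:
                    col += per_locus[locus_id]
            columns.append((tau, k))
            cols.append(col)
    return PRSGrid(geno.sample_ids, columns,
                   np.column_stack(cols) if cols
                   else np.zeros((geno.n_samples, 0)))


def grid_snp_weights2(posteriors: dict[float, dict],
                      subsets_by_tau: dict[float, dict]):
    """Per-variant weights of each (tau, k) column, as a DataFrame."""
    import pandas as pd

    variant_ids, seen = [], set()
    for posterior_set in posteriors.values():
        for post in posterior_set.values():
            for m in post.member_ids:
                if m not in seen:
                    seen.add(m)
                    variant_ids.append(m)
        break
    row = {v: i for i, v in enumerate(variant_ids)}
    columns, data = [], []
    for tau, posterior_set in posteriors.items():
        for k, subset in subsets_by_tau[tau].items():
            w = np.zeros(len(variant_ids))
            for locus_id in subset:
                post = posterior_set.get(locus_id)
                if post is None:
                    continue
                for m, b in zip(post.member_ids, post.beta_tilde):
                    w[row[m]] += b
            columns.append((tau, k))
            data.append(w)
    return pd.DataFrame(np.column_stack(data) if data else
                        np.zeros((len(variant_ids), 0)),
                        index=variant_ids, columns=columns)


# ---------------------------------------------------------------------------
# stage-2 driver
# ---------------------------------------------------------------------------

@dataclass
class Stage2Model:
    """Bridged posteriors over the tau grid plus their stacked PRS."""

    sumstats2: SumStats           # harmonized to the stage-1 orientation
    posteriors: dict              # tau -> {locus_id: PosteriorBlock}
    subsets_by_tau: dict          # tau -> {k: set of locus ids}
    fstats: dict                  # tau -> {locus_id: PseudoF}
    sigma2: float
    grid: PRSGrid
    stacked: StackedPRS

    def score_panel(self, geno: GenotypePanel) -> PRSGrid:
        _, geno_h, _ = harmonize(self.sumstats2, geno)
        return score_grid2(self.posteriors, self.subsets_by_tau, geno_h)

    def predict(self, geno: GenotypePanel) -> np.ndarray:
        return self.stacked.apply(self.score_panel(geno))

    def snp_weights(self):
        import pandas as pd

        W = grid_snp_weights2(self.posteriors, self.subsets_by_tau)
        W = W[self.grid.columns]
        return pd.Series(W.to_numpy() @ self.stacked.ridge_weights,
                         index=W.index, name="weight").to_frame()


def save_stage2_model(model: Stage2Model, path) -> None:
    """Serialize a stage-2 fit as a JSON container (mirrors stage 1's)."""
    import json

    import pandas as pd  # noqa: F401  (kept close to its use below)

    any_tau = next(iter(model.posteriors))
    members = {lid: p.member_ids
               for lid, p in model.posteriors[any_tau].items()}
    from .stage1 import _stacked_to_dict
    doc = {
        "kind": "bridgeprs-stage2",
        "sumstats2": {"table": model.sumstats2.table.to_dict("list"),
                      "n": model.sumstats2.n},
        "members": members,
        "posteriors": {str(tau): {lid: p.beta_tilde.tolist()
                                  for lid, p in posts.items()}
                       for tau, posts in model.posteriors.items()},
        "subsets_by_tau": {str(tau): {str(k): sorted(v)
                                      for k, v in subs.items()}
                           for tau, subs in model.subsets_by_tau.items()},
        "fstats": {str(tau): {lid: pf.f_bayes for lid, pf in fs.items()}
                   for tau, fs in model.fstats.items()},
        "sigma2": model.sigma2,
        "stacked": _stacked_to_dict(model.stacked),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_stage2_model(path) -> Stage2Model:
    import json

    import pandas as pd

    from .stage1 import _stacked_from_dict

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("kind") != "bridgeprs-stage2":
        raise ValueError(f"{path} is not a stage-2 model file")
    sumstats2 = SumStats(pd.DataFrame(doc["sumstats2"]["table"]),
                         doc["sumstats2"]["n"])
    members = doc["members"]
    posteriors = {}
    fstats = {}
    for tau_s, posts in doc["posteriors"].items():
        tau = float(tau_s)
        posteriors[tau] = {
            lid: PosteriorBlock(lid, list(members[lid]), np.array(bt), None,
                                PriorSpec2(tau=tau))
            for lid, bt in posts.items()}
        fstats[tau] = {lid: PseudoF(lid, f, sumstats2.n * (1.0 + tau),
                                    len(members[lid]))
                       for lid, f in doc["fstats"][tau_s].items()}
    subsets_by_tau = {float(tau_s): {int(k): set(v) for k, v in subs.items()}
                      for tau_s, subs in doc["subsets_by_tau"].items()}
    stacked = _stacked_from_dict(doc["stacked"])
    return Stage2Model(sumstats2, posteriors, subsets_by_tau, fstats,
                       float(doc["sigma2"]), stacked.grid, stacked)


def run_stage2(stage1_model: Stage1Model, sumstats2: SumStats,
               ld_panel2: GenotypePanel, test_geno: GenotypePanel,
               test_pheno: PhenotypeTable, taus=DEFAULT_TAUS,
               k_grid=None, ranking: str = "fstat",
               jitter: float = 0.0) -> Stage2Model:
    """Bridge the stage-1 best-prior posteriors into the target population.

    Loci are the stage-1 (discovery-defined) loci intersected with the
    variants available in the target summary statistics; the prior at each
    locus is the stage-1 posterior conditioned on non-overlapping variants
    having zero effect. ``ranking`` selects how loci enter the subsets:
    "fstat" (pseudo-F with quantile matching, default) or "pval" (discovery
    top-SNP p-value).
    """
    if ranking not in ("fstat", "pval"):
        raise ValueError("ranking must be 'fstat' or 'pval'")
    if k_grid is None:
        k_grid = sorted(stage1_model.subsets)
    # orient population-2 statistics like the stage-1 model, then the panel
    _, s2_h, _ = harmonize(stage1_model.sumstats, sumstats2)
    s2_h, panel2_h, _ = harmonize(s2_h, ld_panel2)
    s2_pos = {v: i for i, v in enumerate(s2_h.table["id"])}

    restricted: list[tuple[Locus, PosteriorBlock, LDBlock, SumStats]] = []
    for locus in stage1_model.loci:
        post1 = stage1_model.best_posteriors[locus.locus_id]
        keep = [i for i, m in enumerate(post1.member_ids) if m in s2_pos]
        drop = [i for i in range(len(post1.member_ids)) if i not in set(keep)]
        prior = conditional_prior(post1, np.array(keep, int), np.array(drop, int))
        if prior is None:
            continue
        members = prior.member_ids
        sub_locus = Locus(locus.locus_id, locus.lead, members, locus.top_pval,
                          locus.span)
        block2 = compute_phi(sub_locus, panel2_h, jitter=jitter)
        s2_sub = s2_h.subset([s2_pos[m] for m in members])
        restricted.append((sub_locus, prior, block2, s2_sub))
    if not restricted:
        raise ValueError("no stage-1 locus overlaps the population-2 variants")

    sigma2 = estimate_sigma2(s2_h)
    n2 = s2_h.n
    top_pvals = {loc.locus_id: loc.top_pval for loc, *_ in restricted}

    posteriors: dict[float, dict] = {}
    fstats: dict[float, dict] = {}
    subsets_by_tau: dict[float, dict] = {}
    pval_subsets = {int(k): {lid for lid, p in top_pvals.items()
                             if p < 10.0 ** -k} for k in k_grid}
    for tau in taus:
        posts = {loc.locus_id: posterior_update2(block2, s2_sub, tau, prior)
                 for loc, prior, block2, s2_sub in restricted}
        posteriors[tau] = posts
        fstats[tau] = {lid: pseudo_f(post, n2, tau, sigma2)
                       for lid, post in posts.items()}
        if ranking == "fstat":
            subsets_by_tau[tau] = match_quantiles(
                {lid: pf.f_bayes for lid, pf in fstats[tau].items()},
                top_pvals, k_grid)
        else:
            subsets_by_tau[tau] = pval_subsets
    _, test_h, _ = harmonize(s2_h, test_geno)
    grid = score_grid2(posteriors, subsets_by_tau, test_h)
    stacked = stack_ridge(grid, test_pheno)
    logger.info("stage2: %d loci bridged, sigma2=%.3g, %d grid columns",
                len(restricted), sigma2, len(grid.columns))
    return Stage2Model(s2_h, posteriors, subsets_by_tau, fstats, sigma2,
                       grid, stacked)
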