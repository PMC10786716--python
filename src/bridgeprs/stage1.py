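"""Single-population Bayesian ridge PRS from GWAS summary statistics.

Per locus, SNP effects get a zero-centered conjugate Gaussian prior with
SNP-specific precision lambda_k = lambda0 * (theta_k (1 - theta_k))^alpha,
where theta_k is the effect-allele frequency. With Phi the per-locus
genotypic covariance (estimated from a reference panel) the posterior is
Gaussian with mean

    beta_tilde = (diag(lambda) + Phi)^-1  diag(Phi) beta_hat

and precision Omega = diag(lambda) + Phi up to the residual-variance scalar
psi, which cancels from every posterior mean and score and is never given a
value. The right-hand side reconstructs X^T y / n from the marginal GWAS
estimates: (X^T y)_k / n = Var(x_k) * beta_hat_k, with Var(x_k) read off the
panel covariance diagonal (equal to 2 theta (1 - theta) under Hardy-Weinberg
equilibrium). Evaluated with the in-sample covariance this makes the
summary-statistic posterior identical to penalized least squares on the
individual-level data, and the one-SNP flat-prior limit returns beta_hat
exactly.

Loci are then thresholded into nested subsets S_k by their top-SNP p-value
(p < 10^-k), a genome-wide PRS is computed for every (alpha, lambda0, k)
combination, and the resulting score grid is combined by a ridge regression
on held-out test data with the penalty chosen by closed-form leave-one-out
cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import GenotypePanel, PhenotypeTable, SumStats, harmonize
from .loci import LDBlock, Locus, clump, compute_phi

logger = logging.getLogger("bridgeprs")

#: prior grids explored in stage 1
DEFAULT_ALPHAS = (0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_LAMBDA0S = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0)
DEFAULT_K_GRID = tuple(range(1, 9))


@dataclass(frozen=True)
class PriorSpec1:
    """Stage-1 prior: base shrinkage lambda0 > 0, frequency exponent alpha."""

    lambda0: float
    alpha: float

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class PosteriorBlock:
    """Gaussian posterior for one locus: beta ~ N(beta_tilde, psi * Omega^-1)."""

    locus_id: str
    member_ids: list
    beta_tilde: np.ndarray
    omega: np.ndarray
    prior: object  # PriorSpec1 or PriorSpec2


def prior_precision(theta: np.ndarray, spec: PriorSpec1) -> np.ndarray:
    """Per-SNP prior precision lambda0 * (theta(1-theta))^alpha.

    alpha = 0 makes effect size a priori independent of allele frequency;
    alpha = 1 implies larger effects at rarer variants.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 1):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    return spec.lambda0 * (theta * (1.0 - theta)) ** spec.alpha


def posterior_update(block: LDBlock, s: SumStats, spec: PriorSpec1) -> PosteriorBlock:
    """Conjugate posterior for one locus from summary statistics and LD.

    ``s`` must be the summary statistics restricted to the locus members, in
    member order and allele-aligned with the panel that produced ``block``.
    """
    members = block.locus.members
    if len(s) != len(members) or list(s.table["id"]) != list(members):
        raise ValueError("summary statistics not aligned to locus members")
    lam = prior_precision(s.freq, spec)
    omega = np.diag(lam) + block.phi
    rhs = np.diag(block.phi) * s.beta  # (X^T y)/n via panel genotypic variance
    beta_tilde = np.linalg.solve(omega, rhs)
    return PosteriorBlock(block.locus.locus_id, list(members), beta_tilde,
                          omega, spec)


def assign_subsets(loci: list[Locus], k_grid=DEFAULT_K_GRID) -> dict[int, set]:
    """Nested locus subsets S_k = {locus : top-SNP p < 10^-k} (strict)."""
    return {int(k): {loc.locus_id for loc in loci if loc.top_pval < 10.0 ** -k}
            for k in k_grid}


@dataclass
class PRSGrid:
    """Per-sample scores, one column per (prior setting, threshold k) label."""

    sample_ids: np.ndarray
    columns: list            # hashable labels, e.g. (lambda0, alpha, k)
    scores: np.ndarray       # samples x columns

    def __post_init__(self):
        if len(self.columns) != len(set(self.columns)):
            raise ValueError("duplicate grid column labels")
        if self.scores.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores in grid")


def _locus_scores(posterior_set: dict, geno: GenotypePanel):
    """Per-sample score of each locus: X_l beta_tilde_l, absent variants -> 0."""
    pos = {v: j for j, v in enumerate(geno.variants["id"])}
    out = {}
    n_absent = 0
    for locus_id, post in posterior_set.items():
        cols, weights = [], []
        for m, b in zip(post.member_ids, post.beta_tilde):
            j = pos.get(m)
            if j is None:
                n_absent += 1
                continue
            cols.append(j)
            weights.append(b)
        out[locus_id] = (geno.dosages[:, cols] @ np.asarray(weights)
                         if cols else np.zeros(geno.n_samples))
    if n_absent:
        logger.info("score grid: %d posterior variant(s) absent from panel, "
                    "contributing 0", n_absent)
    return out


def score_grid(posteriors: dict, subsets: dict[int, set],
               geno: GenotypePanel) -> PRSGrid:
    """Genome-wide PRS for every (prior setting, k): sum of X_l beta_tilde.

    ``posteriors`` maps a prior label (e.g. ``(lambda0, alpha)``) to a dict
    ``locus_id -> PosteriorBlock``. Empty subsets give an all-zero, labeled
    column.
    """
    columns, score_cols = [], []
    for prior_label, posterior_set in posteriors.items():
        per_locus = _locus_scores(posterior_set, geno)
        for k, subset in subsets.items():
            col = np.zeros(geno.n_samples)
            for locus_id in subset:
                if locus_id in per_locus:
                    col += per_locus[locus_id]
            label = (prior_label + (k,)) if isinstance(prior_label, tuple) \
                else (prior_label, k)
            columns.append(label)
            score_cols.append(col)
    return PRSGrid(geno.sample_ids, columns,
                   np.column_stack(score_cols) if score_cols
                   else np.zeros((geno.n_samples, 0)))


def grid_snp_weights(posteriors: dict, subsets: dict[int, set]) -> pd.DataFrame:
    """Per-variant additive weights of each grid column (variants x columns).

    Row index is the variant id; entry (v, (prior, k)) is beta_tilde_v if v's
    locus is in S_k, else 0. Used to collapse ridge-stacked grids to a single
    SNP-weight vector.
    """
    variant_ids: list = []
    seen = set()
    for posterior_set in posteriors.values():
        for post in posterior_set.values():
            for m in post.member_ids:
                if m not in seen:
                    seen.add(m)
                    variant_ids.append(m)
        break  # every prior covers the same loci/members
    row = {v: i for i, v in enumerate(variant_ids)}
    columns, data = [], []
    for prior_label, posterior_set in posteriors.items():
        for k, subset in subsets.items():
            w = np.zeros(len(variant_ids))
            for locus_id in subset:
                post = posterior_set.get(locus_id)
                if post is None:
                    continue
                for m, b in zip(post.member_ids, post.beta_tilde):
                    w[row[m]] += b
            label = (prior_label + (k,)) if isinstance(prior_label, tuple) \
                else (prior_label, k)
            columns.append(label)
            data.append(w)
    return pd.DataFrame(np.column_stack(data) if data else
                        np.zeros((len(variant_ids), 0)),
                        index=variant_ids, columns=columns)


# ---------------------------------------------------------------------------
# ridge stacking with closed-form leave-one-out cross-validation
# ---------------------------------------------------------------------------

def residualize(y: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of y on an intercept plus covariates (least squares)."""
    y = np.asarray(y, dtype=float)
    if covariates is None or len(covariates) == 0 or covariates.shape[1] == 0:
        return y - y.mean()
    C = np.column_stack([np.ones(len(y)), covariates.to_numpy(float)])
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


@dataclass
class StackedPRS:
    """A PRS grid collapsed to one score by cross-validated ridge."""

    grid: PRSGrid
    ridge_weights: np.ndarray     # per raw (uncentered, unscaled) column
    penalty: float
    prs: np.ndarray               # per training-grid sample
    sigma2: float                 # LOO residual variance at the chosen penalty
    col_means: np.ndarray = field(repr=False, default=None)
    col_stds: np.ndarray = field(repr=False, default=None)
    w_std: np.ndarray = field(repr=False, default=None)
    y_mean: float = 0.0

    def apply(self, grid: PRSGrid) -> np.ndarray:
        """Score a new grid (same columns) with the trained stacking weights."""
        if grid.columns != self.grid.columns:
            raise ValueError("grid columns differ from the stacking fit")
        Z = (grid.scores - self.col_means) / self.col_stds
        return Z @ self.w_std + self.y_mean


def _loo_ridge_path(Z: np.ndarray, yc: np.ndarray, penalties: np.ndarray):
    """LOO error of ridge on centered data for every penalty, via one SVD."""
    U, d, Vt = np.linalg.svd(Z, full_matrices=False)
    Uty = U.T @ yc
    U2 = U ** 2
    errs = np.empty(len(penalties))
    for i, a in enumerate(penalties):
        f = d ** 2 / (d ** 2 + a)
        yhat = U @ (f * Uty)
        h = U2 @ f
        loo = (yc - yhat) / np.maximum(1.0 - h, 1e-12)
        errs[i] = float(np.mean(loo ** 2))
    return errs, (U, d, Vt, Uty)


def stack_ridge(grid: PRSGrid, pheno: PhenotypeTable,
                n_penalties: int = 50) -> StackedPRS:
    """Combine grid columns by ridge regression with LOO-selected penalty.

    Covariates are residualized out of the trait first; columns are centered
    and scaled to unit variance so a single penalty is commensurate across
    columns (zero-variance columns get weight 0). The penalty grid is 50
    log-spaced values spanning [1e-4, 1e4] times the mean (unit) column
    variance times the sample count, i.e. from near-OLS to near-total
    shrinkage; leave-one-out squared error is computed in closed form from
    the hat-matrix diagonal.
    """
    order = {s: i for i, s in enumerate(pheno.sample_ids)}
    idx = [order[s] for s in grid.sample_ids if s in order]
    if len(idx) != len(grid.sample_ids):
        raise ValueError("grid samples missing from phenotype table")
    if len(idx) < 2:
        raise ValueError("need at least 2 samples to stack")
    sub = pheno.subset([pheno.sample_ids[i] for i in idx])
    y = residualize(sub.y, sub.covariates)
    if np.allclose(sub.y, sub.y[0]):
        raise ValueError("constant trait: nothing to stack against")

    X = grid.scores
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    zero = stds <= 0
    stds_safe = np.where(zero, 1.0, stds)
    Z = (X - means) / stds_safe
    Z[:, zero] = 0.0
    yc = y - y.mean()

    penalties = len(y) * np.logspace(-4, 4, n_penalties)
    errs, (U, d, Vt, Uty) = _loo_ridge_path(Z, yc, penalties)
    best = int(np.argmin(errs))
    a = float(penalties[best])
    w_std = Vt.T @ (d / (d ** 2 + a) * Uty)
    w_std[zero] = 0.0
    w_raw = w_std / stds_safe
    w_raw[zero] = 0.0
    prs = Z @ w_std + y.mean()
    return StackedPRS(grid=grid, ridge_weights=w_raw, penalty=a, prs=prs,
                      sigma2=float(errs[best]), col_means=means,
                      col_stds=stds_safe, w_std=w_std, y_mean=float(y.mean()))


def _column_sort_key(label):
    """Lexicographic (lambda0, alpha, k) — or generic tuple — ordering."""
    if isinstance(label, tuple) and len(label) == 3:
        l0, alpha, k = label
        return (l0, alpha, k)
    return label


def select_best_prior(grid: PRSGrid, pheno: PhenotypeTable):
    """Best single grid column by test-data R^2; returns (PriorSpec1, k).

    Ties are broken by the smallest (lambda0, alpha, k) lexicographically.
    """
    order = {s: i for i, s in enumerate(pheno.sample_ids)}
    idx = [order[s] for s in grid.sample_ids]
    sub = pheno.subset([pheno.sample_ids[i] for i in idx])
    y = residualize(sub.y, sub.covariates)
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    best_label, best_r2 = None, -np.inf
    for j, label in enumerate(grid.columns):
        col = grid.scores[:, j] - grid.scores[:, j].mean()
        ss_c = float(col @ col)
        r2 = 0.0 if ss_c <= 0 or ss_y <= 0 else float(col @ yc) ** 2 / (ss_c * ss_y)
        if best_label is None or r2 > best_r2 + 1e-15:
            best_label, best_r2 = label, r2
        elif (abs(r2 - best_r2) <= 1e-15
              and _column_sort_key(label) < _column_sort_key(best_label)):
            best_label = label
    l0, alpha, k = best_label
    return PriorSpec1(lambda0=l0, alpha=alpha), int(k)


# ---------------------------------------------------------------------------
# stage-1 driver
# ---------------------------------------------------------------------------

@dataclass
class Stage1Model:
    """Everything stage 1 learned: loci, posteriors, grid fit, best prior."""

    sumstats: SumStats
    loci: list
    blocks: dict
    posteriors: dict              # (lambda0, alpha) -> {locus_id: PosteriorBlock}
    subsets: dict
    grid: PRSGrid
    stacked: StackedPRS
    best: tuple                   # (PriorSpec1, k)

    @property
    def best_posteriors(self) -> dict:
        spec, _k = self.best
        return self.posteriors[(spec.lambda0, spec.alpha)]

    def score_panel(self, geno: GenotypePanel) -> PRSGrid:
        """PRS grid for a new genotype panel (harmonized to the model)."""
        _, geno_h, _ = harmonize(self.sumstats, geno)
        return score_grid(self.posteriors, self.subsets, geno_h)

    def predict(self, geno: GenotypePanel) -> np.ndarray:
        return self.stacked.apply(self.score_panel(geno))

    def snp_weights(self) -> pd.DataFrame:
        """Collapse the stacked grid to one additive weight per variant."""
        W = grid_snp_weights(self.posteriors, self.subsets)
        W = W[self.grid.columns]
        return pd.Series(W.to_numpy() @ self.stacked.ridge_weights,
                         index=W.index, name="weight").to_frame()


# ---------------------------------------------------------------------------
# model container (JSON)
# ---------------------------------------------------------------------------

def _stacked_to_dict(st: StackedPRS) -> dict:
    return {"columns": [list(c) for c in st.grid.columns],
            "sample_ids": [str(s) for s in st.grid.sample_ids],
            "scores": st.grid.scores.tolist(),
            "ridge_weights": st.ridge_weights.tolist(),
            "penalty": st.penalty, "prs": st.prs.tolist(),
            "sigma2": st.sigma2, "col_means": st.col_means.tolist(),
            "col_stds": st.col_stds.tolist(), "w_std": st.w_std.tolist(),
            "y_mean": st.y_mean}


def _stacked_from_dict(d: dict) -> StackedPRS:
    grid = PRSGrid(np.array(d["sample_ids"], dtype=object),
                   [tuple(c) for c in d["columns"]],
                   np.array(d["scores"], dtype=float))
    return StackedPRS(grid=grid,
                      ridge_weights=np.array(d["ridge_weights"]),
                      penalty=float(d["penalty"]),
                      prs=np.array(d["prs"]), sigma2=float(d["sigma2"]),
                      col_means=np.array(d["col_means"]),
                      col_stds=np.array(d["col_stds"]),
                      w_std=np.array(d["w_std"]), y_mean=float(d["y_mean"]))


def save_stage1_model(model: Stage1Model, path) -> None:
    """Serialize a stage-1 fit as a portable JSON container.

    Posterior means are stored for every prior (needed to score new panels);
    the posterior precision is stored only for the best-fitting prior, which
    is the part stage 2 consumes. Per-locus LD blocks are not stored.
    """
    import json

    spec, k = model.best
    best_key = (spec.lambda0, spec.alpha)
    doc = {
        "kind": "bridgeprs-stage1",
        "sumstats": {"table": model.sumstats.table.to_dict("list"),
                     "n": model.sumstats.n},
        "loci": [{"locus_id": l.locus_id, "lead": l.lead,
                  "members": list(l.members), "top_pval": l.top_pval,
                  "span": list(l.span)} for l in model.loci],
        "posteriors": {f"{l0}|{a}": {lid: p.beta_tilde.tolist()
                                     for lid, p in posts.items()}
                       for (l0, a), posts in model.posteriors.items()},
        "omega_best": {lid: p.omega.tolist()
                       for lid, p in model.posteriors[best_key].items()},
        "subsets": {str(k_): sorted(v) for k_, v in model.subsets.items()},
        "best": [spec.lambda0, spec.alpha, k],
        "stacked": _stacked_to_dict(model.stacked),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_stage1_model(path) -> Stage1Model:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("kind") != "bridgeprs-stage1":
        raise ValueError(f"{path} is not a stage-1 model file")
    sumstats = SumStats(pd.DataFrame(doc["sumstats"]["table"]),
                        doc["sumstats"]["n"])
    loci = [Locus(d["locus_id"], d["lead"], list(d["members"]),
                  float(d["top_pval"]), tuple(d["span"]))
            for d in doc["loci"]]
    members = {l.locus_id: l.members for l in loci}
    l0b, ab, kb = doc["best"]
    posteriors = {}
    for key, posts in doc["posteriors"].items():
        l0, a = (float(x) for x in key.split("|"))
        spec = PriorSpec1(lambda0=l0, alpha=a)
        is_best = (l0, a) == (float(l0b), float(ab))
        posteriors[(l0, a)] = {
            lid: PosteriorBlock(
                lid, members[lid], np.array(bt),
                np.array(doc["omega_best"][lid]) if is_best else None, spec)
            for lid, bt in posts.items()}
    subsets = {int(k_): set(v) for k_, v in doc["subsets"].items()}
    stacked = _stacked_from_dict(doc["stacked"])
    best = (PriorSpec1(lambda0=float(l0b), alpha=float(ab)), int(kb))
    return Stage1Model(sumstats, loci, {}, posteriors, subsets,
                       stacked.grid, stacked, best)


def run_stage1(sumstats: SumStats, ld_panel: GenotypePanel,
               test_geno: GenotypePanel, test_pheno: PhenotypeTable,
               alphas=DEFAULT_ALPHAS, lambda0s=DEFAULT_LAMBDA0S,
               k_grid=DEFAULT_K_GRID, clump_p1: float = 0.01,
               clump_p2: float = 0.01, clump_kb: int = 1000,
               clump_r2: float = 0.01, jitter: float = 0.0) -> Stage1Model:
    """Full stage-1 fit: clump, per-locus posteriors over the prior grid,
    PRS grid on the test panel, and cross-validated ridge stacking."""
    s_h, panel_h, _ = harmonize(sumstats, ld_panel)
    loci = clump(s_h, panel_h, p1=clump_p1, p2=clump_p2, kb=clump_kb,
                 r2=clump_r2)
    blocks = {loc.locus_id: compute_phi(loc, panel_h, jitter=jitter)
              for loc in loci}
    id_pos = {v: i for i, v in enumerate(s_h.table["id"])}
    locus_stats = {loc.locus_id: s_h.subset([id_pos[m] for m in loc.members])
                   for loc in loci}
    posteriors = {}
    for l0 in lambda0s:
        for a in alphas:
            spec = PriorSpec1(lambda0=l0, alpha=a)
            posteriors[(l0, a)] = {
                loc.locus_id: posterior_update(blocks[loc.locus_id],
                                               locus_stats[loc.locus_id], spec)
                for loc in loci}
    subsets = assign_subsets(loci, k_grid)
    _, test_h, _ = harmonize(s_h, test_geno)
    grid = score_grid(posteriors, subsets, test_h)
    stacked = stack_ridge(grid, test_pheno)
    best = select_best_prior(grid, test_pheno)
    logger.info("stage1: %d loci, %d grid columns, best prior %s k=%d",
                len(loci), len(grid.columns), best[0], best[1])
    return Stage1Model(s_h, loci, blocks, posteriors, subsets, grid,
                       stacked, best)
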