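"""Covariate-adjusted variance explained and its uncertainty.

Accuracy of a PRS is the incremental variance explained over covariates:
R^2 = 1 - Var(y | covariates + PRS) / Var(y | covariates). Standard errors
and percentile confidence intervals come from a nonparametric bootstrap over
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import PhenotypeTable

logger = logging.getLogger("bridgeprs")


@dataclass
class R2Result:
    r2: float
    se: float
    ci_low: float
    ci_high: float
    n_boot: int


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None and len(covariates) and covariates.shape[1]:
        C = covariates.to_numpy(float)
        keep = []
        for j in range(C.shape[1]):
            trial = np.column_stack(cols + keep + [C[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep.append(C[:, j])
            else:
                logger.warning("dropping collinear covariate column %s",
                               covariates.columns[j])
        cols += keep
    return np.column_stack(cols)


def _residual_var(design: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ coef
    return float(r @ r) / len(y)


def variance_explained(prs: np.ndarray, pheno: PhenotypeTable) -> float:
    """Incremental R^2 of the PRS over the covariates (may be negative)."""
    y = pheno.y
    if np.allclose(y, y[0]):
        raise ValueError("constant trait")
    M0 = _design(pheno.covariates, len(y))
    M1 = np.column_stack([M0, np.asarray(prs, float)])
    v0 = _residual_var(M0, y)
    if v0 == 0:
        raise ValueError("covariates explain the trait exactly")
    return 1.0 - _residual_var(M1, y) / v0


def bootstrap_r2(prs: np.ndarray, pheno: PhenotypeTable,
                 n_boot: int = 10_000, seed: int = 0) -> R2Result:
    """Bootstrap distribution of the incremental R^2 (percentile 95% CI)."""
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    prs = np.asarray(prs, float)
    point = variance_explained(prs, pheno)
    rng = np.random.default_rng(seed)
    n = len(pheno.y)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cov = (pheno.covariates.iloc[idx].reset_index(drop=True)
               if len(pheno.covariates) else pheno.covariates)
        resampled = PhenotypeTable(np.arange(n).astype(object),
                                   pheno.y[idx], cov)
        draws[b] = variance_explained(prs[idx], resampled)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return R2Result(r2=point, se=float(draws.std(ddof=1)) if n_boot > 1 else 0.0,
                    ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


def compare_methods(r2_a: list[R2Result], r2_b: list[R2Result]) -> float:
    """Two-sided p-value for a paired difference in R^2 across traits.

    Per trait, z = (R2_a - R2_b) / sqrt(se_a^2 + se_b^2); the sum of the z
    scores is N(0, n_traits) under the null of no difference.
    """
    if len(r2_a) != len(r2_b):
        raise ValueError("paired lists must have equal length")
    if not r2_a:
        raise ValueError("need at least one trait")
    z = []
    for a, b in zip(r2_a, r2_b):
        if a.se == 0 or b.se == 0:
            raise ValueError("zero standard error in comparison")
        z.append((a.r2 - b.r2) / np.sqrt(a.se ** 2 + b.se ** 2))
    total = float(np.sum(z))
    return float(2.0 * stats.norm.sf(abs(total) / np.sqrt(len(z))))
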