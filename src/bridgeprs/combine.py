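"""Average the candidate PRS models and export portable SNP weights.

Three candidate models predict the target population: M1, the two-stage
discovery-informed PRS; M2, the target-only PRS; and M3, a ridge stack over
the union of both score grids. Each model's evidence is approximated from
its cross-validated residual variance sigma_i^2 — the log marginal
likelihood of a linear model is, up to a shared constant, -(n/2) log
sigma_i^2 — giving posterior model weights

    w_i = sigma_i^{-n} / sum_j sigma_j^{-n}

computed in log space. The final PRS is the weight-averaged sum of the
component PRS, and the whole pipeline collapses to one additive weight per
SNP so scores can be reproduced from a flat file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import GenotypePanel, PhenotypeTable
from .stage1 import PRSGrid, StackedPRS, Stage1Model, stack_ridge
from .stage2 import Stage2Model

logger = logging.getLogger("bridgeprs")


def model_weights(sigma2: np.ndarray, n: int) -> np.ndarray:
    """Posterior model weights from cross-validated residual variances.

    w_i proportional to exp(-(n/2) log sigma_i^2): lower residual variance
    means higher weight, winner-take-all as n grows. Underflow-safe via
    max-subtraction in log space.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("residual variances must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    logw = -(n / 2.0) * np.log(sigma2)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


@dataclass
class ModelAverage:
    """Component models with their evidence-based weights."""

    components: list          # (model_id, StackedPRS, sigma2_i)
    n: int
    weights: np.ndarray

    def __post_init__(self):
        if abs(self.weights.sum() - 1.0) > 1e-12 or (self.weights < 0).any():
            raise ValueError("weights must be nonnegative and sum to 1")


@dataclass
class FinalPRS:
    sample_ids: np.ndarray
    prs: np.ndarray
    snp_weights: pd.DataFrame  # id, chrom, pos, effect_allele, weight


def build_models(stage2_prs: StackedPRS, target_only_prs: StackedPRS,
                 merged_grid: PRSGrid, pheno: PhenotypeTable,
                 extra: list | None = None) -> ModelAverage:
    """Assemble the model average from the fitted component stacks.

    ``merged_grid`` is the column-wise concatenation of the target-only and
    two-stage score grids on the test samples; it is stacked here by the same
    cross-validated ridge, and every model's sigma_i^2 is its leave-one-out
    residual variance (the common, deterministic fold scheme). ``extra``
    allows additional (model_id, StackedPRS) components from further source
    populations.
    """
    for g in (stage2_prs.grid, target_only_prs.grid, merged_grid):
        if list(g.sample_ids) != list(stage2_prs.grid.sample_ids):
            raise ValueError("component grids cover different samples")
    merged_stack = stack_ridge(merged_grid, pheno)
    components = [("M1", stage2_prs, stage2_prs.sigma2),
                  ("M2", target_only_prs, target_only_prs.sigma2),
                  ("M3", merged_stack, merged_stack.sigma2)]
    for model_id, stacked in (extra or []):
        components.append((model_id, stacked, stacked.sigma2))
    n = len(merged_grid.sample_ids)
    w = model_weights(np.array([c[2] for c in components]), n)
    logger.info("model average over %d test samples: %s", n,
                {mid: round(float(wi), 4) for (mid, *_), wi
                 in zip(components, w)})
    return ModelAverage(components, n, w)


def _merge_weight_frames(frames: list[pd.DataFrame],
                         multipliers: list[float] | None = None) -> pd.DataFrame:
    """Sum weight frames position-wise, respecting effect-allele orientation.

    Each frame has columns id, chrom, pos, effect_allele, weight. When two
    frames report the same variant on opposite effect alleles, the weight
    enters with flipped sign (the constant it leaves behind belongs to the
    score intercept, which PRS comparisons ignore).
    """
    if multipliers is None:
        multipliers = [1.0] * len(frames)
    acc: dict[tuple, list] = {}
    for frame, mult in zip(frames, multipliers):
        for row in frame.itertuples(index=False):
            key = (str(row.chrom), int(row.pos))
            if key not in acc:
                acc[key] = [row.id, row.chrom, row.pos, row.effect_allele, 0.0]
            rec = acc[key]
            rec[4] += mult * row.weight if row.effect_allele == rec[3] \
                else -mult * row.weight
    out = pd.DataFrame([{"id": r[0], "chrom": r[1], "pos": r[2],
                         "effect_allele": r[3], "weight": r[4]}
                        for r in acc.values()])
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def export_weights(avg: ModelAverage,
                   model_weight_frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Collapse per-model SNP weights into one effect-allele-aware table,
    weighting each model's contribution by its posterior model weight."""
    weight_by_model = dict(zip([c[0] for c in avg.components], avg.weights))
    ids = list(model_weight_frames)
    return _merge_weight_frames([model_weight_frames[i] for i in ids],
                                [float(weight_by_model[i]) for i in ids])


def _merge_grids(a: PRSGrid, b: PRSGrid) -> PRSGrid:
    if list(a.sample_ids) != list(b.sample_ids):
        raise ValueError("grids cover different samples")
    return PRSGrid(a.sample_ids, list(a.columns) + list(b.columns),
                   np.hstack([a.scores, b.scores]))


@dataclass
class CombineResult:
    average: ModelAverage
    final: FinalPRS
    component_prs: dict        # model_id -> validation-sample scores


def run_combine(target_only: Stage1Model, bridged: Stage2Model,
                test_pheno: PhenotypeTable,
                validation_geno: GenotypePanel) -> CombineResult:
    """Weight the three candidate models and score the validation panel."""
    merged_test = _merge_grids(target_only.grid, bridged.grid)
    avg = build_models(bridged.stacked, target_only.stacked, merged_test,
                       test_pheno)
    merged_stack = avg.components[2][1]

    # validation-panel predictions per model
    g1_val = bridged.score_panel(validation_geno)
    g2_val = target_only.score_panel(validation_geno)
    preds = {"M1": bridged.stacked.apply(g1_val),
             "M2": target_only.stacked.apply(g2_val),
             "M3": merged_stack.apply(_merge_grids(g2_val, g1_val))}
    final_prs = sum(w * preds[mid] for (mid, *_), w
                    in zip(avg.components, avg.weights))

    # per-model SNP weights with variant metadata, then the weighted merge
    def _with_meta(weights: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
        meta = table.set_index("id")[["chrom", "pos", "effect_allele"]]
        out = weights.join(meta, how="left").reset_index(names="id")
        return out[["id", "chrom", "pos", "effect_allele", "weight"]]

    w1 = _with_meta(bridged.snp_weights(), bridged.sumstats2.table)
    w2 = _with_meta(target_only.snp_weights(), target_only.sumstats.table)
    # M3 splits its ridge weights across the two sub-grids; each half keeps
    # its own allele orientation and the halves are merged position-wise
    from .stage1 import grid_snp_weights
    from .stage2 import grid_snp_weights2
    Wa = grid_snp_weights(target_only.posteriors, target_only.subsets)
    Wa = Wa[list(target_only.grid.columns)]
    Wb = grid_snp_weights2(bridged.posteriors, bridged.subsets_by_tau)
    Wb = Wb[list(bridged.grid.columns)]
    n_a = len(target_only.grid.columns)
    rw_a = merged_stack.ridge_weights[:n_a]
    rw_b = merged_stack.ridge_weights[n_a:]
    w3a = _with_meta(pd.Series(Wa.to_numpy() @ rw_a, index=Wa.index,
                               name="weight").to_frame(),
                     target_only.sumstats.table)
    w3b = _with_meta(pd.Series(Wb.to_numpy() @ rw_b, index=Wb.index,
                               name="weight").to_frame(),
                     bridged.sumstats2.table)
    w3 = _merge_weight_frames([w3a, w3b])

    snp_weights = export_weights(avg, {"M1": w1, "M2": w2, "M3": w3})
    final = FinalPRS(validation_geno.sample_ids, final_prs, snp_weights)
    return CombineResult(avg, final, preds)
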