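"""Ensemble prediction maps with cellwise uncertainty.

The final selected model is not refitted once: one member model is
trained per (repeat, fold) training split of the cross-validation plan
(50 members under the default 5x10 plan), and the map reports, at every
cell, the median of the member predictions (the SOC-stock estimate, kg
m^-2 after denormalization) and their interquartile range (the
prediction-uncertainty surface).  A cell is masked wherever any input
predictor is masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cv import FoldPlan
from .learners import FittedModel, LearnerSpec, make_learner
from .learners import tune as _tune
from .raster import PredictorStack, RasterGrid
from .samples import NormRecord, SampleTable

__all__ = ["EnsemblePrediction", "fit_final_ensemble", "predict_map"]

log = logging.getLogger(__name__)


@dataclass
class EnsemblePrediction:
    """Cellwise ensemble of member predictions with median and IQR grids."""

    member_values: np.ndarray  # (n_members, nrow, ncol), denormalized
    median: RasterGrid
    iqr: RasterGrid

    @property
    def n_members(self) -> int:
        return self.member_values.shape[0]


def fit_final_ensemble(
    final_set: Sequence[str],
    spec: LearnerSpec,
    table: SampleTable,
    plan: FoldPlan,
    *,
    tune_inner: bool = False,
) -> list[FittedModel]:
    """One trained member per (repeat, fold) training split of the plan.

    With ``tune_inner`` each member is grid-tuned on its own training
    split.  A fully degenerate ensemble (every member predicting
    identically on the training data) is flagged with a warning.
    """
    final_set = list(final_set)
    if not final_set:
        raise ValueError("final predictor set is empty")
    X = table.X(final_set)
    y = table.y
    members: list[FittedModel] = []
    for train_idx, _test_idx in plan.splits():
        fit_spec = spec
        if tune_inner and spec.grid:
            sub = table.subset_rows(train_idx)
            from .cv import make_folds

            inner_plan = make_folds(len(train_idx), k=min(10, len(train_idx)), repeats=2, seed=plan.seed)
            best, _ = _tune(fit_spec, sub, inner_plan)
            fit_spec = spec.with_params(**best)
        members.append(make_learner(fit_spec).fit(X[train_idx], y[train_idx]))
    train_preds = np.stack([m.predict(X) for m in members])
    if len(members) > 1 and np.allclose(train_preds, train_preds[0]):
        log.warning("degenerate ensemble: all %d members predict identically", len(members))
    return members


def predict_map(
    ensemble: Sequence[FittedModel],
    stack: PredictorStack,
    norm_record: NormRecord,
    final_set: Sequence[str],
) -> EnsemblePrediction:
    """Predict every member over the stack; median and IQR cellwise.

    Predictor layers are normalized with the training
    :class:`NormRecord`, member predictions are denormalized back to
    physical units, and the IQR is Q3 - Q1 with linear interpolation
    between order statistics.  Raises if a predictor of the final set has
    no layer in the stack, naming it.
    """
    final_set = list(final_set)
    missing = [p for p in final_set if p not in stack]
    if missing:
        raise KeyError(f"stack is missing predictor layers: {missing}")
    ref = stack[final_set[0]]
    mask = np.zeros(ref.shape, dtype=bool)
    for pid in final_set:
        mask |= stack[pid].nodata_mask
    rows, cols = np.nonzero(~mask)
    X = np.column_stack(
        [norm_record.forward_column(pid, stack[pid].values[rows, cols]) for pid in final_set]
    )
    n_members = len(ensemble)
    member_values = np.full((n_members,) + ref.shape, np.nan)
    for i, model in enumerate(ensemble):
        pred = norm_record.inverse_column("response", model.predict(X))
        member_values[i, rows, cols] = pred
    cellpreds = member_values[:, rows, cols]
    med = np.full(ref.shape, np.nan)
    iqr = np.full(ref.shape, np.nan)
    med[rows, cols] = np.median(cellpreds, axis=0)
    q1, q3 = np.percentile(cellpreds, [25, 75], axis=0)
    iqr[rows, cols] = q3 - q1
    return EnsemblePrediction(
        member_values=member_values,
        median=RasterGrid(med, ref.cell_size, ref.origin, mask.copy()),
        iqr=RasterGrid(iqr, ref.cell_size, ref.origin, mask.copy()),
    )
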