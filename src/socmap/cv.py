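"""Repeated k-fold cross-validation with the RMSE criterion.

Model comparison throughout the pipeline uses five repetitions of a
tenfold cross-validation: folds are drawn uniformly at random (balanced
sizes, every sample held out exactly once per repeat), the held-out RMSE
is computed on the normalized response scale, and the criterion is the
arithmetic mean over the 50 (repeat, fold) RMSEs.  Hyperparameter tuning
can be nested inside each training split (the leakage-safe default when
requested) or switched off for candidate screening.

Repeats are mutually independent: each gets its own child seed of the
master seed, so they can be evaluated concurrently with results
identical to serial execution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .learners import LearnerSpec, make_learner
from .learners import tune as _tune
from .samples import RESPONSE, SampleTable

__all__ = ["FoldPlan", "CVResult", "make_folds", "repeated_cv_rmse", "compare_models"]

log = logging.getLogger(__name__)

#: A CVResult with more than this fraction of failed folds is invalid.
MAX_FAILURE_FRACTION = 0.2


@dataclass(frozen=True)
class FoldPlan:
    """Fold assignments for repeated k-fold CV.

    ``assignments`` has shape (repeats, n) with entries in 0..k-1; within
    each repeat the folds are disjoint, cover all samples and differ in
    size by at most one.
    """

    n: int
    k: int
    repeats: int
    seed: int
    assignments: np.ndarray

    def splits(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (train_idx, test_idx) for every (repeat, fold) in order."""
        for rep in range(self.repeats):
            labels = self.assignments[rep]
            for fold in range(self.k):
                test = np.nonzero(labels == fold)[0]
                train = np.nonzero(labels != fold)[0]
                yield train, test


def make_folds(n: int, k: int = 10, repeats: int = 5, seed: int = 0) -> FoldPlan:
    """Uniform random balanced fold assignment, one per repeat.

    Each repeat uses its own child of the master seed, so repeats differ
    from each other but the whole plan is reproducible.
    """
    if not n >= k >= 2:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    children = np.random.SeedSequence(seed).spawn(repeats)
    assignments = np.empty((repeats, n), dtype=int)
    base = np.arange(n) % k  # balanced: sizes differ by <= 1
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        assignments[rep] = base[rng.permutation(n)]
    return FoldPlan(n=n, k=k, repeats=repeats, seed=seed, assignments=assignments)


@dataclass
class CVResult:
    """Outcome of one repeated-CV evaluation of one model."""

    spec: LearnerSpec
    fold_rmse: pd.DataFrame  # columns: repeat, fold, rmse (normalized scale)
    chosen_params: list[dict] = field(default_factory=list)
    n_failed: int = 0
    denorm_scale: float | None = None  # multiply normalized RMSE by this

    @property
    def mean_rmse(self) -> float:
        return float(self.fold_rmse["rmse"].mean())

    @property
    def median_rmse(self) -> float:
        return float(self.fold_rmse["rmse"].median())

    @property
    def iqr_rmse(self) -> float:
        q1, q3 = self.fold_rmse["rmse"].quantile([0.25, 0.75])
        return float(q3 - q1)

    @property
    def mean_rmse_denormalized(self) -> float | None:
        if self.denorm_scale is None:
            return None
        return self.mean_rmse * self.denorm_scale

    @property
    def valid(self) -> bool:
        total = len(self.fold_rmse) + self.n_failed
        return total > 0 and self.n_failed <= MAX_FAILURE_FRACTION * total

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "mean_rmse": self.mean_rmse,
            "median_rmse": self.median_rmse,
            "iqr_rmse": self.iqr_rmse,
            "mean_rmse_denormalized": self.mean_rmse_denormalized,
            "n_failed": self.n_failed,
            "fold_rmse": self.fold_rmse.to_dict(orient="list"),
        }


def _denorm_scale(table: SampleTable) -> float | None:
    rec = table.norm_record
    if rec is None or RESPONSE not in rec.params:
        return None
    p = rec.params[RESPONSE]
    if rec.method == "minmax":
        return p["max"] - p["min"]
    return p["sd"]


def repeated_cv_rmse(
    spec: LearnerSpec,
    table: SampleTable,
    plan: FoldPlan,
    *,
    predictor_ids: Sequence[str] | None = None,
    tune_inner: bool = False,
    inner_k: int = 10,
    inner_repeats: int = 2,
) -> CVResult:
    """Evaluate one model by repeated k-fold CV.

    For every (repeat, fold): fit on the training part — after nested
    grid tuning on an inner fold plan of the training rows when
    ``tune_inner`` is set and the spec has a grid — predict the held-out
    part, and record sqrt(mean squared error) on the normalized response
    scale.  Failed folds are excluded from the mean and counted; a result
    with more than 20% failures is marked invalid.
    """
    if plan.n != len(table):
        raise ValueError(f"fold plan is for n={plan.n}, table has {len(table)} rows")
    X = table.X(predictor_ids)
    y = table.y
    rows = []
    chosen: list[dict] = []
    n_failed = 0
    for split_no, (train_idx, test_idx) in enumerate(plan.splits()):
        rep, fold = divmod(split_no, plan.k)
        if len(train_idx) < 2:
            raise ValueError(f"fold {fold} of repeat {rep} leaves <2 training samples")
        try:
            fit_spec = spec
            if tune_inner and spec.grid:
                inner_table = table.subset_rows(train_idx)
                inner_plan = make_folds(
                    len(train_idx),
                    k=min(inner_k, len(train_idx)),
                    repeats=inner_repeats,
                    seed=int(np.random.SeedSequence([plan.seed, rep, fold]).generate_state(1)[0] % (2**31)),
                )
                if predictor_ids is not None:
                    inner_table = SampleTable(
                        inner_table.frame[["x", "y", RESPONSE] + list(predictor_ids)],
                        list(predictor_ids),
                        norm_record=inner_table.norm_record,
                    )
                best, _curve = _tune(fit_spec, inner_table, inner_plan)
                fit_spec = spec.with_params(**best)
            model = make_learner(fit_spec).fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            rmse = float(np.sqrt(np.mean((pred - y[test_idx]) ** 2)))
            rows.append({"repeat": rep, "fold": fold, "rmse": rmse})
            chosen.append(model.hyperparams)
        except Exception as exc:  # noqa: BLE001 - fold failures are data, not fatal
            log.warning("fold %d of repeat %d failed: %s", fold, rep, exc)
            n_failed += 1
    result = CVResult(
        spec=spec,
        fold_rmse=pd.DataFrame(rows, columns=["repeat", "fold", "rmse"]),
        chosen_params=chosen,
        n_failed=n_failed,
        denorm_scale=_denorm_scale(table),
    )
    if not result.valid:
        log.warning("CV result invalid: %d of %d folds failed", n_failed, n_failed + len(rows))
    return result


def compare_models(
    results: Sequence[CVResult], model_ids: Sequence[str] | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Rank models by mean repeated-CV RMSE (ascending).

    Returns the ranked model ids and a long-form fold-RMSE table
    (model_id, repeat, fold, rmse) — the source data for RMSE boxplots —
    with per-model median and IQR available via :class:`CVResult`.
    """
    if not results:
        raise ValueError("no results to compare")
    if model_ids is None:
        model_ids = [r.spec.family for r in results]
    if len(model_ids) != len(results):
        raise ValueError("model_ids and results lengths differ")
    order = sorted(range(len(results)), key=lambda i: (results[i].mean_rmse, model_ids[i]))
    ranking = [model_ids[i] for i in order]
    frames = []
    for mid, res in zip(model_ids, results):
        df = res.fold_rmse.copy()
        df.insert(0, "model_id", mid)
        frames.append(df)
    return ranking, pd.concat(frames, ignore_index=True)
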