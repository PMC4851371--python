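"""Wrapper predictor selection: 10bestPR, sFS and 3stepFS.

Three strategies pick a predictor subset for a given learner family, all
scoring candidate subsets by their mean repeated-CV RMSE:

1. *Predictor ranking / 10bestPR* — every predictor is scored by its
   one-predictor model; the model built on the ten best-ranked predictors
   is the 10bestPR model.
2. *Simple forward selection (sFS)* — starting from the best-ranked
   predictor, repeatedly evaluate adding each remaining predictor and
   accept the best addition while it improves the mean RMSE by more than
   the tolerance delta.
3. *Three-step forward selection (3stepFS)* — sFS followed by a greedy
   backward subset step (repeatedly drop the member whose removal most
   improves the RMSE), alternating forward and backward until a full
   cycle accepts nothing.

Every candidate evaluation inside one selection run shares a single fold
plan, so RMSE differences between candidates reflect the predictors and
not fold luck.  Ties are broken lexicographically by predictor id.  The
whole run is logged as a :class:`SelectionTrace`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cv import CVResult, FoldPlan, repeated_cv_rmse
from .learners import LearnerSpec
from .learners import tune as _tune
from .samples import SampleTable

TUNING_MODES = ("none", "flat", "nested")

__all__ = [
    "PredictorRanking",
    "SelectionTrace",
    "rank_individual_predictors",
    "ten_best_model",
    "simple_forward_selection",
    "backward_subset_step",
    "three_step_fs",
]

log = logging.getLogger(__name__)


@dataclass
class PredictorRanking:
    """Predictors ordered by one-predictor-model mean RMSE (ascending)."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (e[1], e[0]))

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, m: int) -> list[str]:
        return [pid for pid, _ in self.entries[:m]]

    @property
    def best(self) -> str:
        return self.entries[0][0]


@dataclass
class SelectionTrace:
    """Ordered log of a selection run.

    Each step records the action (``start``, ``add``, ``remove`` or
    ``reject``), the predictor acted on, the resulting predictor set and
    its mean repeated-CV RMSE.  Accepted actions strictly decrease the
    mean RMSE (beyond the tolerance delta); ``final_set`` is the set
    after the last accepted action.
    """

    steps: list[dict] = field(default_factory=list)
    final_set: list[str] = field(default_factory=list)
    final_result: CVResult | None = None

    def record(self, action: str, predictor_id: str | None, current: Sequence[str], rmse: float) -> None:
        self.steps.append(
            {
                "action": action,
                "predictor_id": predictor_id,
                "set": sorted(current),
                "rmse": float(rmse),
            }
        )

    @property
    def accepted_rmses(self) -> list[float]:
        return [s["rmse"] for s in self.steps if s["action"] in ("start", "add", "remove")]

    @property
    def final_rmse(self) -> float:
        return self.accepted_rmses[-1]

    def to_json(self) -> str:
        payload = {
            "steps": self.steps,
            "final_set": sorted(self.final_set),
            "final_rmse": self.final_rmse,
        }
        if self.final_result is not None:
            payload["final_result"] = self.final_result.to_dict()
        return json.dumps(payload, sort_keys=True, indent=1)

    def step_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["action", "predictor_id", "set", "rmse"])


class _Evaluator:
    """Caches subset evaluations within one selection run.

    ``tuning`` controls how each candidate model is scored: ``"none"``
    fits the spec's fixed settings (fast screening mode), ``"flat"``
    grid-tunes the candidate on the shared fold plan and scores it at
    the tuned settings, ``"nested"`` tunes inside every training split
    (leakage-safe, slowest).
    """

    def __init__(self, spec: LearnerSpec, table: SampleTable, plan: FoldPlan, tuning: str):
        if tuning not in TUNING_MODES:
            raise ValueError(f"tuning must be one of {TUNING_MODES}, got {tuning!r}")
        self.spec = spec
        self.table = table
        self.plan = plan
        self.tuning = tuning
        self._cache: dict[frozenset, CVResult] = {}

    def __call__(self, ids: Sequence[str]) -> CVResult:
        key = frozenset(ids)
        if key not in self._cache:
            spec = self.spec
            if self.tuning == "flat" and spec.grid:
                best, _curve = _tune(spec, self.table, self.plan, predictor_ids=sorted(ids))
                spec = spec.with_params(**best)
            self._cache[key] = repeated_cv_rmse(
                spec,
                self.table,
                self.plan,
                predictor_ids=sorted(ids),
                tune_inner=(self.tuning == "nested"),
            )
        return self._cache[key]


def rank_individual_predictors(
    spec: LearnerSpec,
    table: SampleTable,
    plan: FoldPlan,
    *,
    tuning: str = "none",
) -> PredictorRanking:
    """Score every predictor by its one-predictor model's mean CV RMSE.

    Predictors whose CV evaluation is invalid (too many failed folds) are
    dropped from the ranking with a warning.
    """
    if not table.predictor_ids:
        raise ValueError("table has no predictors to rank")
    evaluate = _Evaluator(spec, table, plan, tuning)
    entries = []
    for pid in table.predictor_ids:
        result = evaluate([pid])
        if not result.valid:
            log.warning("predictor %s dropped from ranking (CV failed)", pid)
            continue
        entries.append((pid, result.mean_rmse))
    return PredictorRanking(entries)


def ten_best_model(
    ranking: PredictorRanking,
    spec: LearnerSpec,
    table: SampleTable,
    plan: FoldPlan,
    m: int = 10,
    *,
    tuning: str = "none",
) -> tuple[list[str], CVResult]:
    """The model built on the ``m`` best-ranked predictors (10bestPR)."""
    if len(ranking) < m:
        log.warning("only %d predictors available, using all (requested %d)", len(ranking), m)
        m = len(ranking)
    ids = ranking.top(m)
    return ids, _Evaluator(spec, table, plan, tuning)(ids)


def simple_forward_selection(
    spec: LearnerSpec,
    table: SampleTable,
    plan: FoldPlan,
    start_id: str | None = None,
    delta: float = 0.0,
    *,
    ranking: PredictorRanking | None = None,
    tuning: str = "none",
    _evaluator: _Evaluator | None = None,
    _trace: SelectionTrace | None = None,
) -> SelectionTrace:
    """Greedy forward selection from the best single predictor.

    At every step each remaining predictor is evaluated joined to the
    current set; the best candidate is accepted if it improves the mean
    repeated-CV RMSE by more than ``delta``, otherwise the (rejected)
    best candidate is logged and the procedure stops.
    """
    evaluate = _evaluator or _Evaluator(spec, table, plan, tuning)
    if start_id is None:
        if ranking is None:
            ranking = rank_individual_predictors(spec, table, plan, tuning=tuning)
        start_id = ranking.best
    if start_id not in table.predictor_ids:
        raise ValueError(f"start predictor {start_id!r} not in table")
    trace = _trace or SelectionTrace()
    if _trace is None or not trace.steps:
        current = [start_id]
        incumbent = evaluate(current).mean_rmse
        trace.record("start", start_id, current, incumbent)
    else:
        current = list(trace.final_set)
        incumbent = trace.final_rmse
    while True:
        remaining = [p for p in table.predictor_ids if p not in current]
        if not remaining:
            break
        scored = sorted(
            ((evaluate(current + [pid]).mean_rmse, pid) for pid in remaining),
            key=lambda t: (t[0], t[1]),
        )
        best_rmse, best_pid = scored[0]
        if incumbent - best_rmse > delta:
            current.append(best_pid)
            incumbent = best_rmse
            trace.record("add", best_pid, current, best_rmse)
        else:
            trace.record("reject", best_pid, current, best_rmse)
            break
    trace.final_set = sorted(current)
    trace.final_result = evaluate(current)
    return trace


def backward_subset_step(
    spec: LearnerSpec,
    table: SampleTable,
    plan: FoldPlan,
    current_set: Sequence[str],
    delta: float = 0.0,
    *,
    tuning: str = "none",
    _evaluator: _Evaluator | None = None,
) -> tuple[list[str], list[dict]]:
    """Greedy backward elimination iterated to a fixed point.

    Repeatedly evaluates all single-predictor removals from the current
    set and accepts the removal with the lowest resulting mean RMSE while
    it improves by more than ``delta``.  A one-element set is returned
    unchanged.  Returns the (possibly reduced) set and the trace
    fragment; the removal may eject the starting predictor.
    """
    evaluate = _evaluator or _Evaluator(spec, table, plan, tuning)
    current = list(current_set)
    fragment: list[dict] = []
    if len(current) < 2:
        return current, fragment
    incumbent = evaluate(current).mean_rmse
    while len(current) >= 2:
        scored = sorted(
            (
                (evaluate([p for p in current if p != pid]).mean_rmse, pid)
                for pid in current
            ),
            key=lambda t: (t[0], t[1]),
        )
        best_rmse, best_pid = scored[0]
        if incumbent - best_rmse > delta:
            current = [p for p in current if p != best_pid]
            incumbent = best_rmse
            fragment.append(
                {"action": "remove", "predictor_id": best_pid, "set": sorted(current), "rmse": best_rmse}
            )
        else:
            break
    return current, fragment


def three_step_fs(
    spec: LearnerSpec,
    table: SampleTable,
    plan: FoldPlan,
    delta: float = 0.0,
    *,
    ranking: PredictorRanking | None = None,
    tuning: str = "none",
) -> SelectionTrace:
    """Three-step forward selection.

    Step 1 ranks the predictors (computed once), step 2 is simple forward
    selection, step 3 a greedy backward subset step; steps 2 and 3
    alternate until a full cycle accepts no action.  The final CVResult
    is attached to the trace.  By construction the final mean RMSE is
    never above the plain sFS result on the same plan.
    """
    if len(table.predictor_ids) < 2:
        raise ValueError("three-step selection needs at least 2 predictors")
    evaluate = _Evaluator(spec, table, plan, tuning)
    if ranking is None:
        ranking = rank_individual_predictors(spec, table, plan, tuning=tuning)
    trace = simple_forward_selection(
        spec, table, plan, ranking.best, delta,
        tuning=tuning, _evaluator=evaluate,
    )
    while True:
        accepted_any = False
        reduced, fragment = backward_subset_step(
            spec, table, plan, trace.final_set, delta,
            tuning=tuning, _evaluator=evaluate,
        )
        for step in fragment:
            trace.steps.append(step)
            accepted_any = True
        trace.final_set = sorted(reduced)
        before = len(trace.final_set)
        trace = simple_forward_selection(
            spec, table, plan, None, delta,
            tuning=tuning, _evaluator=evaluate, _trace=trace,
        )
        if len(trace.final_set) > before:
            accepted_any = True
        if not accepted_any:
            break
    trace.final_result = evaluate(trace.final_set)
    return trace
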