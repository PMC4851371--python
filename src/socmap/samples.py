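"""Sample tables: point extraction from predictor stacks and normalization.

The sample table couples field observations (map coordinates + response,
here SOC stock in kg m^-2) with the predictor vector extracted from the
raster stack at each point.  Both predictors and the response are
normalized before model training so learners see comparable scales;
the :class:`NormRecord` keeps the exact per-column parameters so
predictions can be mapped back to physical units.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import PredictorStack

__all__ = [
    "SampleTable",
    "NormRecord",
    "extract_samples",
    "normalize",
    "inverse_normalize",
]

log = logging.getLogger(__name__)

RESPONSE = "response"


@dataclass
class NormRecord:
    """Per-column normalization parameters permitting exact inversion.

    ``method`` is ``"minmax"`` (maps [min, max] to [0, 1]) or ``"zscore"``
    (mean 0, sd 1 with the sample sd, n-1 denominator).  Columns that were
    constant at fit time are recorded as degenerate and mapped to 0.
    """

    method: str
    params: dict[str, dict[str, float]] = field(default_factory=dict)

    def forward_column(self, name: str, x: np.ndarray) -> np.ndarray:
        p = self.params[name]
        if p.get("degenerate"):
            return np.zeros_like(np.asarray(x, dtype=float))
        if self.method == "minmax":
            return (np.asarray(x, dtype=float) - p["min"]) / (p["max"] - p["min"])
        return (np.asarray(x, dtype=float) - p["mean"]) / p["sd"]

    def inverse_column(self, name: str, z: np.ndarray) -> np.ndarray:
        p = self.params[name]
        if p.get("degenerate"):
            return np.full_like(np.asarray(z, dtype=float), p["value"])
        if self.method == "minmax":
            return np.asarray(z, dtype=float) * (p["max"] - p["min"]) + p["min"]
        return np.asarray(z, dtype=float) * p["sd"] + p["mean"]

    def to_json(self) -> str:
        return json.dumps({"method": self.method, "params": self.params}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NormRecord":
        obj = json.loads(text)
        return cls(method=obj["method"], params=obj["params"])


@dataclass
class SampleTable:
    """Rows of (point, response, predictor vector).

    ``frame`` holds columns ``x``, ``y``, ``response`` plus one column per
    predictor id.  ``flagged`` marks rows whose predictor vector fell on a
    nodata cell; those rows are excluded from fitting.  ``norm_record`` is
    set once the table has been normalized.
    """

    frame: pd.DataFrame
    predictor_ids: list[str]
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]
    norm_record: NormRecord | None = None

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(len(self.frame), dtype=bool)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.frame[RESPONSE].isna().any():
            raise ValueError("sample table has missing response values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_valid(self) -> int:
        return int((~self.flagged).sum())

    def valid(self) -> "SampleTable":
        """Rows usable for fitting (predictor vector fully observed)."""
        keep = ~self.flagged
        return SampleTable(
            self.frame.loc[keep].reset_index(drop=True),
            list(self.predictor_ids),
            norm_record=self.norm_record,
        )

    def X(self, predictor_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(predictor_ids) if predictor_ids is not None else self.predictor_ids
        missing = [p for p in ids if p not in self.frame.columns]
        if missing:
            raise KeyError(f"predictors not in table: {missing}")
        return self.frame[ids].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[RESPONSE].to_numpy(dtype=float)

    def subset_rows(self, index: np.ndarray) -> "SampleTable":
        return SampleTable(
            self.frame.iloc[index].reset_index(drop=True),
            list(self.predictor_ids),
            flagged=self.flagged[index],
            norm_record=self.norm_record,
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleTable":
        frame = pd.read_csv(path)
        required = {"x", "y", RESPONSE}
        if not required.issubset(frame.columns):
            raise ValueError(f"sample CSV must have columns {sorted(required)}")
        preds = [c for c in frame.columns if c not in required]
        return cls(frame, preds)


def extract_samples(
    stack: PredictorStack,
    points: Sequence[tuple[float, float]],
    response: Sequence[float],
) -> SampleTable:
    """Extract the predictor vector under each sample point.

    Each point is assigned to the cell containing it (half-open cell
    intervals, so boundary points belong to exactly one cell).  Points
    outside the raster extent raise, listing the offending indices; points
    whose cell is nodata in any layer are flagged, not dropped, so the
    caller can see what was excluded.
    """
    points = [(float(x), float(y)) for x, y in points]
    response = np.asarray(response, dtype=float)
    if len(points) != len(response):
        raise ValueError("points and response lengths differ")
    ref = stack[stack.predictor_ids[0]]
    outside = [i for i, (x, y) in enumerate(points) if not ref.contains(x, y)]
    if outside:
        raise ValueError(f"points outside raster extent at indices {outside}")
    rows = [ref.cell_of(x, y) for x, y in points]
    data = {
        "x": [p[0] for p in points],
        "y": [p[1] for p in points],
        RESPONSE: response,
    }
    flagged = np.zeros(len(points), dtype=bool)
    for pid, grid in stack.items():
        vals = np.array([grid.values[r, c] for r, c in rows], dtype=float)
        hit_nodata = np.array([grid.nodata_mask[r, c] for r, c in rows], dtype=bool)
        vals[hit_nodata] = np.nan
        flagged |= hit_nodata
        data[pid] = vals
    if flagged.any():
        log.warning("%d sample points fall on nodata cells; rows flagged", flagged.sum())
    return SampleTable(pd.DataFrame(data), stack.predictor_ids, flagged=flagged)


def _fit_column(x: np.ndarray, method: str) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if np.ptp(x[~np.isnan(x)]) == 0:
        return {"degenerate": True, "value": float(x[~np.isnan(x)][0])}
    if method == "minmax":
        return {"min": float(np.nanmin(x)), "max": float(np.nanmax(x))}
    return {"mean": float(np.nanmean(x)), "sd": float(np.nanstd(x, ddof=1))}


def normalize(table: SampleTable, method: str = "minmax") -> tuple[SampleTable, NormRecord]:
    """Normalize predictors and response; returns the table and the record.

    Constant predictor columns are dropped with a warning (flat layers are
    common in masked real stacks); a constant response is an error.  The
    record's parameters are fitted on unflagged rows only, but applied to
    all rows.
    """
    if method not in ("minmax", "zscore"):
        raise ValueError(f"unknown normalization method {method!r}")
    record = NormRecord(method=method)
    frame = table.frame.copy()
    fit_rows = ~table.flagged
    kept: list[str] = []
    for pid in table.predictor_ids:
        col = frame[pid].to_numpy(dtype=float)[fit_rows]
        params = _fit_column(col, method)
        if params.get("degenerate"):
            warnings.warn(f"dropping constant predictor column {pid!r}", stacklevel=2)
            frame = frame.drop(columns=[pid])
            continue
        record.params[pid] = params
        kept.append(pid)
    yparams = _fit_column(frame[RESPONSE].to_numpy(dtype=float)[fit_rows], method)
    if yparams.get("degenerate"):
        raise ValueError("response is constant; nothing to model")
    record.params[RESPONSE] = yparams
    for name in kept + [RESPONSE]:
        frame[name] = record.forward_column(name, frame[name].to_numpy(dtype=float))
    out = SampleTable(frame, kept, flagged=table.flagged.copy(), norm_record=record)
    return out, record


def inverse_normalize(values: np.ndarray, record: NormRecord, column: str = RESPONSE) -> np.ndarray:
    """Map normalized values of ``column`` back to the original scale."""
    return record.inverse_column(column, values)
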