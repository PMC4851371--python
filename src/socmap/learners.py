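"""The regression learner families under a uniform fit/predict contract.

Five families mirror the study design for SOC-stock regression, each with
its fixed settings and tuning grid:

``rf``
    Random forest: 1000 trees, mtry = max(1, floor(p/3)), minimum node
    size 5, bootstrap samples of size n drawn with replacement.  Not
    tuned.
``ann``
    Single-hidden-layer feed-forward network with L2 weight penalty
    (regularization weight fixed, default 1e-3), trained by L-BFGS so the
    fit is deterministic under the seed; the number of neurons is tuned
    over 1..20.
``mars``
    Multivariate adaptive regression splines, forward pass only (no
    backward pruning), interaction degree 2; the number of terms is tuned
    over 1..50.  Implemented natively, see :class:`MarsForward`.
``brt``
    Boosted regression trees: shrinkage 0.001, bag fraction 0.90,
    interaction depth 2, minimum node size 5; the iteration count is the
    tuned parameter, up to a configurable cap (500 by default; 10,000 for
    final production fits).
``svr``
    Support vector regression with an RBF kernel; C tuned over 0.1..1.0
    (step 0.1) and gamma over 0.2..0.5 (step 0.05), with an extended
    log-spaced 1e-3..1e4 grid available for both; the tube width epsilon
    is recomputed from each training response as 3*sigma*sqrt(ln(n)/n).

Two further families are diagnostic baselines used by the validation
machinery, not part of the comparison proper: ``ridge`` (deterministic
linear model with a small fixed L2 penalty) and ``constant`` (predicts
the training-mean response, the analytic null model).

All learners expect normalized inputs (see :mod:`socmap.samples`) and are
bit-reproducible given the spec seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

__all__ = [
    "LearnerSpec",
    "FittedModel",
    "FAMILIES",
    "default_spec",
    "make_learner",
    "epsilon_heuristic",
    "MarsForward",
    "mars_forward_pass",
    "svr_extended_grid",
    "tune",
]

FAMILIES = ("rf", "ann", "mars", "brt", "svr", "ridge", "constant")

#: Grid-parameter ordering used for simpler-model tie-breaking in tune().
_COMPLEXITY_PARAM = {"ann": "neurons", "mars": "max_terms", "brt": "n_iterations", "svr": "C"}


@dataclass(frozen=True)
class LearnerSpec:
    """A learner family plus its fixed settings, tuning grid and seed."""

    family: str
    fixed: dict[str, Any] = field(default_factory=dict)
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; choose from {FAMILIES}")

    def with_params(self, **params) -> "LearnerSpec":
        """Copy with grid parameters pinned into the fixed settings."""
        return replace(self, fixed={**self.fixed, **params}, grid={})


def default_spec(family: str, seed: int = 0, *, brt_cap: int = 500) -> LearnerSpec:
    """The study-default :class:`LearnerSpec` for a family."""
    if family == "rf":
        return LearnerSpec("rf", fixed={"n_trees": 1000, "min_node": 5}, seed=seed)
    if family == "ann":
        return LearnerSpec(
            "ann",
            fixed={"alpha": 1e-3, "neurons": 5},
            grid={"neurons": list(range(1, 21))},
            seed=seed,
        )
    if family == "mars":
        return LearnerSpec(
            "mars",
            fixed={"degree": 2, "max_terms": 21},
            grid={"max_terms": list(range(1, 51))},
            seed=seed,
        )
    if family == "brt":
        step = max(brt_cap // 10, 1)
        return LearnerSpec(
            "brt",
            fixed={
                "shrinkage": 0.001,
                "bag_fraction": 0.90,
                "interaction_depth": 2,
                "min_node": 5,
                "n_iterations": brt_cap,
            },
            grid={"n_iterations": list(range(step, brt_cap + 1, step))},
            seed=seed,
        )
    if family == "svr":
        return LearnerSpec(
            "svr",
            fixed={"C": 1.0, "gamma": 0.35},
            grid={
                "C": [round(c, 1) for c in np.arange(0.1, 1.01, 0.1)],
                "gamma": [round(g, 2) for g in np.arange(0.2, 0.501, 0.05)],
            },
            seed=seed,
        )
    if family == "ridge":
        return LearnerSpec("ridge", fixed={"alpha": 1e-2}, seed=seed)
    if family == "constant":
        return LearnerSpec("constant", seed=seed)
    raise ValueError(f"unknown learner family {family!r}")


def svr_extended_grid() -> dict[str, list]:
    """The widened log-spaced C/gamma grid, 1e-3 to 1e4 by decades."""
    decades = [10.0**k for k in range(-3, 5)]
    return {"C": decades, "gamma": list(decades)}


def epsilon_heuristic(y_normalized: np.ndarray) -> float:
    """SVR tube width: epsilon = 3 * sigma(y) * sqrt(ln(n) / n).

    sigma is the sample standard deviation (n-1 denominator).  Requires
    n >= 3.
    """
    y = np.asarray(y_normalized, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError(f"epsilon heuristic needs n >= 3, got {n}")
    sigma = float(np.std(y, ddof=1))
    return 3.0 * sigma * float(np.sqrt(np.log(n) / n))


@dataclass
class FittedModel:
    """A trained model: family, chosen hyperparameters, opaque state."""

    family: str
    hyperparams: dict[str, Any]
    _predict_fn: Any

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.asarray(self._predict_fn(X), dtype=float)


class Learner:
    """fit/predict wrapper around one :class:`LearnerSpec`."""

    def __init__(self, spec: LearnerSpec):
        self.spec = spec

    def fit(self, X: np.ndarray, y: np.ndarray) -> FittedModel:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("empty or malformed training table")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        return _FITTERS[self.spec.family](self.spec, X, y)


def make_learner(spec: LearnerSpec) -> Learner:
    """Instantiate the learner for a spec; raises on unknown family."""
    return Learner(spec)


# ---------------------------------------------------------------------------
# family fitters


def _fit_rf(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    p = X.shape[1]
    mtry = int(spec.fixed.get("mtry", max(1, p // 3)))
    model = RandomForestRegressor(
        n_estimators=int(spec.fixed.get("n_trees", 1000)),
        max_features=mtry,
        min_samples_leaf=int(spec.fixed.get("min_node", 5)),
        bootstrap=True,
        max_samples=None,  # bootstrap samples of size n, with replacement
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return FittedModel("rf", {"n_trees": model.n_estimators, "mtry": mtry}, model.predict)


def _fit_ann(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    neurons = int(spec.fixed.get("neurons", 5))
    alpha = float(spec.fixed.get("alpha", 1e-3))
    model = MLPRegressor(
        hidden_layer_sizes=(neurons,),
        activation="tanh",
        solver="lbfgs",
        alpha=alpha,
        max_iter=2000,
        tol=1e-8,
        random_state=spec.seed,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # stopping at the iteration cap is acceptable for this contract
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return FittedModel("ann", {"neurons": neurons, "alpha": alpha}, model.predict)


def _fit_mars(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    model = MarsForward(
        max_terms=int(spec.fixed.get("max_terms", 21)),
        degree=int(spec.fixed.get("degree", 2)),
    )
    model.fit(X, y)
    return FittedModel(
        "mars",
        {"max_terms": model.max_terms, "degree": model.degree, "n_terms": len(model.terms_)},
        model.predict,
    )


def _fit_brt(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    n_iter = int(spec.fixed.get("n_iterations", 500))
    model = GradientBoostingRegressor(
        n_estimators=n_iter,
        learning_rate=float(spec.fixed.get("shrinkage", 0.001)),
        subsample=float(spec.fixed.get("bag_fraction", 0.90)),
        max_depth=int(spec.fixed.get("interaction_depth", 2)),
        min_samples_leaf=int(spec.fixed.get("min_node", 5)),
        random_state=spec.seed,
    )
    model.fit(X, y)
    return FittedModel("brt", {"n_iterations": n_iter}, model.predict)


def _fit_svr(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    eps = float(spec.fixed.get("epsilon", epsilon_heuristic(y)))
    C = float(spec.fixed.get("C", 1.0))
    gamma = float(spec.fixed.get("gamma", 0.35))
    model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)
    model.fit(X, y)
    return FittedModel("svr", {"C": C, "gamma": gamma, "epsilon": eps}, model.predict)


def _fit_ridge(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    model = Ridge(alpha=float(spec.fixed.get("alpha", 1e-2)))
    model.fit(X, y)
    return FittedModel("ridge", {"alpha": model.alpha}, model.predict)


def _fit_constant(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    mean = float(np.mean(y))
    return FittedModel("constant", {"mean": mean}, lambda X: np.full(len(X), mean))


_FITTERS = {
    "rf": _fit_rf,
    "ann": _fit_ann,
    "mars": _fit_mars,
    "brt": _fit_brt,
    "svr": _fit_svr,
    "ridge": _fit_ridge,
    "constant": _fit_constant,
}


# ---------------------------------------------------------------------------
# MARS forward pass


class MarsForward:
    """Forward-pass multivariate adaptive regression splines.

    The model is a weighted sum of products of piecewise-linear hinge
    functions (x - t)+ and (t - x)+.  Starting from the intercept (the
    mean of the response), terms are added greedily one at a time: every
    candidate is a hinge in some predictor at some knot (a training value
    of that predictor), optionally multiplied onto an existing term when
    ``degree`` is 2, and the candidate giving the largest decrease in
    residual sum of squares under the full least-squares refit is
    accepted.  The pass stops at ``max_terms`` terms (intercept included)
    or when the relative RSS improvement falls below ``tol``.  No
    backward pruning is applied.

    Candidate scoring uses an orthonormal basis of the current model
    columns, so each candidate costs one projection rather than one
    least-squares solve; the selected basis is refitted exactly at the
    end.
    """

    def __init__(self, max_terms: int = 21, degree: int = 2, tol: float = 1e-12):
        if max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        self.max_terms = max_terms
        self.degree = degree
        self.tol = tol

    @staticmethod
    def _hinge(x: np.ndarray, sign: int, knot: float) -> np.ndarray:
        return np.maximum(sign * (x - knot), 0.0)

    def _term_column(self, X: np.ndarray, term: tuple) -> np.ndarray:
        col = np.ones(X.shape[0])
        for j, sign, knot in term:
            col = col * self._hinge(X[:, j], sign, knot)
        return col

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MarsForward":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        max_terms = self.max_terms
        if max_terms > n:
            import warnings

            warnings.warn(
                f"max_terms={max_terms} exceeds n={n}; capping at n", stacklevel=2
            )
            max_terms = n
        terms: list[tuple] = [()]  # intercept
        B = np.ones((n, 1))
        Q = B / np.sqrt(n)
        resid = y - Q @ (Q.T @ y)
        yss = float(y @ y) or 1.0
        knots = [np.unique(X[:, j]) for j in range(p)]
        while len(terms) < max_terms:
            best = None  # (improvement, parent_idx, j, sign, knot, column)
            for parent_idx, parent in enumerate(terms):
                if len(parent) >= self.degree:
                    continue
                parent_col = B[:, parent_idx]
                used = {j for j, _s, _k in parent}
                for j in range(p):
                    if j in used:
                        continue
                    xj = X[:, j]
                    for sign in (1, -1):
                        # columns for all knots at once: (n, n_knots)
                        H = np.maximum(sign * (xj[:, None] - knots[j][None, :]), 0.0)
                        C = parent_col[:, None] * H
                        C_perp = C - Q @ (Q.T @ C)
                        norms = np.einsum("ij,ij->j", C_perp, C_perp)
                        proj = resid @ C_perp
                        with np.errstate(divide="ignore", invalid="ignore"):
                            imp = np.where(norms > 1e-12 * n, proj * proj / norms, 0.0)
                        k = int(np.argmax(imp))
                        if best is None or imp[k] > best[0]:
                            best = (float(imp[k]), parent_idx, j, sign, float(knots[j][k]), C[:, k])
            if best is None or best[0] <= self.tol * yss:
                break
            _imp, parent_idx, j, sign, knot, col = best
            terms.append(terms[parent_idx] + ((j, sign, knot),))
            B = np.column_stack([B, col])
            q = col - Q @ (Q.T @ col)
            q = q / np.linalg.norm(q)
            Q = np.column_stack([Q, q])
            resid = resid - q * (q @ resid)
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        self.terms_ = terms
        self.coef_ = coef
        self.rss_ = float(np.sum((y - B @ coef) ** 2))
        self._B = B
        self._y = y
        return self

    def staged_coefficients(self, n_terms: int) -> np.ndarray:
        """Least-squares coefficients of the first ``n_terms`` basis terms.

        The forward pass adds terms greedily, so the model truncated to
        its first m columns is exactly the forward-pass model with
        ``max_terms`` = m; this lets one fit at the cap score every
        smaller term count.
        """
        m = min(n_terms, len(self.terms_))
        coef, *_ = np.linalg.lstsq(self._B[:, :m], self._y, rcond=None)
        return coef

    def staged_predict(self, X: np.ndarray, n_terms: int) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = min(n_terms, len(self.terms_))
        B = np.column_stack([self._term_column(X, t) for t in self.terms_[:m]])
        return B @ self.staged_coefficients(m)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        B = np.column_stack([self._term_column(X, t) for t in self.terms_])
        return B @ self.coef_


def mars_forward_pass(
    X: np.ndarray, y: np.ndarray, max_terms: int, degree: int = 2
) -> MarsForward:
    """Run the MARS forward pass; returns the fitted basis + coefficients."""
    return MarsForward(max_terms=max_terms, degree=degree).fit(X, y)


# ---------------------------------------------------------------------------
# grid tuning


def _grid_points(grid: dict[str, list]) -> list[dict[str, Any]]:
    keys = list(grid)
    points = [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]
    # ascending complexity so ties resolve toward the simpler model
    comp_keys = [k for k in ("neurons", "max_terms", "n_iterations", "C", "gamma") if k in keys]
    points.sort(key=lambda pt: tuple(pt[k] for k in comp_keys) + tuple(pt[k] for k in keys))
    return points


def tune(
    spec: LearnerSpec,
    table,
    plan,
    *,
    predictor_ids: Sequence[str] | None = None,
    tie_tol: float = 1e-8,
) -> tuple[dict[str, Any], list[tuple[dict[str, Any], float]]]:
    """Select grid hyperparameters by repeated-CV RMSE over ``plan``.

    Returns ``(best_params, tuning_curve)`` where the curve lists every
    evaluated grid point with its mean RMSE (failed points are recorded
    with RMSE NaN and excluded from the argmin).  Ties within ``tie_tol``
    of the minimum go to the simpler model: fewer neurons/terms/
    iterations, smaller C.  BRT iteration counts are scored from a single
    staged fit per fold rather than one fit per grid point.
    """
    from . import cv as _cv  # local import; cv builds on learners

    if not spec.grid:
        raise ValueError("tune() called with an empty grid")
    if spec.family == "brt" and set(spec.grid) == {"n_iterations"}:
        return _tune_brt_staged(spec, table, plan, predictor_ids, tie_tol=tie_tol)
    if spec.family == "mars" and set(spec.grid) == {"max_terms"}:
        return _tune_mars_staged(spec, table, plan, predictor_ids, tie_tol=tie_tol)
    curve: list[tuple[dict[str, Any], float]] = []
    for point in _grid_points(spec.grid):
        candidate = spec.with_params(**point)
        try:
            result = _cv.repeated_cv_rmse(
                candidate, table, plan, predictor_ids=predictor_ids, tune_inner=False
            )
            curve.append((point, result.mean_rmse))
        except Exception:  # noqa: BLE001 - failed grid points are recorded, not fatal
            curve.append((point, float("nan")))
    valid = [(pt, r) for pt, r in curve if np.isfinite(r)]
    if not valid:
        raise RuntimeError("every grid point failed during tuning")
    best_rmse = min(r for _pt, r in valid)
    best = next(pt for pt, r in valid if r <= best_rmse + tie_tol)
    return best, curve


def _tune_mars_staged(spec: LearnerSpec, table, plan, predictor_ids=None, *, tie_tol: float):
    """Score every term count from one forward pass per fold."""
    candidates = sorted(int(v) for v in spec.grid["max_terms"])
    cap = candidates[-1]
    degree = int(spec.fixed.get("degree", 2))
    X = table.X(predictor_ids)
    y = table.y
    rmse_sum = dict.fromkeys(candidates, 0.0)
    n_folds = 0
    for train_idx, test_idx in plan.splits():
        model = MarsForward(max_terms=cap, degree=degree).fit(X[train_idx], y[train_idx])
        for m in candidates:
            pred = model.staged_predict(X[test_idx], m)
            rmse_sum[m] += float(np.sqrt(np.mean((pred - y[test_idx]) ** 2)))
        n_folds += 1
    rmse = np.array([rmse_sum[m] / n_folds for m in candidates])
    curve = [({"max_terms": m}, float(r)) for m, r in zip(candidates, rmse)]
    best_rmse = float(rmse.min())
    best = next(pt for pt, r in curve if r <= best_rmse + tie_tol)
    return best, curve


def _tune_brt_staged(spec: LearnerSpec, table, plan, predictor_ids=None, *, tie_tol: float):
    candidates = sorted(int(v) for v in spec.grid["n_iterations"])
    cand_set = set(candidates)
    cap = candidates[-1]
    X = table.X(predictor_ids)
    y = table.y
    rmse_sum = dict.fromkeys(candidates, 0.0)
    n_folds = 0
    for train_idx, test_idx in plan.splits():
        model = GradientBoostingRegressor(
            n_estimators=cap,
            learning_rate=float(spec.fixed.get("shrinkage", 0.001)),
            subsample=float(spec.fixed.get("bag_fraction", 0.90)),
            max_depth=int(spec.fixed.get("interaction_depth", 2)),
            min_samples_leaf=int(spec.fixed.get("min_node", 5)),
            random_state=spec.seed,
        )
        model.fit(X[train_idx], y[train_idx])
        for i, pred in enumerate(model.staged_predict(X[test_idx]), start=1):
            if i in cand_set:
                rmse_sum[i] += float(np.sqrt(np.mean((pred - y[test_idx]) ** 2)))
        n_folds += 1
    rmse = np.array([rmse_sum[m] / n_folds for m in candidates])
    curve = [({"n_iterations": m}, float(r)) for m, r in zip(candidates, rmse)]
    best_rmse = float(rmse.min())
    best = next(pt for pt, r in curve if r <= best_rmse + tie_tol)
    return best, curve
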