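"""Learner contract: defaults, determinism, MARS forward pass, tuning."""

import numpy as np
import pytest

import socmap as sm
from socmap.learners import MarsForward, default_spec, make_learner, svr_extended_grid


def linear_problem(n=60, p=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, p))
    y = X[:, 0] + noise * rng.standard_normal(n)
    return X, y


class TestDefaults:
    def test_rf_mtry_is_floor_p_over_three(self):
        X, y = linear_problem(p=6)
        model = make_learner(default_spec("rf")).fit(X, y)
        assert model.hyperparams["mtry"] == 2

    def test_rf_mtry_floor_is_one(self):
        X, y = linear_problem(p=2)
        model = make_learner(default_spec("rf")).fit(X, y)
        assert model.hyperparams["mtry"] == 1

    def test_svr_default_grids_match_study_ranges(self):
        spec = default_spec("svr")
        assert spec.grid["C"] == [round(0.1 * k, 1) for k in range(1, 11)]
        assert spec.grid["gamma"] == [0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5]
        ext = svr_extended_grid()
        assert ext["C"][0] == 1e-3 and ext["C"][-1] == 1e4

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sm.LearnerSpec("gp")

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            make_learner(default_spec("rf")).fit(np.empty((0, 2)), np.empty(0))


class TestDeterminism:
    @pytest.mark.parametrize("family", ["rf", "ann", "mars", "brt", "svr", "ridge"])
    def test_same_seed_same_predictions(self, family):
        X, y = linear_problem(noise=0.1)
        spec = default_spec(family, seed=42)
        if family == "brt":
            spec = spec.with_params(n_iterations=50)
        m1 = make_learner(spec).fit(X, y)
        m2 = make_learner(spec).fit(X, y)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


class TestMarsForward:
    def test_single_hinge_exactly_represented(self):
        X = np.linspace(0, 1, 21).reshape(-1, 1)
        y = np.maximum(X[:, 0] - 0.5, 0.0)
        model = MarsForward(max_terms=5).fit(X, y)
        assert model.rss_ < 1e-20
        assert len(model.terms_) == 2  # intercept + one hinge

    def test_intercept_only_predicts_mean(self):
        X, y = linear_problem(noise=0.3, seed=3)
        model = MarsForward(max_terms=1).fit(X, y)
        np.testing.assert_allclose(model.predict(X), np.mean(y))

    def test_linear_function_reproduced(self):
        X = np.linspace(0, 1, 21).reshape(-1, 1)
        model = MarsForward(max_terms=5).fit(X, X[:, 0].copy())
        assert model.rss_ < 1e-10

    def test_degree_two_represents_product(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (80, 2))
        y = X[:, 0] * X[:, 1]
        m2 = MarsForward(max_terms=15, degree=2).fit(X, y)
        m1 = MarsForward(max_terms=15, degree=1).fit(X, y)
        assert m2.rss_ < m1.rss_

    def test_max_terms_capped_at_n_with_warning(self):
        X, y = linear_problem(n=10, noise=0.1)
        with pytest.warns(UserWarning, match="capping"):
            MarsForward(max_terms=50).fit(X, y)

    def test_staged_predict_matches_truncated_refit(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (50, 3))
        y = X[:, 0] + 0.5 * X[:, 1] ** 2 + 0.1 * rng.standard_normal(50)
        full = MarsForward(max_terms=10).fit(X, y)
        for m in (1, 3, 5):
            small = MarsForward(max_terms=m).fit(X, y)
            np.testing.assert_allclose(
                full.staged_predict(X, m), small.predict(X), atol=1e-8
            )

    def test_mars_forward_pass_wrapper(self):
        X, y = linear_problem(noise=0.0)
        model = sm.learners.mars_forward_pass(X, y, max_terms=5)
        assert model.rss_ < 1e-10


class TestEpsilonHeuristic:
    def test_worked_value_n60_sigma1(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(60)
        y = (y - y.mean()) / y.std(ddof=1)  # sigma exactly 1
        eps = sm.epsilon_heuristic(y)
        assert eps == pytest.approx(3 * np.sqrt(np.log(60) / 60), abs=1e-12)
        assert eps == pytest.approx(0.78367, abs=1e-5)

    def test_zero_sigma_gives_zero(self):
        assert sm.epsilon_heuristic(np.full(10, 2.0)) == 0.0

    def test_monotone_decreasing_in_n(self):
        vals = [3 * np.sqrt(np.log(n) / n) for n in range(3, 200)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            sm.epsilon_heuristic(np.array([1.0, 2.0]))

    def test_svr_fit_uses_heuristic_epsilon(self):
        X, y = linear_problem(noise=0.1)
        model = make_learner(default_spec("svr")).fit(X, y)
        assert model.hyperparams["epsilon"] == pytest.approx(sm.epsilon_heuristic(y))


class TestBrt:
    def test_training_rmse_nonincreasing_in_iterations(self):
        X, y = linear_problem(noise=0.2, seed=7)
        spec = default_spec("brt", seed=0)
        rmses = []
        for m in (10, 50, 200, 500):
            fit = make_learner(spec.with_params(n_iterations=m)).fit(X, y)
            rmses.append(np.sqrt(np.mean((fit.predict(X) - y) ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(rmses, rmses[1:]))


def _table_from_arrays(X, y):
    import pandas as pd

    from socmap.samples import RESPONSE, SampleTable

    cols = {f"p{j}": X[:, j] for j in range(X.shape[1])}
    frame = pd.DataFrame({"x": np.zeros(len(y)), "y": np.zeros(len(y)), RESPONSE: y, **cols})
    return SampleTable(frame, list(cols))


class TestTune:
    def test_single_point_grid_returned(self):
        X, y = linear_problem(noise=0.1)
        table = _table_from_arrays(X, y)
        plan = sm.make_folds(len(y), k=5, repeats=2, seed=0)
        spec = sm.LearnerSpec("ridge", fixed={}, grid={"alpha": [0.5]})
        best, curve = sm.tune(spec, table, plan)
        assert best == {"alpha": 0.5}
        assert len(curve) == 1

    def test_tuning_curve_covers_grid(self):
        X, y = linear_problem(noise=0.1)
        table = _table_from_arrays(X, y)
        plan = sm.make_folds(len(y), k=5, repeats=2, seed=0)
        spec = sm.LearnerSpec("ridge", fixed={}, grid={"alpha": [1e-3, 1e-1, 10.0]})
        best, curve = sm.tune(spec, table, plan)
        assert len(curve) == 3
        assert best["alpha"] in (1e-3, 1e-1)  # heavy shrinkage must lose

    def test_exact_tie_broken_toward_fewer_terms(self):
        # y is linear, so intercept + one hinge at the training minimum
        # fits every training fold exactly; caps >= 2 all stop at the
        # same 2-term model and the tie must resolve to the smallest cap
        X = np.linspace(0, 1, 30).reshape(-1, 1)
        y = 1.0 + 2.0 * X[:, 0]
        table = _table_from_arrays(X, y)
        plan = sm.make_folds(len(y), k=5, repeats=2, seed=0)
        spec = sm.LearnerSpec("mars", fixed={"degree": 1}, grid={"max_terms": [2, 5, 10]})
        best, _ = sm.tune(spec, table, plan)
        assert best == {"max_terms": 2}

    def test_mars_staged_tuner_matches_generic_path(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, (40, 2))
        y = X[:, 0] + 0.2 * rng.standard_normal(40)
        table = _table_from_arrays(X, y)
        plan = sm.make_folds(len(y), k=5, repeats=2, seed=0)
        grid = {"max_terms": [1, 3, 6]}
        _, fast = sm.tune(sm.LearnerSpec("mars", fixed={"degree": 2}, grid=grid), table, plan)
        # generic path: pin each cap and evaluate through repeated_cv_rmse
        for (pt, rmse_fast) in fast:
            spec = sm.LearnerSpec("mars", fixed={"degree": 2}).with_params(**pt)
            slow = sm.repeated_cv_rmse(spec, table, plan)
            assert rmse_fast == pytest.approx(slow.mean_rmse, abs=1e-10)

    def test_empty_grid_rejected(self):
        X, y = linear_problem()
        table = _table_from_arrays(X, y)
        plan = sm.make_folds(len(y), k=5, repeats=2, seed=0)
        with pytest.raises(ValueError, match="grid"):
            sm.tune(default_spec("rf"), table, plan)


class TestNoiselessRecoveryContract:
    @pytest.mark.parametrize("family", ["rf", "ann", "mars", "svr", "ridge"])
    def test_single_informative_predictor_low_cv_rmse(self, family):
        """Normalized noiseless y = x must be learnable by every family."""
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (100, 1))
        y = X[:, 0].copy()
        table = _table_from_arrays(X, y)
        plan = sm.make_folds(100, k=10, repeats=2, seed=0)
        spec = default_spec(family, seed=0)
        if family == "mars":
            spec = spec.with_params(max_terms=10)
        if family == "svr":
            # the epsilon heuristic's sigma proxies the *noise* scale;
            # on noiseless data the appropriate tube width is ~0
            spec = spec.with_params(epsilon=1e-3)
        result = sm.repeated_cv_rmse(spec, table, plan)
        assert result.mean_rmse < 0.05, family

    def test_brt_needs_long_boosting_to_capture_the_signal(self):
        """At shrinkage 0.001, 500 iterations leave most of the signal
        unlearned while the 10,000-iteration cap recovers it — the
        motivation for widening the iteration range."""
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (100, 1))
        y = X[:, 0].copy()
        table = _table_from_arrays(X, y)
        plan = sm.make_folds(100, k=5, repeats=1, seed=0)
        short = sm.repeated_cv_rmse(
            default_spec("brt", seed=0).with_params(n_iterations=500), table, plan
        )
        long = sm.repeated_cv_rmse(
            default_spec("brt", seed=0, brt_cap=10000).with_params(n_iterations=10000),
            table,
            plan,
        )
        assert long.mean_rmse < 0.05
        assert short.mean_rmse > 2 * long.mean_rmse
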