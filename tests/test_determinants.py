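"""Determinant analysis: table assembly, filtering, scaling, model fits,
metrics and residual diagnostics."""

import logging

import numpy as np
import pandas as pd
import pytest

import sprintmech as sm
from conftest import analytic_feature_table, with_outcome


def _toy_table(n=40, seed=0, collinear=False):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = rng.normal(0, 1, n)
    cols = {"x1": x1, "x2": x2}
    if collinear:
        cols["x3"] = x1 + rng.normal(0, 1e-4, n)
    frame = pd.DataFrame(cols, index=[f"a{i}" for i in range(n)])
    y = pd.Series(2.0 * x1 - x2 + 3.0, index=frame.index)
    return sm.FeatureTable(frame, y, "t30")


class TestBuildFeatureTable:
    def test_complete_cohort_shape(self):
        t = analytic_feature_table(seed=5)
        assert len(t) == 26
        assert t.columns == list(sm.DEFAULT_PREDICTORS)
        assert t.target_name == "t30"

    def test_target_passthrough(self):
        res = sm.process_cohort(sm.CohortSpec(n=8, seed=2), analytic=True)
        t = sm.build_feature_table([r.fvp for r in res], [r.decel for r in res],
                                   [r.athlete for r in res],
                                   [r.splits for r in res], None, "t30")
        assert np.allclose(t.target.to_numpy(),
                           [r.splits.t30 for r in res])

    def test_missing_component_dropped_with_warning(self, caplog):
        res = sm.process_cohort(sm.CohortSpec(n=8, seed=2), analytic=True)
        decels = [r.decel for r in res]
        decels[3] = None
        with caplog.at_level(logging.WARNING, logger="sprintmech.determinants"):
            t = sm.build_feature_table([r.fvp for r in res], decels,
                                       [r.athlete for r in res],
                                       [r.splits for r in res], None, "t15")
        assert len(t) == 7
        assert res[3].athlete.athlete_id not in t.athlete_ids
        assert "dropped" in caplog.text

    def test_misaligned_and_unknown_target(self):
        res = sm.process_cohort(sm.CohortSpec(n=6, seed=2), analytic=True)
        with pytest.raises(sm.InputError):
            sm.build_feature_table([r.fvp for r in res][:-1],
                                   [r.decel for r in res],
                                   [r.athlete for r in res],
                                   [r.splits for r in res], None, "t30")
        with pytest.raises(sm.InputError):
            sm.build_feature_table([r.fvp for r in res], [r.decel for r in res],
                                   [r.athlete for r in res],
                                   [r.splits for r in res], None, "t100")


class TestCollinearityFilter:
    def test_identical_columns_later_removed(self):
        t = _toy_table()
        frame = t.frame.copy()
        frame["x1_copy"] = frame["x1"]
        t2 = sm.FeatureTable(frame, t.target, "t30")
        filtered, removed = sm.collinearity_filter(t2)
        assert removed == ["x1_copy"]
        assert "x1" in filtered.columns

    def test_uncorrelated_table_unchanged(self):
        filtered, removed = sm.collinearity_filter(_toy_table())
        assert removed == []
        assert filtered.columns == ["x1", "x2"]

    def test_near_duplicate_detected(self):
        filtered, removed = sm.collinearity_filter(_toy_table(collinear=True))
        assert removed == ["x3"]
        assert filtered.columns == ["x1", "x2"]

    def test_constant_column_removed_with_warning(self, caplog):
        t = _toy_table()
        frame = t.frame.copy()
        frame["const"] = 1.0
        with caplog.at_level(logging.WARNING, logger="sprintmech.determinants"):
            _, removed = sm.collinearity_filter(
                sm.FeatureTable(frame, t.target, "t30"))
        assert removed == ["const"]
        assert "constant" in caplog.text


class TestStandardize:
    def test_hand_computed_values(self):
        # x repeats [1, 2, 3]: population-sd scaling maps it to +-1.2247
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0] * 2,
                              "y": [0.0, 1.0, 5.0, 2.0, 4.0, 3.0]})
        t = sm.FeatureTable(frame, pd.Series(np.arange(6.0)), "t5")
        scaled, means, sds = sm.standardize(t)
        assert np.allclose(scaled.frame["x"],
                           [-1.2247448, 0.0, 1.2247448] * 2, atol=1e-6)
        assert means["x"] == 2.0
        assert sds["x"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_idempotent_and_invertible(self):
        t = _toy_table()
        scaled, means, sds = sm.standardize(t)
        again, m2, s2 = sm.standardize(scaled)
        assert np.allclose(scaled.frame.to_numpy(), again.frame.to_numpy(),
                           atol=1e-12)
        back = scaled.frame * sds + means
        assert np.allclose(back.to_numpy(), t.frame.to_numpy(), atol=1e-12)

    def test_constant_column_rejected(self):
        t = _toy_table()
        frame = t.frame.copy()
        frame["const"] = 7.0
        with pytest.raises(sm.InputError, match="const"):
            sm.standardize(sm.FeatureTable(frame, t.target, "t30"))


class TestRegressionMetrics:
    def test_perfect_fit(self):
        assert sm.regression_metrics([1, 2, 3], [1, 2, 3]) == (0, 0, 0, 1)

    def test_hand_example(self):
        mae, mse, rmse, r2 = sm.regression_metrics([1, 2, 3], [2, 2, 2])
        assert mae == pytest.approx(2 / 3)
        assert mse == pytest.approx(2 / 3)
        assert rmse == pytest.approx(np.sqrt(2 / 3))
        assert r2 == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        *_, r2 = sm.regression_metrics([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert r2 < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(sm.EstimationError):
            sm.regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestFitCandidateModels:
    def test_noise_free_planted_recovered_exactly(self):
        t = _toy_table(n=40)
        results = sm.fit_candidate_models(t, sm.ModelSpec(seed=1))
        best = sm.selected_model(results)
        assert best.family == "ols"
        assert best.r2_test == pytest.approx(1.0, abs=1e-12)
        assert best.coefficients["x1"] == pytest.approx(2.0, abs=1e-9)
        assert best.coefficients["x2"] == pytest.approx(-1.0, abs=1e-9)
        assert best.intercept == pytest.approx(3.0, abs=1e-9)

    def test_lasso_full_shrinkage_limit(self):
        # weak signal + alpha 10 on standardized predictors kills every weight
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"x1": rng.normal(0, 1, 30),
                              "x2": rng.normal(0, 1, 30)},
                             index=[f"a{i}" for i in range(30)])
        y = pd.Series(rng.normal(5.0, 0.1, 30), index=frame.index)
        t = sm.FeatureTable(frame, y, "coda")
        spec = sm.ModelSpec(families=("lasso",), alpha_grid=(10.0,), seed=0)
        fit = sm.fit_candidate_models(t, spec)[0]
        assert all(w == 0.0 for w in fit.coefficients_std.values())
        y_train = y.to_numpy()[fit.train_index]
        assert fit.intercept_std == pytest.approx(y_train.mean(), rel=1e-9)

    def test_ridge_vanishing_penalty_approaches_ols(self):
        t = _toy_table(n=40, seed=3)
        t = with_outcome(t, t.target + np.random.default_rng(5).normal(0, 0.1, 40),
                         "t30")
        ols = sm.fit_candidate_models(
            t, sm.ModelSpec(families=("ols",), seed=2))[0]
        ridge = sm.fit_candidate_models(
            t, sm.ModelSpec(families=("ridge",), alpha_grid=(1e-4,), seed=2))[0]
        for c in t.columns:
            assert ridge.coefficients_std[c] == pytest.approx(
                ols.coefficients_std[c], abs=1e-3)

    def test_deterministic_given_seed(self):
        t = analytic_feature_table(seed=9)
        a = sm.fit_candidate_models(*_filtered(t, seed=4))
        b = sm.fit_candidate_models(*_filtered(t, seed=4))
        for ra, rb in zip(a, b):
            assert ra.as_dict() == rb.as_dict()

    def test_no_information_leaks_from_test_rows(self):
        t = _toy_table(n=40, seed=6)
        spec = sm.ModelSpec(seed=3)
        ref = sm.fit_candidate_models(t, spec)
        test_row = ref[0].test_index[0]
        frame = t.frame.copy()
        frame.iloc[test_row, 0] += 50.0  # corrupt one held-out row
        alt = sm.fit_candidate_models(
            sm.FeatureTable(frame, t.target, "t30"), spec)
        for ra, rb in zip(ref, alt):
            assert ra.coefficients_std == rb.coefficients_std
            assert ra.intercept_std == rb.intercept_std

    def test_too_few_rows_and_flat_target(self):
        t = _toy_table(n=6)
        with pytest.raises(sm.InputError):
            sm.fit_candidate_models(t, sm.ModelSpec(seed=0, n_folds=5))
        flat = with_outcome(_toy_table(n=20), np.full(20, 2.0), "t30")
        with pytest.raises(sm.EstimationError):
            sm.fit_candidate_models(flat, sm.ModelSpec(seed=0))

    def test_null_outcomes_give_near_zero_median_r2(self):
        t = analytic_feature_table(seed=7)
        r2 = []
        for rep in range(40):
            y = sm.generate_outcomes(t, {}, 9.28, 0.30, seed=3000 + rep)
            tab = with_outcome(t, y, "coda")
            filt, _ = sm.collinearity_filter(tab)
            fits = sm.fit_candidate_models(filt, sm.ModelSpec(seed=rep))
            r2.append(sm.selected_model(fits).r2_test)
        assert -0.4 < np.median(r2) < 0.15


def _filtered(table, seed):
    filt, _ = sm.collinearity_filter(table)
    return filt, sm.ModelSpec(seed=seed)


class TestDiagnostics:
    def _fit(self, y, frame):
        t = sm.FeatureTable(frame, pd.Series(y, index=frame.index), "t30")
        fits = sm.fit_candidate_models(t, sm.ModelSpec(families=("ols",), seed=0))
        return fits[0], t

    def test_gaussian_residuals_usually_pass_normality(self):
        n, passes = 200, 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame({"x": rng.normal(0, 1, n)},
                                 index=[f"a{i}" for i in range(n)])
            fit, t = self._fit(1.0 + 0.5 * frame["x"] + rng.normal(0, 0.2, n),
                               frame)
            passes += sm.residual_diagnostics(fit, t).pass_normality
        assert passes >= 0.9 * 60

    def test_heteroscedastic_residuals_flagged(self):
        n, flags = 200, 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.5, 3.0, n)
            frame = pd.DataFrame({"x": x}, index=[f"a{i}" for i in range(n)])
            y = 1.0 + 0.5 * x + rng.normal(0, 0.3 * x)  # variance grows with x
            fit, t = self._fit(y, frame)
            flags += not sm.residual_diagnostics(fit, t).pass_homoscedasticity
        assert flags >= 0.9 * 60

    def test_degenerate_residuals_flagged_not_crashing(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"x": rng.normal(0, 1, 30)},
                             index=[f"a{i}" for i in range(30)])
        fit, t = self._fit(2.0 + 3.0 * frame["x"], frame)  # exact fit
        diag = sm.residual_diagnostics(fit, t)
        assert diag.degenerate
        assert np.isnan(diag.shapiro_p)
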