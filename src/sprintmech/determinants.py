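"""Mechanical determinants of sprint and change-of-direction performance.

Statistical stage: assemble the athletes x predictors table, drop collinear
predictors (|Pearson r| > 0.8), hold out a test split, standardize on the
training rows, fit OLS / Ridge / Lasso (penalty chosen by k-fold
cross-validation over a fixed alpha grid), select the best model by test
R^2, and check the residual assumptions (Shapiro-Wilk normality,
Breusch-Pagan homoscedasticity).

Pipeline order is filter -> split -> scale-on-train -> fit, so no scaling
information leaks from the held-out rows.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold, train_test_split
from sklearn.preprocessing import StandardScaler
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from .errors import EstimationError, InputError
from .models import (
    AthleteRecord,
    DecelResult,
    DiagnosticsResult,
    FeatureTable,
    FitResult,
    ModelSpec,
    SplitTimes,
    SprintFVP,
)

logger = logging.getLogger(__name__)

#: Default predictor set, in scan order for the collinearity filter. The
#: relative-F0 and measured-peak-speed predictors come first so that when a
#: correlated absolute/theoretical variant must be dropped, they survive.
DEFAULT_PREDICTORS = (
    "f0_rel", "vmax", "v0", "pmax_rel", "sfv_rel", "rfmax", "drf",
    "decel_early", "mass", "stature", "f0_abs", "pmax_abs",
)

TARGETS = ("t5", "t15", "t30", "coda")

# tie-break preference among equally good candidates: OLS last
_FAMILY_PRIORITY = {"ridge": 0, "lasso": 1, "ols": 2}


def build_feature_table(fvps: Sequence[SprintFVP | None],
                        decels: Sequence[DecelResult | None],
                        athletes: Sequence[AthleteRecord],
                        splits: Sequence[SplitTimes | None],
                        coda: Sequence[float | None] | None,
                        target_name: str,
                        predictors: Sequence[str] = DEFAULT_PREDICTORS,
                        ) -> FeatureTable:
    """Assemble the per-athlete predictor table with one target column.

    All input sequences are aligned by athlete. Athletes with any missing
    component (``None`` entries) are dropped with a logged warning.
    """
    n = len(athletes)
    if not (len(fvps) == len(decels) == len(splits) == n) or (
            target_name == "coda" and (coda is None or len(coda) != n)):
        raise InputError("misaligned input lists; one entry per athlete required")
    if target_name not in TARGETS:
        raise InputError(f"unknown target {target_name!r}; valid: {TARGETS}")
    unknown = set(predictors) - set(DEFAULT_PREDICTORS)
    if unknown:
        raise InputError(f"unknown predictors {sorted(unknown)}")

    rows, targets, ids, dropped = [], [], [], []
    for i, ath in enumerate(athletes):
        fvp, dec, spl = fvps[i], decels[i], splits[i]
        cod = coda[i] if coda is not None else None
        if fvp is None or dec is None or spl is None or (
                target_name == "coda" and cod is None):
            dropped.append(ath.athlete_id)
            continue
        full = {
            "f0_rel": fvp.f0_rel, "vmax": fvp.vmax_measured, "v0": fvp.v0,
            "pmax_rel": fvp.pmax_rel, "sfv_rel": fvp.sfv_rel,
            "rfmax": fvp.rfmax, "drf": fvp.drf,
            "decel_early": dec.decel_early, "mass": ath.mass,
            "stature": ath.stature, "f0_abs": fvp.f0_abs,
            "pmax_abs": fvp.pmax_abs,
        }
        rows.append({k: full[k] for k in predictors})
        ids.append(ath.athlete_id)
        if target_name == "coda":
            targets.append(float(cod))
        else:
            targets.append(spl.time_at(float(target_name[1:])))
    if dropped:
        logger.warning("dropped %d athlete(s) with missing components: %s",
                       len(dropped), ", ".join(dropped))
    frame = pd.DataFrame(rows, index=ids, columns=list(predictors))
    return FeatureTable(frame, pd.Series(targets, index=ids), target_name)


def collinearity_filter(table: FeatureTable, threshold: float = 0.8,
                        ) -> tuple[FeatureTable, list[str]]:
    """Drop predictors with |Pearson r| > threshold with an earlier one.

    Columns are scanned in declared order; of a too-correlated pair the
    later column is removed, iterating until no pair exceeds the threshold.
    Constant columns (undefined correlation) are removed with a warning.
    """
    if len(table.columns) < 2:
        raise InputError("collinearity filter needs at least 2 predictors")
    removed: list[str] = []
    kept: list[str] = []
    X = table.frame
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            logger.warning("removed constant predictor %r (correlation "
                           "undefined)", col)
            removed.append(col)
            continue
        too_close = [k for k in kept
                     if abs(np.corrcoef(X[k].to_numpy(dtype=float), x)[0, 1])
                     > threshold]
        if too_close:
            logger.info("removed %r (|r| > %.2f with %s)", col, threshold,
                        ", ".join(too_close))
            removed.append(col)
        else:
            kept.append(col)
    return table.with_frame(X[kept]), removed


def standardize(table: FeatureTable,
                ) -> tuple[FeatureTable, pd.Series, pd.Series]:
    """Scale every predictor to mean 0, sd 1 (population-sd convention).

    Returns the scaled table plus the means and sds needed to invert the
    transform. The target is left unscaled. Constant predictors raise.
    """
    X = table.frame
    means = X.mean()
    sds = X.std(ddof=0)
    constant = sds[sds == 0.0]
    if len(constant):
        raise InputError(f"constant predictor(s) {list(constant.index)} "
                         "cannot be standardized")
    scaled = (X - means) / sds
    return table.with_frame(scaled), means, sds


def regression_metrics(y_true, y_pred) -> tuple[float, float, float, float]:
    """(MAE, MSE, RMSE, R^2) with R^2 = 1 - SSres/SStot about mean(y_true)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 2:
        raise InputError("y_true and y_pred must be equal-length vectors (n >= 2)")
    err = y_true - y_pred
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0.0:
        raise EstimationError("R^2 undefined: y_true has zero variance")
    r2 = 1.0 - float(np.sum(err**2)) / sstot
    return mae, mse, float(np.sqrt(mse)), r2


def _make_estimator(family: str, alpha: float):
    if family == "ols":
        return LinearRegression()
    if family == "ridge":
        return Ridge(alpha=alpha)
    return Lasso(alpha=alpha, max_iter=100_000)


def _cv_alpha(family: str, X_train: pd.DataFrame, y_train: np.ndarray,
              spec: ModelSpec) -> float:
    """Pick the penalty minimizing mean k-fold validation MSE (ties: first
    alpha in grid order). Scaling is refit inside every fold."""
    kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    best_alpha, best_err = None, np.inf
    Xa = X_train.to_numpy(dtype=float)
    for alpha in spec.alpha_grid:
        errs = []
        for tr, va in kf.split(Xa):
            scaler = StandardScaler().fit(Xa[tr])
            est = _make_estimator(family, alpha)
            est.fit(scaler.transform(Xa[tr]), y_train[tr])
            pred = est.predict(scaler.transform(Xa[va]))
            errs.append(np.mean((y_train[va] - pred) ** 2))
        err = float(np.mean(errs))
        if err < best_err:
            best_alpha, best_err = alpha, err
    return best_alpha


def fit_candidate_models(table: FeatureTable, spec: ModelSpec,
                         ) -> list[FitResult]:
    """Fit every requested family and flag the best model.

    One seeded train/test split at ``spec.test_fraction``; ridge/lasso
    penalties are chosen by ``spec.n_folds``-fold CV *within the training
    rows*; every family is then refit on the full training set and scored on
    the untouched test rows. The candidate with the highest test R^2 is
    flagged ``selected`` (ties: fewer nonzero coefficients, then OLS-last
    preference).
    """
    n = len(table)
    if n < spec.n_folds + 2:
        raise InputError(f"need at least n_folds + 2 = {spec.n_folds + 2} "
                         f"rows, got {n}")
    y = table.target.to_numpy(dtype=float)
    if np.std(y) == 0.0:
        raise EstimationError("target has zero variance")
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=spec.test_fraction, random_state=spec.seed, shuffle=True)
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    X = table.frame
    X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
    y_train, y_test = y[train_idx], y[test_idx]

    means = X_train.mean()
    sds = X_train.std(ddof=0)
    if (sds == 0.0).any():
        raise EstimationError(
            f"constant predictor(s) on the training rows: "
            f"{list(sds.index[sds == 0.0])}")
    Z_train = ((X_train - means) / sds).to_numpy(dtype=float)
    Z_test = ((X_test - means) / sds).to_numpy(dtype=float)

    results: list[FitResult] = []
    for family in spec.families:
        alpha = 0.0 if family == "ols" else _cv_alpha(family, X_train, y_train, spec)
        est = _make_estimator(family, alpha)
        est.fit(Z_train, y_train)
        w_std = dict(zip(X.columns, (float(c) for c in est.coef_)))
        b_std = float(est.intercept_)
        w_raw = {c: w_std[c] / float(sds[c]) for c in X.columns}
        b_raw = b_std - sum(w_std[c] * float(means[c]) / float(sds[c])
                            for c in X.columns)
        pred_test = est.predict(Z_test)
        mae, mse, rmse, r2_test = regression_metrics(y_test, pred_test)
        _, _, _, r2_train = regression_metrics(y_train, est.predict(Z_train))
        results.append(FitResult(
            family=family, alpha=float(alpha), intercept=b_raw,
            coefficients=w_raw, intercept_std=b_std, coefficients_std=w_std,
            r2_train=r2_train, r2_test=r2_test, mae=mae, mse=mse, rmse=rmse,
            train_index=train_idx, test_index=test_idx))

    best = min(results, key=lambda r: (-r.r2_test, r.n_nonzero,
                                       _FAMILY_PRIORITY[r.family]))
    best.selected = True
    return results


def selected_model(results: Sequence[FitResult]) -> FitResult:
    """The candidate flagged as best by :func:`fit_candidate_models`."""
    for r in results:
        if r.selected:
            return r
    raise EstimationError("no model flagged as selected")


def residual_diagnostics(fit: FitResult, table: FeatureTable,
                         ) -> DiagnosticsResult:
    """Shapiro-Wilk and Breusch-Pagan tests on the training residuals.

    Breusch-Pagan regresses squared residuals on the (training-scaled)
    predictors. Degenerate residuals (all ~equal) set ``degenerate=True``
    with NaN statistics instead of crashing.
    """
    if fit.train_index is None:
        raise InputError("fit carries no training rows; refit with "
                         "fit_candidate_models first")
    X_train = table.frame.iloc[fit.train_index]
    y_train = table.target.to_numpy(dtype=float)[fit.train_index]
    if len(y_train) < 3:
        raise InputError("diagnostics need at least 3 training rows")
    pred = fit.intercept + sum(
        w * X_train[c].to_numpy(dtype=float) for c, w in fit.coefficients.items())
    resid = y_train - pred
    if np.ptp(resid) < 1e-12:
        return DiagnosticsResult(
            shapiro_stat=float("nan"), shapiro_p=float("nan"),
            bp_stat=float("nan"), bp_p=float("nan"),
            pass_normality=False, pass_homoscedasticity=False, degenerate=True)
    sw_stat, sw_p = stats.shapiro(resid)
    exog = sm.add_constant(X_train.to_numpy(dtype=float))
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, exog)
    return DiagnosticsResult(
        shapiro_stat=float(sw_stat), shapiro_p=float(sw_p),
        bp_stat=float(bp_stat), bp_p=float(bp_p),
        pass_normality=bool(sw_p >= 0.05),
        pass_homoscedasticity=bool(bp_p >= 0.05))
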