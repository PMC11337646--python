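"""Biomass prediction learners: grid search under 10x10 repeated k-fold
cross-validation, the evaluation metrics, and general-vs-specific model
comparisons.

Four learner families are supported: partial least squares (``plsr``, the
in-package PLS1 with its component path), random forest (``rf``), a
polynomial-kernel support vector machine (``svm_poly``) and gradient-boosted
trees (``xgboost``).  Hyperparameter grids default to three values spanning
each tuning range; the winner minimizes mean cross-validation RMSE over the
folds x repeats and is refit on the full training set.
``plsr_refined`` is accepted as an alias of ``plsr`` (its refinement is the
RFE-selected subset it is trained on, not a different learner).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .selection import PLS1

__all__ = [
    "LEARNERS",
    "ModelConfig",
    "FitResult",
    "split_train_test",
    "evaluate_metrics",
    "train_model",
    "compare_general_specific",
]

LEARNERS = ("plsr", "rf", "svm_poly", "xgboost")


def default_grid(learner: str, n_features: int) -> list[dict]:
    """Hyperparameter grid within the study's tuning ranges."""
    if learner in ("plsr", "plsr_refined"):
        return [{"n_components": k} for k in range(1, n_features + 1)]
    if learner == "rf":
        if n_features <= 6:
            mtry = list(range(1, n_features + 1))
        else:
            mtry = sorted({int(round(v)) for v in np.linspace(1, n_features, 5)})
        return [{"max_features": m} for m in mtry]
    if learner == "svm_poly":
        return [
            {"degree": d, "C": c, "gamma": g}
            for d in (1, 2)
            for c in (100.0, 550.0, 1000.0)
            for g in (1e-4, 1e-3, 1e-2)
        ]
    if learner == "xgboost":
        return [
            {
                "n_estimators": n,
                "max_depth": d,
                "learning_rate": e,
                "gamma": 0.8,
                "colsample_bytree": cs,
            }
            for n in (20, 30, 40)
            for d in (9, 10)
            for e in (0.1, 0.2, 0.3)
            for cs in (0.7, 1.0)
        ]
    raise ValueError(f"unknown learner {learner!r}; known: {LEARNERS}")


@dataclass
class ModelConfig:
    learner: str = "rf"
    grid: list[dict] | None = None  # None -> default_grid at fit time
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0
    rf_trees: int = 200

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS and self.learner != "plsr_refined":
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def make_estimator(learner: str, params: dict, seed: int, rf_trees: int = 200):
    if learner in ("plsr", "plsr_refined"):
        return PLS1(**params)
    if learner == "rf":
        return RandomForestRegressor(
            n_estimators=rf_trees,
            min_samples_leaf=5,
            criterion="squared_error",
            random_state=seed,
            n_jobs=1,
            **params,
        )
    if learner == "svm_poly":
        return Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(kernel="poly", coef0=1.0, **params))]
        )
    if learner == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(
            objective="reg:squarederror",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            **params,
        )
    raise ValueError(f"unknown learner {learner!r}")


def split_train_test(data: pd.DataFrame, train_frac: float = 0.8,
                     strata: str = "experiment", seed: int = 0):
    """Disjoint, exhaustive train/test split, stratified so every level of
    ``strata`` contributes ~``train_frac`` of its rows to the training set."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    groups = data.groupby(strata, sort=True).indices if strata else {"all": np.arange(len(data))}
    for level, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"stratum {level!r} has fewer than 2 rows")
        perm = rng.permutation(idx)
        k = int(round(train_frac * len(idx)))
        k = min(max(k, 1), len(idx) - 1)  # both sides non-empty
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return data.iloc[train_idx], data.iloc[test_idx]


def evaluate_metrics(obs, pred, as_printed: bool = False) -> dict[str, float]:
    """R^2, RMSE (g/m^2) and relative RMSE.

    Standard definitions: R^2 = 1 - SSE/SST, RMSE = sqrt(mean squared
    error), rRMSE = RMSE / mean(obs).  ``as_printed=True`` reproduces the
    study's printed equation forms verbatim for audit (R^2 as the
    unexplained-variance ratio SSE/SST and RMSE without the 1/n).
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("obs and pred must be equal-length vectors, n >= 2")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: zero variance in observations")
    obar = float(obs.mean())
    if obar == 0:
        raise ValueError("rRMSE undefined: mean of observations is zero")
    rmse = float(np.sqrt(sse / obs.size))
    if as_printed:
        return {"r2": sse / sst, "rmse": float(np.sqrt(sse)), "rrmse": rmse / obar}
    return {"r2": 1.0 - sse / sst, "rmse": rmse, "rrmse": rmse / obar}


@dataclass
class FitResult:
    learner: str
    best_params: dict
    cv_metrics: dict[str, float]  # mean over folds x repeats of the winner
    fold_metrics: pd.DataFrame  # one row per fold x repeat of the winner
    grid_rmse: pd.DataFrame  # mean cv RMSE per grid point
    estimator: object  # winner refit on the full training set
    feature_names: list[str]
    cv_predictions: pd.DataFrame  # out-of-fold predictions, averaged over repeats
    test_metrics: dict[str, float] | None = None
    test_predictions: pd.DataFrame | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.estimator.predict(X[self.feature_names].to_numpy(dtype=float))).ravel()

    def evaluate(self, X: pd.DataFrame, y) -> dict[str, float]:
        return evaluate_metrics(np.asarray(y, dtype=float), self.predict(X))

    def summary(self) -> str:
        lines = [
            f"Learner: {self.learner}",
            f"Best hyperparameters: {self.best_params}",
            f"CV ({len(self.fold_metrics)} fold x repeat): "
            f"R2={self.cv_metrics['r2']:.3f}  RMSE={self.cv_metrics['rmse']:.1f} g/m2  "
            f"rRMSE={self.cv_metrics['rrmse']:.3f}",
        ]
        if self.test_metrics:
            lines.append(
                f"Test: R2={self.test_metrics['r2']:.3f}  "
                f"RMSE={self.test_metrics['rmse']:.1f} g/m2  "
                f"rRMSE={self.test_metrics['rrmse']:.3f}"
            )
        return "\n".join(lines)


def _cv_fold_indices(n: int, folds: int, repeats: int, seed: int):
    """(repeat, fold, train_idx, val_idx); fold assignment reseeded
    deterministically per repeat."""
    for r in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=(seed * 1009 + r) % (2**31))
        for f, (tr, va) in enumerate(kf.split(np.arange(n))):
            yield r, f, tr, va


def train_model(X_train: pd.DataFrame, y_train, config: ModelConfig,
                X_test: pd.DataFrame | None = None, y_test=None) -> FitResult:
    """Grid search by repeated k-fold CV, winner refit on the full training
    set.  CV metrics are the mean over all fold x repeat evaluations of the
    winning grid point (not a single pooled evaluation)."""
    y = np.asarray(y_train, dtype=float).ravel()
    if np.std(y) == 0:
        raise ValueError("degenerate response: zero variance")
    names = list(X_train.columns)
    Xv = X_train.to_numpy(dtype=float)
    n = len(y)
    grid = config.grid if config.grid is not None else default_grid(config.learner, len(names))

    folds = list(_cv_fold_indices(n, config.cv_folds, config.cv_repeats, config.seed))
    use_path = config.learner in ("plsr", "plsr_refined") and all(
        set(g) == {"n_components"} for g in grid
    )

    # per grid point, per fold: predictions on the validation rows
    fold_preds: list[list[np.ndarray]] = [[] for _ in grid]
    if use_path:
        comps = [g["n_components"] for g in grid]
        a_max = max(comps)
        for _, _, tr, va in folds:
            model = PLS1(n_components=a_max).fit(Xv[tr], y[tr])
            preds = model.predict_all(Xv[va])
            for gi, k in enumerate(comps):
                fold_preds[gi].append(preds[:, min(k, model.n_components_) - 1])
    else:
        for gi, params in enumerate(grid):
            est = make_estimator(config.learner, params, config.seed, config.rf_trees)
            for _, _, tr, va in folds:
                m = clone(est)
                m.fit(Xv[tr], y[tr])
                fold_preds[gi].append(np.asarray(m.predict(Xv[va])).ravel())

    grid_rmse = []
    for gi, params in enumerate(grid):
        rmses = [
            float(np.sqrt(np.mean((p - y[va]) ** 2)))
            for p, (_, _, _, va) in zip(fold_preds[gi], folds)
        ]
        grid_rmse.append({**params, "cv_rmse": float(np.mean(rmses))})
    grid_df = pd.DataFrame(grid_rmse)
    best_i = int(grid_df["cv_rmse"].idxmin())
    best_params = grid[best_i]

    rows = []
    pred_sum = np.zeros(n)
    for p, (r, f, _, va) in zip(fold_preds[best_i], folds):
        m = evaluate_metrics(y[va], p)
        rows.append({"repeat": r, "fold": f, **m})
        pred_sum[va] += p
    fold_df = pd.DataFrame(rows)
    cv_metrics = {k: float(fold_df[k].mean()) for k in ("r2", "rmse", "rrmse")}
    cv_pred = pd.DataFrame(
        {"obs": y, "pred": pred_sum / config.cv_repeats}, index=X_train.index
    )

    winner = make_estimator(config.learner, best_params, config.seed, config.rf_trees)
    winner.fit(Xv, y)

    test_metrics = None
    test_pred = None
    if X_test is not None and y_test is not None:
        yt = np.asarray(y_test, dtype=float).ravel()
        pt = np.asarray(winner.predict(X_test[names].to_numpy(dtype=float))).ravel()
        test_metrics = evaluate_metrics(yt, pt)
        test_pred = pd.DataFrame({"obs": yt, "pred": pt}, index=X_test.index)

    return FitResult(
        learner=config.learner,
        best_params=best_params,
        cv_metrics=cv_metrics,
        fold_metrics=fold_df,
        grid_rmse=grid_df,
        estimator=winner,
        feature_names=names,
        cv_predictions=cv_pred,
        test_metrics=test_metrics,
        test_predictions=test_pred,
    )


def compare_general_specific(data: pd.DataFrame, features: list[str], response: str,
                             axis: str, config: ModelConfig, seed: int = 0,
                             strata: str = "experiment",
                             min_rows: int = 10) -> pd.DataFrame:
    """Paired test RMSE of a general model (trained on all training rows)
    versus level-specific models, per level of ``axis`` (stage or
    experiment).  Levels with fewer than ``min_rows`` rows are skipped."""
    train, test = split_train_test(data, 0.8, strata=strata, seed=seed)
    general = train_model(train[features], train[response], config)
    rows = []
    for level, sub in data.groupby(axis, sort=True):
        if len(sub) < min_rows:
            continue
        tr = train[train[axis] == level]
        te = test[test[axis] == level]
        if len(te) < 2 or len(tr) < config.cv_folds:
            continue
        specific = train_model(tr[features], tr[response], config)
        m_gen = general.evaluate(te, te[response])
        m_spec = specific.evaluate(te, te[response])
        rows.append(
            {
                axis: level,
                "n_train": len(tr),
                "n_test": len(te),
                "rmse_general": m_gen["rmse"],
                "rmse_specific": m_spec["rmse"],
                "rmse_diff": m_spec["rmse"] - m_gen["rmse"],
                "r2_general": m_gen["r2"],
                "r2_specific": m_spec["r2"],
            }
        )
    return pd.DataFrame(rows)
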