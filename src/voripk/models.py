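"""Regression learners, metric suite and validation for trough prediction.

Six tree-ensemble regressors are compared on the Boruta-selected features
(XGBoost, LightGBM, GBDT, CatBoost, AdaBoost, random forest); a backend
that is not importable is skipped with a warning and the comparison
proceeds with the rest.  Metrics are MSE, RMSE, MAE, R2 and RA20 (the
fraction of predictions within +/-20% relative error).  Stability of the
chosen learner is probed with a 10-iteration bootstrap cross-validation
(fit on a resample, score R2 out-of-bag), and an untouched external set is
scored without refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)

from .structural import ConfigError, DataError

__all__ = [
    "ModelMetrics",
    "ModelComparison",
    "split_data",
    "available_learners",
    "train_all",
    "compute_metrics",
    "select_best",
    "compare_models",
    "bootstrap_cv",
    "evaluate_external",
]

#: shared boosting defaults (hyperparameters are a config choice here,
#: fixed for reproducibility rather than tuned per dataset)
N_TREES = 500
LEARNING_RATE = 0.05
MAX_DEPTH = 4


@dataclass(frozen=True)
class ModelMetrics:
    mse: float
    rmse: float
    mae: float
    r2: float | None
    ra20: float

    def as_dict(self) -> dict:
        return {"MSE": self.mse, "RMSE": self.rmse, "MAE": self.mae,
                "R2": self.r2, "RA20": self.ra20}


@dataclass
class ModelComparison:
    train_metrics: dict[str, ModelMetrics]
    val_metrics: dict[str, ModelMetrics]
    selected_best: str
    models: dict


def split_data(matrix: pd.DataFrame, train_frac: float = 0.7, seed: int = 0):
    """Random row split into train/validation at the given fraction.

    The train set takes floor(n * train_frac) rows; the split is a disjoint,
    exhaustive partition and reproducible under the seed.
    """
    if not (0.0 < train_frac < 1.0):
        raise ConfigError("train_frac must be in (0, 1)")
    if len(matrix) < 10:
        raise DataError("need at least 10 rows to split")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(matrix))
    n_train = int(np.floor(len(matrix) * train_frac))
    return (
        matrix.iloc[np.sort(idx[:n_train])].copy(),
        matrix.iloc[np.sort(idx[n_train:])].copy(),
    )


def _make_learners(seed: int) -> dict:
    learners: dict = {}
    try:
        from xgboost import XGBRegressor

        learners["XGBoost"] = XGBRegressor(
            n_estimators=N_TREES, learning_rate=LEARNING_RATE, max_depth=MAX_DEPTH,
            random_state=seed, n_jobs=1, verbosity=0,
        )
    except ImportError:  # pragma: no cover
        warnings.warn("xgboost unavailable: XGBoost skipped")
    try:
        from lightgbm import LGBMRegressor

        learners["LightGBM"] = LGBMRegressor(
            n_estimators=N_TREES, learning_rate=LEARNING_RATE, max_depth=MAX_DEPTH,
            num_leaves=2**MAX_DEPTH, random_state=seed, n_jobs=1, verbose=-1,
        )
    except ImportError:  # pragma: no cover
        warnings.warn("lightgbm unavailable: LightGBM skipped")
    learners["GBDT"] = GradientBoostingRegressor(
        n_estimators=N_TREES, learning_rate=LEARNING_RATE, max_depth=MAX_DEPTH,
        random_state=seed,
    )
    try:
        from catboost import CatBoostRegressor

        learners["CatBoost"] = CatBoostRegressor(
            n_estimators=N_TREES, learning_rate=LEARNING_RATE, depth=MAX_DEPTH,
            random_state=seed, verbose=0,
        )
    except ImportError:
        warnings.warn("catboost unavailable: CatBoost skipped")
    learners["AdaBoost"] = AdaBoostRegressor(
        n_estimators=200, learning_rate=LEARNING_RATE, random_state=seed,
    )
    learners["RF"] = RandomForestRegressor(
        n_estimators=N_TREES, random_state=seed, n_jobs=1,
    )
    return learners


def available_learners() -> list[str]:
    return list(_make_learners(0))


def train_all(train: pd.DataFrame, target: str = "CONC", seed: int = 0,
              features: list[str] | None = None) -> dict:
    """Fit every available learner on the training rows; returns name -> model."""
    if train[target].isna().any() or train.drop(columns=[target]).isna().any().any():
        raise DataError("training matrix contains missing cells")
    features = features or [c for c in train.columns if c != target]
    X = train[features]
    y = train[target].to_numpy(dtype=float)
    fitted = {}
    for name, model in _make_learners(seed).items():
        model.fit(X, y)
        model.feature_names_ = list(features)
        fitted[name] = model
    return fitted


def compute_metrics(y_obs, y_pred, ra_threshold: float = 0.20) -> ModelMetrics:
    """Metric suite; R2 is None (not-applicable) when y_obs has no variance."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise DataError("y_obs and y_pred must be equal-length with >= 2 values")
    if np.any(y_obs <= 0):
        raise DataError("relative accuracy requires positive observations")
    resid = y_pred - y_obs
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(resid)))
    sstot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    r2 = None if sstot == 0 else float(1.0 - np.sum(resid**2) / sstot)
    ra20 = float(np.mean(np.abs(resid) / y_obs <= ra_threshold))
    return ModelMetrics(mse=mse, rmse=rmse, mae=mae, r2=r2, ra20=ra20)


def _predict(model, frame: pd.DataFrame) -> np.ndarray:
    return np.asarray(model.predict(frame[model.feature_names_]))


def select_best(val_metrics: dict[str, ModelMetrics]) -> str:
    """Lowest validation RMSE; ties broken by higher R2, then by name."""
    def key(name):
        m = val_metrics[name]
        r2 = m.r2 if m.r2 is not None else -np.inf
        return (m.rmse, -r2, name)

    return min(val_metrics, key=key)


def compare_models(train: pd.DataFrame, validation: pd.DataFrame,
                   target: str = "CONC", seed: int = 0,
                   features: list[str] | None = None) -> ModelComparison:
    """Train all learners and rank them on the validation rows."""
    models = train_all(train, target=target, seed=seed, features=features)
    tm, vm = {}, {}
    for name, model in models.items():
        tm[name] = compute_metrics(train[target], _predict(model, train))
        vm[name] = compute_metrics(validation[target], _predict(model, validation))
    return ModelComparison(train_metrics=tm, val_metrics=vm,
                           selected_best=select_best(vm), models=models)


def bootstrap_cv(matrix: pd.DataFrame, algorithm: str = "XGBoost",
                 target: str = "CONC", n_iter: int = 10, seed: int = 0,
                 features: list[str] | None = None) -> dict:
    """Bootstrap cross-validation: fit on a resample, score R2 out-of-bag."""
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    features = features or [c for c in matrix.columns if c != target]
    r2s = []
    n = len(matrix)
    for _ in range(n_iter):
        while True:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if len(oob) >= 2:
                break
        boot = matrix.iloc[idx]
        model = _make_learners(int(rng.integers(2**31 - 1)))[algorithm]
        model.fit(boot[features], boot[target].to_numpy(dtype=float))
        pred = np.asarray(model.predict(matrix.iloc[oob][features]))
        m = compute_metrics(matrix.iloc[oob][target], pred)
        r2s.append(m.r2)
    return {"r2": r2s, "mean": float(np.mean(r2s)),
            "min": float(np.min(r2s)), "max": float(np.max(r2s))}


def evaluate_external(model, external: pd.DataFrame, train_medians=None,
                      target: str = "CONC") -> ModelMetrics:
    """Score a fitted model on an untouched external set (no refitting).

    Missing cells are imputed with the frozen training medians when given.
    """
    if len(external) == 0:
        raise DataError("external set is empty")
    missing = [c for c in model.feature_names_ if c not in external.columns]
    if missing:
        raise DataError("external set missing columns: " + ", ".join(missing))
    work = external.copy()
    if train_medians is not None:
        from .preprocess import impute_missing

        work, _ = impute_missing(work, medians=train_medians)
    elif work[model.feature_names_].isna().any().any():
        raise DataError("external set has missing cells and no training medians given")
    return compute_metrics(work[target], _predict(model, work))
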