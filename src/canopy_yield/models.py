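"""Regression models for yield estimation, with grid-search tuning.

Six models: three grouped as linear (PLSR, Elastic-Net, kernel ridge) and
three nonlinear (SVR, MLP, extreme learning machine). The ELM is implemented
here: a single hidden layer whose input weights and biases are drawn once
from a seeded uniform(−1, 1) and never trained; only the output weights are
solved by (ridge-regularised) least squares on the hidden activations,

    H = act(X·W_in + b),   β = (HᵀH + λI)⁻¹ Hᵀ y   (pseudoinverse when λ=0).

All models are wrapped in a pipeline that z-scores features using training
statistics only; hyperparameters are tuned by exhaustive grid search with
seeded k-fold cross-validation minimising RMSE, then refit on the full
training split.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .evaluation import EvalMetrics, compute_metrics
from .io_core import FeatureTable

MODEL_NAMES = ("PLSR", "ElasticNet", "KRR", "SVR", "MLP", "ELM")
LINEAR_MODELS = ("PLSR", "ElasticNet", "KRR")
NONLINEAR_MODELS = ("SVR", "MLP", "ELM")


class ELMRegressor(BaseEstimator, RegressorMixin):
    """Extreme learning machine: random fixed hidden layer + least squares.

    Parameters
    ----------
    n_hidden
        Hidden units.
    activation
        "sigmoid" or "tanh".
    ridge
        λ of the ridge solve for the output weights; 0 uses the
        minimum-norm least-squares solution (pseudoinverse).
    random_state
        Seed for the input weights/biases; refits are bit-identical.

    Inputs are affinely rescaled to [−1, 1] per feature using training
    min/max (constant features map to 0).
    """

    def __init__(self, n_hidden: int = 50, activation: str = "sigmoid",
                 ridge: float = 0.0, random_state: int = 0):
        self.n_hidden = n_hidden
        self.activation = activation
        self.ridge = ridge
        self.random_state = random_state

    def _act(self, Z: np.ndarray) -> np.ndarray:
        if self.activation == "sigmoid":
            return 1.0 / (1.0 + np.exp(-Z))
        if self.activation == "tanh":
            return np.tanh(Z)
        raise ValueError(f"unknown activation {self.activation!r}")

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = self.x_max_ - self.x_min_
        span = np.where(span > 0, span, 1.0)
        return 2.0 * (X - self.x_min_) / span - 1.0

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        self.x_min_ = X.min(axis=0)
        self.x_max_ = X.max(axis=0)
        rng = np.random.default_rng(self.random_state)
        p = X.shape[1]
        self.W_in_ = rng.uniform(-1.0, 1.0, size=(p, self.n_hidden))
        self.bias_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = self._act(self._scale(X) @ self.W_in_ + self.bias_)
        # unpenalised intercept via centring: constant targets are exact
        self.h_mean_ = H.mean(axis=0)
        Hc, yc = H - self.h_mean_, y - y.mean()
        if self.ridge > 0:
            A = Hc.T @ Hc + self.ridge * np.eye(self.n_hidden)
            self.beta_ = np.linalg.solve(A, Hc.T @ yc)
        else:
            self.beta_, *_ = np.linalg.lstsq(Hc, yc, rcond=None)
        self.intercept_ = float(y.mean())
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        H = self._act(self._scale(X) @ self.W_in_ + self.bias_)
        return (H - self.h_mean_) @ self.beta_ + self.intercept_


def fit_elm(train: FeatureTable, n_hidden: int = 50, activation: str = "sigmoid",
            ridge: float = 0.0, seed: int = 0) -> ELMRegressor:
    """Fit a standalone ELM on a feature table (no grid search)."""
    elm = ELMRegressor(n_hidden=n_hidden, activation=activation,
                       ridge=ridge, random_state=seed)
    return elm.fit(train.X.to_numpy(), train.y.to_numpy())


# ---------------------------------------------------------------------------
# splits

DEFAULT_SPLIT_RATIO = 199 / 315  # 199 training / 116 validation samples


def split_train_validation(table: FeatureTable, ratio: float = DEFAULT_SPLIT_RATIO,
                           seed: int = 42) -> tuple[FeatureTable, FeatureTable]:
    """Seeded random partition into train and validation tables."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    idx = table.data.index
    return (table.select_rows(idx[np.sort(perm[:n_train])]),
            table.select_rows(idx[np.sort(perm[n_train:])]))


# ---------------------------------------------------------------------------
# grid-search fitting

def default_grids(n_features: int, seed: int) -> dict[str, tuple[BaseEstimator, dict]]:
    """Estimator + hyperparameter grid per model name."""
    log_grid = [1e-3, 1e-2, 1e-1, 1.0, 10.0]
    return {
        "PLSR": (PLSRegression(),
                 {"model__n_components": list(range(1, min(10, n_features) + 1))}),
        "ElasticNet": (ElasticNet(max_iter=20000),
                       {"model__alpha": [1e-3, 1e-2, 1e-1, 1.0, 10.0],
                        "model__l1_ratio": [0.1, 0.5, 0.9]}),
        "KRR": (KernelRidge(kernel="rbf"),
                {"model__alpha": log_grid, "model__gamma": log_grid}),
        "SVR": (SVR(kernel="rbf"),
                {"model__C": [1.0, 10.0, 100.0],
                 "model__epsilon": [0.01, 0.1],
                 "model__gamma": log_grid}),
        "MLP": (MLPRegressor(hidden_layer_sizes=(32,), solver="lbfgs",
                             max_iter=2000, random_state=seed),
                {"model__hidden_layer_sizes": [(8,), (32,), (128,)],
                 "model__alpha": [1e-4, 1e-2]}),
        "ELM": (ELMRegressor(random_state=seed),
                {"model__n_hidden": [20, 50, 100, 200],
                 "model__ridge": [0.0, 1e-6, 1e-3]}),
    }


@dataclasses.dataclass
class ModelSpec:
    """One model to tune: name, grid override, CV folds and seed."""

    name: str
    grid: Mapping[str, list] | None = None
    cv_folds: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; use {MODEL_NAMES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclasses.dataclass
class FitReport:
    """Fitted pipeline with its tuning choices, predictions and metrics."""

    model: str
    selector: str
    best_params: dict
    pipeline: Pipeline
    feature_names: list[str]
    train_pred: pd.Series
    val_pred: pd.Series | None
    train_metrics: EvalMetrics
    val_metrics: EvalMetrics | None


def fit_model(spec: ModelSpec, train: FeatureTable,
              validation: FeatureTable | None = None,
              selector: str = "-") -> FitReport:
    """Grid-search fit of one model; metrics on the train and validation splits.

    The training metrics are refit-on-train metrics (the tuned pipeline
    re-applied to its own training split), not cross-validation scores.
    """
    est, grid = default_grids(len(train.feature_names), spec.seed)[spec.name]
    if spec.grid is not None:
        grid = {f"model__{k}" if not k.startswith("model__") else k: v
                for k, v in spec.grid.items()}
    pipe = Pipeline([("scale", StandardScaler()), ("model", est)])
    cv = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1,
                          scoring="neg_root_mean_squared_error",
                          error_score=np.nan, refit=True)
    X, y = train.X.to_numpy(), train.y.to_numpy()
    search.fit(X, y)
    best = search.best_estimator_
    tp = pd.Series(np.ravel(best.predict(X)), index=train.data.index)
    tm = compute_metrics(train.y, tp)
    vp = vm = None
    if validation is not None:
        vp = pd.Series(np.ravel(predict(best, validation, train.feature_names)),
                       index=validation.data.index)
        vm = compute_metrics(validation.y, vp)
    return FitReport(model=spec.name, selector=selector,
                     best_params={k.removeprefix("model__"): v
                                  for k, v in search.best_params_.items()},
                     pipeline=best, feature_names=train.feature_names,
                     train_pred=tp, val_pred=vp,
                     train_metrics=tm, val_metrics=vm)


def predict(fitted, table: FeatureTable, feature_names: list[str] | None = None,
            clip_at_zero: bool = False) -> np.ndarray:
    """Predict yields (t·ha⁻¹) for a table; columns must match training.

    *fitted* is a FitReport or any fitted estimator/pipeline. Column names
    and order are checked against *feature_names* (taken from the report
    when available).
    """
    if isinstance(fitted, FitReport):
        feature_names = fitted.feature_names
        fitted = fitted.pipeline
    if feature_names is not None:
        missing = [c for c in feature_names if c not in table.feature_names]
        extra = [c for c in table.feature_names if c not in feature_names]
        if missing or extra:
            raise ValueError(
                f"feature columns mismatch: missing {missing}, extra {extra}")
        X = table.data[list(feature_names)].to_numpy()
    else:
        X = table.X.to_numpy()
    if len(X) == 0:
        return np.empty(0)
    out = np.ravel(fitted.predict(X))
    return np.clip(out, 0.0, None) if clip_at_zero else out
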