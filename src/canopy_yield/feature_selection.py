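"""Feature screening: Pearson, MIC, random-forest and RFE scores.

Each method produces a raw score per feature against yield; scores are
min-max normalised to a [0, 1] "screening probability" so methods are
comparable, and the top-k features are selected (k=6 within a family, or the
top-3 vegetation indices plus top-3 texture features in fusion mode).

MIC is computed by a quantile-grid approximation of the maximal information
coefficient: over all grid shapes (kx, ky) with kx·ky ≤ n^alpha, both
variables are binned at empirical quantiles and the normalised mutual
information I/log2(min(kx, ky)) is maximised. Being rank-based, the score is
exactly invariant under strictly monotone transforms and attains 1 for any
monotone functional relationship.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import StandardScaler

from .io_core import FeatureTable

METHODS = ("P", "MIC", "RF", "RFE")


@dataclasses.dataclass
class SelectionResult:
    """Scores, screening probabilities and the selected feature set."""

    method: str
    raw_scores: pd.Series
    probabilities: pd.Series
    selected: list[str]
    params: dict
    seed: int | None = None


def score_pearson(table: FeatureTable) -> pd.Series:
    """|Pearson r| of each feature with yield; constant features score 0."""
    if len(table) < 3:
        raise ValueError("need at least 3 samples for correlation")
    y = table.y.to_numpy()
    if np.std(y) == 0:
        raise ValueError("target is constant")
    out = {}
    for c in table.feature_names:
        x = table.data[c].to_numpy()
        ok = np.isfinite(x)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            out[c] = 0.0
        else:
            out[c] = abs(float(stats.pearsonr(x[ok], y[ok])[0]))
    return pd.Series(out)


def _mic_xy(x: np.ndarray, y: np.ndarray, alpha: float, c: float) -> float:
    n = len(x)
    B = max(n ** alpha, 4.0)
    max_k = max(int(min(B / 2, c)), 2)
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    best = 0.0
    for kx in range(2, max_k + 1):
        for ky in range(2, max_k + 1):
            if kx * ky > B:
                break
            bx = np.minimum((rx - 1) * kx // n, kx - 1).astype(int)
            by = np.minimum((ry - 1) * ky // n, ky - 1).astype(int)
            joint = np.bincount(bx * ky + by, minlength=kx * ky).reshape(kx, ky)
            p = joint / n
            px = p.sum(axis=1, keepdims=True)
            py = p.sum(axis=0, keepdims=True)
            nz = p > 0
            mi = float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())
            best = max(best, mi / np.log2(min(kx, ky)))
    return min(best, 1.0)


def score_mic(table: FeatureTable, alpha: float = 0.6, c: float = 15) -> pd.Series:
    """Maximal-information-coefficient score of each feature vs yield."""
    if len(table) < 4:
        raise ValueError("need at least 4 samples for MIC")
    y = table.y.to_numpy()
    out = {}
    for col in table.feature_names:
        x = table.data[col].to_numpy()
        ok = np.isfinite(x)
        if ok.sum() < 4 or np.std(x[ok]) == 0:
            out[col] = 0.0
        else:
            out[col] = _mic_xy(x[ok], y[ok], alpha, c)
    return pd.Series(out)


def score_rf(table: FeatureTable, n_trees: int = 500, seed: int = 42) -> pd.Series:
    """Impurity-decrease importances from a seeded random forest (sum to 1)."""
    if len(table) < 10:
        raise ValueError("need at least 10 samples for a forest")
    y = table.y.to_numpy()
    if np.std(y) == 0:
        raise ValueError("target is constant")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(table.X.to_numpy(), y)
    return pd.Series(rf.feature_importances_, index=table.feature_names)


def score_rfe(table: FeatureTable, base=None, step: int = 1) -> pd.Series:
    """Inverse elimination rank from recursive feature elimination.

    The base estimator (default: ordinary linear regression on z-scored
    features) is refit each round and the lowest-|coefficient| feature is
    dropped; the last survivor gets the highest score.
    """
    k = len(table.feature_names)
    if len(table) < k + 1:
        raise ValueError(f"need at least {k + 1} samples for RFE over {k} features")
    X = StandardScaler().fit_transform(table.X.to_numpy())
    rfe = RFE(base or LinearRegression(), n_features_to_select=1, step=step)
    rfe.fit(X, table.y.to_numpy())
    # ranking_ is 1 for the survivor, k for the first eliminated
    score = k + 1 - rfe.ranking_.astype(float)
    return pd.Series(score, index=table.feature_names)


def normalize_scores(raw: pd.Series) -> pd.Series:
    """Min-max normalisation to [0, 1]; all-equal scores map to 1.0."""
    finite = raw[np.isfinite(raw)]
    if finite.empty:
        raise ValueError("no finite scores to normalise")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        return pd.Series(1.0, index=raw.index)
    return (raw - lo) / (hi - lo)


def normalize_and_select(raw_scores: pd.Series, k: int, *,
                         table: FeatureTable | None = None,
                         fusion: bool = False, method: str = "",
                         params: dict | None = None,
                         seed: int | None = None) -> SelectionResult:
    """Screening probabilities + the top-k feature set.

    In fusion mode (requires *table* for family tags), the top-k vegetation
    indices and top-k texture features are selected (k each). Ties break by
    column order; with all scores equal the selection falls back to column
    order.
    """
    probs = normalize_scores(raw_scores)
    finite = [c for c in raw_scores.index if np.isfinite(raw_scores[c])]

    def top(names: list[str], kk: int) -> list[str]:
        if len(names) < kk:
            raise ValueError(f"cannot select {kk} from {len(names)} scored features")
        order = {c: i for i, c in enumerate(raw_scores.index)}
        return sorted(names, key=lambda c: (-probs[c], order[c]))[:kk]

    if fusion:
        if table is None:
            raise ValueError("fusion selection needs the table for family tags")
        vi = [c for c in finite if table.families.get(c) == "vi"]
        tex = [c for c in finite if table.families.get(c) == "texture"]
        selected = top(vi, k) + top(tex, k)
    else:
        selected = top(finite, k)
    return SelectionResult(method=method, raw_scores=raw_scores,
                           probabilities=probs, selected=selected,
                           params=params or {}, seed=seed)


def run_selector(method: str, table: FeatureTable, k: int = 6, *,
                 fusion: bool = False, seed: int = 42,
                 mic_alpha: float = 0.6, mic_c: float = 15,
                 rf_trees: int = 500) -> SelectionResult:
    """Score with one of the four methods and select the feature set."""
    if method == "P":
        raw, params = score_pearson(table), {}
    elif method == "MIC":
        raw = score_mic(table, alpha=mic_alpha, c=mic_c)
        params = {"alpha": mic_alpha, "c": mic_c}
    elif method == "RF":
        raw = score_rf(table, n_trees=rf_trees, seed=seed)
        params = {"n_trees": rf_trees}
    elif method == "RFE":
        raw, params = score_rfe(table), {"base": "linear", "step": 1}
    else:
        raise ValueError(f"unknown selection method {method!r}; use {METHODS}")
    return normalize_and_select(raw, k, table=table, fusion=fusion,
                                method=method, params=params, seed=seed)
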