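"""LAI estimation models: exhaustive best-subset regression and epsilon-SVR.

Best-subset ("optimal subset") regression fits an ordinary-least-squares
model to every nonempty subset of the candidate features (2^n - 1 models
for n candidates) and keeps the subset maximizing the adjusted R²,

    Adj.R² = 1 - (RSS / (n - k - 1)) / (TSS / (n - 1)),

where k is the subset size.  The support-vector alternative is an
epsilon-SVR with RBF kernel on standardized features, hyperparameters
chosen by grid search with internal cross-validation on the training
partition only.  Data are split 75/25 into modeling and validation sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

MAX_SUBSET_CANDIDATES = 15


@dataclass
class SplitSpec:
    """Random modeling/validation split (default 75% modeling)."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


def train_test_split(n_samples: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation index partition.

    Deterministic under the spec's seed; 48 samples at 0.75 give 36/12.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples to split")
    n_train = int(round(spec.train_fraction * n_samples))
    n_train = min(max(n_train, 1), n_samples - 1)
    perm = np.random.default_rng(spec.seed).permutation(n_samples)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def adjusted_r2(rss: float, tss: float, n: int, k: int) -> float:
    """Adjusted R² = 1 - (RSS/(n-k-1)) / (TSS/(n-1))."""
    if n <= k + 1:
        raise ValueError(f"n={n} leaves no residual degrees of freedom for k={k}")
    if tss <= 0:
        raise ValueError("TSS must be positive")
    return 1.0 - (rss / (n - k - 1)) / (tss / (n - 1))


@dataclass
class SubsetModel:
    """Best-subset OLS model: chosen labels, coefficients, and the full
    Adj.R² ranking of every evaluated subset."""

    feature_labels: list[str]
    intercept: float
    coefficients: np.ndarray
    adj_r2: float
    ranking: list[tuple[tuple[str, ...], float]]
    n_subsets_evaluated: int
    collinear_flagged: list[tuple[str, ...]] = field(default_factory=list)


def _ols(X: np.ndarray, y: np.ndarray):
    design = np.column_stack([np.ones(len(y)), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid), rank < design.shape[1]


def best_subset_regression(
    features, lai: np.ndarray, train_idx: np.ndarray | None = None
) -> SubsetModel:
    """Exhaustively fit all 2^n - 1 feature subsets; return the Adj.R² arg-max.

    Ties break toward the smaller subset, then lexicographic candidate
    order.  Collinear subsets are fitted by pseudo-inverse and flagged.
    ``features`` is a FeatureSelection or a label-keyed DataFrame.
    """
    values = features.values if hasattr(features, "features") else features
    if not isinstance(values, pd.DataFrame):
        raise TypeError("features must be a FeatureSelection or DataFrame")
    labels = list(values.columns)
    p = len(labels)
    if p == 0:
        raise ValueError("no candidate features")
    if p > MAX_SUBSET_CANDIDATES:
        raise ValueError(
            f"{p} candidates exceed the exhaustive-enumeration bound "
            f"({MAX_SUBSET_CANDIDATES})"
        )
    lai = np.asarray(lai, dtype=float)
    if train_idx is None:
        train_idx = np.arange(lai.size)
    X_all = values.to_numpy(dtype=float)[train_idx]
    y = lai[train_idx]
    n = y.size
    tss = float(((y - y.mean()) ** 2).sum())
    best = None  # (-adj, size, subset) ordering key
    ranking: list[tuple[tuple[str, ...], float]] = []
    flagged: list[tuple[str, ...]] = []
    n_eval = 0
    for size in range(1, p + 1):
        if n <= size + 1:
            break  # no residual degrees of freedom for larger subsets
        for subset in itertools.combinations(range(p), size):
            n_eval += 1
            beta, rss, collinear = _ols(X_all[:, subset], y)
            adj = adjusted_r2(rss, tss, n, size)
            names = tuple(labels[j] for j in subset)
            ranking.append((names, adj))
            if collinear:
                flagged.append(names)
            key = (-adj, size, subset)
            if best is None or key < best[0]:
                best = (key, subset, beta, adj)
    assert best is not None
    _, subset, beta, adj = best
    ranking.sort(key=lambda t: (-t[1], len(t[0]), t[0]))
    return SubsetModel(
        [labels[j] for j in subset], float(beta[0]), beta[1:].copy(), adj,
        ranking, n_eval, flagged,
    )


@dataclass
class SvrGrid:
    """RBF-SVR hyperparameter grid searched by internal cross-validation."""

    C: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_factors: tuple[float, ...] = (0.1, 1.0, 10.0)
    epsilon: tuple[float, ...] = (0.01, 0.1)
    cv_folds: int = 5


@dataclass
class SvrModel:
    feature_labels: list[str]
    pipeline: Pipeline
    best_params: dict
    cv_r2: float


def fit_svr(
    features, lai: np.ndarray, train_idx: np.ndarray | None = None,
    grid: SvrGrid | None = None, seed: int = 0,
) -> SvrModel:
    """Epsilon-SVR (RBF) on standardized features, grid-searched by k-fold
    CV on the training partition only.  Zero-variance features are dropped
    with a warning."""
    values = features.values if hasattr(features, "features") else features
    grid = grid or SvrGrid()
    lai = np.asarray(lai, dtype=float)
    if train_idx is None:
        train_idx = np.arange(lai.size)
    X = values.iloc[train_idx]
    y = lai[train_idx]
    keep = [c for c in X.columns if X[c].std() > 0]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    if not keep:
        raise ValueError("all candidate features have zero training variance")
    X = X[keep]
    # After standardization feature variance is 1, so the 'scale' heuristic
    # gamma = 1/(p * var) reduces to 1/p; the grid scans around it.
    base_gamma = 1.0 / len(keep)
    param_grid = {
        "svr__C": list(grid.C),
        "svr__gamma": [f * base_gamma for f in grid.gamma_factors],
        "svr__epsilon": list(grid.epsilon),
    }
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    cv = KFold(n_splits=min(grid.cv_folds, len(y)), shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, param_grid, cv=cv, scoring="r2", n_jobs=1)
    search.fit(X.to_numpy(dtype=float), y)
    return SvrModel(keep, search.best_estimator_, dict(search.best_params_),
                    float(search.best_score_))


def predict(model: SubsetModel | SvrModel, features) -> np.ndarray:
    """Estimate LAI for feature vectors keyed by label (column order free)."""
    values = features.values if hasattr(features, "features") else features
    missing = [c for c in model.feature_labels if c not in values.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    X = values[model.feature_labels].to_numpy(dtype=float)
    if isinstance(model, SubsetModel):
        return model.intercept + X @ model.coefficients
    return model.pipeline.predict(X)
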