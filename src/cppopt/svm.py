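"""RBF-kernel soft-margin classifiers with the exponential (C, gamma) grid.

Hyperparameters are tuned the classical way: base values C = 1 and
gamma = 1/d (d = number of input variables) are scaled by the exponentially
growing factors 1/32 ... 32, giving an 11 x 11 = 121-cell grid evaluated by
stratified tenfold cross-validation on pooled accuracy.  Feature
standardization is refit inside every training fold so the held-out fold
never leaks into the scaler.  The solver behind each cell is scikit-learn's
SVC; the grid search, fold assignment, tie-breaking and the persisted
decision function are this module's own.

Fold assignment is canonical: rows are ordered by content (labels, then
feature values) before the seeded shuffle, so the selected grid cell does
not depend on the order in which rows happen to arrive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io import FormatError, ValidationError

__all__ = [
    "SvmHyperparams",
    "TrainedModel",
    "GridSearchResult",
    "grid_search_train",
    "predict",
    "save_model",
    "load_model",
    "train_management_models",
]

GRID_FACTORS = (1 / 32, 1 / 16, 1 / 8, 1 / 4, 1 / 2, 1, 2, 4, 8, 16, 32)
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SvmHyperparams:
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.gamma > 0):
            raise ValidationError("C and gamma must both be positive")


@dataclass
class GridSearchResult:
    factors: tuple[float, ...]
    c_values: np.ndarray
    gamma_values: np.ndarray
    cv_accuracy: np.ndarray          # shape (len(C), len(gamma))
    best: SvmHyperparams
    best_accuracy: float
    n_folds: int
    folds: np.ndarray                # fold index per training row


@dataclass
class TrainedModel:
    """A fitted RBF SVM plus the training-set standardization.

    ``decision_function`` reproduces the SVM decision value from the stored
    support vectors: f(x) = sum_j alpha_j K(sv_j, z(x)) + b with
    K(u, v) = exp(-gamma ||u - v||^2) and z the *training* z-score transform.
    Labels are {0, 1}; positive decision values map to class 1.
    """

    feature_names: list[str]             # retained (non-constant) features
    feature_names_in: list[str]          # all features seen at fit time
    dropped_features: list[str]
    center: np.ndarray
    scale: np.ndarray
    support_vectors: np.ndarray          # in standardized space
    dual_coef: np.ndarray
    intercept: float
    hyperparams: SvmHyperparams
    schema_version: int = SCHEMA_VERSION

    def _design(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            unknown = set(X.columns) - set(self.feature_names_in)
            if unknown:
                raise ValidationError(f"unknown feature columns: {sorted(unknown)}")
            missing = set(self.feature_names) - set(X.columns)
            if missing:
                raise ValidationError(f"missing feature columns: {sorted(missing)}")
            X = X[self.feature_names].to_numpy(float)
        else:
            X = np.asarray(X, float)
            if X.shape[1] != len(self.feature_names):
                raise ValidationError(
                    f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        return (X - self.center) / self.scale

    def decision_function(self, X) -> np.ndarray:
        Z = self._design(X)
        d2 = (np.sum(Z ** 2, axis=1)[:, None]
              + np.sum(self.support_vectors ** 2, axis=1)[None, :]
              - 2.0 * Z @ self.support_vectors.T)
        K = np.exp(-self.hyperparams.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def _canonical_folds(X: np.ndarray, y: np.ndarray, n_folds: int,
                     seed: int) -> np.ndarray:
    """Stratified fold labels that are invariant to row permutation."""
    order = np.lexsort(tuple(X.T) + (y,))
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = order[y[order] == cls]
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def _prepare(X, y):
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, float)
        names = [f"x{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y).astype(int)
    if Xv.ndim != 2 or Xv.shape[1] == 0:
        raise ValidationError("feature matrix must be 2-D with at least one column")
    if not np.all(np.isfinite(Xv)):
        raise ValidationError("feature matrix contains non-finite values")
    if Xv.shape[0] != y.size:
        raise ValidationError("X and y length mismatch")
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary {0, 1}")
    if np.unique(y).size < 2:
        raise ValidationError("both classes must be present for training")
    return Xv, y, names


def grid_search_train(X, y, seed: int = 0, *, n_folds: int = 10,
                      factors: tuple[float, ...] = GRID_FACTORS,
                      class_weight: str | dict | None = None,
                      ) -> tuple[TrainedModel, GridSearchResult]:
    """Tune (C, gamma) on the exponential grid and refit on all rows.

    Pooled tenfold-CV accuracy decides the winning cell; ties break toward
    the smallest C, then the smallest gamma.  The returned model is refit on
    the full data set at the winning cell with full-data standardization.
    """
    Xv, y, names = _prepare(X, y)
    if y.size < 20:
        raise ValidationError("need at least 20 rows for grid-search training")

    keep = np.std(Xv, axis=0) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    kept_names = [n for n, k in zip(names, keep) if k]
    if not kept_names:
        raise ValidationError("all features are constant")
    Xk = Xv[:, keep]

    min_class = int(np.bincount(y).min())
    if min_class < n_folds:
        warnings.warn(
            f"minority class has {min_class} rows; reducing folds from {n_folds}",
            stacklevel=2)
        n_folds = max(2, min_class)
    folds = _canonical_folds(Xk, y, n_folds, seed)

    base_gamma = 1.0 / Xk.shape[1]
    c_values = np.array([f * 1.0 for f in factors])
    g_values = np.array([f * base_gamma for f in factors])

    # pre-split standardization statistics per fold (train-fold only)
    fold_stats = []
    for k in range(n_folds):
        tr = folds != k
        mu = Xk[tr].mean(axis=0)
        sd = Xk[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        fold_stats.append((tr, mu, sd))

    acc = np.zeros((len(c_values), len(g_values)))
    for i, C in enumerate(c_values):
        for j, g in enumerate(g_values):
            pred = np.empty(y.size, dtype=int)
            for k, (tr, mu, sd) in enumerate(fold_stats):
                te = ~tr
                clf = SVC(C=C, gamma=g, kernel="rbf", class_weight=class_weight)
                clf.fit((Xk[tr] - mu) / sd, y[tr])
                pred[te] = clf.predict((Xk[te] - mu) / sd)
            acc[i, j] = float(np.mean(pred == y))

    best_i = best_j = 0
    best_acc = -np.inf
    for i in range(len(c_values)):          # ascending C, then ascending gamma
        for j in range(len(g_values)):
            if acc[i, j] > best_acc + 1e-12:
                best_acc, best_i, best_j = acc[i, j], i, j
    best = SvmHyperparams(C=float(c_values[best_i]), gamma=float(g_values[best_j]))

    mu = Xk.mean(axis=0)
    sd = Xk.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    clf = SVC(C=best.C, gamma=best.gamma, kernel="rbf", class_weight=class_weight)
    clf.fit((Xk - mu) / sd, y)

    model = TrainedModel(
        feature_names=kept_names,
        feature_names_in=names,
        dropped_features=dropped,
        center=mu,
        scale=sd,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        hyperparams=best,
    )
    result = GridSearchResult(
        factors=tuple(factors),
        c_values=c_values,
        gamma_values=g_values,
        cv_accuracy=acc,
        best=best,
        best_accuracy=float(best_acc),
        n_folds=n_folds,
        folds=folds,
    )
    return model, result


def predict(model: TrainedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels {0,1} and raw decision values (for ROC analysis)."""
    decision = model.decision_function(X)
    return (decision > 0).astype(int), decision


def save_model(model: TrainedModel, path) -> None:
    payload = {
        "schema_version": model.schema_version,
        "feature_names": model.feature_names,
        "feature_names_in": model.feature_names_in,
        "dropped_features": model.dropped_features,
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "C": model.hyperparams.C,
        "gamma": model.hyperparams.gamma,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(f"model schema version {version!r}, expected {SCHEMA_VERSION}")
    return TrainedModel(
        feature_names=list(payload["feature_names"]),
        feature_names_in=list(payload["feature_names_in"]),
        dropped_features=list(payload["dropped_features"]),
        center=np.asarray(payload["center"], float),
        scale=np.asarray(payload["scale"], float),
        support_vectors=np.asarray(payload["support_vectors"], float),
        dual_coef=np.asarray(payload["dual_coef"], float),
        intercept=float(payload["intercept"]),
        hyperparams=SvmHyperparams(C=float(payload["C"]), gamma=float(payload["gamma"])),
        schema_version=int(version),
    )


def train_management_models(X: pd.DataFrame, flags: pd.DataFrame, seed: int = 0,
                            ) -> dict[str, tuple[TrainedModel, GridSearchResult] | None]:
    """Five independent binary SVMs, one per clinical situation flag.

    ``flags`` holds one boolean column per situation (cpp_guided, abp_guided,
    icp_guided, intact, critical).  Situations with a single class in the
    training set cannot be trained and map to None.
    """
    models: dict[str, tuple[TrainedModel, GridSearchResult] | None] = {}
    for name in flags.columns:
        y = flags[name].astype(int).to_numpy()
        if np.unique(y).size < 2 or y.size < 20:
            models[name] = None
            continue
        models[name] = grid_search_train(X, y, seed=seed)
    return models
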