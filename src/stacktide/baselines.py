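"""The 13-algorithm baseline panel: registry, grid-search tuning, fitting.

Crossing the 13 algorithms with the 12 feature encodings yields 156
baseline classifiers. Nine algorithms are tuned by grid search under
stratified 10-fold cross-validation (criterion: mean CV accuracy; ties go
to the first point in documented grid order); DT, KNN, NB and PLS run at
fixed settings. All baselines of a run share one stratified fold partition
so the out-of-fold meta-features are leakage-consistent across the grid.

Margin-output models (PLS regression on 0/1 labels and the two SVMs) do not
emit class probabilities natively; their decision values pass through a
one-dimensional logistic squashing fitted on the training decision values,
falling back to min-max scaling when the logistic fit is degenerate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

ALGORITHM_IDS = (
    "ADA", "DT", "ET", "KNN", "LGBM", "LR", "MLP",
    "NB", "PLS", "RF", "SVMLN", "SVMRBF", "XGB",
)
TUNABLE_IDS = frozenset({"ADA", "ET", "LGBM", "LR", "MLP", "RF", "SVMLN", "SVMRBF", "XGB"})


def derive_seed(*parts) -> int:
    """Stable sub-seed from a run seed plus stage/pair identifiers (< 2^31)."""
    key = "|".join(str(p) for p in parts).encode()
    return zlib.crc32(key) % (2 ** 31)


class MarginSquashClassifier(BaseEstimator, ClassifierMixin):
    """Wraps a margin/regression estimator to expose predict_proba.

    Fits the base estimator, computes decision values on the training data,
    then fits a univariate logistic model mapping decision value to class
    probability. If the logistic fit cannot be performed (constant decision
    values) the decision values are min-max scaled into [0, 1] instead.
    """

    def __init__(self, base, seed: int = 0):
        self.base = base
        self.seed = seed

    def _decision(self, X) -> np.ndarray:
        if hasattr(self.base_, "decision_function"):
            return np.asarray(self.base_.decision_function(X), dtype=float).ravel()
        return np.asarray(self.base_.predict(X), dtype=float).ravel()

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.base_ = clone(self.base)
        self.base_.fit(X, y)
        d = self._decision(X)
        self._dmin, self._dmax = float(d.min()), float(d.max())
        if self._dmax - self._dmin < 1e-12:
            self._squash = None
        else:
            self._squash = LogisticRegression(C=1e3, random_state=self.seed)
            self._squash.fit(d.reshape(-1, 1), y)
            if len(self._squash.classes_) < 2:  # pragma: no cover
                self._squash = None
        return self

    def predict_proba(self, X):
        d = self._decision(X)
        if self._squash is not None:
            return self._squash.predict_proba(d.reshape(-1, 1))
        span = max(self._dmax - self._dmin, 1e-12)
        p1 = np.clip((d - self._dmin) / span, 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass(frozen=True)
class AlgorithmSpec:
    """One machine-learning algorithm: identity, tunability and search grid."""

    id: str
    tunable: bool
    grid: dict = field(default_factory=dict, compare=False)
    defaults: dict = field(default_factory=dict, compare=False)

    def build(self, params: dict | None = None, seed: int = 0):
        return _build_estimator(self.id, {**self.defaults, **(params or {})}, seed)


def _build_estimator(alg_id: str, params: dict, seed: int):
    p = dict(params)
    if alg_id == "ADA":
        return AdaBoostClassifier(random_state=seed, **p)
    if alg_id == "DT":
        return DecisionTreeClassifier(random_state=seed, **p)
    if alg_id == "ET":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **p)
    if alg_id == "KNN":
        return KNeighborsClassifier(n_jobs=1, **p)
    if alg_id == "LGBM":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                              deterministic=True, force_row_wise=True, **p)
    if alg_id == "LR":
        return LogisticRegression(random_state=seed, max_iter=2000, **p)
    if alg_id == "MLP":
        return MLPClassifier(random_state=seed, max_iter=300, **p)
    if alg_id == "NB":
        return GaussianNB(**p)
    if alg_id == "PLS":
        n_comp = p.pop("n_components", 2)
        return MarginSquashClassifier(PLSRegression(n_components=n_comp, **p), seed=seed)
    if alg_id == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
    if alg_id == "SVMLN":
        return MarginSquashClassifier(SVC(kernel="linear", random_state=seed, **p), seed=seed)
    if alg_id == "SVMRBF":
        return MarginSquashClassifier(SVC(kernel="rbf", random_state=seed, **p), seed=seed)
    if alg_id == "XGB":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss", **p)
    raise KeyError(f"unknown algorithm id {alg_id!r}")


_TREE_GRID = {"n_estimators": [20, 50, 100, 200, 500]}
_GRIDS: dict[str, dict] = {
    "ADA": {"n_estimators": [20, 50, 100, 200]},
    "ET": _TREE_GRID,
    "LGBM": {"n_estimators": [20, 50, 100, 200]},
    "LR": {"C": [0.01, 0.1, 1.0, 10.0]},
    "MLP": {"hidden_layer_sizes": [(10,), (50,), (100,)]},
    "RF": _TREE_GRID,
    "SVMLN": {"C": [2.0 ** e for e in range(-5, 6, 2)]},
    "SVMRBF": {"C": [2.0 ** e for e in range(-5, 6, 2)]},
    "XGB": {"n_estimators": [20, 50, 100, 200]},
}

# fast fixed settings used when tuning is skipped
_DEFAULTS: dict[str, dict] = {
    "ADA": {"n_estimators": 50},
    "ET": {"n_estimators": 50},
    "LGBM": {"n_estimators": 50},
    "MLP": {"hidden_layer_sizes": (32,)},
    "RF": {"n_estimators": 50},
    "XGB": {"n_estimators": 50},
    "PLS": {"n_components": 2},
}


def algorithm_registry() -> list[AlgorithmSpec]:
    """The 13 algorithm specs in canonical (alphabetical) order."""
    return [
        AlgorithmSpec(id=a, tunable=a in TUNABLE_IDS,
                      grid=_GRIDS.get(a, {}), defaults=_DEFAULTS.get(a, {}))
        for a in ALGORITHM_IDS
    ]


def make_folds(y, k: int = 10, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """One stratified k-fold partition shared by the whole run."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; needs >= k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _grid_points(grid: dict) -> list[dict]:
    points = [{}]
    for key, values in grid.items():  # documented order: insertion order
        points = [{**pt, key: v} for pt in points for v in values]
    return points


def tune_baseline(X, y, spec: AlgorithmSpec, folds, seed: int = 0) -> dict:
    """Grid search maximizing mean CV accuracy over the shared folds.

    Ties break toward the earlier point in grid order, so the result is
    deterministic for a fixed seed/fold partition.
    """
    if not spec.tunable:
        raise ValueError(f"{spec.id} is not a tunable algorithm")
    X = np.asarray(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for tuning")
    best_params, best_acc = None, -np.inf
    for params in _grid_points(spec.grid):
        correct = 0
        for tr, te in folds:
            est = spec.build(params, seed=seed)
            est.fit(X[tr], y[tr])
            correct += int((np.asarray(est.predict(X[te])) == y[te]).sum())
        acc = correct / len(y)
        if acc > best_acc:
            best_acc, best_params = acc, params
    return best_params


@dataclass
class TrainedBaseline:
    """A fitted (algorithm, encoding) pair: full-data model plus fold models."""

    algorithm: str
    encoding: str
    chosen_params: dict
    full_model: object
    fold_models: list
    folds: list

    @property
    def label(self) -> str:
        return f"{self.algorithm}-{self.encoding}"

    def predict_proba(self, X_new) -> np.ndarray:
        return predict_proba(self, X_new)


def fit_baseline(X, y, spec: AlgorithmSpec, params: dict | None, folds,
                 seed: int = 0, encoding: str = "") -> TrainedBaseline:
    """Fit the full-data model and one model per CV fold.

    The fold models feed out-of-fold probabilistic features; the full model
    serves test-time prediction. A fold whose training part is single-class
    is rejected with advice to enlarge the data.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} labels")
    if len(folds) > len(y):
        raise ValueError(f"k={len(folds)} folds exceed n={len(y)} samples")
    fold_models = []
    for fi, (tr, _te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                f"fold {fi} is single-class; provide more data or fewer folds")
        est = spec.build(params, seed=seed)
        est.fit(X[tr], y[tr])
        fold_models.append(est)
    full = spec.build(params, seed=seed)
    full.fit(X, y)
    return TrainedBaseline(
        algorithm=spec.id, encoding=encoding,
        chosen_params=dict(params or {}),
        full_model=full, fold_models=fold_models,
        folds=[(np.asarray(tr), np.asarray(te)) for tr, te in folds],
    )


def predict_proba(model: TrainedBaseline, X_new) -> np.ndarray:
    """Positive-class probability of the full-data model, one per row."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    n_expected = getattr(model.full_model, "n_features_in_", None)
    if n_expected is None and hasattr(model.full_model, "base_"):
        n_expected = getattr(model.full_model.base_, "n_features_in_", None)
    if n_expected is not None and X_new.shape[1] != n_expected:
        raise ValueError(
            f"{model.label}: expected {n_expected} features, got {X_new.shape[1]}")
    proba = model.full_model.predict_proba(X_new)
    pos_col = int(np.flatnonzero(model.full_model.classes_ == 1)[0]) \
        if hasattr(model.full_model, "classes_") else 1
    return np.clip(np.asarray(proba)[:, pos_col], 0.0, 1.0)
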