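"""Binary-classification metrics and evaluation harness.

Conventions
-----------
ACC = (TP + TN) / n
Sn  = TP / (TP + FN)          (sensitivity, recall on the positive class)
Sp  = TN / (TN + FP)          (specificity)
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
      when any factor of the denominator vanishes.
AUC is computed as the rank statistic: the probability that a random
positive outscores a random negative, ties counted 1/2 (exact and
tie-robust, no thresholded ROC grid).

Cross-validation metrics are pooled: out-of-fold predictions of all folds
are concatenated and one confusion matrix is computed, which keeps MCC
well-defined even with small folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

from stacktide.sequence_io import PeptideDataset


@dataclass
class MetricsReport:
    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    Sn: float
    Sp: float
    MCC: float
    AUC: float | None = None
    context: str = "cross_validation"

    def to_dict(self) -> dict:
        return asdict(self)


def _check_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return arr.astype(int)


def confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """Exact confusion counts (TP, TN, FP, FN) for binary labels."""
    yt = _check_binary(y_true, "y_true")
    yp = _check_binary(y_pred, "y_pred")
    if len(yt) != len(yp):
        raise ValueError(f"length mismatch: {len(yt)} true vs {len(yp)} predicted")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return tp, tn, fp, fn


def metrics(TP: int, TN: int, FP: int, FN: int, auc_value: float | None = None,
            context: str = "cross_validation") -> MetricsReport:
    """Evaluate ACC / Sn / Sp / MCC from confusion counts."""
    if min(TP, TN, FP, FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = TP + TN + FP + FN
    if n == 0:
        raise ValueError("all confusion counts are zero")
    acc = (TP + TN) / n
    sn = TP / (TP + FN) if TP + FN else 0.0
    sp = TN / (TN + FP) if TN + FP else 0.0
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = 0.0 if denom == 0 else (TP * TN - FP * FN) / np.sqrt(denom)
    return MetricsReport(TP=TP, TN=TN, FP=FP, FN=FN, ACC=acc, Sn=sn, Sp=sp,
                         MCC=float(mcc), AUC=auc_value, context=context)


def auc(y_true, scores) -> float | None:
    """Rank-statistic AUC (Mann-Whitney): P(score+ > score-) + P(tie)/2.

    Returns None with a warning when only one class is present.
    """
    yt = _check_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    if len(yt) != len(s):
        raise ValueError("y_true and scores length mismatch")
    n_pos = int(yt.sum())
    n_neg = len(yt) - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined: only one class present", stacklevel=2)
        return None
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_predictions(y_true, scores, threshold: float = 0.5,
                         context: str = "independent_test") -> MetricsReport:
    """Full report from continuous scores: threshold then count, plus AUC."""
    s = np.asarray(scores, dtype=float)
    y_pred = (s >= threshold).astype(int)
    rep = metrics(*confusion(y_true, y_pred), context=context)
    rep.AUC = auc(y_true, s)
    return rep


def cross_validate(model_factory, ds: PeptideDataset, k: int = 10, seed: int = 0,
                   threshold: float = 0.5) -> MetricsReport:
    """Stratified k-fold CV of an end-to-end peptide pipeline.

    ``model_factory()`` must return an object with ``fit(train_ds)`` and
    ``predict_scores(test_ds) -> array``; metrics are computed once from the
    pooled out-of-fold scores.
    """
    from stacktide.baselines import make_folds  # local to avoid import cycle

    y = ds.y
    folds = make_folds(y, k=k, seed=seed)
    scores = np.empty(len(ds), dtype=float)
    for tr, te in folds:
        model = model_factory()
        model.fit(ds.subset(tr))
        scores[te] = np.asarray(model.predict_scores(ds.subset(te)), dtype=float)
    return evaluate_predictions(y, scores, threshold=threshold,
                                context="cross_validation")


def cross_validate_matrix(estimator_factory, X, y, k: int = 10, seed: int = 0,
                          threshold: float = 0.5) -> MetricsReport:
    """Pooled stratified CV for a plain (X, y) problem with an sklearn-style
    probabilistic estimator factory."""
    from stacktide.baselines import make_folds

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = make_folds(y, k=k, seed=seed)
    scores = np.empty(len(y), dtype=float)
    for tr, te in folds:
        est = estimator_factory()
        est.fit(X[tr], y[tr])
        proba = est.predict_proba(X[te])
        pos = int(np.flatnonzero(est.classes_ == 1)[0])
        scores[te] = proba[:, pos]
    return evaluate_predictions(y, scores, threshold=threshold,
                                context="cross_validation")


def feature_importance(model, apf, y, n_repeats: int = 5, seed: int = 0):
    """Rank the selected probabilistic features of a fitted stacked model.

    Primary attribution is the meta-forest's impurity-based importance
    (tree-path additive attribution); a permutation alternative measures the
    drop in training MCC when a column is shuffled. The sign is the
    direction of the column's point-biserial association with the positive
    class. Returns a list of (column label, importance, sign) sorted by
    importance, length = number of selected columns.
    """
    meta = getattr(model, "meta", model)
    if not hasattr(meta, "feature_importances_"):
        raise ValueError("model is not fitted or has no tree-based meta-classifier")
    labels = list(model.selection.selected_columns)
    values = getattr(apf, "values", apf)
    X = np.asarray(values, dtype=float)
    if X.shape[1] != len(labels):
        X = apf.select(labels)  # full-width matrix: restrict to selection
    y = np.asarray(y, dtype=int)
    importances = np.asarray(meta.feature_importances_, dtype=float)
    signs = []
    for j in range(X.shape[1]):
        col = X[:, j]
        r = np.corrcoef(col, y)[0, 1] if col.std() > 0 else 0.0
        signs.append(1 if r >= 0 else -1)
    ranked = sorted(zip(labels, importances, signs), key=lambda t: -t[1])
    return [(l, float(v), s) for l, v, s in ranked]


def permutation_importance_mcc(meta, X, y, n_repeats: int = 5, seed: int = 0) -> np.ndarray:
    """MCC drop when each column is permuted; averaged over repeats."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    base = metrics(*confusion(y, meta.predict(X))).MCC
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[j] += base - metrics(*confusion(y, meta.predict(Xp))).MCC
    return drops / n_repeats
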