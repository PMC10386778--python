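"""The stacked predictor and the flat ensemble baselines it is compared to.

The stacked model trains an extremely-randomized-trees meta-classifier on
the selected out-of-fold probabilistic feature columns; at prediction time
a peptide is encoded by all twelve schemes, scored by every baseline's
full-training model, the selected probability columns are extracted, and
the meta-classifier produces the final score. The average-score and
majority-vote ensembles consume the identical probabilistic feature rows,
so any performance difference is attributable to the combination strategy
alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from stacktide.baselines import TrainedBaseline, derive_seed
from stacktide.ga_sar import SelectionResult
from stacktide.meta_features import ProbFeatureMatrix, build_apf_test
from stacktide.sequence_io import PeptideDataset

DEFAULT_THRESHOLD = 0.5


@dataclass
class StackedModel:
    """Frozen baselines + selected columns + fitted meta-classifier."""

    baselines: list[TrainedBaseline]
    selection: SelectionResult
    meta: ExtraTreesClassifier
    threshold: float = DEFAULT_THRESHOLD
    algorithms: list | None = None  # registries the baselines were built from
    encoders: list | None = None


def fit_stack(apf_train: ProbFeatureMatrix, y, selection: SelectionResult,
              baselines: list[TrainedBaseline], seed: int = 0,
              threshold: float = DEFAULT_THRESHOLD,
              algorithms=None, encoders=None) -> StackedModel:
    """Fit the meta-classifier on the selected out-of-fold columns."""
    if apf_train.origin != "out_of_fold":
        raise ValueError("meta-classifier must be trained on out-of-fold features")
    if not selection.selected_columns:
        raise ValueError("selection is empty")
    X = apf_train.select(selection.selected_columns)  # KeyError on unknown columns
    meta = ExtraTreesClassifier(
        n_estimators=selection.n_estimators, n_jobs=1,
        random_state=derive_seed("meta", seed),
    )
    meta.fit(X, np.asarray(y, dtype=int))
    return StackedModel(baselines=baselines, selection=selection, meta=meta,
                        threshold=threshold, algorithms=algorithms, encoders=encoders)


def predict_stack_apf(model: StackedModel, apf: ProbFeatureMatrix) -> np.ndarray:
    """Meta-classifier scores for rows of an already-built feature matrix."""
    X = apf.select(model.selection.selected_columns)
    proba = model.meta.predict_proba(X)
    pos = int(np.flatnonzero(model.meta.classes_ == 1)[0])
    return proba[:, pos]


def predict_stack(model: StackedModel, peptides: PeptideDataset):
    """Score new peptides end-to-end: encode -> baseline probabilities ->
    selected columns -> meta probability. Returns (scores, labels)."""
    apf = build_apf_test(peptides, model.baselines,
                         algorithms=model.algorithms, encoders=model.encoders)
    scores = predict_stack_apf(model, apf)
    labels = (scores >= model.threshold).astype(int)
    return scores, labels


def average_ensemble(apf_row) -> float:
    """Average-score ensemble: the arithmetic mean of all baseline scores."""
    row = np.asarray(apf_row, dtype=float)
    if row.ndim != 1:
        raise ValueError("expects a single probabilistic feature row")
    return float(row.mean())


def majority_vote(apf_row, vote_threshold: float = 0.5) -> int:
    """Majority-vote ensemble over baseline scores.

    Each baseline votes positive when its score >= vote_threshold; the
    ensemble is positive when positive votes exceed half the panel. An
    exact tie (even panel split) is broken by the mean score >= 0.5.
    """
    row = np.asarray(apf_row, dtype=float)
    if row.ndim != 1:
        raise ValueError("expects a single probabilistic feature row")
    votes = int((row >= vote_threshold).sum())
    half = len(row) / 2
    if votes > half:
        return 1
    if votes < half:
        return 0
    return int(row.mean() >= 0.5)


def average_scores(apf: ProbFeatureMatrix) -> np.ndarray:
    return apf.values.mean(axis=1)


def majority_labels(apf: ProbFeatureMatrix, vote_threshold: float = 0.5) -> np.ndarray:
    return np.array([majority_vote(r, vote_threshold) for r in apf.values], dtype=int)
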