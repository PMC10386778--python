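"""Probabilistic meta-features: the per-peptide vector of baseline outputs.

Every (algorithm, encoding) baseline contributes one probability column, so
the full panel produces a 156-dimensional vector per peptide. For training
data each entry is the strictly out-of-fold probability — the prediction of
the fold model whose held-out fold contains the sample — which is the
leakage-safe input for the stacked meta-classifier. For test data each
entry comes from the baseline's full-training refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stacktide.baselines import TrainedBaseline, algorithm_registry
from stacktide.encoders import EncoderSpec, encode_dataset, encoder_registry
from stacktide.sequence_io import PeptideDataset


@dataclass
class ProbFeatureMatrix:
    """n_samples x n_pairs matrix of baseline probabilities in [0, 1].

    Column order is fixed: algorithms in canonical order, each crossed with
    the encoders in canonical order; labels read "<algorithm>-<encoding>".
    origin records whether values are out-of-fold (training) or full-model
    refits (test-time).
    """

    values: np.ndarray
    columns: list[str]
    origin: str  # {"out_of_fold", "refit_full"}

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column label count does not match matrix width")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("probabilistic features must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def select(self, labels: list[str]) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.columns)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise KeyError(f"unknown probabilistic feature column(s): {missing}")
        return self.values[:, [index[l] for l in labels]]

    def to_frame(self, row_ids=None) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns, index=row_ids)

    def to_csv(self, path, row_ids=None) -> None:
        self.to_frame(row_ids).to_csv(path, index=row_ids is not None)


def expected_pairs(algorithms=None, encoders=None) -> list[tuple[str, str]]:
    algs = [a.id for a in (algorithms or algorithm_registry())]
    encs = [e.name for e in (encoders or encoder_registry())]
    return [(a, e) for a in algs for e in encs]


def _ordered_baselines(baselines: list[TrainedBaseline], algorithms, encoders):
    by_pair = {(b.algorithm, b.encoding): b for b in baselines}
    pairs = expected_pairs(algorithms, encoders)
    missing = [p for p in pairs if p not in by_pair]
    if missing:
        raise ValueError(f"missing baseline model(s) for pairs: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    return [by_pair[p] for p in pairs], pairs


def _encodings_by_name(ds: PeptideDataset, encoders) -> dict[str, np.ndarray]:
    specs: list[EncoderSpec] = encoders or encoder_registry()
    return {spec.name: encode_dataset(ds, spec).values for spec in specs}


def build_apf_train(ds: PeptideDataset, baselines: list[TrainedBaseline],
                    algorithms=None, encoders=None) -> ProbFeatureMatrix:
    """Out-of-fold probabilistic feature matrix for the training set.

    Requires every baseline to share one fold partition over ``ds``; sample
    s's entry in column (i, j) comes from the fold model of baseline (i, j)
    that did not train on s.
    """
    ordered, pairs = _ordered_baselines(baselines, algorithms, encoders)
    feats = _encodings_by_name(ds, encoders)
    n = len(ds)
    values = np.empty((n, len(ordered)))
    for col, model in enumerate(ordered):
        X = feats[model.encoding]
        if X.shape[0] != n:
            raise ValueError("dataset size does not match the fold partition")
        col_vals = np.full(n, np.nan)
        for est, (tr, te) in zip(model.fold_models, model.folds):
            proba = est.predict_proba(X[te])
            pos = int(np.flatnonzero(est.classes_ == 1)[0])
            col_vals[te] = proba[:, pos]
        if np.isnan(col_vals).any():
            raise ValueError(f"{model.label}: folds do not cover all samples")
        values[:, col] = np.clip(col_vals, 0.0, 1.0)
    return ProbFeatureMatrix(values=values,
                             columns=[f"{a}-{e}" for a, e in pairs],
                             origin="out_of_fold")


def build_apf_test(test_ds: PeptideDataset, baselines: list[TrainedBaseline],
                   algorithms=None, encoders=None) -> ProbFeatureMatrix:
    """Probabilistic feature matrix for new data from full-training refits."""
    ordered, pairs = _ordered_baselines(baselines, algorithms, encoders)
    feats = _encodings_by_name(test_ds, encoders)
    values = np.empty((len(test_ds), len(ordered)))
    for col, model in enumerate(ordered):
        values[:, col] = model.predict_proba(feats[model.encoding])
    return ProbFeatureMatrix(values=values,
                             columns=[f"{a}-{e}" for a, e in pairs],
                             origin="refit_full")
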