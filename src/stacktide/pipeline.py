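"""End-to-end orchestration: encode -> baselines -> meta-features ->
selection -> stacked model, with a serializable run report.

One global run seed fans out deterministically to per-stage seeds (a CRC of
the stage name and the seed), so a run is reproducible from a single knob.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from stacktide import __version__
from stacktide.baselines import (
    AlgorithmSpec,
    TrainedBaseline,
    algorithm_registry,
    derive_seed,
    fit_baseline,
    make_folds,
    tune_baseline,
)
from stacktide.encoders import EncoderSpec, encode_dataset, encoder_registry, tables_fingerprint
from stacktide.evaluation import cross_validate_matrix, MetricsReport
from stacktide.ga_sar import GAConfig, run_ga, SelectionResult
from stacktide.meta_features import build_apf_train, ProbFeatureMatrix
from stacktide.sequence_io import PeptideDataset
from stacktide.stacking import StackedModel, fit_stack

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; embedded in every artifact it writes."""

    seed: int = 0
    k: int = 10
    tune: bool = False
    threshold: float = 0.5
    algorithm_ids: list[str] | None = None  # None = full 13-algorithm panel
    encoder_names: list[str] | None = None  # None = full 12-encoder panel
    ga: GAConfig | None = None  # None = defaults sized to the panel

    def algorithms(self) -> list[AlgorithmSpec]:
        regs = algorithm_registry()
        if self.algorithm_ids is None:
            return regs
        by_id = {a.id: a for a in regs}
        return [by_id[i] for i in self.algorithm_ids]

    def encoders(self) -> list[EncoderSpec]:
        regs = encoder_registry()
        if self.encoder_names is None:
            return regs
        by_name = {e.name: e for e in regs}
        return [by_name[n] for n in self.encoder_names]

    def to_dict(self) -> dict:
        ga = self.ga
        return {
            "seed": self.seed, "k": self.k, "tune": self.tune,
            "threshold": self.threshold,
            "algorithms": [a.id for a in self.algorithms()],
            "encoders": [e.name for e in self.encoders()],
            "ga": None if ga is None else {
                "pop_size": ga.pop_size, "generations": ga.generations,
                "p_m": ga.p_m, "r_begin": ga.r_begin, "m_stop": ga.m_stop,
                "tree_grid": list(ga.tree_grid), "seed": ga.seed, "k": ga.k,
            },
            "tables_fingerprint": tables_fingerprint(),
            "version": __version__,
        }


@dataclass
class TrainResult:
    model: StackedModel
    apf_train: ProbFeatureMatrix
    selection: SelectionResult
    baselines: list[TrainedBaseline]
    report: dict = field(default_factory=dict)


def stacked_cv_metrics(apf: ProbFeatureMatrix, y, selection: SelectionResult,
                       k: int = 10, seed: int = 0,
                       threshold: float = 0.5) -> MetricsReport:
    """Pooled stratified CV of the meta-classifier over the out-of-fold
    probabilistic features restricted to the selected columns."""
    from sklearn.ensemble import ExtraTreesClassifier

    X = apf.select(selection.selected_columns)
    return cross_validate_matrix(
        lambda: ExtraTreesClassifier(n_estimators=selection.n_estimators,
                                     n_jobs=1, random_state=derive_seed("meta-cv", seed)),
        X, y, k=k, seed=seed, threshold=threshold)


def train_baseline_grid(ds: PeptideDataset, cfg: RunConfig):
    """Fit every (algorithm, encoding) baseline on one shared fold partition.

    Returns (baselines, folds). With cfg.tune the nine tunable algorithms
    are grid-searched per encoding first; otherwise fast fixed defaults are
    used.
    """
    y = ds.y
    folds = make_folds(y, k=cfg.k, seed=derive_seed("folds", cfg.seed))
    baselines = []
    for enc in cfg.encoders():
        X = encode_dataset(ds, enc).values
        for alg in cfg.algorithms():
            seed = derive_seed(alg.id, enc.name, cfg.seed)
            params = dict(alg.defaults)
            if cfg.tune and alg.tunable:
                params = tune_baseline(X, y, alg, folds, seed=seed)
            t0 = time.perf_counter()
            baselines.append(
                fit_baseline(X, y, alg, params, folds, seed=seed, encoding=enc.name))
            logger.debug("fitted %s-%s in %.2fs", alg.id, enc.name,
                         time.perf_counter() - t0)
        logger.info("encoding %s: %d baselines fitted", enc.name, len(cfg.algorithms()))
    return baselines, folds


def train_pipeline(ds: PeptideDataset, cfg: RunConfig) -> TrainResult:
    """Run the full three-stage training procedure on a labeled dataset."""
    y = ds.y
    t0 = time.perf_counter()
    baselines, _folds = train_baseline_grid(ds, cfg)
    t_base = time.perf_counter() - t0

    algorithms, encoders = cfg.algorithms(), cfg.encoders()
    apf = build_apf_train(ds, baselines, algorithms=algorithms, encoders=encoders)

    ga_cfg = cfg.ga or GAConfig(n_genes=apf.width, seed=derive_seed("ga", cfg.seed),
                                k=cfg.k, m_stop=min(20, apf.width))
    if ga_cfg.n_genes != apf.width:
        raise ValueError(f"GA configured for {ga_cfg.n_genes} genes but the "
                         f"feature matrix has {apf.width} columns")
    t0 = time.perf_counter()
    selection = run_ga(apf, y, ga_cfg)
    t_ga = time.perf_counter() - t0

    model = fit_stack(apf, y, selection, baselines,
                      seed=derive_seed("stack", cfg.seed), threshold=cfg.threshold,
                      algorithms=algorithms, encoders=encoders)
    cv_report = stacked_cv_metrics(apf, y, selection, k=cfg.k,
                                   seed=derive_seed("stack-cv", cfg.seed),
                                   threshold=cfg.threshold)
    report = {
        "config": cfg.to_dict(),
        "n_train": len(ds),
        "n_baselines": len(baselines),
        "apf_width": apf.width,
        "selected_columns": selection.selected_columns,
        "n_selected": len(selection.selected_columns),
        "meta_n_estimators": selection.n_estimators,
        "ga_best_fitness": selection.best_fitness,
        "ga_history": selection.history,
        "cv_metrics": cv_report.to_dict(),
        "timing": {"baselines_s": round(t_base, 2), "ga_s": round(t_ga, 2)},
    }
    return TrainResult(model=model, apf_train=apf, selection=selection,
                       baselines=baselines, report=report)
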