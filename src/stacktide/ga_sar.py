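"""Genetic-algorithm wrapper selection over probabilistic feature columns.

The chromosome has two parts: a binary gene per probabilistic feature
column (inclusion mask) and one parametric gene choosing the tree count of
the extremely-randomized-trees meta-classifier. Fitness is the pooled
Matthews correlation coefficient of that meta-classifier under stratified
k-fold cross-validation restricted to the active columns.

Default configuration: population 20, 20 generations,
mutation probability 0.05, initial active-gene count r_begin = 5, active
ceiling m_stop = 20, tree grid {20, 50, 100, 200, 500}.

Recombination is a "self-assessment report" (SAR) style guided uniform
crossover between the generation's elite and a tournament-selected mate:
each child gene is copied from the parent whose single-gene marginal
fitness record (mean fitness of evaluated chromosomes carrying that gene
state) is higher, falling back to a uniform coin when no record exists.
The operator sits behind a small interface so alternatives can be plugged
in. Elitist replacement makes the best-fitness history non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from stacktide.baselines import derive_seed, make_folds
from stacktide.evaluation import confusion, metrics

DEFAULT_TREE_GRID = (20, 50, 100, 200, 500)


@dataclass
class GAConfig:
    """Tunable knobs of the selection run."""

    n_genes: int = 156
    pop_size: int = 20
    generations: int = 20
    p_m: float = 0.05
    r_begin: int = 5
    m_stop: int = 20
    tree_grid: tuple[int, ...] = DEFAULT_TREE_GRID
    tournament_size: int = 2
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.r_begin <= self.m_stop <= self.n_genes):
            raise ValueError("need 1 <= r_begin <= m_stop <= n_genes")
        if not (0.0 <= self.p_m <= 1.0):
            raise ValueError("mutation probability must lie in [0, 1]")


@dataclass
class Chromosome:
    binary_genes: np.ndarray  # bool, length n_genes
    parametric_gene: int
    fitness: float | None = None

    def key(self) -> tuple:
        return (self.binary_genes.tobytes(), self.parametric_gene)

    def copy(self) -> "Chromosome":
        return Chromosome(self.binary_genes.copy(), self.parametric_gene, self.fitness)


@dataclass
class SelectionResult:
    """Decoded best chromosome: the selected column subset and tree count."""

    selected_columns: list[str]
    selected_indices: list[int]
    n_estimators: int
    best_fitness: float
    history: list[float] = field(default_factory=list)


def init_population(cfg: GAConfig, rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Random population: each chromosome has exactly r_begin active bits and
    a uniformly drawn tree count."""
    rng = rng or np.random.default_rng(cfg.seed)
    pop = []
    for _ in range(cfg.pop_size):
        genes = np.zeros(cfg.n_genes, dtype=bool)
        genes[rng.choice(cfg.n_genes, size=cfg.r_begin, replace=False)] = True
        pop.append(Chromosome(genes, int(rng.choice(cfg.tree_grid))))
    return pop


def repair(ch: Chromosome, cfg: GAConfig, rng: np.random.Generator) -> Chromosome:
    """Enforce 1 <= active bits <= m_stop by random deactivation/activation."""
    active = np.flatnonzero(ch.binary_genes)
    if len(active) > cfg.m_stop:
        drop = rng.choice(active, size=len(active) - cfg.m_stop, replace=False)
        ch.binary_genes[drop] = False
    elif len(active) == 0:
        ch.binary_genes[rng.integers(cfg.n_genes)] = True
    ch.fitness = None
    return ch


class FitnessEvaluator:
    """Cached CV-MCC fitness of chromosomes over a fixed feature matrix.

    The fold partition is built once from (y, k, seed) and shared by every
    evaluation, mirroring the single-partition policy of baseline training.
    """

    def __init__(self, apf_values: np.ndarray, y, k: int = 10, seed: int = 0):
        self.X = np.asarray(apf_values, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.folds = make_folds(self.y, k=k, seed=derive_seed("ga-folds", seed))
        self.seed = seed
        self._cache: dict[tuple, float] = {}
        # marginal fitness bookkeeping: per gene, (sum, count) of fitness of
        # evaluated chromosomes in which the gene was active / inactive
        n = self.X.shape[1]
        self._marg_sum = np.zeros((2, n))
        self._marg_cnt = np.zeros((2, n))

    def __call__(self, ch: Chromosome) -> float:
        key = ch.key()
        if key in self._cache:
            ch.fitness = self._cache[key]
            return ch.fitness
        active = np.flatnonzero(ch.binary_genes)
        if len(active) == 0:
            raise ValueError("chromosome has no active genes; repair first")
        X = self.X[:, active]
        pred = np.empty_like(self.y)
        for tr, te in self.folds:
            est = ExtraTreesClassifier(
                n_estimators=ch.parametric_gene, n_jobs=1,
                random_state=derive_seed("ga-fitness", self.seed),
            )
            est.fit(X[tr], self.y[tr])
            pred[te] = est.predict(X[te])
        fit = metrics(*confusion(self.y, pred)).MCC
        self._cache[key] = fit
        ch.fitness = fit
        state = ch.binary_genes.astype(int)
        self._marg_sum[state, np.arange(len(state))] += fit
        self._marg_cnt[state, np.arange(len(state))] += 1
        return fit

    def marginal(self, gene: int, state: bool) -> float | None:
        cnt = self._marg_cnt[int(state), gene]
        if cnt == 0:
            return None
        return self._marg_sum[int(state), gene] / cnt


def _rank_key(ch: Chromosome) -> tuple:
    """Selection order: fitness first; exact ties go to the smaller tree
    count (a cheaper, lower-variance meta-classifier — parsimony rule)."""
    return (ch.fitness if ch.fitness is not None else -2.0, -ch.parametric_gene)


def sar_crossover(elite: Chromosome, mate: Chromosome, evaluator: FitnessEvaluator,
                  rng: np.random.Generator) -> Chromosome:
    """Guided uniform recombination (the SAR operator).

    Where parents disagree on a binary gene, the child takes the state with
    the higher recorded marginal fitness; unknown marginals fall back to a
    fair coin. The parametric gene is inherited from the fitter parent.
    """
    n = len(elite.binary_genes)
    child = elite.binary_genes.copy()
    disagree = np.flatnonzero(elite.binary_genes != mate.binary_genes)
    for g in disagree:
        m_on = evaluator.marginal(g, True)
        m_off = evaluator.marginal(g, False)
        if m_on is None or m_off is None:
            child[g] = rng.random() < 0.5
        else:
            child[g] = m_on > m_off
    fitter = max((elite, mate), key=_rank_key)
    return Chromosome(child, fitter.parametric_gene)


def _tournament(pop: list[Chromosome], size: int, rng: np.random.Generator) -> Chromosome:
    contenders = [pop[i] for i in rng.integers(len(pop), size=size)]
    return max(contenders, key=_rank_key)


def evolve(population: list[Chromosome], apf, y, cfg: GAConfig,
           columns: list[str] | None = None) -> SelectionResult:
    """Run the GA for cfg.generations and decode the best chromosome.

    ``apf`` may be a ProbFeatureMatrix or a plain array; ``columns`` names
    the genes when a plain array is given. With generations = 0 the result
    is simply the best member of the initial population.
    """
    values = getattr(apf, "values", apf)
    columns = columns or getattr(apf, "columns", None) \
        or [f"col{i}" for i in range(np.asarray(values).shape[1])]
    evaluator = FitnessEvaluator(values, y, k=cfg.k, seed=cfg.seed)
    rng = np.random.default_rng(derive_seed("ga-evolve", cfg.seed))

    pop = [ch.copy() for ch in population]
    for ch in pop:
        evaluator(ch)
    best = max(pop, key=_rank_key).copy()
    history = [best.fitness]

    for _gen in range(cfg.generations):
        children = [best.copy()]  # elitism
        while len(children) < cfg.pop_size:
            mate = _tournament(pop, cfg.tournament_size, rng)
            child = sar_crossover(best, mate, evaluator, rng)
            flip = rng.random(cfg.n_genes) < cfg.p_m
            child.binary_genes ^= flip
            if rng.random() < cfg.p_m:
                child.parametric_gene = int(rng.choice(cfg.tree_grid))
            repair(child, cfg, rng)
            children.append(child)
        pop = children
        for ch in pop:
            evaluator(ch)
        gen_best = max(pop, key=_rank_key)
        if _rank_key(gen_best) > _rank_key(best):
            best = gen_best.copy()
        history.append(best.fitness)

    idx = np.flatnonzero(best.binary_genes).tolist()
    return SelectionResult(
        selected_columns=[columns[i] for i in idx],
        selected_indices=idx,
        n_estimators=best.parametric_gene,
        best_fitness=float(best.fitness),
        history=[float(h) for h in history],
    )


def run_ga(apf, y, cfg: GAConfig) -> SelectionResult:
    """Convenience wrapper: initialize a population and evolve it."""
    rng = np.random.default_rng(derive_seed("ga-init", cfg.seed))
    return evolve(init_population(cfg, rng), apf, y, cfg)
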