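"""Genetic-algorithm hyperparameter tuning with noise-subset-weighted AUC fitness.

Five hyperparameters are evolved jointly: the elastic-net mixing fraction
``alpha`` and penalty strength (as log10 lambda), the upweighting factor and
the Gensini threshold that triggers it, and the correlation-reduction
threshold.  A genome is evaluated by running the full model-development
pipeline (correlation filter -> upweighting -> elastic-net fit -> continuous
prediction) and scoring ranking performance against the binary CAD labels
on five nested noise subsets of both the training and validation sets:

    fitness = - sum_{i=1..5} [ (1 - AUC(T_i))^2 + 1.5 * (1 - AUC(V_i))^2 ]

The subsets are nested by per-subject noise volume: subset 1 is everything,
and each further subset drops the noisiest remaining acquisitions (above the
next-largest of four ascending thresholds), so clean data is weighted more
heavily.  Fitness is 0 only for perfect ranking on every subset.

Evolution uses rank-weighted parent selection with elitism, per-gene
mutation with probability 0.33 (half perturbations, half uniform re-draws),
single-point crossover on half of the offspring, and stops after 10
generations without improvement of the best fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .elastic_net import (
    ElasticNetParams,
    ModelWeights,
    TrainingData,
    apply_upweighting,
    fit,
    predict,
)
from .feature_reduction import ReductionResult, abs_correlation_matrix, reduce_by_correlation

__all__ = [
    "Genome",
    "GeneRanges",
    "GAConfig",
    "NoiseSubsetPartition",
    "FitnessValue",
    "SplitData",
    "EvolveResult",
    "build_noise_subsets",
    "rank_auc",
    "fitness",
    "fit_genome",
    "evaluate_genome",
    "mutate",
    "crossover",
    "evolve",
]

GENE_NAMES = (
    "alpha",
    "log_lambda",
    "upweight_factor",
    "gensini_weight_threshold",
    "corr_threshold",
)


@dataclass(frozen=True)
class Genome:
    """One candidate hyperparameter vector."""

    alpha: float
    log_lambda: float
    upweight_factor: float
    gensini_weight_threshold: float
    corr_threshold: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, g) for g in GENE_NAMES])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "Genome":
        return cls(**{g: float(v) for g, v in zip(GENE_NAMES, a)})

    def to_dict(self) -> dict:
        return {g: float(getattr(self, g)) for g in GENE_NAMES}


@dataclass(frozen=True)
class GeneRanges:
    """Inclusive bounds for each gene; mutated values are clipped to these.

    The Gensini-threshold range should span the observed modified-Gensini
    scores in the training data; the default covers 0 (clean angiogram)
    up to ln(1 + 32 * 5) (occluded left main).
    """

    alpha: tuple[float, float] = (0.0, 1.0)
    log_lambda: tuple[float, float] = (-4.0, 2.0)
    upweight_factor: tuple[float, float] = (1.0, 10.0)
    gensini_weight_threshold: tuple[float, float] = (0.0, 5.1)
    corr_threshold: tuple[float, float] = (0.80, 1.0)

    def bounds(self) -> np.ndarray:
        return np.array([getattr(self, g) for g in GENE_NAMES])

    def clip(self, values: np.ndarray) -> np.ndarray:
        b = self.bounds()
        return np.clip(values, b[:, 0], b[:, 1])

    def sample(self, rng: np.random.Generator) -> Genome:
        b = self.bounds()
        return Genome.from_array(rng.uniform(b[:, 0], b[:, 1]))


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    mutation_prob: float = 0.33
    crossover_fraction: float = 0.5
    stagnation_limit: int = 10
    elitism: int = 2
    max_generations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for name in ("mutation_prob", "crossover_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than the population")


@dataclass
class NoiseSubsetPartition:
    """Five nested index sets per split, from four ascending noise cutoffs."""

    thresholds: np.ndarray
    train_subsets: list[np.ndarray]
    val_subsets: list[np.ndarray]


@dataclass
class FitnessValue:
    fitness: float
    auc_train: np.ndarray
    auc_val: np.ndarray


@dataclass
class SplitData:
    """One split's design matrix, Gensini targets, CAD labels and noise volumes."""

    X: np.ndarray
    y_gensini: np.ndarray
    labels: np.ndarray
    noise_volume: np.ndarray

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for name in ("y_gensini", "labels", "noise_volume"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match X")


def build_noise_subsets(
    noise_volumes_train: np.ndarray,
    noise_volumes_val: np.ndarray,
    thresholds: np.ndarray,
) -> NoiseSubsetPartition:
    """Nested noise subsets: subset 1 is all subjects; subset i+1 keeps only
    those with noise volume <= the i-th largest threshold.

    Raises on an empty subset (fitness is undefined there).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (4,) or np.any(np.diff(thresholds) <= 0):
        raise ValueError("need 4 strictly ascending thresholds")

    def nest(volumes: np.ndarray, split: str) -> list[np.ndarray]:
        volumes = np.asarray(volumes, dtype=float)
        subsets = [np.arange(volumes.shape[0])]
        for i, t in enumerate(thresholds[::-1], start=2):
            idx = subsets[-1][volumes[subsets[-1]] <= t]
            if idx.size == 0:
                raise ValueError(f"{split} noise subset {i} is empty")
            subsets.append(idx)
        return subsets

    return NoiseSubsetPartition(
        thresholds=thresholds,
        train_subsets=nest(noise_volumes_train, "training"),
        val_subsets=nest(noise_volumes_val, "validation"),
    )


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney statistic: the fraction of
    (positive, negative) pairs ranked concordantly, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fitness(
    scores_train: np.ndarray,
    labels_train: np.ndarray,
    scores_val: np.ndarray,
    labels_val: np.ndarray,
    partition: NoiseSubsetPartition,
) -> FitnessValue:
    """Noise-subset-weighted fitness; 0 iff every subset AUC equals 1."""
    auc_t = np.empty(5)
    auc_v = np.empty(5)
    for i in range(5):
        idx_t = partition.train_subsets[i]
        idx_v = partition.val_subsets[i]
        try:
            auc_t[i] = rank_auc(scores_train[idx_t], labels_train[idx_t])
        except ValueError as exc:
            raise ValueError(f"training subset {i + 1}: {exc}") from None
        try:
            auc_v[i] = rank_auc(scores_val[idx_v], labels_val[idx_v])
        except ValueError as exc:
            raise ValueError(f"validation subset {i + 1}: {exc}") from None
    value = -float(np.sum((1.0 - auc_t) ** 2 + 1.5 * (1.0 - auc_v) ** 2))
    return FitnessValue(fitness=value, auc_train=auc_t, auc_val=auc_v)


def fit_genome(
    genome: Genome,
    train: SplitData,
    *,
    n_reducible: int | None = None,
    corr: np.ndarray | None = None,
    en_params: ElasticNetParams | None = None,
) -> tuple[ReductionResult, ModelWeights]:
    """Run the development pipeline for one genome on the training split.

    Columns beyond ``n_reducible`` (the appended age/sex/heart-rate
    demographics) bypass the correlation filter and are always retained.
    The returned ``ModelWeights.feature_index`` refers to the full matrix.
    """
    p = train.X.shape[1]
    if n_reducible is None:
        n_reducible = p
    reduction = reduce_by_correlation(
        train.X[:, :n_reducible], genome.corr_threshold, corr=corr
    )
    kept = np.concatenate([reduction.kept_indices, np.arange(n_reducible, p)])
    if kept.size == 0:
        raise ValueError("correlation reduction removed every feature")
    u = apply_upweighting(
        train.y_gensini, genome.gensini_weight_threshold, genome.upweight_factor
    )
    base = en_params if en_params is not None else ElasticNetParams()
    params = replace(base, alpha=genome.alpha, lam=10.0 ** genome.log_lambda)
    weights = fit(TrainingData(train.X[:, kept], train.y_gensini, u), params)
    weights.feature_index = kept
    return reduction, weights


def evaluate_genome(
    genome: Genome,
    train: SplitData,
    val: SplitData,
    partition: NoiseSubsetPartition,
    *,
    n_reducible: int | None = None,
    corr: np.ndarray | None = None,
    en_params: ElasticNetParams | None = None,
) -> FitnessValue:
    """Fitness of one genome: develop on the training split, score on both.

    A genome that empties the feature set, or whose elastic-net fit does not
    converge within its sweep budget, scores the worst possible fitness
    (-inf) so evolution simply selects against it instead of aborting.
    """
    from .elastic_net import ConvergenceError

    try:
        _, weights = fit_genome(
            genome, train, n_reducible=n_reducible, corr=corr, en_params=en_params
        )
    except ConvergenceError:
        return FitnessValue(-np.inf, np.full(5, np.nan), np.full(5, np.nan))
    except ValueError as exc:
        if "removed every feature" in str(exc):
            return FitnessValue(-np.inf, np.full(5, np.nan), np.full(5, np.nan))
        raise
    scores_t = predict(weights, train.X[:, weights.feature_index])
    scores_v = predict(weights, val.X[:, weights.feature_index])
    return fitness(scores_t, train.labels, scores_v, val.labels, partition)


def mutate(
    genome: Genome,
    config: GAConfig,
    rng: np.random.Generator,
    ranges: GeneRanges = GeneRanges(),
) -> Genome:
    """Per-gene mutation with probability ``config.mutation_prob``: half the
    mutations perturb by Gaussian noise (sigma = 10% of the gene range), the
    rest re-draw uniformly; results are clipped to the gene range."""
    values = genome.as_array()
    b = ranges.bounds()
    span = b[:, 1] - b[:, 0]
    for j in range(values.size):
        if rng.random() < config.mutation_prob:
            if rng.random() < 0.5:
                values[j] += rng.normal(0.0, 0.1 * span[j])
            else:
                values[j] = rng.uniform(b[j, 0], b[j, 1])
    return Genome.from_array(ranges.clip(values))


def crossover(parent_a: Genome, parent_b: Genome, rng: np.random.Generator) -> Genome:
    """Single-point crossover: genes before a uniform random cut (one of the
    4 internal positions) come from ``parent_a``, the rest from ``parent_b``."""
    cut = int(rng.integers(1, len(GENE_NAMES)))
    a, b = parent_a.as_array(), parent_b.as_array()
    return Genome.from_array(np.concatenate([a[:cut], b[cut:]]))


@dataclass
class EvolveResult:
    best_genome: Genome
    best_fitness: float
    history: pd.DataFrame
    truncated: bool
    seed: int
    n_generations: int


def evolve(
    train: SplitData,
    val: SplitData,
    partition: NoiseSubsetPartition,
    config: GAConfig,
    *,
    ranges: GeneRanges = GeneRanges(),
    n_reducible: int | None = None,
    en_params: ElasticNetParams | None = None,
    evaluator=None,
) -> EvolveResult:
    """Generational GA over the five hyperparameters.

    Each generation: evaluate the population, carry the ``elitism`` best
    genomes unchanged, select parents by rank-weighted sampling, build the
    remaining offspring (the first ``crossover_fraction`` of them via
    single-point crossover, the rest as clones), and mutate every offspring.
    Stops when the best fitness has not strictly improved for
    ``stagnation_limit`` consecutive generations, or at ``max_generations``
    (returned with ``truncated=True``).

    ``evaluator`` (genome -> float) can replace the model-development
    fitness, e.g. for toy benchmark functions.
    """
    rng = np.random.default_rng(config.seed)
    if evaluator is None:
        corr = (
            abs_correlation_matrix(train.X[:, : n_reducible or train.X.shape[1]])
            if train.X.shape[1] > 0
            else None
        )

        def evaluator(g: Genome) -> float:
            return evaluate_genome(
                g, train, val, partition,
                n_reducible=n_reducible, corr=corr, en_params=en_params,
            ).fitness

    cache: dict[tuple, float] = {}

    def score(g: Genome) -> float:
        key = tuple(g.as_array())
        if key not in cache:
            cache[key] = evaluator(g)
        return cache[key]

    population = [ranges.sample(rng) for _ in range(config.population_size)]
    best_genome: Genome | None = None
    best_fitness = -np.inf
    stagnant = 0
    rows = []
    truncated = False
    generation = 0

    for generation in range(1, config.max_generations + 1):
        fits = np.array([score(g) for g in population])
        order = np.argsort(fits)[::-1]  # best first
        gen_best = fits[order[0]]
        improved = gen_best > best_fitness
        if improved or best_genome is None:
            if improved:
                best_fitness = float(gen_best)
                stagnant = 0
            else:
                stagnant += 1
            best_genome = population[order[0]]
        else:
            stagnant += 1
        finite = fits[np.isfinite(fits)]
        rows.append(
            {
                "generation": generation,
                "best_fitness": best_fitness,
                "gen_best_fitness": float(gen_best),
                "mean_fitness": float(finite.mean()) if finite.size else -np.inf,
                **{f"best_{g}": getattr(best_genome, g) for g in GENE_NAMES},
            }
        )
        if stagnant >= config.stagnation_limit:
            break

        # rank-weighted selection: weight proportional to rank (best highest)
        n = config.population_size
        weights = np.empty(n)
        weights[order] = np.arange(n, 0, -1, dtype=float)
        weights /= weights.sum()

        elites = [population[i] for i in order[: config.elitism]]
        n_off = n - config.elitism
        n_cross = int(round(config.crossover_fraction * n_off))
        offspring = []
        for k in range(n_off):
            if k < n_cross:
                ia, ib = rng.choice(n, size=2, replace=False, p=weights)
                child = crossover(population[ia], population[ib], rng)
            else:
                child = population[int(rng.choice(n, p=weights))]
            offspring.append(mutate(child, config, rng, ranges))
        population = elites + offspring
    else:
        truncated = True

    return EvolveResult(
        best_genome=best_genome,
        best_fitness=best_fitness,
        history=pd.DataFrame(rows),
        truncated=truncated,
        seed=config.seed,
        n_generations=generation,
    )
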