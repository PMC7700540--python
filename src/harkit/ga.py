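"""Reweighted genetic-algorithm feature selection.

Each individual (chromosome) is a per-feature weight vector in [0, 1];
fitness reweights the feature table, trains a linear SVM and a random
forest on a stratified 80% split of the training partition, and scores
each on the held-out 20%. The fitness is the mean of the two
accuracies. Evolution uses tournament selection, single-point
crossover, per-gene uniform-resample mutation at rate 0.05, and
one-elite carry-over, so the best-fitness history is non-decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .types import GAConfig


@dataclass
class FitnessRecord:
    """Held-out accuracies of the two fitness classifiers and their mean."""

    acc_lsvm: float
    acc_rf: float

    @property
    def combined(self) -> float:
        return (self.acc_lsvm + self.acc_rf) / 2.0


@dataclass
class Chromosome:
    """A per-feature weight vector in [0, 1] with an optional fitness record."""

    weights: np.ndarray
    fitness: FitnessRecord | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("gene weights must lie in [0, 1]")


@dataclass
class Population:
    members: list[Chromosome]
    generation: int = 0


def init_population(n_members: int, n_features: int, seed: int) -> Population:
    """Population of i.i.d. uniform-[0,1] weight chromosomes; deterministic
    given seed."""
    if n_members < 2:
        raise ValueError("population needs at least 2 members")
    if n_features < 1:
        raise ValueError("need at least 1 feature")
    rng = np.random.default_rng(seed)
    members = [
        Chromosome(rng.uniform(0.0, 1.0, size=n_features)) for _ in range(n_members)
    ]
    return Population(members=members, generation=0)


def crossover(
    parent1: Chromosome, parent2: Chromosome, seed: int | np.random.Generator = 0
) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover at a uniformly drawn cut in [1, n-1].

    The positionwise gene multiset across the pair is conserved.
    """
    if len(parent1.weights) != len(parent2.weights):
        raise ValueError("parent chromosomes have mismatched lengths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(parent1.weights)
    if n < 2:
        return Chromosome(parent1.weights.copy()), Chromosome(parent2.weights.copy())
    k = int(rng.integers(1, n))
    c1 = np.concatenate([parent1.weights[:k], parent2.weights[k:]])
    c2 = np.concatenate([parent2.weights[:k], parent1.weights[k:]])
    return Chromosome(c1), Chromosome(c2)


def mutate(
    chromosome: Chromosome, rate: float = 0.05, seed: int | np.random.Generator = 0
) -> Chromosome:
    """Resample each gene uniformly on [0, 1] independently with
    probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.uniform(size=len(chromosome.weights)) < rate
    new = chromosome.weights.copy()
    new[mask] = rng.uniform(0.0, 1.0, size=int(mask.sum()))
    return Chromosome(new)


def reweight(feature_table: np.ndarray, chromosome: Chromosome) -> np.ndarray:
    """Multiply column j of the table by gene j."""
    X = np.asarray(feature_table, dtype=float)
    if X.shape[1] != len(chromosome.weights):
        raise ValueError(
            f"table has {X.shape[1]} columns but chromosome has "
            f"{len(chromosome.weights)} genes"
        )
    return X * chromosome.weights


def _make_classifiers(config: GAConfig):
    lsvm = LinearSVC(C=config.svm_c, dual="auto", max_iter=5000, random_state=0)
    rf = RandomForestClassifier(
        n_estimators=config.rf_estimators, random_state=0, n_jobs=1
    )
    return lsvm, rf


def fitness(
    chromosome: Chromosome,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    seed: int = 0,
    config: GAConfig | None = None,
) -> FitnessRecord:
    """Evaluate a chromosome: reweight, stratified 80/20 split, train the
    linear SVM and the random forest on the 80%, score on the 20%."""
    config = config or GAConfig()
    y = np.asarray(train_labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("fitness evaluation needs at least 2 classes")
    if counts.min() < 5:
        raise ValueError("fitness evaluation needs at least 5 samples per class")
    Xw = reweight(train_features, chromosome)
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xw, y, test_size=0.2, stratify=y, random_state=seed % (2**31)
    )
    lsvm, rf = _make_classifiers(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        lsvm.fit(X_tr, y_tr)
    rf.fit(X_tr, y_tr)
    rec = FitnessRecord(
        acc_lsvm=float(lsvm.score(X_te, y_te)),
        acc_rf=float(rf.score(X_te, y_te)),
    )
    chromosome.fitness = rec
    return rec


def evolve(
    feature_table: np.ndarray,
    labels: np.ndarray,
    config: GAConfig | None = None,
    seed: int = 0,
) -> tuple[Chromosome, list[float]]:
    """Run the GA; returns the best chromosome and the per-generation
    best-fitness history (non-decreasing thanks to elitism).

    Tournament selection (size 3 by default), crossover with
    probability 0.8, mutation at 0.05, one elite. Stops at
    ``max_generations`` or when the best fitness is unchanged for
    ``patience`` consecutive generations. All chromosomes in a run are
    scored on the same seeded 80/20 split so fitnesses are comparable.
    """
    config = config or GAConfig()
    X = np.asarray(feature_table, dtype=float)
    y = np.asarray(labels)
    n_features = X.shape[1]
    rng = np.random.default_rng(seed)
    split_seed = int(rng.integers(0, 2**31))

    cache: dict[bytes, FitnessRecord] = {}

    def score(ch: Chromosome) -> float:
        key = ch.weights.tobytes()
        if key not in cache:
            cache[key] = fitness(ch, X, y, seed=split_seed, config=config)
        ch.fitness = cache[key]
        return cache[key].combined

    pop = init_population(config.population_size, n_features, int(rng.integers(0, 2**31)))
    history: list[float] = []
    best: Chromosome | None = None
    stall = 0

    for gen in range(config.max_generations):
        scored = [(score(ch), i, ch) for i, ch in enumerate(pop.members)]
        scored.sort(key=lambda t: (-t[0], t[1]))
        gen_best = scored[0][2]
        if best is None or gen_best.fitness.combined > best.fitness.combined:
            best = Chromosome(gen_best.weights.copy(), gen_best.fitness)
            stall = 0
        else:
            stall += 1
        history.append(best.fitness.combined)
        if stall >= config.patience or gen == config.max_generations - 1:
            break

        def tournament() -> Chromosome:
            idx = rng.integers(0, len(pop.members), size=config.tournament_size)
            contenders = [(score(pop.members[i]), int(i)) for i in idx]
            contenders.sort(key=lambda t: (-t[0], t[1]))
            return pop.members[contenders[0][1]]

        next_members: list[Chromosome] = [
            Chromosome(best.weights.copy(), best.fitness)
        ][: config.elitism]
        while len(next_members) < config.population_size:
            p1, p2 = tournament(), tournament()
            if rng.uniform() < config.crossover_prob:
                o1, o2 = crossover(p1, p2, rng)
            else:
                o1, o2 = Chromosome(p1.weights.copy()), Chromosome(p2.weights.copy())
            next_members.append(mutate(o1, config.mutation_rate, rng))
            if len(next_members) < config.population_size:
                next_members.append(mutate(o2, config.mutation_rate, rng))
        pop = Population(members=next_members, generation=gen + 1)

    assert best is not None
    return best, history


def select_features(best: Chromosome, feature_names: list[str]) -> list[str]:
    """Retain features whose weight is at least the mean of all weights;
    always retains at least one feature."""
    if best.fitness is None:
        raise ValueError("chromosome has no fitness record")
    w = best.weights
    threshold = float(np.mean(w))
    retained = [name for name, wi in zip(feature_names, w) if wi >= threshold]
    if not retained:
        retained = [feature_names[int(np.argmax(w))]]
    return retained


class GAFeatureSelector(BaseEstimator, TransformerMixin):
    """Genetic-algorithm feature reweighting and selection, sklearn-style.

    ``fit`` evolves a per-feature weight vector whose fitness is the
    mean held-out accuracy of a linear SVM and a random forest on the
    reweighted table; ``transform`` multiplies features by the evolved
    weights and keeps those at or above the mean weight.

    Parameters mirror :class:`harkit.types.GAConfig`. After ``fit``:

    - ``weights_`` : evolved gene vector, one weight per input feature
    - ``support_`` : boolean retained-feature mask
    - ``history_`` : best combined fitness per generation
    - ``fitness_`` : FitnessRecord of the best chromosome
    """

    def __init__(
        self,
        population_size: int = 30,
        max_generations: int = 50,
        crossover_prob: float = 0.8,
        mutation_rate: float = 0.05,
        tournament_size: int = 3,
        elitism: int = 1,
        patience: int = 10,
        rf_estimators: int = 100,
        svm_c: float = 1.0,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.max_generations = max_generations
        self.crossover_prob = crossover_prob
        self.mutation_rate = mutation_rate
        self.tournament_size = tournament_size
        self.elitism = elitism
        self.patience = patience
        self.rf_estimators = rf_estimators
        self.svm_c = svm_c
        self.random_state = random_state

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            crossover_prob=self.crossover_prob,
            mutation_rate=self.mutation_rate,
            tournament_size=self.tournament_size,
            elitism=self.elitism,
            patience=self.patience,
            rf_estimators=self.rf_estimators,
            svm_c=self.svm_c,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.n_features_in_ = X.shape[1]
        best, history = evolve(X, y, self._config(), seed=self.random_state)
        self.best_chromosome_ = best
        self.weights_ = best.weights
        self.fitness_ = best.fitness
        self.history_ = history
        threshold = float(np.mean(best.weights))
        support = best.weights >= threshold
        if not support.any():
            support[int(np.argmax(best.weights))] = True
        self.support_ = support
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; selector was fitted with "
                f"{self.n_features_in_}"
            )
        return (X * self.weights_)[:, self.support_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.where(self.support_)[0] if indices else self.support_
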