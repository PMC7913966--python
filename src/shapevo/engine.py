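"""Genetic evolution of shapelet sets.

A population of shapelet sets (individuals) is evolved generationally:
tournament selection picks parents, three crossover operators recombine
whole sets, individual shapelets, or shapelet means (barycenters), and
three mutation operators trim, drop, or add shapelets. Fitness is the
in-sample mean log loss of a ridge-penalized multinomial logistic
regression fitted on the distance transform, with the sum of shapelet
lengths as lexicographic tie-breaker, so that among equally predictive
sets the simplest wins. The incumbent best individual (the elite) is
re-injected each generation and exempt from variation, which makes the
best fitness non-increasing over generations; the loop stops after a
configurable number of stagnant generations (patience) or a generation
cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import total_ordering
from typing import Callable, Optional

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss

from .core import (
    MIN_SHAPELET_LEN,
    LengthError,
    Shapelet,
    ShapeletSet,
    TimeSeriesDataset,
    distance_matrix,
)

INIT_OPS = ("kmeans", "random")
CROSSOVER_OPS = ("set", "shapelet", "merge")
MUTATION_OPS = ("mask", "remove", "add")


class ConfigError(ValueError):
    pass


@total_ordering
@dataclass(frozen=True)
class FitnessValue:
    """(error, complexity), ordered lexicographically — lower is fitter."""

    error: float
    complexity: int

    def __post_init__(self) -> None:
        if self.error < 0 or self.complexity <= 0:
            raise ValueError("error must be >= 0 and complexity > 0")

    def as_tuple(self) -> tuple[float, int]:
        return (self.error, self.complexity)

    def __lt__(self, other: "FitnessValue") -> bool:
        return self.as_tuple() < other.as_tuple()


@dataclass
class EvolutionConfig:
    """Hyper-parameters of the evolutionary search.

    ``max_shapelets`` (W) bounds the size of newly initialized individuals;
    its default, ceil(sqrt(M)), keeps initial sets small so they grow only
    when growth pays off. ``max_len`` defaults to the shortest series length
    M. Operator toggles select which initialization / crossover / mutation
    operators may fire.
    """

    max_shapelets: Optional[int] = None       # W; None -> ceil(sqrt(M))
    population_size: int = 100                # P
    generations: int = 100                    # G
    patience: int = 10
    p_mutation: float = 0.1
    p_crossover: float = 0.4
    max_len: Optional[int] = None             # None -> M
    min_len: int = MIN_SHAPELET_LEN
    tournament_size: int = 3
    enabled_init: tuple[str, ...] = INIT_OPS
    enabled_crossover: tuple[str, ...] = CROSSOVER_OPS
    enabled_mutation: tuple[str, ...] = MUTATION_OPS
    seed: Optional[int] = None

    def resolved(self, dataset: TimeSeriesDataset) -> "EvolutionConfig":
        """Fill data-dependent defaults and validate against the dataset."""
        M = dataset.min_length
        max_len = self.max_len if self.max_len is not None else M
        W = (
            self.max_shapelets
            if self.max_shapelets is not None
            else max(2, math.ceil(math.sqrt(M)))
        )
        cfg = replace(self, max_len=max_len, max_shapelets=W)
        cfg.validate(M)
        return cfg

    def validate(self, M: Optional[int] = None) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if self.generations < 1 or self.patience < 1:
            raise ConfigError("generations and patience must be >= 1")
        for name in ("p_mutation", "p_crossover"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.tournament_size < 1:
            raise ConfigError("tournament_size must be >= 1")
        if self.max_shapelets is not None and self.max_shapelets < 2:
            raise ConfigError("max_shapelets (W) must be >= 2")
        if self.max_len is not None:
            if self.max_len < self.min_len:
                raise ConfigError("max_len must be >= min_len")
            if M is not None and self.max_len > M:
                raise ConfigError(
                    f"max_len={self.max_len} exceeds shortest series length {M}"
                )
        unknown = set(self.enabled_init) - set(INIT_OPS)
        unknown |= set(self.enabled_crossover) - set(CROSSOVER_OPS)
        unknown |= set(self.enabled_mutation) - set(MUTATION_OPS)
        if unknown:
            raise ConfigError(f"unknown operator names: {sorted(unknown)}")
        if not self.enabled_init:
            raise ConfigError("at least one initialization operator is required")


@dataclass
class GenerationRecord:
    generation: int
    best_error: float
    best_complexity: int
    best_size: int
    mean_error: float
    evaluations: int


@dataclass
class EvolutionLog:
    records: list[GenerationRecord] = field(default_factory=list)
    stopping_reason: str = "max_generations"

    @property
    def best_fitness_trace(self) -> list[tuple[float, int]]:
        return [(r.best_error, r.best_complexity) for r in self.records]


# ---------------------------------------------------------------- sampling

def _random_subsequence(
    dataset: TimeSeriesDataset, length: int, rng: np.random.Generator
) -> np.ndarray:
    candidates = [i for i, t in enumerate(dataset.series) if t.size >= length]
    idx = candidates[rng.integers(len(candidates))]
    t = dataset.series[idx]
    start = int(rng.integers(t.size - length + 1))
    return t[start : start + length].copy()


def init_random(
    dataset: TimeSeriesDataset,
    k: int,
    rng: np.random.Generator,
    min_len: int = MIN_SHAPELET_LEN,
    max_len: Optional[int] = None,
) -> ShapeletSet:
    """K verbatim subsequences with independent uniform lengths and offsets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    max_len = dataset.min_length if max_len is None else max_len
    if max_len < min_len:
        raise LengthError(f"max_len={max_len} below min_len={min_len}")
    shapelets = []
    for _ in range(k):
        length = int(rng.integers(min_len, max_len + 1))
        shapelets.append(Shapelet(_random_subsequence(dataset, length, rng)))
    return ShapeletSet(shapelets)


def init_kmeans(
    dataset: TimeSeriesDataset,
    k: int,
    rng: np.random.Generator,
    min_len: int = MIN_SHAPELET_LEN,
    max_len: Optional[int] = None,
) -> ShapeletSet:
    """K-means centroids of random equal-length subsequences.

    One length is drawn uniformly from [min_len, max_len]; max(10*k, 50)
    subsequences of that length are sampled and clustered into k groups.
    The centroids — which need not be subsequences of any input series —
    form the individual.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    max_len = dataset.min_length if max_len is None else max_len
    if max_len < min_len:
        raise LengthError(f"max_len={max_len} below min_len={min_len}")
    length = int(rng.integers(min_len, max_len + 1))
    n_draws = max(10 * k, 50)
    X = np.stack(
        [_random_subsequence(dataset, length, rng) for _ in range(n_draws)]
    )
    km = KMeans(
        n_clusters=k,
        n_init=1,
        random_state=int(rng.integers(2**31)),
    ).fit(X)
    centroids = km.cluster_centers_
    counts = np.bincount(km.labels_, minlength=k)
    shapelets = []
    for j in range(k):
        if counts[j] == 0:  # defensive: replace an empty cluster
            shapelets.append(
                Shapelet(_random_subsequence(dataset, length, rng))
            )
        else:
            shapelets.append(Shapelet(centroids[j]))
    return ShapeletSet(shapelets)


_INIT_FUNCS: dict[str, Callable] = {"kmeans": init_kmeans, "random": init_random}


def initialize_population(
    dataset: TimeSeriesDataset, config: EvolutionConfig, rng: np.random.Generator
) -> list[ShapeletSet]:
    """P individuals; per individual, K ~ Uniform{2..W} and the strategy is
    chosen uniformly among the enabled initialization operators."""
    cfg = config if config.max_len is not None else config.resolved(dataset)
    ops = [_INIT_FUNCS[name] for name in cfg.enabled_init]
    if not ops:
        raise ConfigError("no initialization operator enabled")
    population = []
    for _ in range(cfg.population_size):
        k = int(rng.integers(2, cfg.max_shapelets + 1))
        op = ops[int(rng.integers(len(ops)))]
        population.append(
            op(dataset, k, rng, min_len=cfg.min_len, max_len=cfg.max_len)
        )
    return population


# ----------------------------------------------------------------- fitness

def evaluate_fitness(
    shapelet_set: ShapeletSet,
    dataset: TimeSeriesDataset,
    y: Optional[np.ndarray] = None,
) -> FitnessValue:
    """In-sample mean log loss of a ridge multinomial LR on the transform.

    The solver (lbfgs, fixed C=1) is deterministic, so identical sets on
    identical data always score identically; the result is cached on the
    individual.
    """
    y = dataset.labels if y is None else np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("fitness is undefined for single-class labels")
    D = distance_matrix(shapelet_set, dataset)
    # exact duplicate columns are dropped before the fit: ridge loss is not
    # duplicate-column invariant (a doubled column halves its effective
    # penalty), and rewarding redundancy would defeat the complexity
    # tie-break that keeps sets small
    _, keep = np.unique(D, axis=1, return_index=True)
    D = D[:, np.sort(keep)]
    model = LogisticRegression(C=1.0, max_iter=1000)
    model.fit(D, y)
    error = float(log_loss(y, model.predict_proba(D), labels=model.classes_))
    fit = FitnessValue(error=error, complexity=shapelet_set.complexity)
    shapelet_set.fitness = fit
    return fit


# --------------------------------------------------------------- crossover

def _cut_points(n: int, two_point: bool, rng: np.random.Generator):
    if two_point:
        i, j = sorted(int(rng.integers(0, n + 1)) for _ in range(2))
        return i, j
    c = int(rng.integers(1, n)) if n >= 2 else 1
    return c, None


def crossover_set_point(
    a: ShapeletSet, b: ShapeletSet, rng: np.random.Generator
) -> tuple[ShapeletSet, ShapeletSet]:
    """One- or two-point crossover on the ordered member lists.

    Children are composed of whole shapelets from both parents; the multiset
    union of the children equals that of the parents. Degenerate cuts that
    would empty a child fall back to clones.
    """
    la, lb = list(a.shapelets), list(b.shapelets)
    if rng.random() < 0.5:  # one-point
        ca, _ = _cut_points(len(la), False, rng)
        cb, _ = _cut_points(len(lb), False, rng)
        c1, c2 = la[:ca] + lb[cb:], lb[:cb] + la[ca:]
    else:  # two-point
        i1, i2 = _cut_points(len(la), True, rng)
        j1, j2 = _cut_points(len(lb), True, rng)
        c1 = la[:i1] + lb[j1:j2] + la[i2:]
        c2 = lb[:j1] + la[i1:i2] + lb[j2:]
    if not c1 or not c2:
        return a.copy(), b.copy()
    return ShapeletSet(c1), ShapeletSet(c2)


def _splice(s: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One- or two-point crossover of two value arrays at a cut common to
    both, drawn within the shorter length."""
    short = min(s.size, r.size)
    if rng.random() < 0.5:
        c = int(rng.integers(1, short)) if short >= 2 else 1
        return np.concatenate([s[:c], r[c:]])
    c1, c2 = sorted(int(rng.integers(0, short + 1)) for _ in range(2))
    return np.concatenate([s[:c1], r[c1:c2], s[c2:]])


def crossover_shapelet_point(
    a: ShapeletSet, b: ShapeletSet, rng: np.random.Generator
) -> tuple[ShapeletSet, ShapeletSet]:
    """Point crossover applied per shapelet rather than per set: each member
    of one parent is spliced with a uniformly chosen member of the other."""
    def spliced(src: ShapeletSet, other: ShapeletSet) -> ShapeletSet:
        out = []
        for s in src:
            r = other.shapelets[int(rng.integers(len(other)))]
            child = _splice(s.values, r.values, rng)
            if child.size < MIN_SHAPELET_LEN:
                child = s.values  # too short to splice; keep the original
            out.append(Shapelet(child))
        return ShapeletSet(out)

    return spliced(a, b), spliced(b, a)


def crossover_merge(
    a: ShapeletSet, b: ShapeletSet, rng: np.random.Generator
) -> tuple[ShapeletSet, ShapeletSet]:
    """Barycenter crossover: each member is averaged pointwise with a
    uniformly chosen member of the other parent. Unequal lengths average the
    shorter shapelet against a uniformly placed window of the longer one;
    the child keeps the shorter length."""
    def merged(src: ShapeletSet, other: ShapeletSet) -> ShapeletSet:
        out = []
        for s in src:
            r = other.shapelets[int(rng.integers(len(other)))]
            x, y = s.values, r.values
            if x.size > y.size:
                x, y = y, x
            off = int(rng.integers(0, y.size - x.size + 1))
            out.append(Shapelet((x + y[off : off + x.size]) / 2.0))
        return ShapeletSet(out)

    return merged(a, b), merged(b, a)


_CROSSOVER_FUNCS: dict[str, Callable] = {
    "set": crossover_set_point,
    "shapelet": crossover_shapelet_point,
    "merge": crossover_merge,
}


# ---------------------------------------------------------------- mutation

def mutate_mask(
    s_set: ShapeletSet, rng: np.random.Generator, min_len: int = MIN_SHAPELET_LEN
) -> ShapeletSet:
    """Trim m ~ Uniform[1, |s|//2] points off the start or end of one
    uniformly chosen shapelet; no-op when the trim would violate min_len."""
    idx = int(rng.integers(len(s_set)))
    s = s_set.shapelets[idx]
    hi = len(s) // 2
    if hi < 1:
        return s_set.copy()
    m = int(rng.integers(1, hi + 1))
    from_start = rng.random() < 0.5
    if len(s) - m < min_len:
        return s_set.copy()
    vals = s.values[m:] if from_start else s.values[:-m]
    members = list(s_set.shapelets)
    members[idx] = Shapelet(vals)
    return ShapeletSet(members)


def mutate_remove(s_set: ShapeletSet, rng: np.random.Generator) -> ShapeletSet:
    """Drop one uniformly chosen shapelet; no-op on singleton sets."""
    if len(s_set) <= 1:
        return s_set.copy()
    idx = int(rng.integers(len(s_set)))
    members = [s for i, s in enumerate(s_set.shapelets) if i != idx]
    return ShapeletSet(members)


def mutate_add(
    s_set: ShapeletSet,
    dataset: TimeSeriesDataset,
    rng: np.random.Generator,
    min_len: int = MIN_SHAPELET_LEN,
    max_len: Optional[int] = None,
) -> ShapeletSet:
    """Append one fresh random-subsequence shapelet (the growth operator)."""
    extra = init_random(dataset, 1, rng, min_len=min_len, max_len=max_len)
    return ShapeletSet(list(s_set.shapelets) + list(extra.shapelets))


# --------------------------------------------------------------- selection

def tournament_select(
    population: list[ShapeletSet],
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> ShapeletSet:
    """Sample ``tournament_size`` individuals without replacement and pick
    one with probability proportional to its reverse fitness rank (the best
    of a size-k tournament is picked with weight k, the worst with 1)."""
    k = min(config.tournament_size, len(population))
    idx = rng.choice(len(population), size=k, replace=False)
    entrants = [population[i] for i in idx]
    order = sorted(range(k), key=lambda i: entrants[i].fitness.as_tuple())
    weights = np.empty(k)
    for rank, i in enumerate(order):  # rank 0 = fittest
        weights[i] = k - rank
    pick = int(rng.choice(k, p=weights / weights.sum()))
    return entrants[pick]


# -------------------------------------------------------------------- loop

def evolve(
    dataset: TimeSeriesDataset,
    config: Optional[EvolutionConfig] = None,
    initial_population: Optional[list[ShapeletSet]] = None,
) -> tuple[ShapeletSet, EvolutionLog]:
    """Run the generational loop and return the elite set and its log.

    Each generation: select P parents by tournament, pair them consecutively,
    fire each enabled crossover independently with probability p_crossover
    and each enabled mutation independently with probability p_mutation on
    every offspring, evaluate what changed (fitness is cached by shapelet
    content), then inject the incumbent elite in place of the worst
    offspring. The elite is never crossed or mutated, so the best fitness
    trace is non-increasing. Stops at the generation cap, after ``patience``
    generations without strict improvement, or immediately if the elite's
    loss reaches zero ("converged").

    ``initial_population`` replaces the built-in initialization (used e.g.
    to seed a single-shapelet search); it is copied, not mutated in place.
    """
    config = (config or EvolutionConfig()).resolved(dataset)
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, FitnessValue] = {}
    n_evals = 0

    def ensure_evaluated(ind: ShapeletSet) -> None:
        nonlocal n_evals
        if ind.fitness is not None:
            return
        key = ind.content_key()
        fit = cache.get(key)
        if fit is None:
            fit = evaluate_fitness(ind, dataset)
            cache[key] = fit
            n_evals += 1
        ind.fitness = fit

    if initial_population is not None:
        population = [ind.copy() for ind in initial_population]
    else:
        population = initialize_population(dataset, config, rng)
    for ind in population:
        ensure_evaluated(ind)
    elite = min(population, key=lambda s: s.fitness.as_tuple()).copy()

    log = EvolutionLog()

    def record(gen: int) -> None:
        errors = [ind.fitness.error for ind in population]
        log.records.append(
            GenerationRecord(
                generation=gen,
                best_error=elite.fitness.error,
                best_complexity=elite.fitness.complexity,
                best_size=len(elite),
                mean_error=float(np.mean(errors)),
                evaluations=n_evals,
            )
        )

    record(0)
    xover_ops = [_CROSSOVER_FUNCS[name] for name in config.enabled_crossover]
    stagnant = 0
    for gen in range(1, config.generations + 1):
        parents = [
            tournament_select(population, config, rng).copy()
            for _ in range(config.population_size)
        ]
        offspring: list[ShapeletSet] = []
        for i in range(0, len(parents) - 1, 2):
            a, b = parents[i], parents[i + 1]
            for op in xover_ops:
                if rng.random() < config.p_crossover:
                    a, b = op(a, b, rng)
                    a.fitness = b.fitness = None
            offspring.extend([a, b])
        if len(parents) % 2:
            offspring.append(parents[-1])
        mutated: list[ShapeletSet] = []
        for child in offspring:
            for name in config.enabled_mutation:
                if rng.random() < config.p_mutation:
                    if name == "mask":
                        child = mutate_mask(child, rng, min_len=config.min_len)
                    elif name == "remove":
                        child = mutate_remove(child, rng)
                    else:
                        child = mutate_add(
                            child,
                            dataset,
                            rng,
                            min_len=config.min_len,
                            max_len=config.max_len,
                        )
                    child.fitness = None
            mutated.append(child)
        for child in mutated:
            ensure_evaluated(child)
        # elitism: the incumbent replaces the worst offspring
        worst = max(range(len(mutated)), key=lambda i: mutated[i].fitness.as_tuple())
        mutated[worst] = elite.copy()
        population = mutated
        challenger = min(population, key=lambda s: s.fitness.as_tuple())
        if challenger.fitness.as_tuple() < elite.fitness.as_tuple():
            elite = challenger.copy()
            stagnant = 0
        else:
            stagnant += 1
        record(gen)
        if elite.fitness.error <= 1e-12:
            log.stopping_reason = "converged"
            break
        if stagnant >= config.patience:
            log.stopping_reason = "patience"
            break
    else:
        log.stopping_reason = "max_generations"
    return elite, log
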