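"""End-to-end demonstration experiments, shared by the CLI, the examples
and the acceptance checks.

Two set pieces:

* the *imbalance* comparison — on a skewed three-class collection the
  set-based (dependent) evolutionary search with two shapelets separates
  all three classes, while the top-2 candidates ranked independently by
  information gain both isolate the easy majority class and leave the two
  minority classes indistinguishable;
* the *outside-the-data* demonstration — on the nested-amplitude four-series
  collection no subsequence of the inputs splits the classes by a distance
  threshold, but a single evolved shapelet (reachable as the barycenter of
  the two class-B bumps) does, with a positive margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import (
    best_split_accuracy,
    enumerate_candidates,
    top_k_independent,
)
from .classify import evaluate_accuracy, fit_tuned_lr
from .core import ShapeletSet, TimeSeriesDataset, distance_matrix, sliding_distance
from .engine import EvolutionConfig, evolve, init_kmeans, init_random
from .synthetic import make_imbalanced_three_class, make_nested_amplitude_two_class


def two_shapelet_config(
    seed: int | None = None,
    population_size: int = 50,
    generations: int = 60,
    patience: int = 10,
) -> EvolutionConfig:
    """Configuration that constrains the search to exactly two shapelets:
    initial sets have W = 2 members and only size-preserving operators
    (per-shapelet point crossover, barycenter merge, mask mutation) fire."""
    return EvolutionConfig(
        max_shapelets=2,
        population_size=population_size,
        generations=generations,
        patience=patience,
        enabled_crossover=("shapelet", "merge"),
        enabled_mutation=("mask",),
        seed=seed,
    )


@dataclass
class ImbalanceResult:
    genetic_accuracy: float
    independent_accuracy: float
    genetic_set: ShapeletSet
    independent_set: ShapeletSet
    minority_confusable: bool  # independent model confuses classes 1 and 2


def run_imbalance_comparison(
    seed: int = 0,
    population_size: int = 50,
    generations: int = 60,
) -> ImbalanceResult:
    """Dependent (set-based, 2 shapelets) vs independent top-2 comparison on
    the imbalanced 25/5/5 three-class collection."""
    train, test = make_imbalanced_three_class(seed=seed)

    cfg = two_shapelet_config(
        seed=seed + 1,
        population_size=population_size,
        generations=generations,
    )
    elite, _ = evolve(train, cfg)
    clf_dep = fit_tuned_lr(distance_matrix(elite, train), train.labels)
    acc_dep = evaluate_accuracy(clf_dep, elite, test)

    independent = top_k_independent(train, k=2)
    clf_ind = fit_tuned_lr(distance_matrix(independent, train), train.labels)
    acc_ind = evaluate_accuracy(clf_ind, independent, test)

    pred = clf_ind.predict(distance_matrix(independent, test))
    minority = np.isin(test.labels, [1, 2])
    confusable = float(np.mean(pred[minority] == test.labels[minority])) < 1.0
    return ImbalanceResult(
        genetic_accuracy=acc_dep,
        independent_accuracy=acc_ind,
        genetic_set=elite,
        independent_set=independent,
        minority_confusable=confusable,
    )


@dataclass
class OutsideDataResult:
    brute_force_split_accuracy: float  # best over ALL in-data subsequences
    evolved_split_accuracy: float      # best single evolved shapelet
    evolved_margin: float              # inter-class distance gap, > 0 if split
    evolved_shapelet: ShapeletSet = field(repr=False, default=None)
    evolved_distances: np.ndarray = field(repr=False, default=None)


def exhaustive_best_split(dataset: TimeSeriesDataset) -> float:
    """Best threshold-split training accuracy over every in-data candidate."""
    best = 0.0
    for cand in enumerate_candidates(dataset):
        d = [sliding_distance(cand, t) for t in dataset.series]
        best = max(best, best_split_accuracy(d, dataset.labels))
        if best == 1.0:
            break
    return best


def evolve_single_shapelet(
    dataset: TimeSeriesDataset,
    population_size: int = 50,
    generations: int = 60,
    patience: int = 15,
    seed: int | None = None,
) -> tuple[ShapeletSet, "object"]:
    """Single-shapelet variant of the search: the population holds singleton
    sets and only size-preserving operators fire, so the result is one
    shapelet rather than a set."""
    cfg = EvolutionConfig(
        max_shapelets=2,  # unused: the population below is supplied directly
        population_size=population_size,
        generations=generations,
        patience=patience,
        enabled_crossover=("shapelet", "merge"),
        enabled_mutation=("mask",),
        seed=seed,
    ).resolved(dataset)
    rng = np.random.default_rng(seed)
    population = []
    for i in range(population_size):
        op = init_kmeans if i % 2 == 0 else init_random
        population.append(
            op(dataset, 1, rng, min_len=cfg.min_len, max_len=cfg.max_len)
        )
    return evolve(dataset, cfg, initial_population=population)


def _split_margin(distances: np.ndarray, labels: np.ndarray) -> float:
    """Largest gap between the two classes' distance ranges (positive iff a
    threshold separates them perfectly)."""
    d0 = distances[labels == 0]
    d1 = distances[labels == 1]
    return float(max(d1.min() - d0.max(), d0.min() - d1.max()))


def run_outside_data_demo(
    seed: int = 0,
    population_size: int = 50,
    generations: int = 60,
) -> OutsideDataResult:
    """Exhaustive in-data search vs a single evolved shapelet on the
    nested-amplitude four-series collection."""
    data = make_nested_amplitude_two_class(seed=seed)
    brute = exhaustive_best_split(data)
    elite, _ = evolve_single_shapelet(
        data,
        population_size=population_size,
        generations=generations,
        seed=seed + 1,
    )
    d = np.array([sliding_distance(elite.shapelets[0], t) for t in data.series])
    return OutsideDataResult(
        brute_force_split_accuracy=brute,
        evolved_split_accuracy=best_split_accuracy(d, data.labels),
        evolved_margin=_split_margin(d, data.labels),
        evolved_shapelet=elite,
        evolved_distances=d,
    )
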