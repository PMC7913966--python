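"""Genetic-operator contracts, fitness semantics, and the generational loop."""

import numpy as np
import pytest

from shapevo import (
    EvolutionConfig,
    FitnessValue,
    Shapelet,
    ShapeletSet,
    TimeSeriesDataset,
    evaluate_fitness,
    evolve,
    init_kmeans,
    init_random,
    initialize_population,
)
from shapevo.engine import (
    ConfigError,
    crossover_merge,
    crossover_set_point,
    crossover_shapelet_point,
    mutate_add,
    mutate_mask,
    mutate_remove,
    tournament_select,
)


def _contains_verbatim(dataset, shapelet):
    from numpy.lib.stride_tricks import sliding_window_view

    L = len(shapelet)
    return any(
        t.size >= L
        and (np.abs(sliding_window_view(t, L) - shapelet.values) < 1e-15)
        .all(axis=1)
        .any()
        for t in dataset.series
    )


# ------------------------------------------------------------ initialization

def test_init_random_members_are_verbatim_subsequences(tiny_dataset, rng):
    S = init_random(tiny_dataset, 5, rng)
    assert len(S) == 5
    for s in S:
        assert 4 <= len(s) <= tiny_dataset.min_length
        assert _contains_verbatim(tiny_dataset, s)


def test_init_random_degenerate_length_range(tiny_dataset, rng):
    S = init_random(tiny_dataset, 4, rng, max_len=4)
    assert all(len(s) == 4 for s in S)


def test_init_random_deterministic_under_seed(tiny_dataset):
    a = init_random(tiny_dataset, 3, np.random.default_rng(9))
    b = init_random(tiny_dataset, 3, np.random.default_rng(9))
    assert a.content_key() == b.content_key()


def test_init_kmeans_k1_is_mean_of_draws(rng):
    # identical constant series: every subsequence is constant, so any
    # centroid must be that constant
    ds = TimeSeriesDataset([np.full(10, 2.5)] * 3, [0, 1, 0])
    S = init_kmeans(ds, 2, rng)
    assert len(S) == 2
    for s in S:
        assert np.allclose(s.values, 2.5)


def test_init_kmeans_common_length_and_count(tiny_dataset, rng):
    S = init_kmeans(tiny_dataset, 3, rng)
    lengths = {len(s) for s in S}
    assert len(S) == 3 and len(lengths) == 1
    assert 4 <= lengths.pop() <= tiny_dataset.min_length


def test_initialize_population_sizes_and_restriction(tiny_dataset, rng):
    cfg = EvolutionConfig(
        population_size=25, max_shapelets=3, enabled_init=("random",)
    ).resolved(tiny_dataset)
    pop = initialize_population(tiny_dataset, cfg, rng)
    assert len(pop) == 25
    for ind in pop:
        assert 2 <= len(ind) <= 3
        for s in ind:
            assert _contains_verbatim(tiny_dataset, s)


def test_initialize_population_w2_forces_pairs(tiny_dataset, rng):
    cfg = EvolutionConfig(population_size=10, max_shapelets=2).resolved(tiny_dataset)
    pop = initialize_population(tiny_dataset, cfg, rng)
    assert all(len(ind) == 2 for ind in pop)


def test_config_validation_errors(tiny_dataset):
    with pytest.raises(ConfigError):
        EvolutionConfig(population_size=1).validate()
    with pytest.raises(ConfigError):
        EvolutionConfig(p_mutation=1.5).validate()
    with pytest.raises(ConfigError):
        EvolutionConfig(max_len=200).resolved(tiny_dataset)
    with pytest.raises(ConfigError):
        EvolutionConfig(enabled_init=()).validate()
    with pytest.raises(ConfigError):
        EvolutionConfig(enabled_mutation=("shrink",)).validate()


# ------------------------------------------------------------------ fitness

def test_fitness_lexicographic_order():
    assert FitnessValue(0.1, 20) < FitnessValue(0.2, 10)
    assert FitnessValue(0.1, 10) < FitnessValue(0.1, 12)  # complexity breaks tie
    assert not FitnessValue(0.1, 10) < FitnessValue(0.1, 10)


def test_fitness_low_loss_on_separable_transform(motif_dataset):
    # a shapelet exactly matching each class motif yields a separable D;
    # scaling the series doubles the margin in distance units so the
    # ridge-penalized fit can be confident
    from shapevo.synthetic import _class_motif

    scaled = TimeSeriesDataset(
        [2 * t for t in motif_dataset.series], motif_dataset.labels.copy()
    )
    S = ShapeletSet(
        [Shapelet(2 * _class_motif(0, 8)), Shapelet(2 * _class_motif(1, 8))]
    )
    fit = evaluate_fitness(S, scaled)
    assert fit.error < 0.1
    assert fit.complexity == 16
    assert S.fitness == fit


def test_fitness_rejects_single_class():
    ds = TimeSeriesDataset([[0, 1, 2, 3], [1, 2, 3, 4]], [0, 0])
    with pytest.raises(ValueError, match="single-class"):
        evaluate_fitness(ShapeletSet([Shapelet([0, 1, 2, 3])]), ds)


def test_duplicated_shapelet_strictly_worsens_fitness(motif_dataset):
    from shapevo.synthetic import half_sine_bump

    base = ShapeletSet(
        [Shapelet(half_sine_bump(8, 1.5)), Shapelet(half_sine_bump(8, -1.5))]
    )
    doubled = ShapeletSet(list(base.shapelets) + [base.shapelets[0]])
    f1 = evaluate_fitness(base, motif_dataset)
    f2 = evaluate_fitness(doubled, motif_dataset)
    assert f2.error == pytest.approx(f1.error, abs=1e-12)
    assert f2.complexity > f1.complexity
    assert f1 < f2


# ---------------------------------------------------------------- crossover

def _mk(*lists):
    return ShapeletSet([Shapelet(x) for x in lists])


def test_set_crossover_conserves_multiset(rng):
    a = _mk([1, 1, 1, 1], [2, 2, 2, 2], [3, 3, 3, 3])
    b = _mk([4, 4, 4, 4], [5, 5, 5, 5])
    for _ in range(20):
        c, d = crossover_set_point(a, b, rng)
        assert sorted(s.values.tobytes() for s in list(c) + list(d)) == sorted(
            s.values.tobytes() for s in list(a) + list(b)
        )


def test_set_crossover_identity_on_identical_parents(rng):
    a = _mk([1, 2, 3, 4], [5, 6, 7, 8])
    for _ in range(10):
        c, d = crossover_set_point(a, a.copy(), rng)
        key = a.content_key()
        assert sorted(c.content_key() + d.content_key()) == sorted(key + key)


def test_set_crossover_one_point_cut_after_first():
    # force one-point (first uniform draw < 0.5) with cut 1 in both lists
    class FixedRng:
        def __init__(self):
            self.int_calls = 0

        def random(self):
            return 0.0  # one-point branch

        def integers(self, lo, hi=None):
            return 1  # cut after position 1 in each parent

    a = _mk([1, 1, 1, 1], [2, 2, 2, 2], [3, 3, 3, 3])
    b = _mk([4, 4, 4, 4], [5, 5, 5, 5])
    c, d = crossover_set_point(a, b, FixedRng())
    assert [s.values[0] for s in c] == [1, 5]
    assert [s.values[0] for s in d] == [4, 2, 3]


def test_shapelet_crossover_identity_and_bounds(rng):
    a = _mk([1, 1, 1, 1], [2, 2, 2, 2, 2, 2])
    b = _mk([9, 9, 9, 9, 9], [7, 7, 7, 7])
    for _ in range(30):
        c, d = crossover_shapelet_point(a, b, rng)
        for child in list(c) + list(d):
            assert 4 <= len(child) <= 6
    same, _ = crossover_shapelet_point(a, a.copy(), rng)
    for s, orig in zip(same, a):
        assert np.allclose(np.sort(np.unique(s.values)), np.sort(np.unique(orig.values)))


def test_shapelet_crossover_one_point_splice():
    class FixedRng:
        def random(self):
            return 0.0  # one-point

        def integers(self, lo, hi=None):
            return 0 if hi is None else 2  # member index 0, cut position 2

    a = _mk([1, 1, 1, 1])
    b = _mk([9, 9, 9, 9])
    c, _ = crossover_shapelet_point(a, b, FixedRng())
    assert list(c.shapelets[0].values) == [1, 1, 9, 9]


def test_merge_equal_lengths_is_pointwise_mean(rng):
    a = _mk([0, 2, 4, 6])
    b = _mk([2, 4, 6, 8])
    c, d = crossover_merge(a, b, rng)
    assert np.allclose(c.shapelets[0].values, [1, 3, 5, 7])
    assert np.allclose(d.shapelets[0].values, [1, 3, 5, 7])


def test_merge_idempotent_on_identical(rng):
    a = _mk([1.5, 2.5, 3.5, 4.5])
    c, _ = crossover_merge(a, a.copy(), rng)
    assert np.allclose(c.shapelets[0].values, a.shapelets[0].values)


def test_merge_unequal_lengths_keeps_shorter(rng):
    a = _mk([0, 0, 0, 0])
    b = _mk([4, 4, 4, 4, 4, 4, 4, 4])
    for _ in range(10):
        c, _ = crossover_merge(a, b, rng)
        assert len(c.shapelets[0]) == 4
        assert np.allclose(c.shapelets[0].values, 2.0)


# ----------------------------------------------------------------- mutation

def test_mask_noop_at_minimum_length(rng):
    s = _mk([1, 2, 3, 4])
    out = mutate_mask(s, rng)
    assert out.content_key() == s.content_key()


def test_mask_trims_verbatim(rng):
    s = _mk(list(range(10)))
    for _ in range(20):
        out = mutate_mask(s, rng)
        assert len(out) == 1
        vals = out.shapelets[0].values
        assert 4 <= vals.size <= 10
        # retained values are a contiguous run of the original
        joined = ",".join(str(int(v)) for v in vals)
        assert joined in ",".join(str(i) for i in range(10))


def test_remove_floor_and_contract(rng):
    single = _mk([1, 2, 3, 4])
    assert mutate_remove(single, rng).content_key() == single.content_key()
    five = _mk(*[[i] * 4 for i in range(5)])
    out = mutate_remove(five, rng)
    assert len(out) == 4
    assert set(out.content_key()) < set(five.content_key())
    assert out.complexity < five.complexity


def test_add_appends_verbatim_subsequence(tiny_dataset, rng):
    s = _mk([9, 9, 9, 9])
    out = mutate_add(s, tiny_dataset, rng)
    assert len(out) == 2
    assert out.shapelets[0] == s.shapelets[0]
    assert _contains_verbatim(tiny_dataset, out.shapelets[1])


# ---------------------------------------------------------------- selection

def test_tournament_size_one_returns_sample(rng):
    pop = [_mk([1, 2, 3, 4]), _mk([5, 6, 7, 8])]
    pop[0].fitness = FitnessValue(0.1, 4)
    pop[1].fitness = FitnessValue(0.9, 4)
    cfg = EvolutionConfig(tournament_size=1)
    picks = {tournament_select(pop, cfg, rng).content_key() for _ in range(50)}
    assert len(picks) == 2  # both get sampled


def test_tournament_rank_weights_two_to_one():
    pop = [_mk([1, 2, 3, 4]), _mk([5, 6, 7, 8])]
    pop[0].fitness = FitnessValue(0.1, 4)
    pop[1].fitness = FitnessValue(0.9, 4)
    cfg = EvolutionConfig(tournament_size=2)
    rng = np.random.default_rng(0)
    wins = sum(
        tournament_select(pop, cfg, rng).fitness.error == 0.1 for _ in range(10000)
    )
    assert abs(wins / 10000 - 2 / 3) < 0.02


# -------------------------------------------------------------------- loop

def test_evolve_fitness_trace_non_increasing(motif_dataset):
    cfg = EvolutionConfig(population_size=16, generations=12, patience=6, seed=11)
    elite, log = evolve(motif_dataset, cfg)
    trace = log.best_fitness_trace
    assert all(b <= a for a, b in zip(trace, trace[1:]))
    assert log.records[-1].best_error == elite.fitness.error


def test_evolve_reproducible_under_seed(motif_dataset):
    cfg = EvolutionConfig(population_size=12, generations=8, patience=5, seed=3)
    e1, l1 = evolve(motif_dataset, cfg)
    e2, l2 = evolve(motif_dataset, cfg)
    assert e1.content_key() == e2.content_key()
    assert l1.best_fitness_trace == l2.best_fitness_trace
    assert l1.stopping_reason == l2.stopping_reason


def test_evolve_respects_length_and_size_bounds(motif_dataset):
    cfg = EvolutionConfig(
        population_size=12, generations=10, patience=10, max_len=12, seed=2
    )
    elite, _ = evolve(motif_dataset, cfg)
    assert len(elite) >= 1
    for s in elite:
        assert 4 <= len(s) <= 12


def test_early_stopping_after_exact_patience_when_frozen(motif_dataset):
    # no variation operators: the population cannot improve, so the loop
    # must stop after exactly `patience` stagnant generations
    cfg = EvolutionConfig(
        population_size=8,
        generations=50,
        patience=4,
        seed=1,
        enabled_crossover=(),
        enabled_mutation=(),
    )
    _, log = evolve(motif_dataset, cfg)
    assert log.stopping_reason == "patience"
    assert log.records[-1].generation == 4


def test_evolve_improves_and_classifies_separable_data(motif_dataset):
    from shapevo import distance_matrix, evaluate_accuracy, fit_tuned_lr

    cfg = EvolutionConfig(population_size=25, generations=25, patience=10, seed=4)
    elite, log = evolve(motif_dataset, cfg)
    assert elite.fitness.error < log.records[0].best_error
    clf = fit_tuned_lr(distance_matrix(elite, motif_dataset), motif_dataset.labels)
    assert evaluate_accuracy(clf, elite, motif_dataset) == 1.0


def test_per_evaluation_cost_within_quadratic_bound(tiny_dataset):
    # pointwise-comparison count for one fitness evaluation is O(K*N*M^2)
    from shapevo.core import OP_COUNTER

    S = _mk([1, 2, 3, 4], [2, 3, 4, 5], [0, 1, 2, 3])
    OP_COUNTER["pointwise"] = 0
    evaluate_fitness(S, tiny_dataset)
    K, N = len(S), tiny_dataset.n_series
    M = max(t.size for t in tiny_dataset.series)
    assert OP_COUNTER["pointwise"] <= K * N * M * M
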