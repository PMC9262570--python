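"""Bee-colony optimizer: phases, fitness, selection, convergence."""

import numpy as np
import pytest
from scipy.stats import chisquare

from rlmdpa.abc_search import (ABCConfig, FitnessContext, FoodSource,
                               employed_phase, init_population,
                               mutate_coordinate, neighbor_solution,
                               onlooker_phase, roulette_select, run_abc,
                               scout_phase, selection_probabilities,
                               sphere_fitness)
from rlmdpa.exceptions import ConfigurationError, DimensionMismatchError
from rlmdpa.network import QNetwork


class TestInitialization:
    def test_coordinates_within_bounds(self):
        cfg = ABCConfig(colony_size=100, bounds=(-1.0, 1.0))
        pop = init_population(cfg, 10, np.random.default_rng(0), sphere_fitness)
        coords = np.concatenate([s.position for s in pop])
        assert coords.size == 1000
        assert np.all((coords >= -1.0) & (coords <= 1.0))
        assert all(s.trial == 0 for s in pop)

    def test_degenerate_bounds_give_all_zero_positions(self):
        cfg = ABCConfig(colony_size=5, bounds=(0.0, 0.0))
        pop = init_population(cfg, 4, np.random.default_rng(0), sphere_fitness)
        assert all(np.array_equal(s.position, np.zeros(4)) for s in pop)

    def test_seeded_initialization_is_reproducible(self):
        cfg = ABCConfig(colony_size=8)
        a = init_population(cfg, 6, np.random.default_rng(3), sphere_fitness)
        b = init_population(cfg, 6, np.random.default_rng(3), sphere_fitness)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.position, sb.position)


class TestNeighborSearch:
    def test_mutation_arithmetic(self):
        # v_j = s_j + phi (s_j - partner_j): 1 + 0.5 (1 - 0) = 1.5
        v = mutate_coordinate(np.array([1.0, 2.0]), np.array([0.0, 2.0]),
                              j=0, phi=0.5, bounds=(-2.0, 2.0))
        assert v[0] == 1.5 and v[1] == 2.0

    def test_candidates_leaving_bounds_are_clipped(self):
        v = mutate_coordinate(np.array([1.0]), np.array([0.0]),
                              j=0, phi=0.9, bounds=(-1.0, 1.0))
        assert v[0] == 1.0

    def test_identical_positions_give_identical_candidate(self):
        pop = [FoodSource(np.ones(5), 0.5), FoodSource(np.ones(5), 0.5)]
        v = neighbor_solution(pop, 0, np.random.default_rng(0), ABCConfig(colony_size=2))
        assert np.array_equal(v, np.ones(5))

    def test_candidate_differs_in_exactly_one_coordinate(self):
        rng = np.random.default_rng(1)
        pop = [FoodSource(rng.normal(size=8), 0.5) for _ in range(4)]
        for trial in range(50):
            i = trial % 4
            v = neighbor_solution(pop, i, rng, ABCConfig(colony_size=4))
            assert int(np.sum(v != pop[i].position)) <= 1

    def test_changed_coordinate_uniform_over_dimensions(self):
        rng = np.random.default_rng(2)
        dim = 10
        pop = [FoodSource(np.zeros(dim), 0.5), FoodSource(np.ones(dim), 0.5)]
        counts = np.zeros(dim)
        for _ in range(2000):
            v = neighbor_solution(pop, 0, rng, ABCConfig(colony_size=2))
            counts[int(np.argmax(v != pop[0].position))] += 1
        assert chisquare(counts).pvalue > 1e-3

    def test_single_source_population_rejected(self):
        with pytest.raises(ConfigurationError):
            neighbor_solution([FoodSource(np.zeros(2), 0.5)], 0,
                              np.random.default_rng(0), ABCConfig(colony_size=2))


class TestFitness:
    def test_perfect_classification_gives_fitness_one(self, tiny_arch):
        from rlmdpa.env import LabeledImageSet
        # zero network ties -> argmax 0 everywhere; all-zero labels are all correct
        data = LabeledImageSet(images=np.zeros((5, 16, 16)), labels=np.zeros(5, dtype=int))
        ctx = FitnessContext(data, tiny_arch)
        assert ctx(QNetwork.zeros(tiny_arch).encode().values) == 1.0

    def test_two_samples_both_wrong_gives_one_third(self, tiny_arch):
        from rlmdpa.env import LabeledImageSet
        images = np.zeros((2, 16, 16))
        data = LabeledImageSet(images=images, labels=np.array([1, 1]))
        # zero network ties -> argmax 0, both labels are 1: two misclassified
        ctx = FitnessContext(data, tiny_arch)
        assert ctx(np.zeros(tiny_arch.n_parameters)) == pytest.approx(1.0 / 3.0)

    def test_fitness_matches_independent_predict_and_count(self, tiny_arch, separable_set):
        ctx = FitnessContext(separable_set, tiny_arch)
        v = np.random.default_rng(7).uniform(-1, 1, tiny_arch.n_parameters)
        net = QNetwork.from_vector(v, tiny_arch)
        miscount = 0
        for img, label in zip(separable_set.images, separable_set.labels):
            q = net.forward(img[None])[0]
            miscount += int(np.argmax(q) != label)
        assert ctx(v) == pytest.approx(1.0 / (1.0 + miscount))

    def test_length_mismatch_raises(self, tiny_arch, separable_set):
        ctx = FitnessContext(separable_set, tiny_arch)
        with pytest.raises(DimensionMismatchError):
            ctx(np.zeros(3))


class TestSelection:
    def test_equal_fitness_gives_uniform_probabilities(self):
        pop = [FoodSource(np.zeros(1), 0.4) for _ in range(8)]
        assert np.allclose(selection_probabilities(pop), 1 / 8)

    def test_probabilities_proportional_to_fitness(self):
        pop = [FoodSource(np.zeros(1), 1.0), FoodSource(np.zeros(1), 1 / 3)]
        np.testing.assert_allclose(selection_probabilities(pop), [0.75, 0.25])

    def test_probabilities_normalize(self):
        rng = np.random.default_rng(0)
        pop = [FoodSource(np.zeros(1), float(f)) for f in rng.uniform(0.01, 1, 30)]
        assert abs(selection_probabilities(pop).sum() - 1.0) < 1e-12

    def test_roulette_frequency_matches_probability(self):
        pop = [FoodSource(np.zeros(1), 0.99), FoodSource(np.zeros(1), 0.01)]
        rng = np.random.default_rng(5)
        hits = sum(roulette_select(pop, rng) == 0 for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.99, abs=0.01)


class TestPhases:
    def test_worse_candidate_leaves_position_and_bumps_trial(self):
        pop = [FoodSource(np.array([0.1]), 0.9), FoodSource(np.array([0.2]), 0.9)]
        cfg = ABCConfig(colony_size=2)
        employed_phase(pop, np.random.default_rng(0), cfg, lambda v: 0.1)
        assert pop[0].fitness == 0.9 and pop[0].trial == 1

    def test_better_candidate_replaces_and_resets_trial(self):
        pop = [FoodSource(np.array([0.1]), 0.2, trial=3),
               FoodSource(np.array([0.9]), 0.2, trial=3)]
        cfg = ABCConfig(colony_size=2)
        employed_phase(pop, np.random.default_rng(0), cfg, lambda v: 0.95)
        assert pop[0].fitness == 0.95 and pop[0].trial == 0

    def test_phases_never_decrease_best_fitness(self):
        rng = np.random.default_rng(8)
        cfg = ABCConfig(colony_size=10, bounds=(-2.0, 2.0))
        pop = init_population(cfg, 5, rng, sphere_fitness)
        best = max(s.fitness for s in pop)
        for _ in range(5):
            employed_phase(pop, rng, cfg, sphere_fitness)
            onlooker_phase(pop, rng, cfg, sphere_fitness)
            new_best = max(s.fitness for s in pop)
            assert new_best >= best
            best = new_best

    def test_scout_ignores_sources_under_limit(self):
        cfg = ABCConfig(colony_size=2, limit=10)
        pop = [FoodSource(np.array([0.5]), 0.4, trial=2),
               FoodSource(np.array([0.6]), 0.4, trial=0)]
        before = [s.position.copy() for s in pop]
        scout_phase(pop, np.random.default_rng(0), cfg, sphere_fitness, dim=1)
        assert all(np.array_equal(a, s.position) for a, s in zip(before, pop))

    def test_scout_redraws_exhausted_source_within_bounds(self):
        cfg = ABCConfig(colony_size=2, limit=3, bounds=(-1.0, 1.0))
        pop = [FoodSource(np.array([5.0]), 0.01, trial=4),
               FoodSource(np.array([0.0]), 1.0, trial=0)]
        scout_phase(pop, np.random.default_rng(0), cfg, sphere_fitness, dim=1)
        assert pop[0].trial == 0
        assert -1.0 <= pop[0].position[0] <= 1.0


class TestRun:
    def test_budget_smaller_than_colony_rejected(self):
        with pytest.raises(ConfigurationError):
            run_abc(ABCConfig(colony_size=50, max_evaluations=10), sphere_fitness, dim=3)

    def test_history_is_non_decreasing(self):
        res = run_abc(ABCConfig(colony_size=10, max_evaluations=500),
                      sphere_fitness, dim=4, seed=3)
        assert np.all(np.diff(res.history) >= 0)

    def test_sphere_optimum_found(self):
        res = run_abc(ABCConfig(colony_size=20, max_evaluations=2000),
                      sphere_fitness, dim=3, seed=1)
        assert res.best_fitness >= 0.95

    def test_identical_seeds_give_identical_best_positions(self):
        cfg = ABCConfig(colony_size=10, max_evaluations=400)
        a = run_abc(cfg, sphere_fitness, dim=4, seed=9)
        b = run_abc(cfg, sphere_fitness, dim=4, seed=9)
        assert np.array_equal(a.best_position, b.best_position)
        assert a.best_fitness == b.best_fitness

    def test_zero_width_bounds_are_a_fixed_point(self):
        cfg = ABCConfig(colony_size=4, max_evaluations=100, bounds=(0.0, 0.0))
        res = run_abc(cfg, sphere_fitness, dim=3, seed=0)
        assert np.array_equal(res.best_position, np.zeros(3))
        assert res.best_fitness == 1.0  # the origin is the sphere optimum

    def test_final_fitness_at_least_initial_best_on_images(self, tiny_arch, separable_set):
        ctx = FitnessContext(separable_set, tiny_arch)
        cfg = ABCConfig(colony_size=6, max_evaluations=60)
        rng = np.random.default_rng(4)
        init_best = max(s.fitness for s in init_population(cfg, ctx.dimension, rng, ctx))
        res = run_abc(cfg, ctx, seed=4)
        assert res.best_fitness >= init_best
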