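"""Shared binary-search machinery and invariants of the ten update schemes."""

import numpy as np
import pytest

from budl import (
    ALGORITHMS,
    CostConfig,
    OptimizerConfig,
    benchmark_function,
    binarize,
    make_fitness,
    minimize_continuous,
    repair_mask,
    run_optimizer,
)
from budl.optimizers import (
    _FunctionObjective,
    initialize_population,
    update_population,
)


class TestBinarizeRepair:
    def test_strict_threshold_rule(self):
        assert binarize([0.2, 0.7, 0.5], 0.5).tolist() == [0, 1, 0]

    def test_extremes(self):
        assert binarize(np.ones(4)).tolist() == [1, 1, 1, 1]
        assert binarize(np.zeros(4)).tolist() == [0, 0, 0, 0]

    def test_repair_activates_one_bit_reproducibly(self):
        m1 = repair_mask(np.zeros(5, dtype=np.int8), np.random.default_rng(3))
        m2 = repair_mask(np.zeros(5, dtype=np.int8), np.random.default_rng(3))
        assert m1.sum() == 1
        assert np.array_equal(m1, m2)

    def test_repair_is_identity_on_nonempty(self):
        m = np.array([0, 1, 0], dtype=np.int8)
        assert np.array_equal(repair_mask(m, np.random.default_rng(0)), m)


class TestConfig:
    def test_unknown_algorithm_lists_valid_names(self):
        with pytest.raises(ValueError, match="mpa.*pro"):
            OptimizerConfig(algorithm="simulated-annealing")

    def test_degenerate_run_is_valid(self, small_table, small_split, small_fitness):
        table, _ = small_table
        cfg = OptimizerConfig(algorithm="eo", population_size=2, max_iterations=1, seed=0)
        res = run_optimizer(table, small_split, CostConfig(), cfg, fitness=small_fitness)
        assert len(res.trace) == 1
        assert 1 <= res.n_selected <= table.n_features


class TestInitialization:
    def test_deterministic_and_best_is_min(self):
        sphere = benchmark_function("sphere")
        cfg = OptimizerConfig(algorithm="eo", population_size=10, seed=9)
        obj1 = _FunctionObjective(sphere)
        pos1, costs1 = initialize_population(5, cfg, obj1, np.random.default_rng(9))
        obj2 = _FunctionObjective(sphere)
        pos2, costs2 = initialize_population(5, cfg, obj2, np.random.default_rng(9))
        assert np.array_equal(pos1, pos2)
        assert obj1.best_cost == costs1.min()


@pytest.mark.parametrize("algorithm", ALGORITHMS)
class TestSchemeInvariants:
    """Elitism, box bounds, mask repair, determinism — per algorithm."""

    def test_bounds_and_elitism_iteration_by_iteration(self, algorithm):
        sphere = benchmark_function("sphere")
        cfg = OptimizerConfig(algorithm=algorithm, population_size=6, max_iterations=20, seed=2)
        obj = _FunctionObjective(sphere)
        rng = np.random.default_rng(2)
        pos, costs = initialize_population(8, cfg, obj, rng)
        aux = {}
        prev_best = obj.best_cost
        for t in range(1, 21):
            pos, costs = update_population(algorithm, pos, costs, aux, t, 20, rng, obj, 0.0, 1.0)
            assert np.all(pos >= 0.0) and np.all(pos <= 1.0)
            assert obj.best_cost <= prev_best
            prev_best = obj.best_cost

    def test_descent_on_sphere(self, algorithm):
        sphere = benchmark_function("sphere")
        cfg = OptimizerConfig(algorithm=algorithm, population_size=10, max_iterations=100, seed=4)
        res = minimize_continuous(sphere, 10, cfg)
        # strict improvement over the best of the initial uniform population
        init = np.random.default_rng(4).random((10, 10))
        init_best = min(float(np.sum(x * x)) for x in init)
        assert res.best_value < init_best
        assert res.best_value <= res.trace.best_cost[0]
        assert res.trace.is_monotone

    def test_deterministic_selection_run(self, algorithm, small_table, small_split):
        table, _ = small_table
        cfg = OptimizerConfig(algorithm=algorithm, population_size=6, max_iterations=10, seed=5)
        runs = []
        for _ in range(2):
            fit = make_fitness(table, small_split)  # fresh cache each run
            runs.append(run_optimizer(table, small_split, CostConfig(), cfg, fitness=fit))
        a, b = runs
        assert a.trace.best_cost == b.trace.best_cost
        assert np.array_equal(a.best_mask, b.best_mask)
        assert a.best_cost == b.best_cost

    def test_no_empty_mask_is_ever_scored(self, algorithm, small_table, small_split):
        table, _ = small_table
        fit = make_fitness(table, small_split)
        seen = []

        class Spy:
            n_features = fit.n_features

            def __call__(self, mask):
                seen.append(int(np.asarray(mask).sum()))
                return fit(mask)

        cfg = OptimizerConfig(algorithm=algorithm, population_size=6, max_iterations=8, seed=6)
        run_optimizer(table, small_split, CostConfig(), cfg, fitness=Spy())
        assert seen and min(seen) >= 1


class TestSelectionRun:
    def test_reduces_features_and_beats_baseline(self, small_table, small_split, small_fitness):
        table, _ = small_table
        full = small_fitness(np.ones(table.n_features, dtype=bool))
        cfg = OptimizerConfig(algorithm="eo", population_size=10, max_iterations=50, seed=1)
        res = run_optimizer(table, small_split, CostConfig(), cfg, fitness=small_fitness)
        assert res.n_selected < table.n_features
        assert res.best_accuracy >= full.accuracy
        assert res.best_cost == pytest.approx(
            0.99 * (1 - res.best_accuracy) + 0.01 * res.n_selected / table.n_features,
            abs=1e-12,
        )
        assert res.n_selected == int(res.best_mask.sum())

    def test_selected_feature_ids_match_mask(self, small_table, small_split, small_fitness):
        table, _ = small_table
        cfg = OptimizerConfig(algorithm="mpa", population_size=6, max_iterations=10, seed=2)
        res = run_optimizer(table, small_split, CostConfig(), cfg, fitness=small_fitness)
        ids = res.selected_feature_ids
        assert len(ids) == res.n_selected
        assert set(ids) <= set(table.feature_ids)
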