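"""Evolutionary optimizer: selection machinery and toy-problem checks."""

import numpy as np
import pytest

from stellate.optimize import (
    Individual,
    OptimizerConfig,
    ParameterSpace,
    hypervolume_2d,
    optimize,
    pareto_front,
    sc_parameter_space,
    select_best,
)


def _toy_space(n=2):
    return ParameterSpace(
        names=tuple(f"x{i}" for i in range(n)),
        low=np.full(n, 1e-3),
        high=np.full(n, 10.0),
    )


def _biobjective(genome):
    """Classic convex front: f1 = x0, f2 = 1/x0 (x in log space).

    The Pareto front is the whole curve f2 = 1/f1; any point off the
    curve (from x1 interfering) is dominated.
    """
    x = genome[0]
    penalty = abs(np.log10(genome[1]))  # x1 should go to 1
    return np.array([x + penalty, 1.0 / x + penalty]), {}


class TestParameterSpace:
    def test_sc_space_has_36_dimensions(self):
        space = sc_parameter_space(np.full(36, 1e-3), span=2.0)
        assert space.n == 36
        np.testing.assert_allclose(space.high / space.low, 4.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace(("a",), np.array([0.0]), np.array([1.0]))


class TestSelection:
    def test_pareto_front_minimal_example(self):
        inds = [
            Individual(np.array([1.0]), np.array([1.0, 4.0])),
            Individual(np.array([2.0]), np.array([2.0, 2.0])),
            Individual(np.array([3.0]), np.array([4.0, 1.0])),
            Individual(np.array([4.0]), np.array([3.0, 3.0])),  # dominated
        ]
        front = pareto_front(inds)
        assert inds[3] not in front
        assert len(front) == 3

    def test_select_best_tie_broken_by_total_conductance(self):
        a = Individual(np.array([5.0, 5.0]), np.array([1.0, 1.0]))
        b = Individual(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert select_best([a, b], n=1)[0] is b

    def test_select_best_empty_archive_rejected(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_hypervolume_known_value(self):
        pts = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        # ref (4,4): strips of width (4-1)*(4-3) + (4-2)*(3-2) + (4-3)*(2-1)
        assert hypervolume_2d(pts, (4.0, 4.0)) == pytest.approx(3 + 2 + 1)


class TestToyOptimization:
    @pytest.mark.parametrize("algorithm", ["ibea", "nsga2"])
    def test_front_approaches_analytic_curve(self, algorithm):
        space = _toy_space()
        cfg = OptimizerConfig(population=24, generations=20, seed=5,
                              algorithm=algorithm)
        res = optimize(space, cfg, _biobjective)
        # the best compromise approaches min_x (x + 1/x) = 2 at x = 1
        assert res.best.total_error <= 2.3
        # most central archive points lie near the analytic curve f2 = 1/f1
        central = [
            ind.objectives for ind in res.archive if 0.2 <= ind.objectives[0] <= 5.0
        ]
        assert central
        near = [f1 * f2 < 1.3 for f1, f2 in central]
        assert np.mean(near) >= 0.7

    def test_best_error_monotone_over_generations(self):
        space = _toy_space()
        cfg = OptimizerConfig(population=16, generations=12, seed=3)
        res = optimize(space, cfg, _biobjective)
        best = np.array(res.best_per_generation)
        assert np.all(np.diff(best) <= 1e-12)

    def test_same_seed_reproducible(self):
        space = _toy_space()
        cfg = OptimizerConfig(population=10, generations=5, seed=11)
        a = optimize(space, cfg, _biobjective)
        b = optimize(space, cfg, _biobjective)
        np.testing.assert_array_equal(a.best.genome, b.best.genome)

    def test_hypervolume_non_decreasing(self):
        space = _toy_space()
        cfg = OptimizerConfig(population=16, generations=10, seed=2)
        hv = []

        def track(gen, res):
            pts = np.array([i.objectives for i in res.archive])
            hv.append(hypervolume_2d(pts, (50.0, 50.0)))

        optimize(space, cfg, _biobjective, progress=track)
        assert all(b >= a - 1e-9 for a, b in zip(hv, hv[1:]))

    def test_all_failures_abort(self):
        space = _toy_space()
        cfg = OptimizerConfig(population=4, generations=2, seed=0)

        def failing(genome):
            return np.full(2, 250.0), {}

        with pytest.raises(RuntimeError):
            optimize(space, cfg, failing)

    def test_checkpoints_written(self, tmp_path):
        space = _toy_space()
        cfg = OptimizerConfig(population=6, generations=3, seed=1,
                              checkpoint_dir=str(tmp_path))
        optimize(space, cfg, _biobjective)
        files = sorted(p.name for p in tmp_path.iterdir())
        assert files == ["gen0001.json", "gen0002.json", "gen0003.json"]
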