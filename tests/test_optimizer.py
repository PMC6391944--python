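"""Complex-method search: initialization, reflection geometry, loop
invariants, and oracle agreement on analytic surfaces."""

import numpy as np
import pytest

from flowopt import OptimizerConfig, init_complex, reflect_worst
from flowopt import optimizer as opt
from flowopt.space import ParameterSpace, reaction_space

SPACE_1D = ParameterSpace(("x",), np.array([0.0]), np.array([1.0]))
TRAMADOL_SPACE = reaction_space((30.0, 70.0), (5.0, 20.0), (0.5, 1.6))


def test_init_complex_inside_bounds_and_deterministic():
    config = OptimizerConfig(n_vertices=2, seed=11)
    points = init_complex(SPACE_1D, config)
    assert points.shape == (2, 1)
    assert np.all(points > 0.0) and np.all(points < 1.0)
    assert abs(points[0, 0] - points[1, 0]) > 1e-12
    again = init_complex(SPACE_1D, OptimizerConfig(n_vertices=2, seed=11))
    np.testing.assert_array_equal(points, again)


def test_init_complex_covers_reaction_ranges():
    config = OptimizerConfig(n_vertices=4, seed=0)
    points = init_complex(TRAMADOL_SPACE, config)
    assert points.shape == (4, 3)
    for point in points:
        assert TRAMADOL_SPACE.contains(point)


def test_init_complex_rejects_too_few_vertices():
    with pytest.raises(ValueError):
        init_complex(TRAMADOL_SPACE, OptimizerConfig(n_vertices=3, seed=0))


def test_reflection_arithmetic_with_bound_clipping():
    """1-D: worst 0.2, other 0.6, alpha 1.3 -> 1.12, clipped to 0.99."""
    config = OptimizerConfig(reflection_factor=1.3, bound_inset=0.01)
    vertices = np.array([[0.2], [0.6]])
    new = reflect_worst(vertices, [0.1, 0.9], SPACE_1D, config)
    assert new[0] == pytest.approx(0.99)


def test_reflection_of_worst_at_centroid_is_identity():
    space = ParameterSpace(("a", "b"), np.zeros(2), np.ones(2))
    vertices = np.array([[0.5, 0.5], [0.4, 0.6], [0.6, 0.4]])  # worst = centroid of rest
    new = reflect_worst(vertices, [0.0, 1.0, 1.0], space, OptimizerConfig())
    np.testing.assert_allclose(new, [0.5, 0.5])


def test_reflection_moves_along_the_diagonal_ray():
    """2-D square: worst at a corner, centroid at center -> reflected point
    lies on the ray toward the opposite corner."""
    space = ParameterSpace(("a", "b"), np.zeros(2), np.ones(2))
    vertices = np.array([[0.0, 0.0], [0.4, 0.6], [0.6, 0.4]])
    new = reflect_worst(vertices, [0.0, 1.0, 1.0], space, OptimizerConfig())
    direction = new - np.array([0.5, 0.5])
    assert direction[0] == pytest.approx(direction[1])
    assert direction[0] > 0


def test_degenerate_complex_is_detected():
    vertices = np.array([[0.5], [0.5], [0.5]])
    with pytest.raises(opt.DegenerateComplexError):
        reflect_worst(vertices, [0.0, 0.0, 0.0], SPACE_1D, OptimizerConfig())


def test_budget_smaller_than_complex_is_an_error():
    with pytest.raises(opt.BudgetError):
        opt.run(SPACE_1D, lambda x: (None, 0.0), OptimizerConfig(n_vertices=4, max_evaluations=3))


def _noisy_bowl(rng):
    center = np.array([50.0, 12.0, 1.0])

    def evaluate(x):
        z = (x - center) / TRAMADOL_SPACE.range
        return None, 1.0 - float(z @ z) + rng.normal(0.0, 0.005)

    return evaluate


def test_trace_containment_and_monotone_running_best():
    """Every evaluated point stays in the box; the running best never drops."""
    rng = np.random.default_rng(5)
    result = opt.run(TRAMADOL_SPACE, _noisy_bowl(rng), OptimizerConfig(seed=5))
    assert result.n_evaluations == len(result.trace) <= 40
    for entry in result.trace:
        assert TRAMADOL_SPACE.contains(entry.point)
    best = result.running_best
    assert np.all(np.diff(best) >= 0)
    assert result.best_score == pytest.approx(best[-1])


def test_fixed_budget_runs_are_bit_reproducible():
    """conv_rel_tol=0 with a fixed budget: same seed, bit-identical traces."""

    def noiseless(x):
        z = (x - TRAMADOL_SPACE.lower) / TRAMADOL_SPACE.range
        return None, float(z.sum())

    config = OptimizerConfig(seed=123, conv_rel_tol=0.0, max_evaluations=30)
    first = opt.run(TRAMADOL_SPACE, noiseless, config)
    second = opt.run(TRAMADOL_SPACE, noiseless, config)
    assert first.n_evaluations == second.n_evaluations == 30
    for a, b in zip(first.trace, second.trace):
        np.testing.assert_array_equal(a.point, b.point)
        assert a.score == b.score


def test_concave_quadratic_recovers_the_interior_maximum():
    """Noiseless concave bowl: median returned point within 2% of range of
    the center (fixed-budget configuration resolves that displacement)."""
    center = (TRAMADOL_SPACE.lower + TRAMADOL_SPACE.upper) / 2

    def bowl(x):
        z = (x - center) / TRAMADOL_SPACE.range
        return None, 1.0 - float(z @ z)

    errs = []
    for seed in range(1, 21):
        config = OptimizerConfig(seed=seed, conv_rel_tol=0.0, max_evaluations=100)
        result = opt.run(TRAMADOL_SPACE, bowl, config)
        errs.append(np.abs(result.best_point - center) / TRAMADOL_SPACE.range)
    assert np.all(np.median(errs, axis=0) <= 0.02)


def test_monotone_objective_drives_to_the_upper_corner():
    """Coordinate-wise increasing objective: best point ends within the
    bound inset of the favored corner in every coordinate."""

    def mono(x):
        z = (x - TRAMADOL_SPACE.lower) / TRAMADOL_SPACE.range
        return None, float(z.sum())

    errs = []
    for seed in range(1, 11):
        config = OptimizerConfig(seed=seed, conv_rel_tol=0.0, max_evaluations=100)
        result = opt.run(TRAMADOL_SPACE, mono, config)
        errs.append((TRAMADOL_SPACE.upper - result.best_point) / TRAMADOL_SPACE.range)
    med = np.median(errs, axis=0)
    assert np.all(med <= OptimizerConfig().bound_inset + 1e-9)


def test_calibrated_tramadol_matches_grid_oracle(calibrated):
    """Noiseless search on the calibrated problem reaches the exhaustive
    41^3 grid-search maximum within 2% (median over seeds)."""
    from flowopt import grid_argmax

    cal = calibrated("tramadol")
    _point, grid_best = grid_argmax(cal.kinetics, cal.reactor, cal.objective)
    rels = []
    for seed in range(1, 21):
        config = OptimizerConfig(seed=seed, conv_rel_tol=0.0, max_evaluations=100)
        result = opt.run(cal.campaign.space, cal.make_evaluator(noisy=False), config)
        rels.append(abs(result.best_score - grid_best) / grid_best)
    assert np.median(rels) <= 0.02
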