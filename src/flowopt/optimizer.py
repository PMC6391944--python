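"""Bounded derivative-free search with the complex method (Box, 1965).

The algorithm maintains k candidate points ("the complex") inside a
bounded box.  Each iteration reflects the worst-scoring vertex through the
centroid of the remaining vertices by a factor alpha > 1, clipping the
result just inside the bounds.  If the reflected point is still the worst
it retreats toward the centroid by successive halvings; after
``max_retreats`` failed halvings the vertex is re-drawn uniformly at
random, which keeps the search alive on noisy objectives.  The loop stops
when the relative spread of the vertex scores falls below a tolerance or
the evaluation budget is exhausted.

The optimizer is a pure search kernel: it never re-evaluates or averages
noisy objectives - smoothing is the process-control layer's job - and all
randomness flows through one explicitly seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .space import ParameterSpace


class DegenerateComplexError(RuntimeError):
    """All vertices coincide: the reflection direction is undefined."""


class BudgetError(ValueError):
    """The evaluation budget cannot even score the initial complex."""


@dataclass(frozen=True)
class OptimizerConfig:
    """Tuning knobs of the complex search.

    ``n_vertices=None`` resolves to dimension+1, small enough that campaign
    experiment counts land in the single digits to low tens, matching how
    few trials a flow rig can afford.
    """

    n_vertices: int | None = None
    reflection_factor: float = 1.3
    bound_inset: float = 0.01
    max_retreats: int = 3
    conv_rel_tol: float = 0.01
    max_evaluations: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reflection_factor <= 1.0:
            raise ValueError("reflection_factor must exceed 1")
        if not 0.0 <= self.bound_inset < 0.5:
            raise ValueError("bound_inset must lie in [0, 0.5)")
        if self.max_retreats < 0:
            raise ValueError("max_retreats must be non-negative")
        if self.conv_rel_tol < 0:
            raise ValueError("conv_rel_tol must be non-negative")

    def resolve_k(self, dimension: int) -> int:
        k = self.n_vertices if self.n_vertices is not None else dimension + 1
        if k < dimension + 1:
            raise ValueError(f"n_vertices must be at least dimension+1 ({dimension + 1}), got {k}")
        return k


@dataclass(frozen=True)
class TraceEntry:
    """One objective evaluation: the point, the sensor payload, the score."""

    point: np.ndarray
    reading: Any
    score: float


@dataclass(frozen=True)
class OptimizationResult:
    best_point: np.ndarray
    best_score: float
    n_evaluations: int
    converged: bool
    trace: tuple[TraceEntry, ...] = field(repr=False)

    @property
    def running_best(self) -> np.ndarray:
        """Best score so far after each evaluation (non-decreasing)."""
        return np.maximum.accumulate([e.score for e in self.trace])


def init_complex(
    space: ParameterSpace,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial complex: k points sampled uniformly per coordinate, inside the box."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.resolve_k(space.dimension)
    return space.sample(rng, k)


def _worst_index(scores: Sequence[float]) -> int:
    # Lowest score; ties broken by earliest insertion order (np.argmin does both).
    return int(np.argmin(scores))


def reflect_worst(
    vertices: np.ndarray,
    scores: Sequence[float],
    space: ParameterSpace,
    config: OptimizerConfig,
) -> np.ndarray:
    """Reflect the worst vertex through the centroid of the rest, clipped inward."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != space.dimension:
        raise ValueError("vertices must be a (k, dimension) array matching the space")
    if len(scores) != len(vertices) or len(vertices) < 2:
        raise ValueError("need at least two scored vertices")
    if np.all(np.ptp(vertices, axis=0) < 1e-12 * np.maximum(space.range, 1.0)):
        raise DegenerateComplexError("all vertices coincide")
    worst = _worst_index(scores)
    centroid = np.mean(np.delete(vertices, worst, axis=0), axis=0)
    reflected = centroid + config.reflection_factor * (centroid - vertices[worst])
    return space.clip_inset(reflected, config.bound_inset)


def _spread(scores: np.ndarray) -> float:
    best = float(np.max(scores))
    worst = float(np.min(scores))
    return (best - worst) / max(abs(best), 1e-12)


def run(
    space: ParameterSpace,
    evaluate: Callable[[np.ndarray], tuple[Any, float]],
    config: OptimizerConfig,
) -> OptimizationResult:
    """Drive the complex method over the box until convergence or budget.

    ``evaluate`` maps a point (ndarray) to a ``(reading, score)`` pair; one
    call is one simulated experiment and one trace row.
    """
    rng = np.random.default_rng(config.seed)
    k = config.resolve_k(space.dimension)
    if config.max_evaluations < k:
        raise BudgetError(
            f"budget {config.max_evaluations} cannot score the initial complex of {k}"
        )
    trace: list[TraceEntry] = []

    def score_point(x: np.ndarray) -> float:
        reading, s = evaluate(x)
        trace.append(TraceEntry(point=x.copy(), reading=reading, score=float(s)))
        return float(s)

    vertices = space.sample(rng, k)
    scores = np.array([score_point(v) for v in vertices])
    converged = _spread(scores) < config.conv_rel_tol

    while not converged and len(trace) < config.max_evaluations:
        worst = _worst_index(scores)
        try:
            candidate = reflect_worst(vertices, scores, space, config)
        except DegenerateComplexError:
            candidate = space.sample(rng, 1)[0]
        centroid = np.mean(np.delete(vertices, worst, axis=0), axis=0)
        cand_score = score_point(candidate)
        retreats = 0
        # Retreat halfway toward the centroid while the candidate is still the
        # worst of the complex; after max_retreats, re-draw that vertex.
        while (
            cand_score <= np.min(scores)
            and retreats < config.max_retreats
            and len(trace) < config.max_evaluations
        ):
            candidate = space.clip_inset(0.5 * (candidate + centroid), config.bound_inset)
            cand_score = score_point(candidate)
            retreats += 1
        if cand_score <= np.min(scores) and len(trace) < config.max_evaluations:
            candidate = space.sample(rng, 1)[0]
            cand_score = score_point(candidate)
        vertices[worst] = candidate
        scores[worst] = cand_score
        converged = _spread(scores) < config.conv_rel_tol

    best = int(np.argmax([e.score for e in trace]))
    return OptimizationResult(
        best_point=trace[best].point.copy(),
        best_score=trace[best].score,
        n_evaluations=len(trace),
        converged=bool(converged),
        trace=tuple(trace),
    )
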