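"""Bounded parameter spaces and reactor operating points.

A :class:`ParameterSpace` is an axis-aligned box with named, unit-labelled
coordinates; the search and evaluation layers treat it as the feasible region.
:class:`OperatingPoint` is the chemistry-facing view of a point in the
canonical three-parameter space (temperature, residence time, equivalents).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical coordinate order for three-parameter reaction condition spaces.
CANONICAL_NAMES = ("temperature", "residence_time", "equivalents")


@dataclass(frozen=True)
class ParameterSpace:
    """Axis-aligned box of admissible operating conditions."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        units = tuple(self.units) if self.units else ("",) * len(self.names)
        object.__setattr__(self, "units", units)
        if len(self.names) < 1:
            raise ValueError("parameter space needs at least one dimension")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"parameter names must be unique: {self.names}")
        if lower.shape != (len(self.names),) or upper.shape != (len(self.names),):
            raise ValueError("bounds must match the number of parameter names")
        if len(units) != len(self.names):
            raise ValueError("units must match the number of parameter names")
        bad = [n for n, lo, hi in zip(self.names, lower, upper) if not lo < hi]
        if bad:
            raise ValueError(f"lower bound must be strictly below upper for: {bad}")

    @property
    def dimension(self) -> int:
        return len(self.names)

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol))

    def clip_inset(self, x: np.ndarray, inset: float) -> np.ndarray:
        """Clip out-of-bounds coordinates to ``bound +/- inset * range`` (inward)."""
        x = np.asarray(x, dtype=float).copy()
        pad = inset * self.range
        low = x < self.lower
        high = x > self.upper
        x[low] = (self.lower + pad)[low]
        x[high] = (self.upper - pad)[high]
        return x

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """``n`` points sampled uniformly per coordinate, strictly inside the box."""
        u = rng.uniform(size=(n, self.dimension))
        return self.lower + u * self.range

    def grid(self, n: int) -> list[np.ndarray]:
        """Per-axis arrays of ``n`` evenly spaced values spanning the box."""
        return [np.linspace(lo, hi, n) for lo, hi in zip(self.lower, self.upper)]


def reaction_space(
    t_bounds: tuple[float, float],
    tau_bounds: tuple[float, float],
    x_bounds: tuple[float, float],
) -> ParameterSpace:
    """The canonical (temperature, residence time, equivalents) box."""
    lower = np.array([t_bounds[0], tau_bounds[0], x_bounds[0]], dtype=float)
    upper = np.array([t_bounds[1], tau_bounds[1], x_bounds[1]], dtype=float)
    return ParameterSpace(CANONICAL_NAMES, lower, upper, ("degC", "min", "equiv"))


@dataclass(frozen=True)
class OperatingPoint:
    """One candidate reaction condition: T (degC), residence time tau (min), equivalents x."""

    temperature: float
    residence_time: float
    equivalents: float

    def __post_init__(self) -> None:
        if self.residence_time <= 0:
            raise ValueError("residence_time must be positive")
        if self.equivalents <= 0:
            raise ValueError("equivalents must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.temperature, self.residence_time, self.equivalents])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "OperatingPoint":
        t, tau, eq = np.asarray(x, dtype=float)
        return cls(float(t), float(tau), float(eq))
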