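"""Evaluation functions: scalar scores from IR feedback and operating conditions.

The score E multiplies a conversion factor with optional throughput,
reagent-consumption and energy factors, each normalized by the parameter
space so that every factor - and hence E - lies in (0, 1]:

    E = c^w_c * (tau_min/tau)^w_tau * (x_min/x)^w_x
        * (1 - gamma*(T - T_lo)/(T_hi - T_lo))^w_T

where c = p/(p+s) is the IR peak-ratio conversion estimate, tau the
residence time, x the reagent equivalents and T the reactor temperature.
Omitting a term sets its factor to 1.  Conversion is always present:
optimizing throughput or energy alone would reward making no product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .campaigns import get_campaign
from .space import OperatingPoint, ParameterSpace

VALID_TERMS = ("conversion", "throughput", "consumption", "energy")


class NoSignalError(ValueError):
    """Raised when both monitored IR bands read zero absorbance."""


@dataclass(frozen=True)
class IRReading:
    """Product (p) and starting-material (s) absorbances at their monitored bands."""

    p: float
    s: float
    wavenumber_p: float = float("nan")
    wavenumber_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.p < 0 or self.s < 0:
            raise ValueError(f"absorbances must be non-negative, got p={self.p}, s={self.s}")


def conversion(reading: IRReading) -> float:
    """Peak-ratio conversion estimate c = p / (p + s), in [0, 1]."""
    total = reading.p + reading.s
    if total <= 0.0:
        raise NoSignalError("no IR signal: both monitored absorbances are zero")
    return reading.p / total


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which evaluation terms are active, their exponents, and the normalizing space."""

    space: ParameterSpace
    terms: frozenset[str]
    weights: dict[str, float] = field(default_factory=dict)
    energy_gamma: float = 0.3

    def __post_init__(self) -> None:
        unknown = set(self.terms) - set(VALID_TERMS)
        if unknown:
            raise ValueError(f"unknown objective terms: {sorted(unknown)}")
        if "conversion" not in self.terms:
            raise ValueError("the conversion term must always be active")
        if not 0.0 <= self.energy_gamma < 1.0:
            raise ValueError("energy_gamma must lie in [0, 1)")
        bad = [t for t, w in self.weights.items() if w <= 0]
        if bad:
            raise ValueError(f"term exponents must be positive: {bad}")
        if self.space.dimension != 3:
            raise ValueError("objective normalization requires the 3-parameter reaction space")

    def weight(self, term: str) -> float:
        return float(self.weights.get(term, 1.0))


def evaluate(spec: ObjectiveSpec, point: OperatingPoint, reading: IRReading) -> float:
    """Score E in [0, 1] for one experiment; higher is better."""
    x = point.as_array()
    if not spec.space.contains(x, atol=1e-9):
        raise ValueError(f"operating point {x} outside the parameter box")
    c = conversion(reading)
    t_lo, tau_min, x_min = spec.space.lower
    t_hi = spec.space.upper[0]
    score = c ** spec.weight("conversion")
    if "throughput" in spec.terms:
        score *= (tau_min / point.residence_time) ** spec.weight("throughput")
    if "consumption" in spec.terms:
        score *= (x_min / point.equivalents) ** spec.weight("consumption")
    if "energy" in spec.terms:
        frac = (point.temperature - t_lo) / (t_hi - t_lo)
        score *= (1.0 - spec.energy_gamma * frac) ** spec.weight("energy")
    return float(score)


def evaluate_grid(
    spec: ObjectiveSpec,
    c: np.ndarray,
    t: np.ndarray,
    tau: np.ndarray,
    x: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`evaluate` on broadcastable condition/conversion arrays.

    Used by the grid-search oracle; conversions are supplied directly
    (noise-free) instead of via IRReading objects.
    """
    t_lo, tau_min, x_min = spec.space.lower
    t_hi = spec.space.upper[0]
    score = np.asarray(c, dtype=float) ** spec.weight("conversion")
    if "throughput" in spec.terms:
        score = score * (tau_min / tau) ** spec.weight("throughput")
    if "consumption" in spec.terms:
        score = score * (x_min / x) ** spec.weight("consumption")
    if "energy" in spec.terms:
        frac = (t - t_lo) / (t_hi - t_lo)
        score = score * (1.0 - spec.energy_gamma * frac) ** spec.weight("energy")
    return score


def preset(name: str) -> ObjectiveSpec:
    """The evaluation function of a named campaign, bound to its printed space."""
    campaign = get_campaign(name)
    return ObjectiveSpec(space=campaign.space, terms=campaign.terms)
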