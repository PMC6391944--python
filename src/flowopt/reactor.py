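"""Plug-flow reactor simulator: Arrhenius kinetics with a series degradation
pathway, Beer-Lambert IR readout, and throughput arithmetic.

The mechanism is A + B -> P (second order, rate constant k1) followed by
P -> Q (first order, k2).  The degradation step is what makes interior
optima in temperature and residence time representable: without it, any
conversion-seeking objective would pin T and tau to their upper bounds.
Along a plug-flow coil the composition evolves over t in [0, tau]:

    dA/dt = -k1 A B        dP/dt = k1 A B - k2 P
    dB/dt = -k1 A B        dQ/dt = k2 P

Temperatures are degC at the interface and Kelvin inside the Arrhenius law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .objective import IRReading
from .space import OperatingPoint

#: Gas constant, J/(mol K).
R_GAS = 8.314

#: Absolute zero in degC.
T_ZERO_C = -273.15


class IntegrationError(RuntimeError):
    """Raised when the kinetic ODE integration fails at an operating point."""


@dataclass(frozen=True)
class KineticParams:
    """Arrhenius parameters of the two-step mechanism.

    A1 is in L/(mol min) (second-order formation), A2 in 1/min (first-order
    degradation); activation energies in J/mol.
    """

    A1: float
    Ea1: float
    A2: float
    Ea2: float

    def __post_init__(self) -> None:
        if min(self.A1, self.Ea1, self.A2, self.Ea2) <= 0:
            raise ValueError("all kinetic parameters must be strictly positive")


@dataclass(frozen=True)
class ReactorSpec:
    """Coil volume, feed concentration and lumped Beer-Lambert coefficients."""

    volume: float = 20.0  # mL
    feed_conc_A: float = 0.5  # mol/L of limiting substrate at the mixer outlet
    product_mw: float = 200.0  # g/mol
    eps_p: float = 1.0  # AU per mol/L at the product band
    eps_s: float = 1.0  # AU per mol/L at the starting-material band
    wavenumber_p: float = float("nan")
    wavenumber_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.feed_conc_A <= 0 or self.product_mw <= 0:
            raise ValueError("volume, feed_conc_A and product_mw must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian absorbance noise (AU std dev) with its own seed."""

    sigma_abs: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_abs < 0:
            raise ValueError("sigma_abs must be non-negative")


@dataclass(frozen=True)
class SimResult:
    """Outlet composition of one plug-flow simulation."""

    conc_A: float
    conc_B: float
    conc_P: float
    conc_Q: float
    yield_P: float  # fraction of fed A leaving as surviving product


def rate_constant(pre_exp: float, ea: float, temperature_c: float) -> float:
    """Arrhenius rate constant k = A exp(-Ea / (R T)) at a Celsius temperature."""
    if temperature_c <= T_ZERO_C:
        raise ValueError(f"temperature {temperature_c} degC is at or below absolute zero")
    return pre_exp * math.exp(-ea / (R_GAS * (temperature_c - T_ZERO_C)))


def second_order_conversion(k1: float, a0: float, x: float, tau) -> np.ndarray | float:
    """Closed-form fractional conversion of A for A + B -> P alone (k2 = 0).

    For x != 1:  c_A = x (1 - e^(-k1 a0 (x-1) tau)) / (x - e^(-k1 a0 (x-1) tau));
    the equimolar limit x -> 1 gives c_A = k1 a0 tau / (1 + k1 a0 tau).
    """
    tau = np.asarray(tau, dtype=float)
    theta = k1 * a0 * tau
    if abs(x - 1.0) < 1e-9:
        out = theta / (1.0 + theta)
    else:
        e = np.exp(-theta * (x - 1.0))
        out = x * (1.0 - e) / (x - e)
    return out if out.ndim else float(out)


def _rates(kin: KineticParams, temperature_c: float) -> tuple[float, float]:
    return (
        rate_constant(kin.A1, kin.Ea1, temperature_c),
        rate_constant(kin.A2, kin.Ea2, temperature_c),
    )


def pfr_outlet(kin: KineticParams, rx: ReactorSpec, point: OperatingPoint) -> SimResult:
    """Integrate the mechanism over one residence time and return the outlet state.

    Uses an adaptive stiff-capable integrator at tight tolerance; the
    closed-form second-order solution (k2 = 0) is the agreement oracle.
    """
    a0 = rx.feed_conc_A
    b0 = point.equivalents * a0
    k1, k2 = _rates(kin, point.temperature)

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        a, b, p, _q = y
        r1 = k1 * a * b
        r2 = k2 * p
        return [-r1, -r1, r1 - r2, r2]

    if point.residence_time == 0.0:
        y = np.array([a0, b0, 0.0, 0.0])
    else:
        sol = solve_ivp(
            rhs,
            (0.0, point.residence_time),
            [a0, b0, 0.0, 0.0],
            method="LSODA",
            rtol=1e-10,
            atol=1e-13,
        )
        if not sol.success:
            raise IntegrationError(f"kinetic integration failed at {point}: {sol.message}")
        y = sol.y[:, -1]
    a, b, p, q = (max(float(v), 0.0) for v in y)
    return SimResult(conc_A=a, conc_B=b, conc_P=p, conc_Q=q, yield_P=p / a0)


def _a_frac(theta: np.ndarray, x: np.ndarray, s) -> np.ndarray:
    """Closed-form fraction A/a0 at normalized time s for Damkohler number theta.

    Stable for arbitrarily large theta: the exponent is arranged so the
    exponential never overflows on either side of x = 1.
    """
    d = x - 1.0
    z = np.clip(theta * d * s, -700.0, 700.0)
    with np.errstate(over="ignore", invalid="ignore"):
        a_excess = d * np.exp(-z) / (x - np.exp(-z))  # x > 1 branch, z >= 0
        a_deficit = d / (x * np.exp(z) - 1.0)  # x < 1 branch, z <= 0
    a = np.where(d > 0, a_excess, a_deficit)
    a_equi = 1.0 / (1.0 + theta * s)
    return np.where(np.abs(d) < 1e-8, a_equi, a)


def series_outlet_frac(
    theta: np.ndarray,
    kappa: np.ndarray,
    x: np.ndarray,
    n_steps: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Outlet fractions (A/a0, P/a0) of the series mechanism in dimensionless form.

    theta = k1 a0 tau and kappa = k2 tau are the Damkohler numbers of the
    formation and degradation steps.  A follows its closed-form second-order
    solution; P is propagated with an exponential (integrating-factor) rule
    using the midpoint formation rate on each substep, which is
    unconditionally stable however stiff the degradation becomes.
    """
    theta = np.asarray(theta, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    x = np.asarray(x, dtype=float)
    shape = np.broadcast_shapes(theta.shape, kappa.shape, x.shape)
    theta, kappa, x = (np.broadcast_to(v, shape) for v in (theta, kappa, x))
    d = x - 1.0
    h = 1.0 / n_steps
    kh = kappa * h
    decay = np.exp(-np.clip(kh, 0.0, 700.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(kappa > 1e-12, -np.expm1(-np.clip(kh, 0.0, 700.0)) / kappa, h)
    p = np.zeros(shape)
    for i in range(n_steps):
        a_mid = _a_frac(theta, x, (i + 0.5) * h)
        r1 = theta * a_mid * (a_mid + d)
        p = p * decay + r1 * phi
    return _a_frac(theta, x, 1.0), np.clip(p, 0.0, None)


def pfr_outlet_grid(
    kin: KineticParams,
    rx: ReactorSpec,
    temperature_c: np.ndarray,
    tau: np.ndarray,
    x: np.ndarray,
    n_steps: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized outlet over arrays of conditions via :func:`series_outlet_frac`.

    Returns ``(conc_A, conc_P)`` arrays broadcast over the inputs.  This is
    the fast path behind the exhaustive grid-search oracle and calibration;
    :func:`pfr_outlet` is the high-accuracy scalar reference.
    """
    t_k = np.asarray(temperature_c, dtype=float) - T_ZERO_C
    k1 = kin.A1 * np.exp(-kin.Ea1 / (R_GAS * t_k))
    k2 = kin.A2 * np.exp(-kin.Ea2 / (R_GAS * t_k))
    a0 = rx.feed_conc_A
    a, p = series_outlet_frac(k1 * a0 * np.asarray(tau), k2 * np.asarray(tau), x, n_steps)
    return a * a0, p * a0


def ir_from(
    result: SimResult,
    rx: ReactorSpec,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> IRReading:
    """Beer-Lambert absorbances of the outlet with additive Gaussian noise.

    Without an explicit generator the draw is re-seeded from ``noise.seed``,
    so repeated calls are identical; campaign runners pass their own stream.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    p = rx.eps_p * result.conc_P
    s = rx.eps_s * result.conc_A
    if noise.sigma_abs > 0:
        p += rng.normal(0.0, noise.sigma_abs)
        s += rng.normal(0.0, noise.sigma_abs)
    return IRReading(
        p=max(p, 0.0),
        s=max(s, 0.0),
        wavenumber_p=rx.wavenumber_p,
        wavenumber_s=rx.wavenumber_s,
    )


def throughput(point: OperatingPoint, yield_p: float, rx: ReactorSpec) -> float:
    """Steady-state product mass rate, g/h."""
    if point.residence_time <= 0:
        raise ValueError("residence time must be positive")
    flow_ml_min = rx.volume / point.residence_time
    mol_per_min = yield_p * rx.feed_conc_A * flow_ml_min * 1e-3
    return mol_per_min * 60.0 * rx.product_mw


def volumetric_yield(point: OperatingPoint, yield_p: float, rx: ReactorSpec) -> float:
    """Space-time productivity, g product per mL reactor per hour."""
    return throughput(point, yield_p, rx) / rx.volume


def doses_per_day(vol_yield: float, volume_ml: float, dose_g: float) -> int:
    """Whole drug doses producible per day at a given volumetric yield."""
    return int(vol_yield * volume_ml * 24.0 / dose_g)
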