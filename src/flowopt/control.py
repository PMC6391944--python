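"""Process control: simulated clock, transients, steady-state detection,
flush steps, and full optimization campaigns run the way the rig runs them.

Each "experiment" on the simulated rig is: flush the coil (dead time), step
the setpoint, watch the outlet IR approach the new steady state first-order
with time constant equal to the residence time, and declare steady state
when a rolling window of samples stays inside a tolerance band on both
monitored bands.  The band combines a relative tolerance with an absolute
deadband tied to the detector noise, so channels sitting near the baseline
do not chase their own noise.

The simulated clock is decoupled from wall time: full multi-hour campaigns
run in well under a second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import CalibratedCampaign
from .objective import IRReading, NoSignalError, evaluate as evaluate_objective
from .optimizer import OptimizationResult, OptimizerConfig, run as run_optimizer
from .reactor import ir_from
from .space import OperatingPoint

PHASES = ("startup", "steady_state", "shutdown")


class StalledExperimentError(RuntimeError):
    """Steady state was not reached within the per-experiment time cap."""


class FailedStartupError(RuntimeError):
    """The staged-startup trigger threshold was never crossed."""


@dataclass(frozen=True)
class SteadyStateCriteria:
    """Rolling-window steady-state test.

    A window of ``window`` consecutive samples is steady when every sample
    of both bands deviates from the window mean by at most
    ``rel_tol * |mean| + abs_tol``.
    """

    window: int = 5
    rel_tol: float = 0.01
    sample_period: float = 0.5  # min
    abs_tol: float = 0.0  # AU; deadband for near-baseline channels

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be at least 3 samples")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")


@dataclass(frozen=True)
class Event:
    """A feed interruption or its refill on a named stream."""

    kind: str  # feed_outage | refill
    stream_id: str
    time: float  # h

    def __post_init__(self) -> None:
        if self.kind not in ("feed_outage", "refill"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class Sample:
    time: float  # min on the campaign clock
    reading: IRReading
    phase: str


@dataclass
class CampaignTimeSeries:
    """Ordered (time, IRReading, phase) samples with strictly increasing time."""

    samples: list[Sample] = field(default_factory=list)

    def append(self, sample: Sample) -> None:
        if self.samples and sample.time <= self.samples[-1].time:
            raise ValueError("sample times must be strictly increasing")
        self.samples.append(sample)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples])

    @property
    def p(self) -> np.ndarray:
        return np.array([s.reading.p for s in self.samples])

    @property
    def s(self) -> np.ndarray:
        return np.array([s.reading.s for s in self.samples])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times / 60.0,
                "absorbance_p": self.p,
                "absorbance_s": self.s,
                "phase": [s.phase for s in self.samples],
            }
        )


def _window_steady(values: np.ndarray, criteria: SteadyStateCriteria) -> bool:
    mean = float(np.mean(values))
    tol = criteria.rel_tol * abs(mean) + criteria.abs_tol
    return bool(np.max(np.abs(values - mean)) <= tol)


def detect_steady(series: CampaignTimeSeries, criteria: SteadyStateCriteria) -> float | None:
    """Earliest sample time at which both bands hold steady over the window.

    Returns None when no admissible window exists (e.g. a ramp steeper than
    the tolerance band).
    """
    n = len(series)
    w = criteria.window
    if n < w:
        return None
    p, s, times = series.p, series.s, series.times
    for end in range(w, n + 1):
        if _window_steady(p[end - w : end], criteria) and _window_steady(
            s[end - w : end], criteria
        ):
            return float(times[end - 1])
    return None


@dataclass
class ExperimentRunner:
    """Runs successive steady-state experiments on a calibrated simulator.

    Keeps the campaign clock and the reactor's previous steady outlet, so
    each new setpoint is approached through a first-order transient from
    where the rig actually was.
    """

    cal: CalibratedCampaign
    criteria: SteadyStateCriteria = None  # type: ignore[assignment]
    flush_dead_time: float = 5.0  # min of solvent flush between experiments
    transient_cap: float = 6.0  # multiples of tau before declaring a stall
    rng: np.random.Generator | None = None
    clock: float = 0.0  # min
    series: CampaignTimeSeries = field(default_factory=CampaignTimeSeries)
    _prev: tuple[float, float] = (0.0, 0.0)  # clean (p, s) the coil last held

    def __post_init__(self) -> None:
        if self.criteria is None:
            # Deadband tied to detector noise: 6 sigma keeps false motion
            # detection negligible over long windows without masking drift.
            self.criteria = SteadyStateCriteria(abs_tol=6.0 * self.cal.noise.sigma_abs)
        if self.rng is None:
            self.rng = np.random.default_rng(self.cal.noise.seed)

    def run_experiment(self, point: OperatingPoint) -> IRReading:
        """Flush, settle at the new conditions, return the steady window mean."""
        sim = self.cal.simulate(point)
        clean_p = self.cal.reactor.eps_p * sim.conc_P
        clean_s = self.cal.reactor.eps_s * sim.conc_A
        self.clock += self.flush_dead_time

        tau = point.residence_time
        dt = self.criteria.sample_period
        # Adaptive window: span at least one transient time constant
        # (criteria.window is a floor) so a window that passes the deviation
        # test cannot be a slowly drifting first-order tail.
        w = max(self.criteria.window, int(np.ceil(tau / dt)))
        max_samples = max(int(np.ceil(self.transient_cap * tau / dt)), w) + w
        # Trend rejection: the remaining first-order offset R relates to the
        # half-window mean drift D by R = D * e^-r * r / (2(1-e^-r/2)^2) with
        # r = window duration / tau; bound R inside the band, 1.5x margin.
        r = w * dt / tau
        trend_factor = 1.5 * math.exp(-r) * r / (2.0 * (1.0 - math.exp(-r / 2.0)) ** 2)
        window_p: list[float] = []
        window_s: list[float] = []
        sigma = self.cal.noise.sigma_abs
        for i in range(1, max_samples + 1):
            t = i * dt
            decay = np.exp(-t / tau)
            p = clean_p + (self._prev[0] - clean_p) * decay
            s = clean_s + (self._prev[1] - clean_s) * decay
            if sigma > 0:
                p += self.rng.normal(0.0, sigma)
                s += self.rng.normal(0.0, sigma)
            p, s = max(p, 0.0), max(s, 0.0)
            self.clock += dt
            self.series.append(
                Sample(self.clock, IRReading(p, s, self.cal.reactor.wavenumber_p,
                                             self.cal.reactor.wavenumber_s), "startup")
            )
            window_p.append(p)
            window_s.append(s)
            if len(window_p) > w:
                window_p.pop(0)
                window_s.pop(0)
            if len(window_p) == w and _window_steady(
                np.array(window_p), self.criteria
            ) and _window_steady(np.array(window_s), self.criteria) and self._trend_ok(
                window_p, trend_factor
            ) and self._trend_ok(window_s, trend_factor):
                self._prev = (clean_p, clean_s)
                return IRReading(
                    float(np.mean(window_p)),
                    float(np.mean(window_s)),
                    self.cal.reactor.wavenumber_p,
                    self.cal.reactor.wavenumber_s,
                )
        raise StalledExperimentError(
            f"no steady state within {self.transient_cap:g} tau at {point}"
        )

    def _trend_ok(self, window: list[float], factor: float) -> bool:
        half = len(window) // 2
        drift = abs(
            float(np.mean(window[half:])) - float(np.mean(window[:half]))
        )
        mean = abs(float(np.mean(window)))
        return drift * factor <= self.criteria.rel_tol * mean + self.criteria.abs_tol


@dataclass(frozen=True)
class CampaignResult:
    """Outcome of one closed-loop optimization campaign."""

    optimization: OptimizationResult
    series: CampaignTimeSeries
    duration_h: float
    seed: int
    clocks: tuple[float, ...] = ()  # campaign clock (min) after each experiment


def run_campaign(
    cal: CalibratedCampaign,
    seed: int = 0,
    opt_config: OptimizerConfig | None = None,
    criteria: SteadyStateCriteria | None = None,
    flush_dead_time: float = 5.0,
) -> CampaignResult:
    """Closed-loop self-optimization with full experiment timing.

    The single campaign seed fans out deterministically: ``seed`` drives the
    optimizer's vertex sampling, ``seed + 1`` the detector noise.
    """
    if opt_config is None:
        opt_config = OptimizerConfig(seed=seed)
    elif opt_config.seed != seed:
        from dataclasses import replace

        opt_config = replace(opt_config, seed=seed)
    runner = ExperimentRunner(
        cal=cal,
        criteria=criteria,
        flush_dead_time=flush_dead_time,
        rng=np.random.default_rng(seed + 1),
    )

    clocks: list[float] = []

    def evaluate(x: np.ndarray):
        point = OperatingPoint.from_array(x)
        reading = runner.run_experiment(point)
        clocks.append(runner.clock)
        try:
            score = evaluate_objective(cal.objective, point, reading)
        except NoSignalError:
            score = 0.0
        return reading, score

    result = run_optimizer(cal.campaign.space, evaluate, opt_config)
    return CampaignResult(
        optimization=result,
        series=runner.series,
        duration_h=runner.clock / 60.0,
        seed=seed,
        clocks=tuple(clocks),
    )


def staged_startup(series: CampaignTimeSeries, threshold: float) -> float:
    """Trigger time for the second stage: first sample where the intermediate
    band (the s channel of a telescoped series) reaches the threshold.

    Raises :class:`FailedStartupError` when the threshold is never crossed.
    """
    if threshold <= 0.0:
        return float(series.times[0]) if len(series) else 0.0
    s = series.s
    above = np.nonzero(s >= threshold)[0]
    if len(above) == 0:
        raise FailedStartupError(
            f"intermediate absorbance never reached the trigger threshold {threshold:g} AU"
        )
    return float(series.times[above[0]])


def inject_disturbance(
    series: CampaignTimeSeries,
    event: Event,
    holdup_ml: float,
    main_flow: float,
    outage_flow: float,
    duration_min: float = 3.0,
    rel_tol: float = 0.01,
) -> tuple[CampaignTimeSeries, float]:
    """Propagate a feed outage through a stirred holdup; returns the
    perturbed series and the fluctuation duration in minutes.

    During the outage the named stream's flow is zero, so the composition
    entering the holdup is enriched by the ratio of total to remaining flow
    and the washout slows down; after the refill the holdup washes back to
    its steady composition first-order with time constant holdup/flow.  The
    fluctuation duration is the time the relative deviation stays outside
    ``rel_tol``.
    """
    if event.kind != "feed_outage":
        raise ValueError("only feed_outage events are injected directly")
    if outage_flow >= main_flow:
        raise ValueError("outage flow must be smaller than the main flow")
    t0 = event.time * 60.0  # min
    times = series.times
    if len(times) == 0 or not times[0] <= t0 <= times[-1]:
        raise ValueError("event lies outside the recorded run")
    if duration_min <= 0.0:
        return series, 0.0
    enrich = main_flow / (main_flow - outage_flow)
    c_rel = 1.0
    out = CampaignTimeSeries()
    deviation_times: list[float] = []
    prev_t = times[0]
    for sample in series.samples:
        dt = sample.time - prev_t
        prev_t = sample.time
        in_outage = t0 <= sample.time < t0 + duration_min
        inlet = enrich if in_outage else 1.0
        tc = holdup_ml / ((main_flow - outage_flow) if in_outage else main_flow)
        if dt > 0:
            c_rel += (inlet - c_rel) * -np.expm1(-dt / tc)
        if abs(c_rel - 1.0) > rel_tol:
            deviation_times.append(sample.time)
        out.append(
            Sample(
                sample.time,
                IRReading(
                    sample.reading.p * c_rel,
                    sample.reading.s * c_rel,
                    sample.reading.wavenumber_p,
                    sample.reading.wavenumber_s,
                ),
                sample.phase,
            )
        )
    duration = (deviation_times[-1] - deviation_times[0]) if deviation_times else 0.0
    return out, float(duration)


# ---------------------------------------------------------------------------
# Telescoped-process timeline.


@dataclass(frozen=True)
class TelescopedRun:
    """Timeline of one telescoped campaign."""

    series: CampaignTimeSeries
    trigger_time_min: float  # staged start-up of the second stage
    steady_time_min: float | None
    disturbances: tuple[tuple[Event, float], ...]  # (event, fluctuation minutes)


def simulate_telescoped(
    process,
    duration_h: float = 10.0,
    seed: int = 0,
    criteria: SteadyStateCriteria | None = None,
    events: tuple[Event, ...] = (),
    startup_threshold_frac: float = 0.5,
    shutdown_min: float = 30.0,
) -> TelescopedRun:
    """Three-stage telescoped campaign: start-up, steady operation, shutdown.

    The s channel tracks the bromide intermediate leaving the workup and
    evaporation train (a cascade of the stage-1 residence-time lag and the
    junction holdup); the second stage's feeds start only once that band
    crosses ``startup_threshold_frac`` of its plateau, and the p channel -
    the final product at the stage-2 outlet - then rises through its own
    residence-time lag.  Feed-outage events wash through the junction
    holdup.  Phases are assigned from the detected chain steady state and
    the scheduled shutdown, during which all feeds stop and both bands
    decay through the same lags.
    """
    from .telescope import chain_streams, telescoped_rate

    streams = chain_streams(process)
    s_plateau = process.cal1.reactor.eps_p * streams["evaporator_out"].conc["bromide"]
    rate = telescoped_rate(process)
    mw2 = process.cal2.campaign.product_molar_mass
    inlet2 = streams["stage2_inlet"]
    p_plateau = process.cal2.reactor.eps_p * rate / (60.0 * mw2 * inlet2.flow * 1e-3)

    dt = (criteria or SteadyStateCriteria()).sample_period
    criteria = criteria or SteadyStateCriteria(
        abs_tol=4.0 * 0.005 * max(s_plateau, p_plateau)
    )
    rng = np.random.default_rng(seed + 2)
    sigma_s = 0.005 * s_plateau
    sigma_p = 0.005 * p_plateau

    tau1 = process.stage1_point.residence_time
    tau2 = process.stage2_point.residence_time
    tc_holdup = process.holdup_ml / process.evaporator_outlet_flow

    n = int(round(duration_h * 60.0 / dt))
    shutdown_start = duration_h * 60.0 - shutdown_min
    times = np.arange(1, n + 1) * dt
    s_stage, s_hold, p_stage = 0.0, 0.0, 0.0
    trigger_time = None
    s_vals, p_vals = [], []
    for t in times:
        feeds_on = t < shutdown_start
        s_target = s_plateau if feeds_on else 0.0
        s_stage += (s_target - s_stage) * -np.expm1(-dt / tau1)
        s_hold += (s_stage - s_hold) * -np.expm1(-dt / tc_holdup)
        if trigger_time is None and s_hold >= startup_threshold_frac * s_plateau:
            trigger_time = t
        stage2_on = trigger_time is not None and feeds_on
        p_stage += ((p_plateau if stage2_on else 0.0) - p_stage) * -np.expm1(-dt / tau2)
        s_vals.append(s_hold)
        p_vals.append(p_stage)
    if trigger_time is None:
        raise FailedStartupError(
            "intermediate band never crossed the staged start-up threshold"
        )

    clean = CampaignTimeSeries()
    for t, sv, pv in zip(times, s_vals, p_vals):
        clean.append(Sample(float(t), IRReading(max(pv, 0.0), max(sv, 0.0)), "startup"))
    steady_time = detect_steady_after(clean, criteria, after=trigger_time + tau2)

    disturbances = []
    series = clean
    for event in events:
        if event.kind != "feed_outage":
            continue
        refills = [
            e for e in events
            if e.kind == "refill" and e.stream_id == event.stream_id and e.time > event.time
        ]
        dur = (min(r.time for r in refills) - event.time) * 60.0 if refills else 3.0
        series, fluct = inject_disturbance(
            series,
            event,
            process.holdup_ml,
            process.evaporator_outlet_flow,
            process.nmp_flow,
            duration_min=dur,
            rel_tol=criteria.rel_tol,
        )
        disturbances.append((event, fluct))

    final = CampaignTimeSeries()
    for sample in series.samples:
        if steady_time is not None and sample.time >= shutdown_start:
            phase = "shutdown"
        elif steady_time is not None and sample.time >= steady_time:
            phase = "steady_state"
        else:
            phase = "startup"
        p = max(sample.reading.p + rng.normal(0.0, sigma_p), 0.0) if sigma_p else sample.reading.p
        s = max(sample.reading.s + rng.normal(0.0, sigma_s), 0.0) if sigma_s else sample.reading.s
        final.append(Sample(sample.time, IRReading(p, s), phase))
    return TelescopedRun(
        series=final,
        trigger_time_min=float(trigger_time),
        steady_time_min=steady_time,
        disturbances=tuple(disturbances),
    )


def detect_steady_after(
    series: CampaignTimeSeries, criteria: SteadyStateCriteria, after: float
) -> float | None:
    """detect_steady restricted to samples at or after a given time."""
    sub = CampaignTimeSeries()
    for sample in series.samples:
        if sample.time >= after:
            sub.append(sample)
    return detect_steady(sub, criteria)
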