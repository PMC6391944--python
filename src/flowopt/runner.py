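"""Run orchestration: turn a validated RunConfig into artifacts on disk.

Every run directory receives the resolved configuration, the experiment
trace (CSV, 6 significant digits), a full-precision summary JSON and a
plain-text log carrying the seed, so a run can be reproduced exactly from
its own output.  The config seed fans out deterministically: ``seed``
drives the optimizer, ``seed + 1`` the detector noise, ``seed + 2`` the
telescoped timeline noise.
"""

from __future__ import annotations

import json
from dataclasses import replace
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibratedCampaign, calibrate
from .campaigns import Campaign, get_campaign
from .config import RunConfig
from .control import CampaignResult, Event, run_campaign, simulate_telescoped
from .objective import IRReading, ObjectiveSpec, conversion, evaluate as evaluate_objective
from .optimizer import OptimizerConfig
from .reactor import KineticParams, NoiseSpec, ReactorSpec
from .space import OperatingPoint

TRACE_COLUMNS = (
    "experiment",
    "temperature",
    "residence_time",
    "equivalents",
    "absorbance_p",
    "absorbance_s",
    "conversion",
    "score",
    "clock_min",
)


def _package_version() -> str:
    try:
        return version("flowopt")
    except PackageNotFoundError:
        return "unknown"


def calibrated_from_config(cfg: RunConfig) -> CalibratedCampaign:
    """Resolve a RunConfig into a calibrated (or explicitly specified) simulator."""
    if cfg.campaign is not None:
        campaign = get_campaign(cfg.campaign)
        if cfg.space is not None:
            campaign = replace(campaign, space=cfg.space.build())
        if cfg.objective is not None:
            campaign = replace(campaign, terms=frozenset(cfg.objective.terms))
        if cfg.reactor.feed_conc is not None:
            campaign = replace(campaign, feed_conc=cfg.reactor.feed_conc)
    else:
        campaign = Campaign(
            name="custom",
            space=cfg.space.build(),
            terms=frozenset(cfg.objective.terms),
            product_formula="C10H12ClNO",
            target_point=OperatingPoint(*cfg.calibration.target_point)
            if cfg.calibration
            else OperatingPoint(*(cfg.space.build().lower + cfg.space.build().upper) / 2),
            target_yield=cfg.calibration.target_yield if cfg.calibration else 0.5,
            feed_conc=cfg.reactor.feed_conc or 0.5,
            wavenumber_p=float("nan"),
            wavenumber_s=float("nan"),
            trials_reported=0,
        )

    if cfg.kinetics is not None:
        kin = KineticParams(**cfg.kinetics.model_dump())
        rx = ReactorSpec(
            volume=cfg.reactor.volume,
            feed_conc_A=campaign.feed_conc,
            product_mw=campaign.product_molar_mass,
            eps_p=cfg.reactor.eps_p,
            eps_s=cfg.reactor.eps_s,
            wavenumber_p=campaign.wavenumber_p,
            wavenumber_s=campaign.wavenumber_s,
        )
        sigma = cfg.noise.sigma_abs
        if sigma is None:
            sigma = 0.005 * rx.eps_p * rx.feed_conc_A
        noise = NoiseSpec(sigma_abs=sigma, seed=cfg.seed + 1)
        spec = ObjectiveSpec(
            space=campaign.space,
            terms=campaign.terms,
            weights=cfg.objective.weights if cfg.objective else {},
            energy_gamma=cfg.objective.energy_gamma if cfg.objective else 0.3,
        )
        return CalibratedCampaign(
            campaign=campaign,
            kinetics=kin,
            reactor=rx,
            noise=noise,
            objective=spec,
            diagnostics={"source": "explicit kinetics"},
        )

    target = cfg.resolved_calibration()
    cal = calibrate(
        campaign,
        target_point=OperatingPoint(*target.target_point),
        target_yield=target.target_yield,
    )
    if cfg.noise.sigma_abs is not None:
        cal = replace(cal, noise=NoiseSpec(sigma_abs=cfg.noise.sigma_abs, seed=cfg.seed + 1))
    else:
        cal = replace(cal, noise=replace(cal.noise, seed=cfg.seed + 1))
    return cal


def trace_dataframe(cal: CalibratedCampaign, result: CampaignResult) -> pd.DataFrame:
    rows = []
    trace = result.optimization.trace
    for i, entry in enumerate(trace):
        t, tau, x = entry.point
        reading: IRReading = entry.reading
        total = reading.p + reading.s
        rows.append(
            {
                "experiment": i + 1,
                "temperature": t,
                "residence_time": tau,
                "equivalents": x,
                "absorbance_p": reading.p,
                "absorbance_s": reading.s,
                "conversion": reading.p / total if total > 0 else np.nan,
                "score": entry.score,
                "clock_min": result.clocks[i] if i < len(result.clocks) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def _write_trace(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_optimize(cfg: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run one closed-loop campaign and write its artifact set."""
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal = calibrated_from_config(cfg)
    opt = OptimizerConfig(seed=cfg.seed, **cfg.optimizer.model_dump())
    result = run_campaign(cal, seed=cfg.seed, opt_config=opt)

    best = result.optimization.best_point
    summary = {
        "campaign": cal.campaign.name,
        "seed": cfg.seed,
        "best_point": {
            "temperature": float(best[0]),
            "residence_time": float(best[1]),
            "equivalents": float(best[2]),
        },
        "best_score": result.optimization.best_score,
        "n_evaluations": result.optimization.n_evaluations,
        "converged": result.optimization.converged,
        "duration_h": result.duration_h,
        "calibration": {
            "yield_at_target": float(cal.diagnostics.get("yield_at_target", np.nan)),
            "kinetics": {
                "A1": cal.kinetics.A1,
                "Ea1": cal.kinetics.Ea1,
                "A2": cal.kinetics.A2,
                "Ea2": cal.kinetics.Ea2,
            },
        },
        "version": _package_version(),
    }
    (out / "resolved_config.yaml").write_text(cfg.to_yaml())
    _write_trace(trace_dataframe(cal, result), out / "trace.csv")
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "flowopt.log").write_text(
        f"flowopt {_package_version()}\ncampaign={cal.campaign.name} seed={cfg.seed}\n"
        f"evaluations={summary['n_evaluations']} duration_h={result.duration_h:.3f}\n"
    )
    return summary


def run_telescope(cfg: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Simulate the telescoped two-step process and write its timeline."""
    from .telescope import build_process, chain_streams, telescoped_rate

    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal1 = calibrate("bupropion_step1")
    cal2 = calibrate("bupropion_step2")
    process = build_process(cal1, cal2)
    events = tuple(Event(e.kind, e.stream_id, e.time) for e in cfg.events)
    run = simulate_telescoped(process, seed=cfg.seed, events=events)
    df = run.series.to_dataframe()
    df.to_csv(out / "timeseries.csv", index=False, float_format="%.6g")
    streams = chain_streams(process)
    summary = {
        "production_g_h": telescoped_rate(process),
        "trigger_time_min": run.trigger_time_min,
        "steady_time_h": None if run.steady_time_min is None else run.steady_time_min / 60.0,
        "disturbances": [
            {"stream": e.stream_id, "time_h": e.time, "fluctuation_min": d}
            for e, d in run.disturbances
        ],
        "holdup_ml": process.holdup_ml,
        "streams": {
            name: {
                "flow_ml_min": s.flow,
                "conc": dict(s.conc),
                "solvent_frac": dict(s.solvent_frac),
            }
            for name, s in streams.items()
        },
        "seed": cfg.seed,
        "version": _package_version(),
    }
    (out / "resolved_config.yaml").write_text(cfg.to_yaml())
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def replay_csv(path: str | Path, spec: ObjectiveSpec, point: OperatingPoint) -> pd.DataFrame:
    """Score a recorded IR time series against an evaluation function.

    The CSV must carry columns ``time_min, absorbance_p, absorbance_s``;
    the returned frame adds per-row ``conversion`` and ``score`` computed
    at the stated operating conditions.
    """
    df = pd.read_csv(path)
    missing = {"time_min", "absorbance_p", "absorbance_s"} - set(df.columns)
    if missing:
        raise ValueError(f"replay CSV missing columns: {sorted(missing)}")
    convs, scores = [], []
    for _, row in df.iterrows():
        reading = IRReading(max(row.absorbance_p, 0.0), max(row.absorbance_s, 0.0))
        convs.append(conversion(reading))
        scores.append(evaluate_objective(spec, point, reading))
    out = df.copy()
    out["conversion"] = convs
    out["score"] = scores
    return out
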