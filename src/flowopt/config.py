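"""Run configuration: validated YAML schema, defaults, and round-tripping.

A run is described by one YAML document.  The minimal form names a
campaign preset and a seed; everything else (parameter space, objective
terms, calibration targets, reactor, noise, optimizer and steady-state
settings) defaults from the preset and can be overridden key by key.
Unknown keys are rejected with every offending key named.  Exactly one of
``kinetics`` (explicit Arrhenius parameters) or ``calibration`` (fit to a
target point and yield) must be in effect; a campaign preset supplies the
calibration block when neither is given.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .campaigns import CAMPAIGNS, get_campaign
from .space import ParameterSpace, reaction_space


class ConfigError(ValueError):
    """Configuration file violates the schema; message lists every problem."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpaceConfig(_Model):
    temperature: tuple[float, float]
    residence_time: tuple[float, float]
    equivalents: tuple[float, float]

    @model_validator(mode="after")
    def _ordered(self) -> "SpaceConfig":
        for name in ("temperature", "residence_time", "equivalents"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound {lo} must be below upper bound {hi}")
        return self

    def build(self) -> ParameterSpace:
        return reaction_space(self.temperature, self.residence_time, self.equivalents)


class ObjectiveConfig(_Model):
    terms: list[Literal["conversion", "throughput", "consumption", "energy"]]
    weights: dict[str, float] = Field(default_factory=dict)
    energy_gamma: float = 0.3


class KineticsConfig(_Model):
    A1: float
    Ea1: float
    A2: float
    Ea2: float


class CalibrationConfig(_Model):
    target_point: tuple[float, float, float]  # (T degC, tau min, x equiv)
    target_yield: float


class ReactorConfig(_Model):
    volume: float = 20.0
    feed_conc: float | None = None
    eps_p: float = 1.0
    eps_s: float = 1.0


class NoiseConfig(_Model):
    sigma_abs: float | None = None  # None: 0.5 % of full scale after calibration


class OptimizerSettings(_Model):
    n_vertices: int | None = None
    reflection_factor: float = 1.3
    bound_inset: float = 0.01
    max_retreats: int = 3
    conv_rel_tol: float = 0.01
    max_evaluations: int = 40


class SteadyStateConfig(_Model):
    window: int = 5
    rel_tol: float = 0.01
    sample_period: float = 0.5


class EventConfig(_Model):
    kind: Literal["feed_outage", "refill"]
    stream_id: str
    time: float  # h


class RunConfig(_Model):
    campaign: str | None = None
    seed: int = 0
    space: SpaceConfig | None = None
    objective: ObjectiveConfig | None = None
    kinetics: KineticsConfig | None = None
    calibration: CalibrationConfig | None = None
    reactor: ReactorConfig = Field(default_factory=ReactorConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    optimizer: OptimizerSettings = Field(default_factory=OptimizerSettings)
    steady_state: SteadyStateConfig = Field(default_factory=SteadyStateConfig)
    events: list[EventConfig] = Field(default_factory=list)
    output_dir: str = "runs"

    @model_validator(mode="after")
    def _resolve(self) -> "RunConfig":
        if self.campaign is not None and self.campaign not in CAMPAIGNS:
            raise ValueError(f"unknown campaign {self.campaign!r}; known: {sorted(CAMPAIGNS)}")
        if self.kinetics is not None and self.calibration is not None:
            raise ValueError("give exactly one of 'kinetics' or 'calibration', not both")
        if self.campaign is None:
            if self.space is None or self.objective is None:
                raise ValueError("without a campaign preset, 'space' and 'objective' are required")
            if self.kinetics is None and self.calibration is None:
                raise ValueError(
                    "without a campaign preset, one of 'kinetics' or 'calibration' is required"
                )
        for i, event in enumerate(self.events):
            if event.kind == "refill":
                outages = [
                    e
                    for e in self.events[:i]
                    if e.kind == "feed_outage" and e.stream_id == event.stream_id
                    and e.time < event.time
                ]
                if not outages:
                    raise ValueError(
                        f"refill of {event.stream_id!r} at {event.time} h has no preceding outage"
                    )
        return self

    # -- resolution helpers -------------------------------------------------

    def resolved_space(self) -> ParameterSpace:
        if self.space is not None:
            return self.space.build()
        return get_campaign(self.campaign).space

    def resolved_calibration(self) -> CalibrationConfig | None:
        if self.kinetics is not None:
            return None
        if self.calibration is not None:
            return self.calibration
        c = get_campaign(self.campaign)
        return CalibrationConfig(
            target_point=tuple(c.target_point.as_array()), target_yield=c.target_yield
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.model_dump(exclude_none=True)), sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` listing every offending key on schema
    violations, and FileNotFoundError when the file does not exist.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config_dict(raw, source=str(path))


def parse_config_dict(raw: dict, source: str = "<dict>") -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors()
        )
        raise ConfigError(f"{source}: {problems}") from None
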