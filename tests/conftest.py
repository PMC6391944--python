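"""Shared fixtures: calibrated simulators and recovery runs are expensive,
so they are computed lazily once per session and cached."""

from __future__ import annotations

import numpy as np
import pytest

from flowopt import OptimizerConfig, calibrate
from flowopt import optimizer as opt_mod


class _CalibrationCache:
    def __init__(self) -> None:
        self._cache = {}

    def __call__(self, name: str):
        if name not in self._cache:
            self._cache[name] = calibrate(name)
        return self._cache[name]


@pytest.fixture(scope="session")
def calibrated() -> _CalibrationCache:
    """calibrated('tramadol') -> CalibratedCampaign, cached per session."""
    return _CalibrationCache()


class _RecoveryCache:
    """20-seed optimizer recovery runs per campaign, at default settings."""

    N_SEEDS = 20

    def __init__(self, calibrated: _CalibrationCache) -> None:
        self._calibrated = calibrated
        self._cache = {}

    def __call__(self, name: str):
        if name not in self._cache:
            cal = self._calibrated(name)
            points, n_evals = [], []
            for seed in range(1, self.N_SEEDS + 1):
                config = OptimizerConfig(seed=seed)
                evaluator = cal.make_evaluator(seed=10_000 + seed)
                result = opt_mod.run(cal.campaign.space, evaluator, config)
                points.append(result.best_point)
                n_evals.append(result.n_evaluations)
            self._cache[name] = (np.array(points), np.array(n_evals))
        return self._cache[name]


@pytest.fixture(scope="session")
def recoveries(calibrated) -> _RecoveryCache:
    """recoveries('tramadol') -> (best_points (20, 3), n_evaluations (20,))."""
    return _RecoveryCache(calibrated)


@pytest.fixture(scope="session")
def telescoped_process(calibrated):
    from flowopt import build_process

    return build_process(calibrated("bupropion_step1"), calibrated("bupropion_step2"))


@pytest.fixture(scope="session")
def telescoped_run(telescoped_process):
    from flowopt import Event, simulate_telescoped

    return simulate_telescoped(
        telescoped_process,
        duration_h=10.0,
        seed=1,
        events=(Event("feed_outage", "nmp", 6.9), Event("refill", "nmp", 6.95)),
    )
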