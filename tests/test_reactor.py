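"""Reactor simulator: Arrhenius law, plug-flow integration against the
closed-form oracle, mole balance, Beer-Lambert readout, throughput math."""

import numpy as np
import pytest
import sympy

from flowopt import (
    IRReading,
    KineticParams,
    NoiseSpec,
    OperatingPoint,
    ReactorSpec,
    conversion,
    doses_per_day,
    ir_from,
    pfr_outlet,
    rate_constant,
    second_order_conversion,
    throughput,
    volumetric_yield,
)
from flowopt.reactor import series_outlet_frac

KIN = KineticParams(A1=5e4, Ea1=4.5e4, A2=2e3, Ea2=5.5e4)
RX = ReactorSpec(volume=20.0, feed_conc_A=0.5, product_mw=250.0)


def test_rate_constant_degenerate_and_monotone():
    assert rate_constant(3.0, 1e-300, 25.0) == pytest.approx(3.0)
    ks = [rate_constant(1e8, 6e4, t) for t in (20.0, 40.0, 60.0)]
    assert ks[0] < ks[1] < ks[2]
    with pytest.raises(ValueError):
        rate_constant(1.0, 1e4, -300.0)


def test_rate_constant_against_high_precision_arithmetic():
    """Independent oracle: evaluate the Arrhenius expression with sympy at
    50 digits and compare."""
    a, ea, t = 1e8, 6e4, 41.0
    expected = float(
        (sympy.Float(a, 50) * sympy.exp(-sympy.Float(ea, 50) /
         (sympy.Float("8.314", 50) * sympy.Float(t + 273.15, 50)))).evalf(50)
    )
    assert rate_constant(a, ea, t) == pytest.approx(expected, rel=1e-12)


def test_zero_residence_time_returns_the_inlet():
    out = pfr_outlet(KIN, RX, OperatingPoint(50.0, 1e-12, 1.2))
    assert out.yield_P == pytest.approx(0.0, abs=1e-9)
    assert out.conc_A == pytest.approx(RX.feed_conc_A, abs=1e-9)


@pytest.mark.parametrize("x, cap", [(2.0, 1.0), (0.95, 0.95)])
def test_long_residence_limits_hit_the_stoichiometric_cap(x, cap):
    """Without degradation the yield tends to min(1, x): excess reagent
    drives completion, sub-stoichiometric feed caps at x."""
    kin = KineticParams(A1=5e6, Ea1=4.5e4, A2=1e-12, Ea2=1e5)
    out = pfr_outlet(kin, RX, OperatingPoint(70.0, 500.0, x))
    assert out.yield_P == pytest.approx(cap, abs=1e-3)


def test_pfr_matches_the_closed_form_second_order_solution():
    """k2 ~ 0: numerical integration agrees with the closed form to 1e-6
    over a random sample of the condition box."""
    kin = KineticParams(A1=KIN.A1, Ea1=KIN.Ea1, A2=1e-300, Ea2=1.0)
    rng = np.random.default_rng(7)
    for _ in range(25):
        t = rng.uniform(30.0, 70.0)
        tau = rng.uniform(5.0, 20.0)
        x = rng.uniform(0.5, 1.6)
        k1 = rate_constant(kin.A1, kin.Ea1, t)
        expected = second_order_conversion(k1, RX.feed_conc_A, x, tau)
        out = pfr_outlet(kin, RX, OperatingPoint(t, tau, x))
        assert out.yield_P == pytest.approx(expected, abs=1e-6)


def test_equimolar_closed_form_limit():
    assert second_order_conversion(2.0, 0.5, 1.0, 3.0) == pytest.approx(3.0 / 4.0)


def test_mole_balance_on_the_substrate_skeleton():
    """A + P + Q equals the feed to 1e-9 at every outlet."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        point = OperatingPoint(
            rng.uniform(30, 70), rng.uniform(5, 20), rng.uniform(0.5, 1.6)
        )
        out = pfr_outlet(KIN, RX, point)
        total = out.conc_A + out.conc_P + out.conc_Q
        assert total == pytest.approx(RX.feed_conc_A, abs=1e-9)
        assert 0.0 <= out.yield_P <= min(1.0, point.equivalents) + 1e-9


def test_yield_monotone_without_degradation():
    kin = KineticParams(A1=KIN.A1, Ea1=KIN.Ea1, A2=1e-300, Ea2=1.0)

    def y(t, tau, x):
        return pfr_outlet(kin, RX, OperatingPoint(t, tau, x)).yield_P

    assert y(40, 10, 1.2) < y(50, 10, 1.2) < y(60, 10, 1.2)
    assert y(50, 6, 1.2) < y(50, 10, 1.2) < y(50, 16, 1.2)
    assert y(50, 10, 0.8) < y(50, 10, 1.2) < y(50, 10, 1.6)


def test_yield_unimodal_in_residence_time_with_degradation():
    """With the series pathway active the yield has a single interior peak
    along tau (checked by sign changes on a grid scan)."""
    kin = KineticParams(A1=1.2e7, Ea1=4.5e4, A2=7e6, Ea2=5.0e4)
    taus = np.linspace(0.5, 60.0, 80)
    ys = [pfr_outlet(kin, RX, OperatingPoint(60.0, t, 1.5)).yield_P for t in taus]
    diffs = np.sign(np.diff(ys))
    changes = np.count_nonzero(np.diff(diffs[diffs != 0]))
    assert changes == 1  # rises then falls exactly once
    assert 0.5 < taus[int(np.argmax(ys))] < 60.0


def test_vectorized_grid_agrees_with_scalar_integrator():
    t = np.array([40.0, 55.0]); tau = np.array([8.0, 15.0]); x = np.array([0.9, 1.4])
    from flowopt.reactor import pfr_outlet_grid

    a, p = pfr_outlet_grid(KIN, RX, t, tau, x, n_steps=1200)
    for i in range(2):
        out = pfr_outlet(KIN, RX, OperatingPoint(t[i], tau[i], x[i]))
        assert a[i] == pytest.approx(out.conc_A, abs=2e-6)
        assert p[i] == pytest.approx(out.conc_P, abs=2e-6)


def test_ir_readout_proportionality_and_determinism():
    out = pfr_outlet(KIN, RX, OperatingPoint(50.0, 10.0, 1.2))
    clean = ir_from(out, RX, NoiseSpec(sigma_abs=0.0))
    assert conversion(clean) == pytest.approx(out.conc_P / (out.conc_P + out.conc_A))
    noisy_a = ir_from(out, RX, NoiseSpec(sigma_abs=0.01, seed=42))
    noisy_b = ir_from(out, RX, NoiseSpec(sigma_abs=0.01, seed=42))
    assert (noisy_a.p, noisy_a.s) == (noisy_b.p, noisy_b.s)
    assert noisy_a.p >= 0.0 and noisy_a.s >= 0.0


def test_ir_zero_product_zero_absorbance():
    out = pfr_outlet(KIN, RX, OperatingPoint(50.0, 1e-12, 1.0))
    reading = ir_from(out, RX, NoiseSpec(sigma_abs=0.0))
    assert reading.p == pytest.approx(0.0, abs=1e-12)


def test_series_outlet_is_stable_for_extreme_damkohler_numbers():
    a, p = series_outlet_frac(1e6, 1e6, 2.0)
    assert np.isfinite(a) and np.isfinite(p)
    assert 0.0 <= float(p) <= 1.0


def test_throughput_arithmetic():
    point = OperatingPoint(41.0, 10.9, 1.6)
    assert throughput(point, 0.0, RX) == 0.0
    rate = throughput(point, 0.86, RX)
    # yield * conc * (V/tau) * MW with mL->L and min->h conversions
    assert rate == pytest.approx(0.86 * 0.5 * (20.0 / 10.9) * 1e-3 * 60 * 250.0)
    assert volumetric_yield(point, 0.86, RX) == pytest.approx(rate / 20.0)
    assert doses_per_day(0.172, 20.0, 0.050) == 1651
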