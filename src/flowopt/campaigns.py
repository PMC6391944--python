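"""Registry of the five self-optimization campaigns.

Each campaign bundles what the operator would configure on the real rig:
the bounded condition space, the active evaluation-function terms, the
monitored IR bands, and the anchor used to calibrate the reactor simulator
(the reported optimal conditions and the yield obtained there).

Feed concentrations are not free choices: where a production rate was
reported they are back-calculated so that throughput arithmetic at the
calibrated optimum reproduces it (tramadol from its volumetric yield,
the bupropion steps from their g/h rates); otherwise a generic 0.5 M is
used.  Molar masses are recomputed from molecular formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import molar_mass
from .space import OperatingPoint, ParameterSpace, reaction_space

#: Reactor coil volume, mL (same coil across campaigns).
COIL_VOLUME_ML = 20.0

#: Tramadol unit dose used for doses/day arithmetic, g.
TRAMADOL_DOSE_G = 0.050


@dataclass(frozen=True)
class Campaign:
    """Configuration and calibration anchor of one optimization campaign."""

    name: str
    space: ParameterSpace
    terms: frozenset[str]
    product_formula: str
    target_point: OperatingPoint
    target_yield: float
    feed_conc: float  # limiting substrate at mixer outlet, mol/L
    wavenumber_p: float  # product band monitored, 1/cm
    wavenumber_s: float  # starting-material band monitored, 1/cm
    trials_reported: int  # experiment count of the original campaign

    @property
    def product_molar_mass(self) -> float:
        return molar_mass(self.product_formula)


def _feed_from_volumetric_yield(vy: float, tau: float, yield_frac: float, mw: float) -> float:
    # vy [g/mL/h] = yield * feed [mol/L] * mw [g/mol] * 0.06 / tau [min]
    return vy * tau / (yield_frac * mw * 0.06)


def _feed_from_rate(rate_g_h: float, tau: float, yield_frac: float, mw: float, volume: float) -> float:
    # rate [g/h] = yield * feed [mol/L] * (volume/tau) [mL/min] * mw * 0.06
    return rate_g_h * tau / (yield_frac * volume * mw * 0.06)


def _build() -> dict[str, Campaign]:
    campaigns = {}

    # Grignard addition to tramadol. Anchors: 86 % yield at (41 degC,
    # 10.9 min, 1.6 equiv); volumetric yield 0.172 g/mL/h fixes the feed.
    mw = molar_mass("C16H25NO2")  # tramadol
    campaigns["tramadol"] = Campaign(
        name="tramadol",
        space=reaction_space((30.0, 70.0), (5.0, 20.0), (0.5, 1.6)),
        terms=frozenset({"conversion", "throughput", "consumption"}),
        product_formula="C16H25NO2",
        target_point=OperatingPoint(41.0, 10.9, 1.6),
        target_yield=0.86,
        feed_conc=_feed_from_volumetric_yield(0.172, 10.9, 0.86, mw),
        wavenumber_p=1044.0,
        wavenumber_s=1683.0,
        trials_reported=9,
    )

    # Lidocaine step 1: acylation of 2,6-dimethylaniline with chloroacetyl
    # chloride, four-term objective including the energy penalty.
    campaigns["lidocaine_step1"] = Campaign(
        name="lidocaine_step1",
        space=reaction_space((40.0, 130.0), (5.0, 25.0), (0.8, 2.5)),
        terms=frozenset({"conversion", "throughput", "consumption", "energy"}),
        product_formula="C10H12ClNO",  # chloroacetamide intermediate
        target_point=OperatingPoint(105.0, 5.0, 1.98),
        target_yield=0.87,
        feed_conc=0.5,
        wavenumber_p=1672.0,
        wavenumber_s=1622.0,
        trials_reported=10,
    )

    # Lidocaine step 2: amine alkylation with diethylamine, throughput +
    # conversion objective.
    campaigns["lidocaine_step2"] = Campaign(
        name="lidocaine_step2",
        space=reaction_space((70.0, 130.0), (5.0, 30.0), (1.0, 4.0)),
        terms=frozenset({"conversion", "throughput"}),
        product_formula="C14H22N2O",  # lidocaine
        target_point=OperatingPoint(99.0, 17.8, 3.9),
        target_yield=0.98,
        feed_conc=0.5,
        wavenumber_p=1664.0,
        wavenumber_s=1672.0,
        trials_reported=10,
    )

    # Bupropion step 1: alpha-bromination of 3'-chloropropiophenone;
    # bands 1300 (bromide) / 1216 (ketone) 1/cm; 8.1 g/h fixes the feed.
    mw = molar_mass("C9H8BrClO")  # alpha-bromoketone intermediate
    campaigns["bupropion_step1"] = Campaign(
        name="bupropion_step1",
        space=reaction_space((30.0, 80.0), (5.0, 20.0), (0.95, 2.0)),
        terms=frozenset({"conversion", "throughput", "consumption"}),
        product_formula="C9H8BrClO",
        target_point=OperatingPoint(44.0, 9.7, 0.95),
        target_yield=0.95,
        feed_conc=_feed_from_rate(8.1, 9.7, 0.95, mw, COIL_VOLUME_ML),
        wavenumber_p=1300.0,
        wavenumber_s=1216.0,
        trials_reported=9,
    )

    # Bupropion step 2: amine alkylation with tert-butylamine in NMP,
    # conversion-only objective; 0.72 g/h fixes the feed.
    mw = molar_mass("C13H18ClNO")  # bupropion
    campaigns["bupropion_step2"] = Campaign(
        name="bupropion_step2",
        space=reaction_space((30.0, 90.0), (5.0, 30.0), (0.95, 3.0)),
        terms=frozenset({"conversion"}),
        product_formula="C13H18ClNO",
        target_point=OperatingPoint(90.0, 20.0, 3.0),
        target_yield=0.80,
        feed_conc=_feed_from_rate(0.72, 20.0, 0.80, mw, COIL_VOLUME_ML),
        wavenumber_p=1690.0,
        wavenumber_s=1300.0,
        trials_reported=11,
    )
    return campaigns


CAMPAIGNS: dict[str, Campaign] = _build()


def get_campaign(name: str) -> Campaign:
    try:
        return CAMPAIGNS[name]
    except KeyError:
        raise KeyError(f"unknown campaign {name!r}; known: {sorted(CAMPAIGNS)}") from None
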