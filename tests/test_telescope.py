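"""Telescoped mass balance: mixing, evaporation, concentration alignment,
and the chained production rate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowopt import EvaporatorSpec, Stream, evaporate, mix, required_feed_conc
from flowopt.telescope import DegenerateStreamError, chain_streams, telescoped_rate


def _stream(flow, conc, solvents):
    return Stream(flow=flow, conc=conc, solvent_frac=solvents)


def test_mix_with_zero_flow_is_identity():
    s = _stream(2.0, {"bromide": 0.1}, {"dcm": 1.0})
    z = _stream(0.0, {}, {})
    assert mix(s, z) is s
    with pytest.raises(ValueError):
        mix(z, z)


def test_equal_flow_mixing_halves_a_one_sided_concentration():
    a = _stream(1.0, {"bromide": 0.2}, {"dcm": 1.0})
    b = _stream(1.0, {}, {"dcm": 1.0})
    out = mix(a, b)
    assert out.flow == pytest.approx(2.0)
    assert out.conc["bromide"] == pytest.approx(0.1)


@settings(max_examples=40, deadline=None)
@given(
    fa=st.floats(0.1, 5.0),
    fb=st.floats(0.1, 5.0),
    ca=st.floats(0.0, 2.0),
    cb=st.floats(0.0, 2.0),
    frac=st.floats(0.05, 0.95),
)
def test_mix_and_evaporate_conserve_species_moles(fa, fb, ca, cb, frac):
    """Species molar rates in equal rates out to 1e-12 through mix and
    through evaporation (solutes fully retained)."""
    a = _stream(fa, {"bromide": ca}, {"dcm": 1.0})
    b = _stream(fb, {"bromide": cb}, {"nmp": 1.0})
    mixed = mix(a, b)
    rate_in = a.species_rate("bromide") + b.species_rate("bromide")
    assert mixed.species_rate("bromide") == pytest.approx(rate_in, abs=1e-12)
    evap = evaporate(mixed, EvaporatorSpec(removal_frac=frac, target_solvent="dcm"))
    assert evap.species_rate("bromide") == pytest.approx(rate_in, abs=1e-12)
    dcm_in = mixed.solvent_rates()["dcm"]
    assert evap.solvent_rates()["dcm"] == pytest.approx((1 - frac) * dcm_in, rel=1e-9)


def test_evaporate_edge_cases():
    s = _stream(2.0, {"bromide": 0.1}, {"dcm": 1.0})
    unchanged = evaporate(s, EvaporatorSpec(0.0, "dcm"))
    assert unchanged.flow == pytest.approx(s.flow)
    with pytest.raises(ValueError):
        evaporate(s, EvaporatorSpec(0.5, "nmp"))  # solvent absent
    with pytest.raises(DegenerateStreamError):
        evaporate(s, EvaporatorSpec(1.0, "dcm"))  # solute left with no carrier


def test_dcm_removal_enriches_solutes():
    s = mix(
        _stream(2.0, {"bromide": 0.1}, {"dcm": 1.0}),
        _stream(0.5, {}, {"nmp": 1.0}),
    )
    out = evaporate(s, EvaporatorSpec(0.87, "dcm"))
    assert out.conc["bromide"] > s.conc["bromide"]
    assert out.flow < s.flow


def test_evaporate_commutes_with_mixing_only_without_the_target_solvent():
    spec = EvaporatorSpec(0.5, "dcm")
    a = _stream(1.0, {"bromide": 0.2}, {"dcm": 1.0})
    nmp_only = _stream(1.0, {"amine": 0.3}, {"nmp": 1.0})
    dcm_rich = _stream(1.0, {"amine": 0.3}, {"dcm": 1.0})

    route1 = mix(evaporate(a, spec), nmp_only)
    route2 = evaporate(mix(a, nmp_only), spec)
    assert route1.flow == pytest.approx(route2.flow)
    for k in route1.conc:
        assert route1.conc[k] == pytest.approx(route2.conc[k])

    route3 = mix(evaporate(a, spec), dcm_rich)
    route4 = evaporate(mix(a, dcm_rich), spec)
    assert route3.flow != pytest.approx(route4.flow)  # second stream's DCM also boils


def test_required_feed_conc_inverts_the_junction_balance():
    inter = _stream(1.0, {"bromide": 0.6427}, {"nmp": 1.0})
    assert required_feed_conc(inter, "bromide", 0.0, 1.0) == 0.0
    conc = required_feed_conc(inter, "bromide", 3.0, 1.0)
    assert conc == pytest.approx(1.928, abs=1e-3)
    assert required_feed_conc(inter, "bromide", 3.0, 2.0) == pytest.approx(conc / 2)
    with pytest.raises(ValueError):
        required_feed_conc(inter, "ketone", 3.0, 1.0)


def test_stream_validation():
    with pytest.raises(ValueError):
        Stream(flow=-1.0)
    with pytest.raises(ValueError):
        Stream(flow=1.0, conc={"x": -0.1})
    with pytest.raises(ValueError):
        Stream(flow=1.0, solvent_frac={"dcm": 0.4, "nmp": 0.4})


def test_chain_alignment_and_rate(telescoped_process):
    """The resolved chain reproduces the printed concentration alignment:
    3.0 amine equivalents at 1.928 M, and a steady rate near 2.88 g/h."""
    proc = telescoped_process
    streams = chain_streams(proc)
    evap = streams["evaporator_out"]
    needed = required_feed_conc(evap, "bromide", 3.0, proc.amine_flow)
    assert needed == pytest.approx(proc.amine_feed_conc, rel=1e-6)
    inlet = streams["stage2_inlet"]
    assert inlet.conc["amine"] / inlet.conc["bromide"] == pytest.approx(3.0, rel=1e-6)
    rate = telescoped_rate(proc)
    assert rate == pytest.approx(2.88, rel=0.10)


def test_chain_rate_bounded_by_stage2_standalone(telescoped_process):
    """Yields at or below one compose: the chained rate cannot exceed what
    stage 2 would produce if fed its inlet stream at unit yield upstream."""
    from flowopt.telescope import _stage_yield

    proc = telescoped_process
    streams = chain_streams(proc)
    inlet = streams["stage2_inlet"]
    standalone_cap = (
        inlet.species_rate("bromide") * 60.0 * proc.cal2.campaign.product_molar_mass
    )
    assert telescoped_rate(proc) <= standalone_cap + 1e-9
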