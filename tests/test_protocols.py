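"""Protocol construction, the named-experiment registry, and SR-content
preparation."""

import numpy as np
import pytest

from cicrsim import state as S
from cicrsim.protocols import (ClampProtocol, PharmacologyConfig,
                               build_named_protocol, clamp_voltage,
                               apply_sr_content_sweep, NAMED_PROTOCOLS)


def test_clamp_waveform_levels_and_transitions():
    p = ClampProtocol(holding=-40.0, level=10.0, duration=50.0,
                      pre_hold=100.0, transition=1.0)
    assert clamp_voltage(50.0, p) == -40.0          # before the pulse
    assert clamp_voltage(120.0, p) == 10.0          # mid-pulse
    assert clamp_voltage(100.5, p) == pytest.approx(-15.0)  # mid-ramp
    assert clamp_voltage(1e9, p) == -40.0


def test_protocol_round_trip():
    p = ClampProtocol(level=30.0, duration=80.0, n_pulses=3, frequency=2.0)
    q = ClampProtocol.from_dict(p.to_dict())
    assert q == p


def test_invalid_timing_rejected():
    with pytest.raises(ValueError):
        ClampProtocol(duration=-1.0)
    with pytest.raises(ValueError):
        ClampProtocol(duration=600.0, n_pulses=5, frequency=4.0)


@pytest.mark.parametrize("name, level, duration, n, freq", [
    ("fig14_train4hz", 10.0, 50.0, 10, 4.0),
    ("fig20_long", 10.0, 800.0, 40, 0.33),
    ("fig20_short", 10.0, 100.0, 40, 0.33),
    ("fig18_thapsigargin", 0.0, 100.0, 10, 0.05),
])
def test_named_protocols_match_printed_values(name, level, duration, n, freq):
    prot, _ = build_named_protocol(name)
    assert prot.level == level
    assert prot.duration == duration
    assert prot.n_pulses == n
    assert prot.frequency == freq


def test_s1s2_registry_entry():
    prot, pharm = build_named_protocol("fig13_s1s2")
    assert pharm.inject
    assert prot.meta["t2_list"] == list(range(50, 275, 25))


def test_unknown_protocol_raises():
    with pytest.raises(KeyError):
        build_named_protocol("fig99")
    assert "fig12_gain" in NAMED_PROTOCOLS


def test_pharmacology_validation():
    with pytest.raises(ValueError):
        PharmacologyConfig(barium=True, ryanodine=True).validate()
    with pytest.raises(ValueError):
        PharmacologyConfig(inject=True).validate()
    PharmacologyConfig(caffeine_um=5000.0).validate()


def test_sr_content_sweep_equilibrates_sensor(params, y0):
    """Each prepared state carries the target jSR Ca with the sensor at its
    conditional steady state (residual sensor rates ~0)."""
    from cicrsim.ryr import luminal_derivatives
    targets = [400.0, 918.0]
    family = apply_sr_content_sweep(y0, targets, params)
    lum = params.rates.luminal
    for tgt, y in zip(targets, family):
        assert y[S.CA_JSR] == pytest.approx(tgt * 1e-3)
        ls = np.array([y[S.LS_A1], y[S.LS_I2], y[S.LS_I3], y[S.LS_B6]])
        d = luminal_derivatives(
            ls, tgt, lum["k12_ls"], lum["k21_ls"], lum["k14_ls"],
            lum["k41_ls"], lum["k42_ls"], lum["k43_ls"], lum["k34_ls"],
            lum["k23_ls"], lum["k32_ls"], lum["k56_ls"], lum["k65_ls"],
            lum["k24_ls"], lum["k25_ls"])
        assert np.max(np.abs(d)) < 1e-6
    # sensitization rises with content
    assert family[1][S.LS_A1] > family[0][S.LS_A1]
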