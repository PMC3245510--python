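"""L-type channel: printed rate formulas, the CaM gate, derivatives and the
stationary distribution."""

import numpy as np
import pytest

from cicrsim import dhpr
from cicrsim.dhpr import (dhpr_rates, dhpr_derivatives, cam_gate_ks12,
                          cam_gate_derivative, channel_open_fraction,
                          stationary_occupancies, RATE_REGISTRY,
                          CASE_CONTROL, CASE_RYANODINE, CASE_BARIUM,
                          R_K12, R_K24, R_K36, R_K63, N_RATES)


def test_reexcitation_window_rates_at_midpoint():
    """k36/k63 sit at their half-activation exactly at +41 mV."""
    r = dhpr_rates(41.0, CASE_CONTROL, 0.0, 0.0, 0.0)
    assert r[R_K36] == pytest.approx(50.0)
    assert r[R_K63] == pytest.approx(300.0)


def test_barium_mode_blocks_ca_dependent_inactivation():
    for v in (-40.0, 0.0, 30.0):
        assert RATE_REGISTRY[("barium", "k24")](v, s2=0.5) == 0.0


def test_control_k24_scales_with_gate_occupancy():
    s2 = 0.3
    k24 = RATE_REGISTRY[("control", "k24")](10.0, s2=s2)
    assert k24 == pytest.approx(336160.0 * s2 / 550.0)


def test_cam_gate_reference_point_and_fixed_point():
    assert cam_gate_ks12(100.0) == pytest.approx(4.0)
    # steady state of the two-state gate at ks12 = 4
    s2_star = 4.0 / (4.0 + 18.0)
    assert cam_gate_derivative(s2_star, 100.0) == pytest.approx(0.0, abs=1e-12)
    # occupancy cannot grow past 1
    assert cam_gate_derivative(1.0, 100.0) <= 0.0


@pytest.mark.parametrize("mode", [CASE_CONTROL, CASE_RYANODINE, CASE_BARIUM])
def test_rates_finite_and_nonnegative_over_voltage_range(mode):
    for v in np.linspace(-100, 100, 201):
        r = dhpr_rates(v, mode, 0.5, 40.0, 300.0)
        assert np.all(np.isfinite(r))
        assert np.all(r >= 0.0)


def test_derivatives_zero_when_trapped_in_c1():
    r = np.zeros(N_RATES)
    r[R_K12] = 0.0
    occ = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    d = dhpr_derivatives(occ, r, False)
    assert np.all(d == 0.0)


def test_five_state_pool_conserved_by_construction():
    """Sum of (C1,O2,O3,C4) derivatives equals minus the implied C5 flux."""
    rng = np.random.default_rng(0)
    r = dhpr_rates(10.0, CASE_CONTROL, 0.3, 20.0, 100.0)
    occ = rng.dirichlet(np.ones(5))[:5]
    occ = np.append(occ[:4], 0.1)  # C6 outside the pool
    d = dhpr_derivatives(occ, r, False)
    c1, o2, o3, c4 = occ[:4]
    c5 = 1 - (c1 + o2 + o3 + c4)
    # recompute dC5 from the printed scheme and check it closes the pool
    dc5 = (r[dhpr.R_K15] * c1 + r[dhpr.R_K25] * o2 + r[dhpr.R_K45] * c4
           - (r[dhpr.R_K51] + r[dhpr.R_K52] + r[dhpr.R_K54]) * c5)
    assert d[0] + d[1] + d[2] + d[3] + dc5 == pytest.approx(0.0, abs=1e-9)


def test_c6_pure_decay_without_o3():
    r = dhpr_rates(10.0, CASE_CONTROL, 0.1, 0.0, 0.0)
    occ = np.array([0.5, 0.2, 0.0, 0.1, 0.3])
    d = dhpr_derivatives(occ, r, False)
    assert d[4] == pytest.approx(-r[R_K63] * 0.3 * 1.0)


def test_stationary_distribution_is_nullspace_fixed_point():
    """Relaxing the frozen generator leaves the stationary occupancies."""
    occ = stationary_occupancies(-40.0, CASE_CONTROL, ca4cam=0.086,
                                 camkii_act=5.0, can_act=350.0)
    r = dhpr_rates(-40.0, CASE_CONTROL, occ[5], 5.0, 350.0)
    d = dhpr_derivatives(occ[:5].copy(), r, False)
    # C6 is slaved, the conserved pool is stationary
    assert np.max(np.abs(d[:4])) < 1e-6
    assert occ[0] > 0.9       # holding potential parks the channel in C1


def test_open_fraction():
    assert channel_open_fraction(0.3, 0.2) == pytest.approx(0.5)
    assert channel_open_fraction(0.0, 0.0) == 0.0


def test_iv_peak_shifts_right_without_release_modes():
    """The steady-state I-V peak sits at more positive voltages for the
    ryanodine and barium rate sets than for control."""
    from cicrsim.currents import ghk_currents
    F, RT = 96485.0, 8314.0 * 290.0

    def peak_iv_v(mode):
        vs = np.linspace(-30, 60, 46)
        iv = []
        for v in vs:
            occ = stationary_occupancies(v, mode, ca4cam=0.086)
            i_ca, _, _ = ghk_currents(
                v, occ[1] + occ[2], 1e-4, 16.0, 140.0, 1.0, 140.0, 3.0,
                6.7367e-9, 8.0355e-11, 6.2088e-11, F, RT, 1.0)
            iv.append(i_ca)
        return vs[int(np.argmin(iv))]

    v_ctl = peak_iv_v(CASE_CONTROL)
    assert peak_iv_v(CASE_RYANODINE) > v_ctl
    assert peak_iv_v(CASE_BARIUM) >= v_ctl
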