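"""Membrane currents: GHK continuity, exchanger thermodynamics, pumps."""

import math

import numpy as np
import pytest

from cicrsim.currents import (ghk_currents, ncx_current, pmca_current,
                              nacs_current, background_na_current,
                              partition_tt_sl)

F, RT = 96485.0, 8314.0 * 290.0


def _ghk(v, opening=1.0, ca_i=1e-4, na_i=16.0, cs_i=140.0):
    return ghk_currents(v, opening, ca_i, na_i, cs_i,
                        1.0, 140.0, 3.0,
                        6.7367e-9, 8.0355e-11, 6.2088e-11, F, RT, 1.0)


def test_closed_channel_carries_no_current():
    assert _ghk(10.0, opening=0.0) == (0.0, 0.0, 0.0)


def test_ghk_continuous_across_zero_voltage():
    """The removable singularity at v=0 is bridged smoothly and matches the
    analytic limit P z^2 F^2/(RT) * (RT/zF) * (Ci - 341 Co)/... evaluated
    by series."""
    below = np.array(_ghk(-1e-6))
    above = np.array(_ghk(1e-6))
    at = np.array(_ghk(0.0))
    assert np.allclose(below, above, rtol=1e-6)
    assert np.allclose(at, 0.5 * (below + above), rtol=1e-6)
    # analytic v->0 limit of the Ca branch
    lim = 1e3 * 6.7367e-9 * 4.0 * F * (1e-4 - 341.0) / 2.0
    assert at[0] == pytest.approx(lim, rel=1e-4)


def test_ghk_inward_at_positive_test_potential():
    i_ca, _, _ = _ghk(10.0)
    assert i_ca < 0.0


def _ncx(v, ca_i, na_i=16.746):
    return ncx_current(v, ca_i, na_i, 1.0, 140.0,
                       125e-6, 1.14, 0.0036, 87.5, 12.3,
                       776.2392, F, RT, 1.0)


def test_ncx_reverses_sign_at_thermodynamic_equilibrium():
    """NUM2 = NUM3 defines the reversal; the current changes sign across
    the equilibrium Ca for fixed v and Na."""
    v, na = -40.0, 16.746
    ca_eq = math.exp(v * F / RT) * na ** 3 / (140.0 ** 3)
    assert _ncx(v, ca_eq * 0.9) > 0.0
    assert _ncx(v, ca_eq * 1.1) < 0.0
    assert _ncx(v, ca_eq) == pytest.approx(0.0, abs=1e-6)


def test_ncx_allosteric_gate_closes_at_vanishing_ca():
    assert abs(_ncx(-40.0, 1e-9)) < 1e-4
    assert _ncx(-40.0, 0.0) == 0.0


def test_ncx_matches_independent_formula_evaluation():
    """Brute-force scalar transcription of the exchanger expression."""
    v, ca, na = -40.0, 8.1027e-5, 16.746
    fv = F * v / RT
    num1 = 776.2392 / (1 + (125e-6 / ca) ** 2)
    num2 = math.exp(0.35 * fv) * na ** 3 * 1.0
    num3 = math.exp(-0.65 * fv) * 140.0 ** 3 * ca
    den = (1.14 * na ** 3 + 87.5 ** 3 * ca
           + 12.3 ** 3 * 1.0 * (1 + ca / 0.0036)
           + 0.0036 * 140.0 ** 3 * (1 + (na / 12.3) ** 3)
           + na ** 3 * 1.0 + 140.0 ** 3 * ca)
    expected = num1 * (num2 - num3) / (den * (1 + 0.27 * math.exp(-0.65 * fv)))
    assert _ncx(v, ca) == pytest.approx(expected, rel=1e-12)


def test_ncx_bounded_by_printed_maximum():
    for v in np.linspace(-100, 100, 41):
        for ca in (1e-5, 1e-4, 1e-3, 1e-2):
            assert abs(_ncx(v, ca)) <= 776.2392


def test_pmca_michaelis_points():
    assert pmca_current(5e-4, 5e-4, 1.15) == pytest.approx(1.15 / 2)
    assert pmca_current(1e3, 5e-4, 1.15) == pytest.approx(1.15, rel=1e-3)
    assert pmca_current(0.0, 5e-4, 1.15) == 0.0


def test_nacs_pump_limits():
    assert nacs_current(-40.0, 16.7, 0.0, 1.5, 214.0, 147.3, 1.0) == 0.0
    # Na saturation factor approaches 100
    sat = nacs_current(-40.0, 1e9, 3.0, 1.5, 214.0, 147.3, 1.0)
    lo = nacs_current(-40.0, 16.7, 3.0, 1.5, 214.0, 147.3, 1.0)
    assert sat / lo == pytest.approx(
        100.0 / (100.0 * 16.7 ** 1.5 / (16.7 ** 1.5 + 214.0 ** 1.5)),
        rel=1e-3)
    assert nacs_current(-40.0, 16.7, 3.0, 1.5, 214.0, 147.3, 1.0) > 0


def test_background_na_reversal_and_linearity():
    e_na = RT / F * math.log(140.0 / 16.746)
    assert background_na_current(e_na, 16.746, 140.0, 0.00141, F, RT) == \
        pytest.approx(0.0, abs=1e-12)
    i1 = background_na_current(e_na + 10, 16.746, 140.0, 0.00141, F, RT)
    i2 = background_na_current(e_na + 20, 16.746, 140.0, 0.00141, F, RT)
    assert i2 == pytest.approx(2 * i1)


def test_partition_sums_and_fraction():
    i_tt, i_sl = partition_tt_sl(-100.0, -100.0, 0.9)
    assert i_tt + i_sl == pytest.approx(-100.0)
    assert i_tt / (i_tt + i_sl) == pytest.approx(0.9)
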