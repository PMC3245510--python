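"""CaM/CaMKII/CaN network: closures, printed-state consistency,
conservation and monotone activation."""

import numpy as np
import pytest

from cicrsim import state as S
from cicrsim.parameters import pack_parameters, P_CAMTOT, P_BTOT, P_CNTOT
from cicrsim.cam_signaling import (cam_derivatives, camkii_activity,
                                   can_activity, free_pools, relax_network,
                                   I_C2, I_CB, I_C2B, I_C4B, I_NM, I_N2M,
                                   I_N4M, I_N4)


@pytest.fixture(scope="module")
def P(params):
    return pack_parameters(params)


def _block(y0):
    return y0[S.DY_CA2CAM:S.DY_CA2CAM + 14].copy()


def test_zero_ca_zero_complex_network_is_inert(P):
    """Without Ca every Ca-driven reaction is silent; the only residual
    flux is the Ca-independent binding of free CaM to its buffer."""
    blk = np.zeros(14)
    d = cam_derivatives(blk, 0.0, P)
    camb_rate = 3.5e-4 * 1e-3 * P[P_CAMTOT] * P[P_BTOT]
    assert d[I_CB] == pytest.approx(camb_rate)
    mask = np.ones(14, bool)
    mask[I_CB] = False
    assert np.allclose(d[mask], 0.0, atol=1e-12)


def test_printed_camkii_activity(y0):
    act = camkii_activity(_block(y0))
    expected = 100 * (3.661260e-1 + 9.121920e-8 + 6.277911e-7 + 1.314410e-3)
    assert act == pytest.approx(expected)


def test_printed_state_balances_the_fast_binding_step(y0, P):
    """The printed P1/P2 ratio matches the Ca2CaM binding equilibrium of
    the CaMKII scheme (k21*Ca2CaM/k12) to ~1%."""
    blk = _block(y0)
    p2 = 1 - (blk[5] + blk[6] + blk[7] + blk[8] + blk[9])
    ratio = blk[5] / p2  # P1/P2
    expected = 65.67164 * blk[I_C2] / 328.3582
    assert ratio == pytest.approx(expected, rel=0.02)


def test_free_pools_nonnegative_and_closure(y0, P):
    cam, b, ca2can, p2 = free_pools(_block(y0), P)
    assert cam >= 0 and b >= 0 and ca2can >= 0 and 0 <= p2 <= 1
    # CaN pool: free Ca2CaN + complexes = total
    blk = _block(y0)
    assert ca2can + blk[I_N4] + blk[I_NM] + blk[I_N2M] + blk[I_N4M] == \
        pytest.approx(P[P_CNTOT])


def test_relaxation_conserves_totals(y0, P):
    """CaM, buffer and CaN totals are conserved exactly by construction
    (free pools are closures); bound fractions drift but the invariant
    checked is the bounded, nonnegative evolution."""
    blk = _block(y0)
    out = relax_network(blk.copy(), 0.1, P, 2000.0, 1.0)
    assert np.all(out >= 0.0)
    cam0, b0, cn0, _ = free_pools(blk, P)
    cam1, b1, cn1, _ = free_pools(out, P)
    assert b1 <= P[P_BTOT] and cn1 <= P[P_CNTOT]
    assert np.isfinite([cam1, b1, cn1]).all()


def test_kinase_activation_monotone_in_sustained_ca(y0, P):
    """CaMKII and CaN activities respond monotonically to sustained Ca."""
    acts, cans = [], []
    for ca in (0.1, 0.5, 2.0, 10.0):
        out = relax_network(_block(y0), ca, P, 5000.0, 1.0)
        acts.append(camkii_activity(out))
        cans.append(can_activity(out))
    assert np.all(np.diff(acts) > 0)
    assert np.all(np.diff(cans) > 0)
    assert max(acts) <= 100.0 + 1e-9


def test_derivative_vector_finite_at_printed_state(y0, P):
    d = cam_derivatives(_block(y0), 0.0902, P)
    assert np.all(np.isfinite(d))


def test_subsystem_derivative_views(y0, P):
    from cicrsim.cam_signaling import camkii_derivatives, can_derivatives
    blk = _block(y0)
    dk, act = camkii_derivatives(blk, 0.1, P)
    dn, can = can_derivatives(blk, 0.1, P)
    full = cam_derivatives(blk, 0.1, P)
    assert np.allclose(dk, full[5:10])
    assert np.allclose(dn, full[10:14])
    assert act == pytest.approx(camkii_activity(blk))
    assert can == pytest.approx(can_activity(blk))
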