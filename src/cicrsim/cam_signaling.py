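"""Ca/calmodulin binding, CaM buffering, CaMKII activation (with
autophosphorylation and PP1 dephosphorylation) and calcineurin activation.

One network instance runs per compartment (dyadic space, driven by the mean
cleft Ca, and cytosol, driven by [Ca]_myo).  State species in uM, CaMKII
fractions P1..P6 dimensionless (P2 by closure); free CaM, free buffer B and
free Ca2CaN follow from the conserved totals.

The network is exposed both as plain derivatives (for tests and direct use)
and as a production/loss split (a, b with dx/dt = a - b*x) consumed by the
integrator's exponential update.  Rates per ms; Ca in uM.
"""

from __future__ import annotations

import numpy as np

from .dhpr import njit
from . import parameters as pm
from .parameters import (
    P_CAMTOT, P_BTOT, P_CKTOT, P_CNTOT, P_PP1TOT,
    P_CM_K02, P_CM_K20, P_CM_K24, P_CM_K42, P_CM_K0BON, P_CM_K0BOFF,
    P_CK_KPP1, P_CK_KMPP1, P_CK_K21, P_CK_K12, P_CK_K13, P_CK_K23,
    P_CK_K32, P_CK_K45, P_CK_K54, P_CK_K46, P_CK_K64, P_CK_K56, P_CK_K65,
    P_CN_KCAON, P_CN_KCAOFF, P_CN_K02, P_CN_K20, P_CN_K24, P_CN_K42,
    P_CN_K0ON, P_CN_K0OFF, P_CN_K2ON, P_CN_K2OFF, P_CN_K4ON, P_CN_K4OFF,
)

# species offsets within one 14-long network block
I_C2, I_C4, I_CB, I_C2B, I_C4B, I_P1, I_P3, I_P4, I_P5, I_P6, \
    I_N4, I_NM, I_N2M, I_N4M = range(14)


@njit(cache=True)
def free_pools(block, P, camtot=-1.0):
    """(CaM, B, Ca2CaN, P2) derived from the conservation closures,
    clipped at zero.  ``camtot`` overrides the cytosolic CaM total (the
    dyadic instance carries a nanodomain-enriched pool)."""
    if camtot < 0.0:
        camtot = P[P_CAMTOT]
    cam = (camtot - block[I_C2] - block[I_C4] - block[I_CB]
           - block[I_C2B] - block[I_C4B] - block[I_NM] - block[I_N2M]
           - block[I_N4M]
           - P[P_CKTOT] * (block[I_P1] + block[I_P3] + block[I_P5]
                           + block[I_P4]))
    b = P[P_BTOT] - (block[I_CB] + block[I_C2B] + block[I_C4B])
    ca2can = (P[P_CNTOT] - block[I_N4] - block[I_NM] - block[I_N2M]
              - block[I_N4M])
    p2 = 1.0 - (block[I_P1] + block[I_P3] + block[I_P4] + block[I_P5]
                + block[I_P6])
    return max(cam, 0.0), max(b, 0.0), max(ca2can, 0.0), max(p2, 0.0)


@njit(cache=True)
def camkii_activity(block):
    """Percent-scale CaMKII activity: 100*(P3+P4+P5+P6)."""
    return 100.0 * (block[I_P3] + block[I_P4] + block[I_P5] + block[I_P6])


@njit(cache=True)
def can_activity(block):
    """Weighted calcineurin activity (percent-like scale)."""
    return (100.0 * (block[I_N4M] + 0.1 * block[I_N2M])
            + 10.0 * block[I_N4M] + 0.1 * block[I_NM] + 0.1 * block[I_N4])


@njit(cache=True)
def network_ab(block, ca_um, P, a, b, camtot=-1.0):
    """Fill production a[14] and loss-rate b[14] for one network instance."""
    cam, bfree, ca2can, p2 = free_pools(block, P, camtot)
    ca2 = ca_um * ca_um
    cktot = P[P_CKTOT]
    pp1 = P[P_CK_KPP1] * P[P_PP1TOT]
    kmpp1 = P[P_CK_KMPP1]

    c2, c4 = block[I_C2], block[I_C4]
    cb, c2b, c4b = block[I_CB], block[I_C2B], block[I_C4B]
    p1, p3, p4, p5, p6 = (block[I_P1], block[I_P3], block[I_P4],
                          block[I_P5], block[I_P6])
    n4, nm, n2m, n4m = block[I_N4], block[I_NM], block[I_N2M], block[I_N4M]

    k02, k20 = P[P_CM_K02], P[P_CM_K20]
    k24, k42 = P[P_CM_K24], P[P_CM_K42]
    k0bon, k0boff = P[P_CM_K0BON], P[P_CM_K0BOFF]
    k02b, k20b = k02, k20 / 100.0          # buffered-CaM variants per table
    k24b, k42b = k24, k42
    k2bon = k4bon = k0bon
    k2boff = k4boff = k0boff

    # Ca2CaM
    a[I_C2] = (k02 * ca2 * cam + k42 * c4 + k2boff * c2b
               + P[P_CN_K2OFF] * n2m
               + cktot * (P[P_CK_K56] * p5 + P[P_CK_K12] * p1))
    b[I_C2] = (k20 + k24 * ca2 + k2bon * bfree + P[P_CN_K2ON] * n4
               + cktot * (P[P_CK_K65] * p6 + P[P_CK_K21] * p2))
    # Ca4CaM
    a[I_C4] = (k24 * ca2 * c2 + P[P_CN_K4OFF] * n4m + k4boff * c4b
               + cktot * (P[P_CK_K46] * p4 + P[P_CK_K32] * p3))
    b[I_C4] = (k42 + P[P_CN_K4ON] * n4 + k4bon * bfree
               + cktot * (P[P_CK_K64] * p6 + P[P_CK_K23] * p2))
    # CaMB
    a[I_CB] = k0bon * cam * bfree + k20b * c2b
    b[I_CB] = k0boff + k02b * ca2
    # Ca2CaMB
    a[I_C2B] = k02b * ca2 * cb + k2bon * c2 * bfree + k42b * c4b
    b[I_C2B] = k20b + k2boff + k24b * ca2
    # Ca4CaMB
    a[I_C4B] = k24b * ca2 * c2b + k4bon * c4 * bfree
    b[I_C4B] = k42b + k4boff
    # CaMKII fractions
    t = p3 + p4 + p5 + p6
    k34 = (0.055 * t + 0.0074 * t * t + 0.015 * t * t * t) * 1e-3  # 1/ms
    a[I_P1] = (P[P_CK_K21] * c2 * p2
               + pp1 * p5 / (kmpp1 + cktot * p5)
               + P[P_CK_K32] * p3)
    b[I_P1] = P[P_CK_K12] + P[P_CK_K13] * ca2
    a[I_P3] = (P[P_CK_K23] * c4 * p2 + P[P_CK_K13] * ca2 * p1
               + pp1 * p4 / (kmpp1 + cktot * p4))
    b[I_P3] = 2.0 * P[P_CK_K32] + k34
    a[I_P4] = k34 * p3 + P[P_CK_K64] * c4 * p6 + P[P_CK_K54] * ca2 * p5
    b[I_P4] = P[P_CK_K46] + P[P_CK_K45] + pp1 / (kmpp1 + cktot * p4)
    a[I_P5] = P[P_CK_K45] * p4 + P[P_CK_K65] * c2 * p6
    b[I_P5] = (P[P_CK_K54] * ca2 + P[P_CK_K56]
               + pp1 / (kmpp1 + cktot * p5))
    a[I_P6] = P[P_CK_K46] * p4 + P[P_CK_K56] * p5
    b[I_P6] = (P[P_CK_K64] * c4 + P[P_CK_K65] * c2
               + pp1 / (kmpp1 + cktot * p6))
    # CaN species
    a[I_N4] = (P[P_CN_KCAON] * ca2 * ca2can + P[P_CN_K0OFF] * nm
               + P[P_CN_K2OFF] * n2m + P[P_CN_K4OFF] * n4m)
    b[I_N4] = (P[P_CN_KCAOFF] + P[P_CN_K0ON] * cam + P[P_CN_K2ON] * c2
               + P[P_CN_K4ON] * c4)
    a[I_NM] = P[P_CN_K0ON] * cam * n4 + P[P_CN_K20] * n2m
    b[I_NM] = P[P_CN_K0OFF] + P[P_CN_K02] * ca2
    a[I_N2M] = (P[P_CN_K2ON] * c2 * n4 + P[P_CN_K02] * ca2 * nm
                + P[P_CN_K42] * n4m)
    b[I_N2M] = P[P_CN_K2OFF] + P[P_CN_K20] + P[P_CN_K24] * ca2
    a[I_N4M] = P[P_CN_K4ON] * c4 * n4 + P[P_CN_K24] * ca2 * n2m
    b[I_N4M] = P[P_CN_K4OFF] + P[P_CN_K42]


@njit(cache=True)
def relax_network(block, ca_um, P, t_ms, dt, camtot=-1.0):
    """Relax one network instance at fixed Ca by the exponential update;
    returns the block after t_ms."""
    a = np.zeros(14)
    b = np.zeros(14)
    n = int(t_ms / dt)
    for _ in range(n):
        network_ab(block, ca_um, P, a, b, camtot)
        for k in range(14):
            if b[k] * dt > 1e-8:
                xinf = a[k] / b[k]
                block[k] = xinf + (block[k] - xinf) * np.exp(-b[k] * dt)
            else:
                block[k] = block[k] + (a[k] - b[k] * block[k]) * dt
            if block[k] < 0.0:
                block[k] = 0.0
    return block


def cam_derivatives(block, ca_um, params: "pm.ModelParameters | np.ndarray",
                    camtot: float = -1.0):
    """Plain d/dt (per ms) of one 14-species network block."""
    P = params if isinstance(params, np.ndarray) else pm.pack_parameters(params)
    block = np.asarray(block, dtype=float)
    a = np.zeros(14)
    b = np.zeros(14)
    network_ab(block, float(ca_um), P, a, b, camtot)
    return a - b * block


def camkii_derivatives(block, ca_um, params, camtot: float = -1.0):
    """(dP1, dP3, dP4, dP5, dP6) per ms and the percent-scale activity."""
    d = cam_derivatives(block, ca_um, params, camtot)
    return d[I_P1:I_P6 + 1], camkii_activity(np.asarray(block, dtype=float))


def can_derivatives(block, ca_um, params, camtot: float = -1.0):
    """(dCa4CaN, dCaMCaN, dCa2CaMCaN, dCa4CaMCaN) per ms and the weighted
    calcineurin activity."""
    d = cam_derivatives(block, ca_um, params, camtot)
    return d[I_N4:I_N4M + 1], can_activity(np.asarray(block, dtype=float))
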