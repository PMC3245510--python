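"""Six-state Markov model of the DHP-sensitive L-type Ca channel.

Three pharmacological rate sets are provided: ``CASE_CONTROL`` (CICR intact),
``CASE_RYANODINE`` (RyR release blocked) and ``CASE_BARIUM`` (Ba2+ as charge
carrier; all Ca-dependent inactivation off, k24 = 0).  A two-state gate (S2)
carries the Ca4CaM interaction that drives Ca-dependent inactivation, and the
high-voltage state C6 recruits "silent" channels for tail currents.

All rate functions return 1/s (as printed); the integrator converts to the
canonical ms time base.  Voltage in mV.  Rates are clamped at zero where the
printed sigmoidal fits dip marginally negative.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
except ImportError:                                        # pragma: no cover
    def njit(*a, **k):
        if a and callable(a[0]):
            return a[0]
        return lambda f: f

CASE_CONTROL = 0
CASE_RYANODINE = 1
CASE_BARIUM = 2

# rate-vector layout
R_K12, R_K21, R_K23, R_K32, R_K24, R_K42, R_K25, R_K52, \
    R_K45, R_K54, R_K15, R_K51, R_K36, R_K63 = range(14)
N_RATES = 14

KS21 = 18.0  # S2 -> S1 unbinding rate (1/s)


@njit(cache=True)
def _sig(x):
    """1/(1+exp(x)) with overflow guard."""
    if x > 500.0:
        return 0.0
    if x < -500.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


@njit(cache=True)
def cam_gate_ks12(ca4cam_dhp):
    """Ca4CaM-dependent binding rate to the channel IQ motif (1/s)."""
    e = (ca4cam_dhp - 100.0) / 90.0
    if e > 500.0:
        e = 500.0
    return 4.0 * math.exp(e)


@njit(cache=True)
def cam_gate_derivative(s2, ca4cam_dhp):
    """dS2/dt (1/s); S1 = 1 - S2."""
    return cam_gate_ks12(ca4cam_dhp) * (1.0 - s2) - KS21 * s2


@njit(cache=True)
def xi_factor(camkii_act, can_act):
    """Kinase/phosphatase modulation of the inactivation pathways."""
    return 550.0 + 6.0 * camkii_act + can_act


@njit(cache=True)
def dhpr_rates(v, mode, s2, camkii_act, can_act):
    """All transition rates (1/s) of the 6-state scheme for one voltage.

    ``mode`` selects the control / ryanodine / barium rate set; ``s2`` is the
    CaM-gate occupancy feeding the Ca-dependent O2->C4 rate.
    """
    r = np.zeros(N_RATES)
    xi = xi_factor(camkii_act, can_act)

    if mode == CASE_CONTROL:
        r[R_K12] = 300.3808 - 301.0817 * _sig((v - 13.5918) / 8.85)
        r[R_K21] = 3359.8754 + 966.95 * _sig((v - 1.66) / 1.4585)
        r[R_K24] = 336160.0 * s2 / xi
        r[R_K25] = (5939.4 + 306806.8 * _sig((v + 1.8716) / 1.3072)) / xi
        r[R_K52] = 0.02925 + 0.48961 * _sig((v + 12.2249) / 0.974)
        r[R_K23] = 1352.0 - 1350.0 * _sig(v / 1.8) + 1700.0 * _sig(v + 5.0)
        r[R_K32] = 1030.0575 - 713.1966 * _sig(v - 5.0)
        r[R_K51] = (383.5435 * _sig(-(v - 8.3702) / 7.047)
                    + 0.16725 * _sig(-(v - 31.8252) / 0.01075)
                    + 378.7085 * _sig((v - 7.8953) / 6.7691)
                    - 373.015)
    elif mode == CASE_RYANODINE:
        r[R_K12] = 30392.87 - 30394.73 * _sig((v - 183.5975) / 28.5662)
        r[R_K21] = 3568.74658 + 21921.25344 * _sig((v + 24.9838) / 0.7372)
        r[R_K24] = 336160.0 * s2 / xi
        r[R_K25] = (0.0893 + 26.3268 * _sig((v + 15.0) / 1.0)
                    + 32.6642 * _sig(-(v - 14.4897) / 0.3131)
                    + 63.808 * _sig((v - 27.411) / 0.0854)) / xi
        r[R_K52] = (2.69 + 0.74152 * _sig((v + 27.945) / 1.46976)
                    - 2.43098 * _sig((v - 40.25) / 0.4034))
        r[R_K23] = (1908.0 - 2687.3087 * _sig((v + 15.0) / 0.9998)
                    + 879.543 * _sig((v - 11.1635) / 0.3238))
        r[R_K32] = (145107.50934 - 150299.048 * _sig((v - 1037.5224) / 312.91482)
                    + 5537.7875 * _sig((v - 9.4649) / 0.2893))
        r[R_K51] = (27.651 * _sig(-(v - 59.48) / 4.444)
                    + 11.488 * _sig(-(v + 15.1148) / 0.9423)
                    - 16.3777 * _sig(-(v + 15.01) / 0.6351)
                    + 5.3384)
    else:  # CASE_BARIUM
        r[R_K12] = (3028.7604 - 6279.833 * _sig((v - 58.1484) / 9.5348)
                    + 3259.706 * _sig((v - 40.2856) / 0.2272))
        r[R_K21] = (26296.0826 * _sig((v + 17.40398) / 0.22797)
                    + 4718.8152 * _sig(-(v + 1.4892) / 4.9581)
                    + 1544.9745 * _sig(-(v - 132.7305) / 3.6234)
                    - 808.0319)
        r[R_K24] = 0.0
        r[R_K25] = (-5883.3476 + 5973.3014 * _sig((v - 41.4221) / 0.5703)
                    + 528.171 * _sig(-(v - 20.4274) / 0.187))
        r[R_K52] = (175.78742 - 174.7872 * _sig((v - 32.3072) / 4.4783)
                    - 229.8479 * _sig(-(v - 36.9508) / 5.4521))
        r[R_K23] = (2601.9597 * _sig((v - 19.882) / 0.4459)
                    - 2647.5114 * _sig((v + 15.6872) / 2.1947)
                    - 2501.6394 * _sig((v - 39.8404) / 0.3926)
                    + 2647.2042)
        r[R_K32] = (1683.7686 * _sig(-(v - 20.0452) / 0.40326)
                    + 2161.9699 * _sig((v - 360.2862) / 1879.441)
                    - 5926.5225 * _sig(-(v + 1.7842) / 13.43183)
                    + 4129.8882)
        r[R_K51] = (11.1993 * _sig(-(v - 35.2478) / 0.2466)
                    + 36.2341 * _sig(-(v + 23.9615) / 15.8653)
                    - 12.163 * _sig(-(v - 27.1529) / 0.9455)
                    + 37.7673)

    r[R_K36] = 100.0 - 100.0 * _sig(v - 41.0)
    r[R_K63] = 600.0 * _sig(v - 41.0)
    r[R_K42] = 1000.0
    r[R_K45] = 600000.0

    for i in range(N_RATES):
        if r[i] < 0.0:
            r[i] = 0.0
        if not np.isfinite(r[i]):
            raise ValueError("non-finite DHPR rate")

    # detailed-balance closures of the C5-C4-O2 and C1-O2-C5 loops
    if r[R_K25] > 0.0:
        r[R_K54] = r[R_K45] * r[R_K52] * r[R_K24] / (r[R_K42] * r[R_K25])
    if r[R_K52] > 0.0 and r[R_K21] > 0.0:
        r[R_K15] = r[R_K51] * r[R_K12] * r[R_K25] / (r[R_K52] * r[R_K21])
    return r


@njit(cache=True)
def dhpr_derivatives(occ, r, conserve_c6):
    """Time derivatives (1/s) of (C1, O2, O3, C4, C6); C5 by closure.

    ``conserve_c6`` adds the symmetric -k36*O3 loss from O3 that the printed
    scheme omits (C6 is otherwise a bookkeeping state outside the conserved
    5-state pool).
    """
    c1, o2, o3, c4, c6 = occ[0], occ[1], occ[2], occ[3], occ[4]
    c5 = 1.0 - (c1 + o2 + o3 + c4)
    d = np.empty(5)
    d[0] = r[R_K21] * o2 + r[R_K51] * c5 - (r[R_K12] + r[R_K15]) * c1
    d[1] = (r[R_K12] * c1 + r[R_K42] * c4 + r[R_K32] * o3 + r[R_K52] * c5
            - (r[R_K21] + r[R_K23] + r[R_K24] + r[R_K25]) * o2)
    d[2] = r[R_K23] * o2 - r[R_K32] * o3
    if conserve_c6:
        d[2] -= r[R_K36] * o3
    d[3] = r[R_K54] * c5 + r[R_K24] * o2 - (r[R_K45] + r[R_K42]) * c4
    d[4] = r[R_K36] * o3 - r[R_K63] * c6
    return d


@njit(cache=True)
def channel_open_fraction(o2, o3):
    """Conducting fraction O2+O3 entering the GHK currents."""
    return o2 + o3


def closure_c5(occ) -> float:
    """Dependent state C5 = 1 - (C1+O2+O3+C4)."""
    return 1.0 - (occ[0] + occ[1] + occ[2] + occ[3])


def stationary_occupancies(v, mode=CASE_CONTROL, s2=None, ca4cam=0.0,
                           camkii_act=0.0, can_act=0.0):
    """Stationary distribution of the frozen 5-state generator at voltage v.

    Returns (C1, O2, O3, C4, C6, S2): the nullspace of the conserved
    {C1,O2,O3,C4,C5} pool's generator, the slaved C6 = k36*O3/k63, and the
    CaM-gate fixed point S2 = ks12/(ks12+ks21) (used for the rates if ``s2``
    is not given).
    """
    if s2 is None:
        ks12 = cam_gate_ks12(ca4cam)
        s2 = ks12 / (ks12 + KS21)
    r = dhpr_rates(v, mode, s2, camkii_act, can_act)
    # states ordered C1, O2, O3, C4, C5
    q = np.zeros((5, 5))

    def link(i, j, k):          # i -> j at rate k
        q[i, i] -= k
        q[j, i] += k

    link(0, 1, r[R_K12]); link(1, 0, r[R_K21])
    link(1, 2, r[R_K23]); link(2, 1, r[R_K32])
    link(1, 3, r[R_K24]); link(3, 1, r[R_K42])
    link(1, 4, r[R_K25]); link(4, 1, r[R_K52])
    link(3, 4, r[R_K45]); link(4, 3, r[R_K54])
    link(0, 4, r[R_K15]); link(4, 0, r[R_K51])
    a = np.vstack([q, np.ones(5)])
    rhs = np.zeros(6)
    rhs[5] = 1.0
    occ, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    occ = np.clip(occ, 0.0, None)
    occ /= occ.sum()
    c6 = r[R_K36] * occ[2] / r[R_K63] if r[R_K63] > 0 else 0.0
    return np.array([occ[0], occ[1], occ[2], occ[3], min(c6, 1.0), s2])


# Table-driven registry for unit-testing individual printed formulas.
def _mk(idx, mode):
    def f(v, s2=0.0, camkii_act=0.0, can_act=0.0):
        return float(dhpr_rates(v, mode, s2, camkii_act, can_act)[idx])
    return f


RATE_REGISTRY = {
    (mode_name, rate_name): _mk(idx, mode)
    for mode, mode_name in ((CASE_CONTROL, "control"),
                            (CASE_RYANODINE, "ryanodine"),
                            (CASE_BARIUM, "barium"))
    for rate_name, idx in (("k12", R_K12), ("k21", R_K21), ("k23", R_K23),
                           ("k32", R_K32), ("k24", R_K24), ("k42", R_K42),
                           ("k25", R_K25), ("k52", R_K52), ("k45", R_K45),
                           ("k54", R_K54), ("k15", R_K15), ("k51", R_K51),
                           ("k36", R_K36), ("k63", R_K63))
}
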