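"""Sarcolemmal currents: GHK fluxes through the L-type channel, NCX, PMCA,
the Na/Cs pump and the background Na current.

Sign convention: inward currents are negative; for the exchanger and pumps a
positive current extrudes the pumped species' net positive charge (NCX
positive = Ca extrusion, 1 net charge per Ca; PMCA/NaCs positive = outward).

Voltages in mV, concentrations in mM, currents in pA.  Whole-cell currents;
unitary (per-dyad) currents are the T-tubular share divided by N_dyad.
"""

from __future__ import annotations

import math

from .dhpr import njit

_X_SMALL = 1e-4


@njit(cache=True)
def _ghk_drive(ci, co, x, xden):
    """(ci*e^x - co)/(e^xden - 1) * xden, the bounded part of the GHK flux.

    Multiplied by the linear prefactor outside.  Handles the removable
    singularity at zero voltage by a second-order expansion.
    """
    if abs(xden) < _X_SMALL:
        # x and xden vanish together (both proportional to v)
        return (ci - co) + ci * x - (ci - co) * xden * 0.5
    return (ci * math.exp(x) - co) / (math.exp(xden) - 1.0) * xden


@njit(cache=True)
def ghk_currents(v, open_fraction, ca_dhp, na_dhp, cs_dhp,
                 ca_o, na_o, cs_o, p_ca, p_na, p_cs,
                 faraday, rt, r_cal):
    """(I_CaL, I_Na, I_Cs) through the open L-type channels (pA, whole cell).

    The Ca flux uses the printed external activity factor 341*[Ca]_o; the
    Na/Cs branches carry the printed Ca-block prefactor and, for Cs, the
    k_Cs=0.5 exponent in the denominator's driving term.
    """
    fvrt = faraday * v / rt
    # Ca2+: z=2 (the drive helper already carries one factor of fvrt)
    pref_ca = r_cal * open_fraction * p_ca * 4.0 * faraday * 1e3
    i_cal = pref_ca * _ghk_drive(ca_dhp, 341.0 * ca_o, 2.0 * fvrt, 2.0 * fvrt) / 2.0

    # Ca-dependent block shared by the monovalent branches
    blk_num = 1.056 * math.exp((v - 21.73) / 21.23841)
    blk = blk_num / (blk_num + ca_o)

    pref_na = open_fraction * p_na * faraday * 1e3 * blk
    i_na = pref_na * _ghk_drive(0.75 * na_dhp, 0.75 * na_o, fvrt, fvrt)

    pref_cs = open_fraction * p_cs * faraday * 1e3 * blk
    i_cs = pref_cs * _ghk_drive(0.75 * cs_dhp, 0.75 * cs_o, fvrt, 0.5 * fvrt) * 2.0

    return i_cal, i_na, i_cs


@njit(cache=True)
def ncx_current(v, ca_i, na_i, ca_o, na_o,
                k_mallo, k_mcao, k_mcai, k_mnao, k_mnai,
                v_max, faraday, rt, r_naca):
    """Na/Ca exchanger current (pA).

    Positive current is reverse mode (3 Na out / 1 Ca in, net charge
    outward); forward-mode Ca extrusion carries an inward (negative)
    current.  Allosteric Ca activation 1/(1+(K_mAllo/Ca)^2) and the full
    substrate denominator; ca_i/na_i are the concentrations at the
    exchanger mouth.
    """
    if ca_i <= 0.0:
        return 0.0
    fvrt = faraday * v / rt
    num1 = r_naca * v_max / (1.0 + (k_mallo / ca_i) ** 2)
    num2 = math.exp(0.35 * fvrt) * na_i ** 3 * ca_o
    num3 = math.exp(-0.65 * fvrt) * na_o ** 3 * ca_i
    den = (k_mcao * na_i ** 3
           + k_mnao ** 3 * ca_i
           + k_mnai ** 3 * ca_o * (1.0 + ca_i / k_mcai)
           + k_mcai * na_o ** 3 * (1.0 + (na_i / k_mnai) ** 3)
           + na_i ** 3 * ca_o
           + na_o ** 3 * ca_i)
    if den <= 0.0:
        raise ValueError("NCX denominator vanished")
    return num1 * (num2 - num3) / (den * (1.0 + 0.27 * math.exp(-0.65 * fvrt)))


@njit(cache=True)
def pmca_current(ca_myo, k_mpca, i_max):
    """Plasma-membrane Ca pump (pA, outward positive); Michaelis in Ca_myo."""
    return i_max * ca_myo / (k_mpca + ca_myo)


@njit(cache=True)
def nacs_current(v, na_myo, cs_o, k_mcs, k_mna, i_max, r_nacs):
    """Na/Cs pump current (pA, outward positive): Cs-activated, Na-dependent
    with the printed 100x saturation factor and voltage dependence."""
    na15 = na_myo ** 1.5
    return (r_nacs * i_max
            * cs_o / (cs_o + k_mcs)
            * 100.0 * na15 / (na15 + k_mna ** 1.5)
            * 0.65558 / (0.18445 + math.exp(-(v + 53.353) / 15.58)))


@njit(cache=True)
def background_na_current(v, na_myo, na_o, g_nab, faraday, rt):
    """Ohmic background Na current (pA); negative (inward) below E_Na."""
    e_na = rt / faraday * math.log(na_o / na_myo)
    return g_nab * (v - e_na)


def partition_tt_sl(i_total_tt_env, i_total_sl_env, f_tt):
    """Split a current computed in the two membrane environments.

    The T-tubular share f_tt of the channels sees the dyadic-mouth
    concentrations, the remainder the bulk cytosol; the whole-cell current is
    the sum of the two weighted components.
    """
    i_tt = f_tt * i_total_tt_env
    i_sl = (1.0 - f_tt) * i_total_sl_env
    return i_tt, i_sl
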