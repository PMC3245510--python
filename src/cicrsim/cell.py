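"""Whole-cell assembly and fixed-step integration.

One integration step advances three sub-systems, each with a scheme suited to
its stiffness, on a common fixed dt (default 1 us):

* compartment concentrations (Ca/Na/Cs in cytosol, jSR, LSR, dyad pools) by
  the Merson variant of fixed-step RK4, re-evaluating the concentration-
  dependent fluxes at every stage;
* all Markov/gating/signaling states by a locally exact exponential update
  (each state's ODE frozen to dx/dt = a - b x over the step), which the
  luminal-sensor feedback rates require — they reach ~1e6/s during the
  refractory period and no explicit scheme survives them;
* the 2-D cleft diffusion field by the unconditionally stable ADI split.

Everything is deterministic; identical configurations produce bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import state as S
from . import parameters as pm
from .parameters import (
    pack_parameters,
    P_NDYAD, P_VMYO, P_VLSR, P_VJSR, P_VCLEFT, P_DR, P_DZ, P_NR, P_NZ,
    P_F, P_RT, P_CAO, P_NAO, P_CSO, P_PCA, P_PNA, P_PCS,
    P_KMALLO, P_KMCAO, P_KMCAI, P_KMNAO, P_KMNAI, P_VMAXNCX,
    P_KMPCA, P_IPMCA, P_KMCS, P_KMNA, P_INACS, P_GNAB,
    P_TAUTR, P_TAUNA, P_TAUCS, P_PRYR, P_DCA,
    P_NH, P_NL, P_KH, P_KL, P_MGMYO, P_F3TOT, P_F3ON, P_F3OFF,
    P_K12PLB, P_K21PLB, P_KCYT, P_KSR, P_SERCATOT, P_PSR, P_PKA,
    P_RCAL, P_RNACA, P_RNACS, P_FTT,
    P_LS_K12, P_LS_K21, P_LS_K14, P_LS_K41, P_LS_K42, P_LS_K43,
    P_LS_K34, P_LS_K23, P_LS_K32, P_LS_K56, P_LS_K65, P_LS_K24, P_LS_K25,
    P_CKTOT, P_RIMSCALE, P_CONSC6, P_F2TOT, P_F2ON, P_F2OFF, P_CAMTOT_DY,
    P_CK_MM_REG, P_CN_MM_REG,
)
from .dhpr import (njit, dhpr_rates, cam_gate_ks12, KS21,
                   R_K12, R_K21, R_K23, R_K32, R_K24, R_K42, R_K25, R_K52,
                   R_K45, R_K54, R_K15, R_K51, R_K36, R_K63,
                   CASE_CONTROL, CASE_RYANODINE, CASE_BARIUM)
from .ryr import (luminal_var, ryr_rates, caffeine_open_probability,
                  ryr_current, Q_K12, Q_K21, Q_K14, Q_K41, Q_K43, Q_K34,
                  Q_K23, Q_K32)
from .currents import (ghk_currents, ncx_current, pmca_current, nacs_current,
                       background_na_current)
from .sr_transport import serca_fluxes, serca_buffer_ab, plb_ab
from .cam_signaling import network_ab, camkii_activity, can_activity
from .buffering import buffer_derivatives, occupancy_flux_to_balance, buffer_ab
from .dyad_diffusion import (adi_step, beta_factor, rim_efflux_current,
                             mean_concentration, face_mean_concentration,
                             source_field, make_grid)
from .protocols import ClampProtocol, PharmacologyConfig

REC_COLUMNS = [
    "t", "v", "Ca_myo", "Ca_jSR", "Ca_LSR", "Ca_dyad_mean", "Ca_dhp",
    "Ca_ryr", "CaF3", "CaF2", "O2_ryr", "open_TT", "open_SL",
    "I_CaL", "I_CaL_TT", "I_CaL_SL", "i_CaL_TT_unit",
    "I_NaCa_TT", "I_NaCa_SL", "I_PMCA", "I_NaCs", "I_Nab",
    "i_ryr", "I_ryr", "i_tr", "I_cyt_serca", "I_serca_sr", "I_dyad",
    "CaMKII_dyad", "CaN_dyad", "CaMKII_cyt", "CaN_cyt",
    "var", "A1_ls", "B6_ls",
    "cdi_rate_TT", "vdi_rate_TT", "cdi_rate_SL", "vdi_rate_SL",
    "O_c", "O_tc", "O_tmgc", "O_tmgmg", "I_Na", "I_Cs",
    "PLB_dp", "Ca_serca",
]
N_REC = len(REC_COLUMNS)

CSQ_CAP_MM = 31.0   # calsequestrin buffering of the jSR Ca balance (mM)


@njit(cache=True)
def _interp(t, ts, vs):
    n = ts.shape[0]
    if t <= ts[0]:
        return vs[0]
    if t >= ts[n - 1]:
        return vs[n - 1]
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ts[mid] <= t:
            lo = mid
        else:
            hi = mid
    w = (t - ts[lo]) / (ts[hi] - ts[lo])
    return vs[lo] + w * (vs[hi] - vs[lo])


@njit(cache=True)
def _schedule_value(t, ts, vs, default):
    out = default
    for k in range(ts.shape[0]):
        if t >= ts[k]:
            out = vs[k]
    return out


@njit(cache=True)
def _injected_current(t, inj_t, inj_i, starts):
    total = 0.0
    if inj_t.shape[0] < 2:
        return 0.0
    dur = inj_t[inj_t.shape[0] - 1]
    for k in range(starts.shape[0]):
        tau = t - starts[k]
        if 0.0 <= tau <= dur:
            total += _interp(tau, inj_t, inj_i)
    return total


@njit(cache=True)
def _conc_rhs(c, P, v, cao, open_tt_frozen, i_cal_sl_frozen, barium,
              o2_eff, i_dyad0, rim_coupling, ca_myo0,
              ca_ryr, ck_mm_cy, plb, caserca, thaps_active,
              ls_b5, ls_b6, occ, caf3, caf2, fura2_on):
    """d/dt (per ms) of the 7 compartment concentrations.

    c = (Ca_myo, Ca_jSR, Ca_LSR, Na_myo, Na_dyad, Cs_myo, Cs_dyad) in mM.
    Quantities that live on the cleft grid or in gating states are frozen
    over the step and passed in.
    """
    ca_myo, ca_jsr, ca_lsr = c[0], c[1], c[2]
    na_myo, na_dyad = c[3], c[4]
    cs_myo, cs_dyad = c[5], c[6]
    F = P[P_F]
    f_tt = P[P_FTT]

    i_pmca = pmca_current(ca_myo, P[P_KMPCA], P[P_IPMCA])
    i_naca_sl = (1.0 - f_tt) * ncx_current(
        v, ca_myo, na_myo, cao, P[P_NAO],
        P[P_KMALLO], P[P_KMCAO], P[P_KMCAI], P[P_KMNAO], P[P_KMNAI],
        P[P_VMAXNCX], F, P[P_RT], P[P_RNACA])
    i_naca_tt = f_tt * ncx_current(
        v, ca_myo0, na_dyad, cao, P[P_NAO],
        P[P_KMALLO], P[P_KMCAO], P[P_KMCAI], P[P_KMNAO], P[P_KMNAI],
        P[P_VMAXNCX], F, P[P_RT], P[P_RNACA])
    i_nacs_sl = (1.0 - f_tt) * nacs_current(
        v, na_myo, P[P_CSO], P[P_KMCS], P[P_KMNA], P[P_INACS], P[P_RNACS])
    i_nacs_tt = f_tt * nacs_current(
        v, na_dyad, P[P_CSO], P[P_KMCS], P[P_KMNA], P[P_INACS], P[P_RNACS])
    i_nab = background_na_current(v, na_myo, P[P_NAO], P[P_GNAB], F, P[P_RT])

    j_cyt, j_sr = serca_fluxes(ca_myo, ca_lsr, caserca, ck_mm_cy, plb,
                               P[P_KCYT], P[P_KSR], P[P_SERCATOT],
                               P[P_PSR], thaps_active)

    i_tr = (ca_lsr - ca_jsr) / P[P_TAUTR] * 2.0 * F * P[P_VJSR] * 1e3
    i_ryr = ryr_current(o2_eff, ca_jsr, ca_ryr, P[P_PRYR], F)
    i_dyad = i_dyad0 - rim_coupling * (ca_myo - ca_myo0)

    # buffer occupancy fluxes at the stage Ca (occupancies frozen)
    ca_um = ca_myo * 1e3
    d_oc, d_otc, d_otmgc, _, d_caf3 = buffer_derivatives(
        occ[0], occ[1], occ[2], occ[3], caf3, ca_um, P[P_MGMYO],
        P[P_F3TOT], P[P_F3ON], P[P_F3OFF])
    d_o = occupancy_flux_to_balance(d_otc, d_otmgc, d_oc)
    d_caf2 = 0.0
    if fura2_on:
        d_caf2 = (P[P_F2ON] * ca_um * (P[P_F2TOT] - caf2)
                  - P[P_F2OFF] * caf2)

    d_b6 = P[P_LS_K56] * ca_jsr * 1e3 * ls_b5 - P[P_LS_K65] * ls_b6

    i_cal_sl_eff = 0.0 if barium else i_cal_sl_frozen
    n_dyad = P[P_NDYAD]

    # NCX: positive current = reverse mode = one Ca entering per net charge
    d = np.empty(7)
    d[0] = (1e-3 * (i_dyad - i_pmca - i_cal_sl_eff + 2.0 * i_naca_sl)
            / (2.0 * F * P[P_VMYO])
            - (j_cyt + d_o + d_caf3 + d_caf2) * 1e-3)
    d[1] = (1e-3 * (i_tr - i_ryr) / (2.0 * F * P[P_VJSR])
            - CSQ_CAP_MM * d_b6)
    d[2] = 1e-3 * (j_sr * 2.0 * F * P[P_VMYO] - n_dyad * i_tr) \
        / (2.0 * F * P[P_VLSR])
    vratio = n_dyad * P[P_VCLEFT] / P[P_VMYO]
    d[3] = (vratio * (na_dyad - na_myo) / P[P_TAUNA]
            + 1e-3 * (-i_nab - 3.0 * i_naca_sl - 3.0 * i_nacs_sl)
            / (F * P[P_VMYO]))
    d[4] = ((na_myo - na_dyad) / P[P_TAUNA]
            + 1e-3 * (-3.0 * i_naca_tt - 3.0 * i_nacs_tt)
            / (F * P[P_VCLEFT] * n_dyad))
    d[5] = (vratio * (cs_dyad - cs_myo) / P[P_TAUCS]
            + 1e-3 * 2.0 * i_nacs_sl / (F * P[P_VMYO]))
    d[6] = ((cs_myo - cs_dyad) / P[P_TAUCS]
            + 1e-3 * 2.0 * i_nacs_tt / (F * P[P_VCLEFT] * n_dyad))
    return d


@njit(cache=True)
def _rl_update(x, a, b, dt):
    """Locally exact update of dx/dt = a - b x; preserves positivity for
    a >= 0, b >= 0."""
    if b * dt > 1e-8:
        xinf = a / b
        out = xinf + (x - xinf) * math.exp(-b * dt)
    else:
        out = x + (a - b * x) * dt
    return out if out > 0.0 else 0.0


@njit(cache=True)
def _dhpr_ab(y, base, r, conserve_c6, a, b):
    """Production/loss split for one DHPR instance (C1,O2,O3,C4,C6) at
    ``base``; rates r in 1/s."""
    c1, o2, o3, c4 = y[base], y[base + 1], y[base + 2], y[base + 3]
    c5 = 1.0 - (c1 + o2 + o3 + c4)
    if c5 < 0.0:
        c5 = 0.0
    ms = 1e-3
    a[base] = (r[R_K21] * o2 + r[R_K51] * c5) * ms
    b[base] = (r[R_K12] + r[R_K15]) * ms
    a[base + 1] = (r[R_K12] * c1 + r[R_K42] * c4 + r[R_K32] * o3
                   + r[R_K52] * c5) * ms
    b[base + 1] = (r[R_K21] + r[R_K23] + r[R_K24] + r[R_K25]) * ms
    a[base + 2] = r[R_K23] * o2 * ms
    b[base + 2] = r[R_K32] * ms
    if conserve_c6:
        b[base + 2] += r[R_K36] * ms
    a[base + 3] = (r[R_K54] * c5 + r[R_K24] * o2) * ms
    b[base + 3] = (r[R_K45] + r[R_K42]) * ms
    a[base + 4] = r[R_K36] * o3 * ms
    b[base + 4] = r[R_K63] * ms


@njit(cache=True)
def _core(y, grid, P, dt, n_steps, stride,
          prot_t, prot_v,
          mode, ryanodine, barium,
          caff_um, caff_t0, caff_t1,
          thaps, thaps_onset,
          sensor_clamp_var,
          cao_t, cao_v,
          ical_scale,
          fura2_on,
          inject, inj_t, inj_i, inj_starts,
          out):
    F = P[P_F]
    f_tt = P[P_FTT]
    n_dyad = P[P_NDYAD]
    nr = int(P[P_NR]); nz = int(P[P_NZ])
    dr = P[P_DR]; dz = P[P_DZ]
    g_rim = P[P_RIMSCALE] * P[P_DCA] / dr
    rim_area = 2.0 * math.pi * (nr * dr) * dz
    # whole-cell pA per mM of bulk-concentration offset at the rim
    rim_coupling = n_dyad * g_rim * nz * rim_area * 2.0 * F * 1e-12
    conserve_c6 = P[P_CONSC6] > 0.5

    a = np.zeros(S.N_STATE)
    b = np.zeros(S.N_STATE)
    beta = np.empty((nr, nz))
    c7 = np.empty(7)
    conc_idx = np.array([S.CA_MYO, S.CA_JSR, S.CA_LSR, S.NA_MYO, S.NA_DYAD,
                         S.CS_MYO, S.CS_DYAD])
    occ = np.empty(4)
    n_rec = 0

    for n in range(n_steps + 1):
        t = n * dt
        v = _interp(t, prot_t, prot_v)
        cao = _schedule_value(t, cao_t, cao_v, P[P_CAO])

        # --- grid samples -------------------------------------------------
        ca_dhp = grid[0, 0]
        ca_ryr = grid[0, nz - 1]
        ca_mean = mean_concentration(grid, dr)
        ca_slface = face_mean_concentration(grid, dr, 0)
        ca_myo = y[S.CA_MYO]
        ca_jsr = y[S.CA_JSR]

        # --- signaling activities ----------------------------------------
        dy_blk = y[S.DY_CA2CAM:S.DY_CA2CAM + 14]
        cy_blk = y[S.CY_CA2CAM:S.CY_CA2CAM + 14]
        ck_dy = camkii_activity(dy_blk)
        cn_dy = can_activity(dy_blk)
        ck_cy = camkii_activity(cy_blk)
        cn_cy = can_activity(cy_blk)
        # pump/PLB regulation at the frozen paced operating point
        ck_mm_cy = P[P_CK_MM_REG]
        cn_mm_cy = P[P_CN_MM_REG]

        # --- DHPR channels ------------------------------------------------
        r_tt = dhpr_rates(v, mode, y[S.TT_S2], ck_dy, cn_dy)
        r_sl = dhpr_rates(v, mode, y[S.SL_S2], ck_cy, cn_cy)
        open_tt = y[S.TT_O2] + y[S.TT_O3]
        open_sl = y[S.SL_O2] + y[S.SL_O3]

        ical_tt_env, ina_tt, ics_tt = ghk_currents(
            v, open_tt, ca_dhp, y[S.NA_DYAD], y[S.CS_DYAD],
            cao, P[P_NAO], P[P_CSO], P[P_PCA], P[P_PNA], P[P_PCS],
            F, P[P_RT], P[P_RCAL])
        ical_sl_env, ina_sl, ics_sl = ghk_currents(
            v, open_sl, ca_myo, y[S.NA_MYO], y[S.CS_MYO],
            cao, P[P_NAO], P[P_CSO], P[P_PCA], P[P_PNA], P[P_PCS],
            F, P[P_RT], P[P_RCAL])
        i_cal_tt = f_tt * ical_tt_env * ical_scale
        i_cal_sl = (1.0 - f_tt) * ical_sl_env
        if inject:
            i_cal_tt_unit = _injected_current(t, inj_t, inj_i, inj_starts)
            i_cal_tt = i_cal_tt_unit * n_dyad
        else:
            i_cal_tt_unit = i_cal_tt / n_dyad
        i_na = f_tt * ina_tt + (1.0 - f_tt) * ina_sl
        i_cs = f_tt * ics_tt + (1.0 - f_tt) * ics_sl

        i_naca_tt = f_tt * ncx_current(
            v, ca_slface, y[S.NA_DYAD], cao, P[P_NAO],
            P[P_KMALLO], P[P_KMCAO], P[P_KMCAI], P[P_KMNAO], P[P_KMNAI],
            P[P_VMAXNCX], F, P[P_RT], P[P_RNACA])
        i_naca_sl = (1.0 - f_tt) * ncx_current(
            v, ca_myo, y[S.NA_MYO], cao, P[P_NAO],
            P[P_KMALLO], P[P_KMCAO], P[P_KMCAI], P[P_KMNAO], P[P_KMNAI],
            P[P_VMAXNCX], F, P[P_RT], P[P_RNACA])
        i_pmca = pmca_current(ca_myo, P[P_KMPCA], P[P_IPMCA])
        i_nacs = (f_tt * nacs_current(v, y[S.NA_DYAD], P[P_CSO], P[P_KMCS],
                                      P[P_KMNA], P[P_INACS], P[P_RNACS])
                  + (1.0 - f_tt) * nacs_current(v, y[S.NA_MYO], P[P_CSO],
                                                P[P_KMCS], P[P_KMNA],
                                                P[P_INACS], P[P_RNACS]))
        i_nab = background_na_current(v, y[S.NA_MYO], P[P_NAO], P[P_GNAB],
                                      F, P[P_RT])

        # --- RyR / luminal sensor ----------------------------------------
        if sensor_clamp_var > 0.0:
            var = sensor_clamp_var
        else:
            var = luminal_var(y[S.LS_A1])
        caff_active = caff_um > 0.0 and caff_t0 <= t < caff_t1
        if ryanodine:
            o2_eff = 0.0
        elif caff_active:
            o2_eff = caffeine_open_probability(caff_um)
        else:
            o2_eff = y[S.RYR_O2]
        i_ryr = ryr_current(o2_eff, ca_jsr, ca_ryr, P[P_PRYR], F)
        # open-channel exchange rate for the implicit mouth-voxel coupling
        ryr_sigma = o2_eff * P[P_PRYR] * 1e15 / (math.pi * dr * dr * dz)

        # --- SR transport -------------------------------------------------
        thaps_active = thaps and t >= thaps_onset
        j_cyt, j_sr = serca_fluxes(ca_myo, y[S.CA_LSR], y[S.CA_SERCA],
                                   ck_mm_cy, y[S.PLB_DP],
                                   P[P_KCYT], P[P_KSR], P[P_SERCATOT],
                                   P[P_PSR], thaps_active)
        i_cyt_serca = j_cyt * 2.0 * F * P[P_VMYO]
        i_serca_sr = j_sr * 2.0 * F * P[P_VMYO]
        i_tr = (y[S.CA_LSR] - ca_jsr) / P[P_TAUTR] * 2.0 * F * P[P_VJSR] * 1e3

        i_dyad_unit = rim_efflux_current(grid, g_rim, ca_myo, dr, dz)
        i_dyad = n_dyad * i_dyad_unit

        # sensor state pieces used by the jSR balance
        ls_b5 = 1.0 - (y[S.LS_I2] + y[S.LS_I3] + y[S.LS_B6])
        if ls_b5 < 0.0:
            ls_b5 = 0.0

        # --- record -------------------------------------------------------
        if n % stride == 0:
            row = out[n_rec]
            row[0] = t; row[1] = v
            row[2] = ca_myo; row[3] = ca_jsr; row[4] = y[S.CA_LSR]
            row[5] = ca_mean; row[6] = ca_dhp; row[7] = ca_ryr
            row[8] = y[S.CAF3]; row[9] = y[S.CAF2]
            row[10] = o2_eff; row[11] = open_tt; row[12] = open_sl
            row[13] = i_cal_tt + i_cal_sl
            row[14] = i_cal_tt; row[15] = i_cal_sl; row[16] = i_cal_tt_unit
            row[17] = i_naca_tt; row[18] = i_naca_sl; row[19] = i_pmca
            row[20] = i_nacs; row[21] = i_nab
            row[22] = i_ryr; row[23] = n_dyad * i_ryr; row[24] = i_tr
            row[25] = i_cyt_serca; row[26] = i_serca_sr; row[27] = i_dyad
            row[28] = ck_dy; row[29] = cn_dy; row[30] = ck_cy; row[31] = cn_cy
            row[32] = var; row[33] = y[S.LS_A1]; row[34] = y[S.LS_B6]
            row[35] = r_tt[R_K24] * y[S.TT_O2]
            row[36] = r_tt[R_K25] * y[S.TT_O2]
            row[37] = r_sl[R_K24] * y[S.SL_O2]
            row[38] = r_sl[R_K25] * y[S.SL_O2]
            row[39] = y[S.O_C]; row[40] = y[S.O_TC]
            row[41] = y[S.O_TMGC]; row[42] = y[S.O_TMGMG]
            row[43] = i_na; row[44] = i_cs
            row[45] = y[S.PLB_DP]; row[46] = y[S.CA_SERCA]
            n_rec += 1
            if not np.isfinite(ca_myo) or not np.isfinite(grid[0, 0]):
                raise ValueError("integration diverged (non-finite state)")
        if n == n_steps:
            break

        # --- RK-Merson step for the concentrations -----------------------
        for k in range(4):
            occ[k] = y[S.O_C + k]
        for k in range(7):
            c7[k] = y[conc_idx[k]]
        args = (P, v, cao, open_tt, i_cal_sl, barium, o2_eff,
                i_dyad, rim_coupling, ca_myo, ca_ryr, ck_mm_cy,
                y[S.PLB_DP], y[S.CA_SERCA], thaps_active,
                ls_b5, y[S.LS_B6], occ, y[S.CAF3], y[S.CAF2], fura2_on)
        k1 = _conc_rhs(c7, *args)
        k2 = _conc_rhs(c7 + dt / 3.0 * k1, *args)
        k3 = _conc_rhs(c7 + dt / 6.0 * (k1 + k2), *args)
        k4 = _conc_rhs(c7 + dt * (0.125 * k1 + 0.375 * k3), *args)
        k5 = _conc_rhs(c7 + dt * (0.5 * k1 - 1.5 * k3 + 2.0 * k4), *args)
        cnew = c7 + dt / 6.0 * (k1 + 4.0 * k4 + k5)
        for k in range(7):
            val = cnew[k]
            y[conc_idx[k]] = val if val > 0.0 else 0.0

        # --- exponential updates: gating and signaling -------------------
        # buffers
        ca_um0 = ca_myo * 1e3
        buffer_ab(y[S.O_TMGC], y[S.O_TMGMG], ca_um0, P[P_MGMYO],
                  P[P_F3TOT], P[P_F3ON], P[P_F3OFF], a, b, S.O_C)
        if fura2_on:
            a[S.CAF2] = P[P_F2ON] * ca_um0 * P[P_F2TOT]
            b[S.CAF2] = P[P_F2ON] * ca_um0 + P[P_F2OFF]
        else:
            a[S.CAF2] = 0.0; b[S.CAF2] = 0.0
        # RyR channel (rates per s -> per ms)
        q = ryr_rates(ca_ryr * 1e3, var, ck_dy)
        c4r = 1.0 - (y[S.RYR_C1] + y[S.RYR_O2] + y[S.RYR_C3])
        if c4r < 0.0:
            c4r = 0.0
        ms = 1e-3
        a[S.RYR_C1] = (q[Q_K41] * c4r + q[Q_K21] * y[S.RYR_O2]) * ms
        b[S.RYR_C1] = (q[Q_K12] + q[Q_K14]) * ms
        a[S.RYR_O2] = (q[Q_K12] * y[S.RYR_C1] + q[Q_K32] * y[S.RYR_C3]) * ms
        b[S.RYR_O2] = (q[Q_K21] + q[Q_K23]) * ms
        a[S.RYR_C3] = (q[Q_K23] * y[S.RYR_O2] + q[Q_K43] * c4r) * ms
        b[S.RYR_C3] = (q[Q_K34] + q[Q_K32]) * ms
        # luminal sensor (rates already per ms)
        i4 = 1.0 - (y[S.LS_A1] + y[S.LS_I2] + y[S.LS_I3])
        if i4 < 0.0:
            i4 = 0.0
        a[S.LS_A1] = P[P_LS_K41] * i4 + P[P_LS_K21] * y[S.LS_I2]
        b[S.LS_A1] = P[P_LS_K12] * ls_b5 + P[P_LS_K14]
        a[S.LS_I2] = (P[P_LS_K12] * ls_b5 * y[S.LS_A1]
                      + P[P_LS_K42] * ls_b5 * i4
                      + P[P_LS_K32] * y[S.LS_I3])
        b[S.LS_I2] = (P[P_LS_K21] + P[P_LS_K24] + P[P_LS_K23] + P[P_LS_K25])
        a[S.LS_I3] = P[P_LS_K43] * ls_b5 * i4 + P[P_LS_K23] * y[S.LS_I2]
        b[S.LS_I3] = P[P_LS_K34] + P[P_LS_K32]
        a[S.LS_B6] = P[P_LS_K56] * ca_jsr * 1e3 * ls_b5
        b[S.LS_B6] = P[P_LS_K65]
        # SERCA buffer and PLB
        aa, bb = serca_buffer_ab(ca_myo, y[S.CA_LSR], ck_mm_cy, y[S.PLB_DP],
                                 P[P_KCYT], P[P_KSR], P[P_SERCATOT],
                                 P[P_PSR], thaps_active)
        a[S.CA_SERCA] = aa; b[S.CA_SERCA] = bb
        aa, bb = plb_ab(ck_mm_cy, cn_mm_cy, P[P_PKA],
                        P[P_K12PLB], P[P_K21PLB])
        a[S.PLB_DP] = aa; b[S.PLB_DP] = bb
        # DHPR instances + CaM gates
        _dhpr_ab(y, S.TT_C1, r_tt, conserve_c6, a, b)
        _dhpr_ab(y, S.SL_C1, r_sl, conserve_c6, a, b)
        ks12_tt = cam_gate_ks12(dy_blk[1])          # dyadic Ca4CaM
        a[S.TT_S2] = ks12_tt * ms
        b[S.TT_S2] = (ks12_tt + KS21) * ms
        ks12_sl = cam_gate_ks12(cy_blk[1])          # cytosolic Ca4CaM
        a[S.SL_S2] = ks12_sl * ms
        b[S.SL_S2] = (ks12_sl + KS21) * ms
        # signaling networks
        network_ab(dy_blk, ca_mean * 1e3, P,
                   a[S.DY_CA2CAM:S.DY_CA2CAM + 14],
                   b[S.DY_CA2CAM:S.DY_CA2CAM + 14], P[P_CAMTOT_DY])
        network_ab(cy_blk, ca_myo * 1e3, P,
                   a[S.CY_CA2CAM:S.CY_CA2CAM + 14],
                   b[S.CY_CA2CAM:S.CY_CA2CAM + 14])

        for idx in range(S.O_C, S.N_STATE):
            val = _rl_update(y[idx], a[idx], b[idx], dt)
            # occupancy-type states stay in [0, 1]
            if val > 1.0 and (idx <= S.O_TMGMG
                              or S.RYR_C1 <= idx <= S.LS_B6
                              or S.PLB_DP <= idx <= S.SL_S2):
                val = 1.0
            y[idx] = val

        # --- cleft PDE ----------------------------------------------------
        for i in range(nr):
            for j in range(nz):
                beta[i, j] = beta_factor(grid[i, j], P[P_NH], P[P_NL],
                                         P[P_KH], P[P_KL])
        src = source_field(nr, nz, dr, dz, i_cal_tt_unit,
                           i_naca_tt / n_dyad)
        if barium:
            src[0, 0] = 0.0    # Ba carries the current; no Ca delivered
        adi_step(grid, src, beta, dt, P[P_DCA], dr, dz, g_rim, ca_myo,
                 ryr_sigma, ca_jsr)

    return n_rec


# ---------------------------------------------------------------------------
@dataclass
class SimulationResult:
    """Tabular time series of states, currents and fluxes plus metadata."""
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)
    final_state: np.ndarray | None = None
    final_grid: np.ndarray | None = None

    def __getitem__(self, col):
        return self.data[col].to_numpy()

    @property
    def t(self):
        return self.data["t"].to_numpy()


class CellModel:
    """The assembled voltage-clamp cell model.

    Parameters default to the packaged set; the initial state to the packaged
    resting conditions.  ``run`` integrates a protocol and returns a
    :class:`SimulationResult`.
    """

    def __init__(self, params: pm.ModelParameters | None = None):
        self.params = params or pm.load_default_parameters()
        self.P = pack_parameters(self.params)
        # Pump/PLB regulation runs at the packaged (paced) operating point:
        # the reconstructed cytosolic kinase cascade decays within ~1 s of
        # quiescence, which would silence SERCA entirely and contradict the
        # model's long-timescale Ca balance.
        y_ref = pm.load_initial_state(self.params)
        cy = y_ref[S.CY_CA2CAM:S.CY_CA2CAM + 14]
        cktot = self.params.rates.totals["CaMKII_tot"]
        self.P[pm.P_CK_MM_REG] = cktot * camkii_activity(cy) / 100.0 * 1e-3
        self.P[pm.P_CN_MM_REG] = can_activity(cy) / 100.0 * 1e-3

    def initial_state(self, equilibrate_at: float | None = None,
                      mode: int = CASE_CONTROL) -> tuple[np.ndarray, np.ndarray]:
        """Packaged initial conditions; optionally with the L-type channel
        occupancies replaced by their stationary distribution at a holding
        potential (the packaged values are a pacing-diastole snapshot whose
        open fraction does not belong to a quiescent cell)."""
        y0 = pm.load_initial_state(self.params)
        if equilibrate_at is not None:
            from .dhpr import stationary_occupancies
            from .buffering import equilibrium_occupancies
            from .cam_signaling import relax_network
            # the dyadic signaling instance tracks its local (nanodomain)
            # Ca; relax it to the resting fixed point.  The cytosolic
            # instance keeps the packaged operating-point values that the
            # global regulators (SERCA/PLB) were made consistent with.
            dy = y0[S.DY_CA2CAM:S.DY_CA2CAM + 14].copy()
            relax_network(dy, pm.resting_dyad_ca() * 1e3, self.P,
                          20000.0, 1.0, self.P[P_CAMTOT_DY])
            y0[S.DY_CA2CAM:S.DY_CA2CAM + 14] = dy
            for base, blk in ((S.TT_C1, S.DY_CA2CAM), (S.SL_C1, S.CY_CA2CAM)):
                net = y0[blk:blk + 14]
                occ = stationary_occupancies(
                    equilibrate_at, mode, ca4cam=net[1],
                    camkii_act=camkii_activity(net),
                    can_act=can_activity(net))
                y0[base:base + 4] = occ[:4]
                y0[base + 4] = occ[4]
                y0[base + 5] = occ[5]
            # cytosolic buffers and the SERCA load at their resting fixed
            # points (the packaged values are a pacing-diastole snapshot
            # that otherwise releases Ca into a quiescent cell)
            t = self.params.transport
            ca_um = y0[S.CA_MYO] * 1e3
            eq = equilibrium_occupancies(ca_um, t.Mg_myo)
            y0[S.O_C] = eq["O_c"]; y0[S.O_TC] = eq["O_tc"]
            y0[S.O_TMGC] = eq["O_tmgc"]; y0[S.O_TMGMG] = eq["O_tmgmg"]
            kd_f3 = t.k_fluo3_off / t.k_fluo3_on
            y0[S.CAF3] = t.fluo3_tot * ca_um / (ca_um + kd_f3)
            se = self.params.rates.serca
            from .sr_transport import serca_regulation
            ck_mm = (self.params.rates.totals["CaMKII_tot"]
                     * (camkii_activity(y0[S.CY_CA2CAM:S.CY_CA2CAM + 14])
                        / 100.0) * 1e-3)
            _, ec50f, _ = serca_regulation(ck_mm, y0[S.PLB_DP], se["PSR"])
            u = (ca_um / ec50f) ** 2
            y0[S.CA_SERCA] = se["SERCA_tot"] * u / (1.0 + u)
        g = self.params.geometry
        grid0 = make_grid(g.nr, g.nz, pm.resting_dyad_ca())
        return y0, grid0

    def run(self, protocol: ClampProtocol,
            pharm: PharmacologyConfig | None = None,
            y0: np.ndarray | None = None,
            grid0: np.ndarray | None = None,
            dt: float | None = None,
            record_stride_ms: float = 0.1,
            t_end: float | None = None,
            equilibrate_dhpr: bool = True) -> SimulationResult:
        pharm = pharm or PharmacologyConfig()
        pharm.validate()
        dt = float(dt if dt is not None else self.params.numerics.dt)
        if y0 is None or grid0 is None:
            mode0 = CASE_CONTROL
            if pharm.ryanodine:
                mode0 = CASE_RYANODINE
            if pharm.barium:
                mode0 = CASE_BARIUM
            hold = protocol.holding if equilibrate_dhpr else None
            y0_d, grid0_d = self.initial_state(equilibrate_at=hold, mode=mode0)
            y0 = y0_d if y0 is None else y0.copy()
            grid0 = grid0_d if grid0 is None else grid0.copy()
        else:
            y0 = y0.copy()
            grid0 = grid0.copy()

        t_total = float(t_end if t_end is not None else protocol.t_end)
        n_steps = int(round(t_total / dt))
        stride = max(1, int(round(record_stride_ms / dt)))
        n_rows = n_steps // stride + 1
        out = np.zeros((n_rows, N_REC))

        prot_t, prot_v = protocol.breakpoints()
        mode = CASE_CONTROL
        if pharm.ryanodine:
            mode = CASE_RYANODINE
        if pharm.barium:
            mode = CASE_BARIUM
        cao_t = np.array([s[0] for s in pharm.cao_schedule], dtype=float)
        cao_v = np.array([s[1] for s in pharm.cao_schedule], dtype=float)
        inj_t = (np.asarray(pharm.inject_t, dtype=float)
                 if pharm.inject_t is not None else np.zeros(0))
        inj_i = (np.asarray(pharm.inject_i, dtype=float)
                 if pharm.inject_i is not None else np.zeros(0))
        inj_starts = np.asarray(pharm.inject_starts, dtype=float)
        clamp = (-1.0 if pharm.sensor_clamp_var is None
                 else float(pharm.sensor_clamp_var))

        n_rec = _core(
            y0, grid0, self.P, dt, n_steps, stride,
            prot_t.astype(float), prot_v.astype(float),
            mode, pharm.ryanodine, pharm.barium,
            float(pharm.caffeine_um), float(pharm.caffeine_window[0]),
            float(pharm.caffeine_window[1]),
            bool(pharm.thapsigargin), float(pharm.thapsigargin_onset),
            clamp, cao_t, cao_v,
            float(pharm.i_cal_tt_scale), bool(pharm.fura2),
            bool(pharm.inject), inj_t, inj_i, inj_starts,
            out)

        df = pd.DataFrame(out[:n_rec], columns=REC_COLUMNS)
        meta = {
            "dt_ms": dt, "record_stride_ms": stride * dt,
            "protocol": protocol.to_dict(),
            "pharmacology": {
                "ryanodine": pharm.ryanodine, "barium": pharm.barium,
                "caffeine_um": pharm.caffeine_um,
                "caffeine_window": list(pharm.caffeine_window),
                "thapsigargin": pharm.thapsigargin,
                "thapsigargin_onset": pharm.thapsigargin_onset,
                "sensor_clamp_var": pharm.sensor_clamp_var,
                "i_cal_tt_scale": pharm.i_cal_tt_scale,
                "fura2": pharm.fura2, "inject": pharm.inject,
            },
            "columns": REC_COLUMNS,
        }
        return SimulationResult(df, meta, y0, grid0)


def calcium_ledger(result: SimulationResult, params: pm.ModelParameters,
                   t0: float | None = None, t1: float | None = None) -> dict:
    """Per-compartment Ca mass audit over [t0, t1] (ms).

    Converts every current to charge (NCX carries one net charge per Ca, all
    others two) and compares each compartment's measured concentration change
    with its integrated fluxes.  Returns absolute and relative audit errors.
    """
    d = result.data
    t = d["t"].to_numpy()
    m = np.ones(len(t), dtype=bool)
    if t0 is not None:
        m &= t >= t0
    if t1 is not None:
        m &= t <= t1
    tt = t[m]

    def integ(col):
        return np.trapezoid(d[col].to_numpy()[m], tt)  # pA*ms = fC

    F = params.transport.F
    v_myo = params.geometry.V_myo

    # cytosol: d[Ca]myo*2F*Vmyo (+ buffer-bound pools) vs integrated currents
    ca = d["Ca_myo"].to_numpy()[m]
    q_in = (integ("I_dyad") - integ("I_PMCA") - integ("I_CaL_SL")
            - 2.0 * integ("I_NaCa_SL") - integ("I_cyt_serca"))
    caf3 = d["CaF3"].to_numpy()[m]
    caf2 = d["CaF2"].to_numpy()[m]
    o_w = (3.2 * d["O_tc"].to_numpy()[m] + 6.4 * d["O_tmgc"].to_numpy()[m]
           + 1.8 * d["O_c"].to_numpy()[m])
    free_delta = (ca[-1] - ca[0])
    bound_delta = (caf3[-1] - caf3[0] + caf2[-1] - caf2[0]
                   + o_w[-1] - o_w[0]) * 1e-3
    q_meas = (free_delta + bound_delta) * 2.0 * F * v_myo * 1e3  # fC
    scale = max(abs(integ("I_CaL_SL")) + abs(integ("I_dyad")), 1e-12)
    return {
        "q_fluxes_fC": q_in,
        "q_measured_fC": q_meas,
        "audit_error_fC": q_meas - q_in,
        "audit_error_rel": abs(q_meas - q_in) / scale,
        "window_ms": (float(tt[0]), float(tt[-1])),
    }


def assemble_derivatives(model: CellModel, y: np.ndarray, grid: np.ndarray,
                         v_clamp: float,
                         pharm: PharmacologyConfig | None = None) -> np.ndarray:
    """Finite-difference snapshot of d(state)/dt at a frozen clamp voltage.

    Convenience for inspection and testing: advances one internal step at
    the given voltage and returns (y' - y)/dt for the ODE states.
    """
    pharm = pharm or PharmacologyConfig()
    prot = ClampProtocol(holding=v_clamp, level=v_clamp, duration=1.0,
                         n_pulses=0, pre_hold=0.0, tail=1.0)
    dt = model.params.numerics.dt
    res = model.run(prot, pharm, y0=y, grid0=grid, dt=dt,
                    record_stride_ms=dt, t_end=dt)
    return (res.final_state - y) / dt
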