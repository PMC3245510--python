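"""Derived observables: CICR gain (flux-ratio and transient-ratio criteria),
per-cycle charge integrals and the balance ledger, refractory-period
measurement from paired-stimulus scans, inactivation-pathway fractions, and
peak/latency/FDHM extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import SimulationResult


# ---------------------------------------------------------------------------
@dataclass
class GainReport:
    gain_flux_ratio: float        # integrated RyR flux / DHPR trigger flux
    gain_transient_ratio: float   # peak dCa_myo with / without release
    clamp_mv: float
    onset_delay_ms: float


def _trapz(y, t, mask=None):
    if mask is not None:
        y, t = y[mask], t[mask]
    return float(np.trapezoid(y, t))


def _release_window(t, flux_dhpr, flux_ryr, t_on, frac=0.01):
    """Integration window: pulse onset until both fluxes fall back below
    ``frac`` of their peaks."""
    after = t >= t_on
    pk_d = np.max(np.abs(flux_dhpr[after]))
    pk_r = np.max(np.abs(flux_ryr[after]))
    below = (np.abs(flux_dhpr) < frac * pk_d) & (np.abs(flux_ryr) < frac * pk_r)
    idx_end = len(t) - 1
    i_peak = int(np.argmax(np.abs(flux_ryr) * after))
    for i in range(i_peak, len(t)):
        if below[i]:
            idx_end = i
            break
    return after & (np.arange(len(t)) <= idx_end)


def _onset_time(t, flux, t_on, frac=0.05):
    after = t >= t_on
    pk = np.max(np.abs(flux[after]))
    if pk <= 0:
        return float("nan")
    idx = np.nonzero(after & (np.abs(flux) >= frac * pk))[0]
    return float(t[idx[0]]) if len(idx) else float("nan")


def compute_gain(res_control: SimulationResult,
                 res_blocked: SimulationResult,
                 t_pulse_on: float) -> GainReport:
    """CICR gain for a matched control / ryanodine pair of runs.

    Criterion 1 integrates the summed RyR release current against the
    dyadic trigger current over the release episode; criterion 2 compares
    baseline-subtracted peak cytosolic transients.  The onset delay is the
    5%-of-peak threshold crossing of the RyR flux relative to the DHPR flux.
    """
    t = res_control.t
    i_dhpr = res_control["I_CaL_TT"]
    i_ryr = res_control["I_ryr"]
    win = _release_window(t, i_dhpr, i_ryr, t_pulse_on)
    q_ryr = _trapz(np.abs(i_ryr), t, win)
    q_dhpr = _trapz(np.abs(i_dhpr), t, win)
    if q_dhpr <= 0:
        raise ValueError("no trigger flux in the release window")
    if np.max(np.abs(i_ryr)) <= 0:
        raise ValueError("no release episode in the control run")

    def peak_delta(res):
        ca = res["Ca_myo"]
        base = ca[res.t <= t_pulse_on][-1]
        return float(np.max(ca[res.t >= t_pulse_on]) - base)

    g2 = peak_delta(res_control) / peak_delta(res_blocked)
    delay = (_onset_time(t, i_ryr, t_pulse_on)
             - _onset_time(t, i_dhpr, t_pulse_on))
    v = float(np.max(res_control["v"]))
    return GainReport(q_ryr / q_dhpr, g2, v, delay)


def gain_voltage_curve(run_pair, voltages, t_pulse_on):
    """Criterion-1 gain per clamp voltage.  ``run_pair(v)`` must return the
    (control, ryanodine) result pair for a voltage."""
    out = []
    for v in voltages:
        rc, rb = run_pair(v)
        out.append(compute_gain(rc, rb, t_pulse_on).gain_flux_ratio)
    return np.asarray(out)


# ---------------------------------------------------------------------------
@dataclass
class ChargeLedger:
    q_cal: float          # pC per cycle, by convention inward negative
    q_naca: float         # x2-adjusted (1 net charge per Ca)
    q_pmca: float
    q_ryr: float
    q_serca: float
    external_sum: float
    internal_sum: float
    cycle: tuple


def charge_balance(result: SimulationResult, t0: float, t1: float) -> ChargeLedger:
    """Per-cycle charge integrals (pC) over one steady cycle [t0, t1].

    External fluxes: I_CaL (inward negative), 2*I_NaCa, I_PMCA (outward
    positive).  Internal (SR) fluxes: summed RyR current (outward of the SR
    positive) and SERCA uptake (inward negative).  The NCX integral is
    doubled because the exchanger moves one net charge per Ca while every
    other Ca current carries two.
    """
    t = result.t
    m = (t >= t0) & (t <= t1)
    tt = t[m]
    pc = 1e-3  # pA*ms -> pC

    # Ca-charge bookkeeping, entry positive: I_CaL is inward (negative), so
    # entry is -integral; the exchanger's electrical sign is positive in
    # reverse mode (Ca entry), and its integral is doubled because it moves
    # one net charge per Ca where every other Ca current moves two.
    q_cal = -_trapz(result["I_CaL"][m], tt) * pc
    q_naca = -2.0 * _trapz(result["I_NaCa_TT"][m]
                           + result["I_NaCa_SL"][m], tt) * pc
    q_pmca = _trapz(result["I_PMCA"][m], tt) * pc
    q_ryr = _trapz(result["I_ryr"][m], tt) * pc
    q_serca = _trapz(result["I_cyt_serca"][m], tt) * pc
    return ChargeLedger(
        q_cal=q_cal, q_naca=q_naca, q_pmca=q_pmca,
        q_ryr=q_ryr, q_serca=q_serca,
        external_sum=q_cal - q_naca - q_pmca,
        internal_sum=q_ryr - q_serca,
        cycle=(float(t0), float(t1)))


# ---------------------------------------------------------------------------
def measure_refractoriness(s1s2_results: dict, s1_start: float,
                           abs_threshold: float = 0.05,
                           rel_threshold: float = 0.95):
    """(ARP, RRP) in ms from a paired-stimulus family.

    ``s1s2_results`` maps the S1-S2 interval T2 (ms) to its result.  ARP is
    the largest T2 whose S2 peak RyR open probability stays below
    ``abs_threshold`` of the S1 peak; RRP the smallest T2 whose S2 cytosolic
    transient recovers to ``rel_threshold`` of S1's.
    """
    t2s = sorted(s1s2_results)
    arp = float("nan")
    rrp = float("nan")
    ratios_o2 = {}
    ratios_ca = {}
    for t2 in t2s:
        res = s1s2_results[t2]
        t = res.t
        o2 = res["O2_ryr"]
        ca = res["Ca_myo"]
        s2_start = s1_start + t2
        m1 = (t >= s1_start) & (t < s2_start)
        m2 = t >= s2_start
        pk1_o2 = float(np.max(o2[m1]))
        pk2_o2 = float(np.max(o2[m2]))
        base1 = ca[t <= s1_start][-1]
        base2 = ca[(t >= s2_start)][0]
        pk1_ca = float(np.max(ca[m1]) - base1)
        pk2_ca = float(np.max(ca[m2]) - base2)
        ratios_o2[t2] = pk2_o2 / pk1_o2 if pk1_o2 > 0 else np.nan
        ratios_ca[t2] = pk2_ca / pk1_ca if pk1_ca > 0 else np.nan
        if ratios_o2[t2] < abs_threshold:
            arp = float(t2)
        if np.isnan(rrp) and ratios_ca[t2] >= rel_threshold:
            rrp = float(t2)
    monotone = all(ratios_ca[a] <= ratios_ca[b] + 0.02
                   for a, b in zip(t2s, t2s[1:]))
    return arp, rrp, {"recovery_o2": ratios_o2, "recovery_ca": ratios_ca,
                      "monotone": monotone}


# ---------------------------------------------------------------------------
def inactivation_pathway_fractions(result: SimulationResult,
                                   t0: float, t1: float,
                                   f_tt: float = 0.9) -> dict:
    """Share of L-type inactivation via the Ca-dependent O2->C4 pathway.

    Integrates the recorded transition fluxes k24*O2 (Ca pathway) and k25*O2
    (voltage pathway) for the T-tubular and free-sarcolemmal channel
    instances over the pulse, and combines them channel-weighted.
    """
    t = result.t
    m = (t >= t0) & (t <= t1)
    tt = t[m]
    cdi_tt = _trapz(result["cdi_rate_TT"][m], tt)
    vdi_tt = _trapz(result["vdi_rate_TT"][m], tt)
    cdi_sl = _trapz(result["cdi_rate_SL"][m], tt)
    vdi_sl = _trapz(result["vdi_rate_SL"][m], tt)
    f_cdi_tt = 100.0 * cdi_tt / (cdi_tt + vdi_tt)
    f_cdi_sl = 100.0 * cdi_sl / (cdi_sl + vdi_sl)
    cdi_tot = f_tt * cdi_tt + (1 - f_tt) * cdi_sl
    vdi_tot = f_tt * vdi_tt + (1 - f_tt) * vdi_sl
    return {"f_cdi_tt": f_cdi_tt, "f_cdi_sl": f_cdi_sl,
            "f_cdi_total": 100.0 * cdi_tot / (cdi_tot + vdi_tot)}


# ---------------------------------------------------------------------------
def peak_extraction(t, y, baseline: float | None = None) -> dict:
    """Peak value/time, 5%-of-peak onset latency, and FDHM of a transient."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    base = float(y[0]) if baseline is None else baseline
    dy = y - base
    ipk = int(np.argmax(dy))
    pk = dy[ipk]
    if pk <= 0 or ipk == 0 or ipk == len(y) - 1 and np.all(np.diff(dy) >= 0):
        return {"peak": float("nan"), "t_peak": float("nan"),
                "onset": float("nan"), "fdhm": float("nan"),
                "flat_or_monotone": True}
    onset_idx = np.nonzero(dy >= 0.05 * pk)[0][0]
    half = 0.5 * pk
    above = dy >= half
    i0 = np.nonzero(above)[0][0]
    i1 = np.nonzero(above)[0][-1]

    def cross(ia, ib):
        if ia == ib or dy[ib] == dy[ia]:
            return t[ia]
        w = (half - dy[ia]) / (dy[ib] - dy[ia])
        return t[ia] + w * (t[ib] - t[ia])

    t_lo = cross(max(i0 - 1, 0), i0)
    t_hi = cross(i1, min(i1 + 1, len(t) - 1))
    return {"peak": float(pk + base), "delta_peak": float(pk),
            "t_peak": float(t[ipk]), "onset": float(t[onset_idx]),
            "fdhm": float(t_hi - t_lo), "flat_or_monotone": False}
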