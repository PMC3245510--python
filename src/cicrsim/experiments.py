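"""Reproduction harness: end-to-end runs of the named voltage-clamp studies
(gain pair, paired-stimulus refractoriness, long/short-pulse charge balance,
luminal-sensor ablation, caffeine) with their derived observables.

These functions wire protocols, pharmacology and analysis together; they are
what the command-line ``reproduce`` targets and the acceptance script call.
"""

from __future__ import annotations

import numpy as np

from .cell import CellModel, SimulationResult
from .protocols import ClampProtocol, PharmacologyConfig
from .analysis import (compute_gain, charge_balance, measure_refractoriness,
                       inactivation_pathway_fractions, peak_extraction)
from .ryr import caffeine_open_probability

# step sizes (ms): short single-beat runs resolve the release at 2 us; long
# trains run at 4 us (dt-halving changes the observables by <0.5%, see tests)
DT_SHORT = 2e-3
DT_TRAIN = 4e-3

PULSE_ON = 200.0          # ms of pre-hold before the standard test pulse


def run_gain_pair(model: CellModel | None = None, level: float = 10.0,
                  duration: float = 50.0, dt: float = DT_SHORT):
    """Control / ryanodine pair for the standard 50 ms step and its gain,
    onset delay and inactivation-pathway report."""
    model = model or CellModel()
    prot = ClampProtocol(level=level, duration=duration,
                         pre_hold=PULSE_ON, tail=150.0)
    rc = model.run(prot, dt=dt)
    rb = model.run(prot, PharmacologyConfig(ryanodine=True), dt=dt)
    gain = compute_gain(rc, rb, PULSE_ON)
    cdi = inactivation_pathway_fractions(
        rc, PULSE_ON, PULSE_ON + duration + 2.0, model.params.rates.f_TT)
    return {"control": rc, "ryanodine": rb, "gain": gain, "cdi": cdi}


def extract_trigger_waveform(res: SimulationResult, t_on: float = PULSE_ON,
                             length: float = 52.0):
    """The unitary dyadic trigger current of a run, re-based to t=0.

    Used as the stored stimulus of the paired-stimulus protocol.
    """
    t = res.t
    m = (t >= t_on) & (t <= t_on + length)
    return t[m] - t_on, res["i_CaL_TT_unit"][m]


def run_s1s2(model: CellModel | None = None, t2_list=None,
             dt: float = DT_SHORT, s1_start: float = 100.0):
    """Paired-stimulus scan: two identical stored trigger waveforms injected
    into the dyad at separation T2; returns per-T2 results and (ARP, RRP)."""
    model = model or CellModel()
    t2_list = list(t2_list if t2_list is not None else range(50, 275, 25))
    base = run_gain_pair(model, dt=dt)
    wav_t, wav_i = extract_trigger_waveform(base["control"])
    results = {}
    for t2 in t2_list:
        prot = ClampProtocol(level=-40.0, duration=1.0, n_pulses=0,
                             pre_hold=0.0,
                             tail=s1_start + t2 + wav_t[-1] + 200.0)
        pharm = PharmacologyConfig(inject=True, inject_t=wav_t,
                                   inject_i=wav_i,
                                   inject_starts=(s1_start, s1_start + t2))
        results[t2] = model.run(prot, pharm, dt=dt)
    arp, rrp, detail = measure_refractoriness(results, s1_start)
    return {"results": results, "arp": arp, "rrp": rrp, "detail": detail,
            "waveform": (wav_t, wav_i)}


def run_pulse_train(model: CellModel | None = None, duration: float = 800.0,
                    n_pulses: int = 5, frequency: float = 0.33,
                    level: float = 10.0, dt: float = DT_TRAIN,
                    record_stride_ms: float = 0.5,
                    pharm: PharmacologyConfig | None = None):
    """Repetitive-stimulation run (long- or short-pulse protocol)."""
    model = model or CellModel()
    prot = ClampProtocol(level=level, duration=duration, n_pulses=n_pulses,
                         frequency=frequency, pre_hold=500.0, tail=100.0)
    res = model.run(prot, pharm, dt=dt, record_stride_ms=record_stride_ms)
    return res, prot


def long_pulse_balance(model: CellModel | None = None, n_pulses: int = 5,
                       dt: float = DT_TRAIN):
    """Charge ledger of the last (steady) cycle of the long-pulse protocol."""
    model = model or CellModel()
    prot = ClampProtocol(level=10.0, duration=800.0, n_pulses=n_pulses,
                         frequency=0.33, pre_hold=500.0,
                         tail=1000.0 / 0.33 - 800.0)   # record a full cycle
    res = model.run(prot, dt=dt, record_stride_ms=0.5)
    t0 = prot.pre_hold + (n_pulses - 1) * prot.period
    t1 = min(t0 + prot.period, res.t[-1])
    ledger = charge_balance(res, t0, t1)
    return {"result": res, "ledger": ledger, "cycle": (t0, t1)}


def short_pulse_staircase(model: CellModel | None = None,
                          n_pulses: int = 16, dt: float = DT_TRAIN):
    """Negative staircase of the 100 ms / 0.33 Hz train: per-pulse peak
    transients and the steady-state peak as % of the first."""
    res, prot = run_pulse_train(model, duration=100.0, n_pulses=n_pulses,
                                dt=dt)
    t = res.t
    ca = res["Ca_myo"]
    peaks = []
    for k in range(n_pulses):
        t0 = prot.pre_hold + k * prot.period
        m = (t >= t0) & (t < t0 + prot.period)
        base = ca[t < t0][-1]
        peaks.append(float(np.max(ca[m]) - base))
    peaks = np.asarray(peaks)
    return {"result": res, "peaks": peaks,
            "staircase_pct": 100.0 * peaks[-1] / peaks[0]}


def sensor_ablation(model: CellModel | None = None, dt: float = DT_TRAIN,
                    n_pulses: int = 10):
    """Luminal-sensor ablation at 4 Hz: control train vs var frozen at its
    steady 4 Hz value; % reduction in steady diastolic jSR Ca."""
    model = model or CellModel()
    prot = ClampProtocol(level=10.0, duration=50.0, n_pulses=n_pulses,
                         frequency=4.0, pre_hold=250.0, tail=50.0)
    ctl = model.run(prot, dt=dt, record_stride_ms=0.5)
    t = ctl.t
    # steady 4 Hz value of var: its end-diastolic level just before the
    # last pulse.  Freezing var there removes the jSR-content feedback
    # while keeping the channel at its normal diastolic sensitization, so
    # the clamped cell releases without refractory protection.
    t_last = prot.pre_hold + (n_pulses - 1) * prot.period
    var_4hz = float(ctl["var"][t <= t_last][-1])
    abl = model.run(prot, PharmacologyConfig(sensor_clamp_var=var_4hz),
                    dt=dt, record_stride_ms=0.5)

    def diastolic_jsr(res):
        # jSR immediately before the last pulse
        tt = res.t
        mm = tt <= prot.pre_hold + (n_pulses - 1) * prot.period
        return float(res["Ca_jSR"][mm][-1])

    j_ctl = diastolic_jsr(ctl)
    j_abl = diastolic_jsr(abl)
    return {"control": ctl, "ablated": abl, "var_4hz": var_4hz,
            "jsr_control": j_ctl, "jsr_ablated": j_abl,
            "reduction_pct": 100.0 * (j_ctl - j_abl) / j_ctl}


def caffeine_study(model: CellModel | None = None, dt: float = DT_SHORT):
    """Caffeine application in a fura-2 dialyzed cell.

    Protocol A: a simple -40 -> 0 mV, 100 ms pulse.  Protocol B: 5 mM
    caffeine for 1 s, then the same pulse.  Observables: the caffeine-evoked
    transient peak, the control voltage-evoked rise, and the jSR before/after
    caffeine.
    """
    model = model or CellModel()
    pre = 1000.0
    prot = ClampProtocol(level=0.0, duration=100.0, pre_hold=pre, tail=400.0)
    ra = model.run(prot, PharmacologyConfig(fura2=True), dt=dt)
    rb = model.run(prot, PharmacologyConfig(
        fura2=True, caffeine_um=5000.0, caffeine_window=(0.0, pre)), dt=dt)

    ca_a = ra["Ca_myo"] * 1e6   # nM
    ca_b = rb["Ca_myo"] * 1e6
    t = ra.t
    ctl_base = float(ca_a[t <= pre][-1])
    ctl_peak = float(np.max(ca_a[t >= pre]))
    caff_peak = float(np.max(ca_b[rb.t <= pre]))
    caff_base = float(ca_b[0])
    jsr_pre = float(rb["Ca_jSR"][0])
    jsr_post = float(rb["Ca_jSR"][rb.t <= pre][-1])
    second_peak = float(np.max(ca_b[rb.t >= pre]))
    return {"control": ra, "caffeine": rb,
            "control_rise_nM": (ctl_base, ctl_peak),
            "caffeine_peak_nM": caff_peak, "caffeine_base_nM": caff_base,
            "jsr_pre_mM": jsr_pre, "jsr_post_mM": jsr_post,
            "second_peak_nM": second_peak,
            "dose_response_5mM": float(caffeine_open_probability(5000.0))}


def graded_release(model: CellModel | None = None,
                   scales=(1.0, 0.75, 0.5, 0.25), dt: float = DT_SHORT):
    """Trigger-current scaling family at the fixed +10 mV step: peak
    transients and release latencies per scale."""
    model = model or CellModel()
    prot = ClampProtocol(level=10.0, duration=50.0, pre_hold=PULSE_ON,
                         tail=150.0)
    out = {}
    for s in scales:
        res = model.run(prot, PharmacologyConfig(i_cal_tt_scale=s), dt=dt)
        pk = peak_extraction(res.t, res["Ca_myo"])
        pk_o2 = peak_extraction(res.t, res["O2_ryr"])
        out[s] = {"result": res, "peak_dca": pk["delta_peak"],
                  "latency": pk_o2["onset"] - PULSE_ON}
    return out
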