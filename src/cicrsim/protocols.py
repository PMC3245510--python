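"""Declarative voltage-clamp protocols and the registry of named
experiments.

A :class:`ClampProtocol` is a holding potential plus a pulse train (level,
duration, repetition count and frequency) realized as a piecewise-linear
waveform with a fixed clamp-transition time (default 1 ms).  A
:class:`PharmacologyConfig` carries the condition switches (ryanodine, Ba2+
substitution, caffeine window, thapsigargin, luminal-sensor clamp,
extracellular-Ca schedule, trigger-current scaling, fura-2 dialysis, and the
trigger-injection mode used by the paired-stimulus protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

TRANSITION_MS = 1.0


@dataclass
class ClampProtocol:
    holding: float = -40.0          # mV
    level: float = 10.0             # mV
    duration: float = 50.0          # ms at the depolarized level
    n_pulses: int = 1
    frequency: float = 1.0          # Hz (pulse repetition)
    transition: float = TRANSITION_MS
    pre_hold: float = 200.0         # ms at holding before the first pulse
    tail: float = 150.0             # ms recorded after the last pulse
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.duration <= 0 or self.n_pulses < 0 or self.transition < 0:
            raise ValueError("invalid protocol timing")
        if self.n_pulses > 1 and self.period < self.duration:
            raise ValueError("pulse period shorter than pulse duration")

    @property
    def period(self) -> float:
        return 1000.0 / self.frequency

    @property
    def t_end(self) -> float:
        if self.n_pulses == 0:
            return self.pre_hold + self.tail
        t_last = self.pre_hold + (self.n_pulses - 1) * self.period
        return t_last + self.duration + 2 * self.transition + self.tail

    def breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, v) nodes of the piecewise-linear waveform."""
        ts = [0.0]
        vs = [self.holding]
        for k in range(self.n_pulses):
            t0 = self.pre_hold + k * self.period
            ts += [t0, t0 + self.transition,
                   t0 + self.transition + self.duration,
                   t0 + 2 * self.transition + self.duration]
            vs += [self.holding, self.level, self.level, self.holding]
        ts.append(self.t_end)
        vs.append(self.holding)
        return np.asarray(ts), np.asarray(vs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClampProtocol":
        return cls(**d)


@dataclass
class PharmacologyConfig:
    ryanodine: bool = False
    barium: bool = False
    caffeine_um: float = 0.0
    caffeine_window: tuple[float, float] = (0.0, 0.0)   # ms
    thapsigargin: bool = False
    thapsigargin_onset: float = 0.0                     # ms
    sensor_clamp_var: float | None = None
    cao_schedule: tuple[tuple[float, float], ...] = ()  # (t_ms, mM) steps
    i_cal_tt_scale: float = 1.0
    fura2: bool = False
    # trigger-current injection (paired-stimulus protocol): a stored
    # i_CaL,TT waveform replayed into the dyad, bypassing the DHPR model
    inject: bool = False
    inject_t: np.ndarray | None = None      # ms, waveform time base
    inject_i: np.ndarray | None = None      # pA (unitary, per dyad)
    inject_starts: tuple[float, ...] = ()   # onset times of each stimulus

    def validate(self, require_waveform: bool = True) -> None:
        if self.barium and self.ryanodine:
            raise ValueError("barium substitution already abolishes release; "
                             "combining with ryanodine is ill-defined")
        if self.caffeine_um < 0 or self.i_cal_tt_scale < 0:
            raise ValueError("negative pharmacology parameter")
        if self.inject and require_waveform and (
                self.inject_t is None or self.inject_i is None):
            raise ValueError("injection mode requires a stored waveform")


def clamp_voltage(t, protocol: ClampProtocol):
    """Clamp potential (mV) at time(s) t (ms)."""
    ts, vs = protocol.breakpoints()
    return np.interp(t, ts, vs)


# ---------------------------------------------------------------------------
def _named() -> dict:
    reg: dict[str, tuple[ClampProtocol, PharmacologyConfig]] = {}

    reg["fig7_positive_steps"] = (
        ClampProtocol(level=10.0, duration=50.0,
                      meta={"sweep_levels": [10, 20, 30, 40]}),
        PharmacologyConfig())
    reg["fig8_negative_steps"] = (
        ClampProtocol(level=0.0, duration=100.0,
                      meta={"sweep_levels": [-30, -20, -10, 0]}),
        PharmacologyConfig())
    reg["fig9_inactivation"] = (
        ClampProtocol(level=10.0, duration=50.0), PharmacologyConfig())
    reg["fig10_graded"] = (
        ClampProtocol(level=10.0, duration=50.0,
                      meta={"trigger_scales": [1.0, 0.75, 0.5, 0.25]}),
        PharmacologyConfig())
    reg["fig11_duration"] = (
        ClampProtocol(level=10.0, duration=80.0,
                      meta={"sweep_durations": [5, 10, 20, 80]}),
        PharmacologyConfig())
    reg["fig12_gain"] = (
        ClampProtocol(level=10.0, duration=50.0), PharmacologyConfig())
    reg["fig13_s1s2"] = (
        ClampProtocol(level=-40.0, duration=50.0, n_pulses=0,
                      pre_hold=100.0,
                      meta={"t2_list": list(range(50, 275, 25)),
                            "s_duration": 50.0}),
        PharmacologyConfig(inject=True))
    reg["fig14_train4hz"] = (
        ClampProtocol(level=10.0, duration=50.0, n_pulses=10, frequency=4.0,
                      tail=100.0),
        PharmacologyConfig())
    reg["fig15_phase"] = (
        ClampProtocol(level=10.0, duration=50.0,
                      meta={"target_jsr_um": 918.0}),
        PharmacologyConfig())
    reg["fig16_sr_content"] = (
        ClampProtocol(level=10.0, duration=50.0,
                      meta={"jsr_sweep_um": [317, 451, 576, 673, 734,
                                             793, 850, 918, 948, 1020]}),
        PharmacologyConfig())
    reg["fig17_caffeine"] = (
        ClampProtocol(level=0.0, duration=100.0, pre_hold=1000.0,
                      tail=400.0),
        PharmacologyConfig(caffeine_um=5000.0, caffeine_window=(0.0, 1000.0),
                           fura2=True))
    reg["fig18_thapsigargin"] = (
        ClampProtocol(level=0.0, duration=100.0, n_pulses=10, frequency=0.05),
        PharmacologyConfig(thapsigargin=True, thapsigargin_onset=0.0,
                           fura2=True))
    reg["fig19_cao"] = (
        ClampProtocol(level=0.0, duration=100.0, n_pulses=20, frequency=0.5),
        PharmacologyConfig(cao_schedule=((0.0, 1.0), (10000.0, 2.0))))
    reg["fig20_long"] = (
        ClampProtocol(level=10.0, duration=800.0, n_pulses=40,
                      frequency=0.33), PharmacologyConfig())
    reg["fig20_short"] = (
        ClampProtocol(level=10.0, duration=100.0, n_pulses=40,
                      frequency=0.33), PharmacologyConfig())
    reg["fig21_tails"] = (
        ClampProtocol(level=50.0, duration=50.0,
                      meta={"sweep_durations": list(range(50, 225, 25))}),
        PharmacologyConfig())
    return reg


NAMED_PROTOCOLS = sorted(_named())


def build_named_protocol(name: str) -> tuple[ClampProtocol, PharmacologyConfig]:
    """Return the printed protocol (amplitudes, durations, frequencies) and
    pharmacological condition for a named experiment."""
    reg = _named()
    if name not in reg:
        raise KeyError(f"unknown protocol {name!r}; known: {NAMED_PROTOCOLS}")
    prot, pharm = reg[name]
    pharm.validate(require_waveform=False)
    return prot, pharm


def apply_sr_content_sweep(y0: np.ndarray, targets_um, params) -> list[np.ndarray]:
    """Initial-state family with prescribed diastolic jSR (and LSR) Ca.

    Each target (uM) sets [Ca]_jSR = [Ca]_LSR and relaxes the luminal-sensor
    states to their conditional steady values at that jSR Ca (fixed-point
    iteration of the sensor scheme).
    """
    from . import state as S
    from .parameters import pack_parameters
    from .ryr import luminal_derivatives

    P = pack_parameters(params)
    lum = params.rates.luminal
    out = []
    for tgt in targets_um:
        y = y0.copy()
        y[S.CA_JSR] = tgt * 1e-3
        y[S.CA_LSR] = tgt * 1e-3
        ls = np.array([y[S.LS_A1], y[S.LS_I2], y[S.LS_I3], y[S.LS_B6]])
        for _ in range(200000):   # forward-Euler relaxation, dt = 0.05 ms
            d = luminal_derivatives(
                ls, tgt,
                lum["k12_ls"], lum["k21_ls"], lum["k14_ls"], lum["k41_ls"],
                lum["k42_ls"], lum["k43_ls"], lum["k34_ls"], lum["k23_ls"],
                lum["k32_ls"], lum["k56_ls"], lum["k65_ls"],
                lum["k24_ls"], lum["k25_ls"])
            ls += 0.05 * d
            if np.max(np.abs(d)) < 1e-12:
                break
        y[S.LS_A1], y[S.LS_I2], y[S.LS_I3], y[S.LS_B6] = ls
        out.append(y)
    return out
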