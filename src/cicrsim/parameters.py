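"""Model constants, geometry and initial conditions.

All printed constants are shipped in ``data/parameters.yaml`` and
``data/initial_state.yaml`` in their source units; :func:`load_default_parameters`
converts them once into the canonical internal unit system

    time ms | voltage mV | current pA | volume nL | length nm
    compartment Ca/Na/Cs in mM | signaling species and SL sites in uM

and records every conversion in ``ModelParameters.metadata``.  The compiled
integrator consumes a flat float64 vector built by :func:`pack_parameters`;
the ``P_*`` index constants below are the only way the core addresses it.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import state as S

__all__ = [
    "GeometryParams", "TransportParams", "RateTables", "NumericsParams",
    "ModelParameters", "load_default_parameters", "load_initial_state",
    "validate", "pack_parameters",
]


# ---------------------------------------------------------------------------
# packed-vector index registry (order is frozen; append only)
_c = iter(range(1000)).__next__

P_NDYAD = _c(); P_VMYO = _c(); P_VLSR = _c(); P_VJSR = _c(); P_VCLEFT = _c()
P_DR = _c(); P_DZ = _c(); P_NR = _c(); P_NZ = _c()
P_F = _c(); P_RT = _c()
P_CAO = _c(); P_NAO = _c(); P_CSO = _c()
P_PCA = _c(); P_PNA = _c(); P_PCS = _c()
P_KMALLO = _c(); P_KMCAO = _c(); P_KMCAI = _c(); P_KMNAO = _c()
P_KMNAI = _c(); P_VMAXNCX = _c()
P_KMPCA = _c(); P_IPMCA = _c()
P_KMCS = _c(); P_KMNA = _c(); P_INACS = _c()
P_GNAB = _c()
P_TAUTR = _c(); P_TAUNA = _c(); P_TAUCS = _c()
P_PRYR = _c(); P_DCA = _c()
P_NH = _c(); P_NL = _c(); P_KH = _c(); P_KL = _c()
P_MGMYO = _c(); P_F3TOT = _c(); P_F3ON = _c(); P_F3OFF = _c()
P_K12PLB = _c(); P_K21PLB = _c(); P_KCYT = _c(); P_KSR = _c()
P_SERCATOT = _c(); P_PSR = _c(); P_PKA = _c()
P_RCAL = _c(); P_RNACA = _c(); P_RNACS = _c(); P_FTT = _c()
P_LS_K12 = _c(); P_LS_K21 = _c(); P_LS_K14 = _c(); P_LS_K41 = _c()
P_LS_K42 = _c(); P_LS_K43 = _c(); P_LS_K34 = _c(); P_LS_K23 = _c()
P_LS_K32 = _c(); P_LS_K56 = _c(); P_LS_K65 = _c(); P_LS_K24 = _c()
P_LS_K25 = _c()
P_CAMTOT = _c(); P_BTOT = _c(); P_CKTOT = _c(); P_CNTOT = _c(); P_PP1TOT = _c()
P_CM_K02 = _c(); P_CM_K20 = _c(); P_CM_K24 = _c(); P_CM_K42 = _c()
P_CM_K0BON = _c(); P_CM_K0BOFF = _c()
P_CK_KPP1 = _c(); P_CK_KMPP1 = _c(); P_CK_K21 = _c(); P_CK_K12 = _c()
P_CK_K13 = _c(); P_CK_K31 = _c(); P_CK_K23 = _c(); P_CK_K32 = _c()
P_CK_K45 = _c(); P_CK_K54 = _c(); P_CK_K46 = _c(); P_CK_K64 = _c()
P_CK_K56 = _c(); P_CK_K65 = _c()
P_CN_KCAON = _c(); P_CN_KCAOFF = _c(); P_CN_K02 = _c(); P_CN_K20 = _c()
P_CN_K24 = _c(); P_CN_K42 = _c(); P_CN_K0ON = _c(); P_CN_K0OFF = _c()
P_CN_K2ON = _c(); P_CN_K2OFF = _c(); P_CN_K4ON = _c(); P_CN_K4OFF = _c()
P_RIMSCALE = _c(); P_CONSC6 = _c()
P_F2TOT = _c(); P_F2ON = _c(); P_F2OFF = _c()
P_CAMTOT_DY = _c()
# SERCA/PLB regulatory activities, frozen at the packaged operating point
# (active-enzyme concentrations in mM; see sr_transport and docs/methods.md)
P_CK_MM_REG = _c(); P_CN_MM_REG = _c()

N_PARAM = _c()


# ---------------------------------------------------------------------------
@dataclass
class GeometryParams:
    """Sub-cellular morphology (volumes nL, lengths nm, areas um^2)."""
    N_dyad: int
    V_myo: float
    V_LSR: float
    V_jSR_total: float
    V_cleft: float
    d: float
    h: float
    dr: float
    dz: float
    areas: dict[str, float] = field(default_factory=dict)

    @property
    def V_jSR(self) -> float:
        """Junctional-SR volume of a single dyadic unit (nL)."""
        return self.V_jSR_total / self.N_dyad

    @property
    def nr(self) -> int:
        """Radial cells across the cleft radius."""
        return round((self.d / 2) / self.dr)

    @property
    def nz(self) -> int:
        """Axial cells across the cleft length."""
        return round(self.h / self.dz)


@dataclass
class TransportParams:
    """Sarcolemmal and intracellular transport constants (canonical units)."""
    F: float            # C/mol
    R: float            # mJ/mol/K
    T: float            # K
    Ca_o: float         # mM
    Na_o: float         # mM
    Cs_o: float         # mM
    P_Ca: float         # uL/s (GHK permeability, used as printed)
    P_Na: float
    P_Cs: float
    K_mAllo: float      # mM
    K_mCao: float       # mM
    K_mCai: float       # mM
    K_mNao: float       # mM
    K_mNai: float       # mM
    V_max: float        # pA
    k_mpca: float       # mM
    I_PMCA_max: float   # pA
    K_mcs: float        # mM
    K_mna: float        # mM
    I_NaCs_max: float   # pA
    G_Nab: float        # nS
    tau_tr: float       # ms
    tau_Na: float       # ms
    tau_Cs: float       # ms
    P_ryr: float        # uL/s
    D_Ca: float         # nm^2/ms
    N_h: float          # uM
    N_l: float          # uM
    K_h: float          # uM
    K_l: float          # uM
    Mg_myo: float       # uM
    fluo3_tot: float    # uM
    k_fluo3_on: float   # 1/uM/ms
    k_fluo3_off: float  # 1/ms


@dataclass
class RateTables:
    """Tabulated rate constants (time unit ms; concentration powers as noted),
    pool totals, and the whole-cell scaling / partition factors."""
    serca: dict[str, float]
    cam: dict[str, float]
    camkii: dict[str, float]
    can: dict[str, float]
    luminal: dict[str, float]
    totals: dict[str, float]
    R_CaL: float = 1.0
    R_NaCa: float = 1.0
    R_NaCs: float = 1.0
    f_TT: float = 0.9


@dataclass
class NumericsParams:
    dt: float = 1.0e-3            # ms
    rim_exchange_scale: float = 1.0
    conserve_C6: bool = False
    fura2_tot: float = 2000.0     # uM
    fura2_kon: float = 0.080      # 1/uM/ms
    fura2_koff: float = 0.0192    # 1/ms


@dataclass
class ModelParameters:
    geometry: GeometryParams
    transport: TransportParams
    rates: RateTables
    numerics: NumericsParams
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("metadata")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            geometry=GeometryParams(**d["geometry"]),
            transport=TransportParams(**d["transport"]),
            rates=RateTables(**d["rates"]),
            numerics=NumericsParams(**d["numerics"]),
        )


# ---------------------------------------------------------------------------
def _read_yaml(name: str) -> dict:
    ref = importlib.resources.files("cicrsim.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _val(table: dict, key: str) -> float:
    v = table[key]
    return float(v[0]) if isinstance(v, (list, tuple)) else float(v)


_MS = 1e-3  # printed 1/s -> 1/ms


def load_default_parameters(overrides: dict[str, float] | None = None) -> ModelParameters:
    """Load the packaged default parameter set.

    ``overrides`` maps dotted keys (e.g. ``"scaling.R_CaL"`` or
    ``"luminal_sensor.k25_ls"``) to replacement values *in source units*.
    The returned object is validated; a :class:`ValueError` naming the
    offending field is raised on failure.
    """
    raw = _read_yaml("parameters.yaml")
    if overrides:
        for dotted, value in overrides.items():
            section, key = dotted.split(".", 1)
            if section not in raw or key not in raw[section]:
                raise KeyError(f"unknown parameter override: {dotted}")
            unit = raw[section][key][1]
            raw[section][key] = [float(value), unit]

    g = raw["geometry"]
    geometry = GeometryParams(
        N_dyad=int(_val(g, "N_dyad")),
        V_myo=_val(g, "V_myo"), V_LSR=_val(g, "V_LSR"),
        V_jSR_total=_val(g, "V_jSR_total"), V_cleft=_val(g, "V_cleft"),
        d=_val(g, "d"), h=_val(g, "h"), dr=_val(g, "dr"), dz=_val(g, "dz"),
        areas={k: _val(g, k) for k in g if k.startswith("A_")},
    )

    t = raw["transport"]
    transport = TransportParams(
        F=_val(t, "F"), R=_val(t, "R"), T=_val(t, "T"),
        Ca_o=_val(t, "Ca_o"), Na_o=_val(t, "Na_o"), Cs_o=_val(t, "Cs_o"),
        P_Ca=_val(t, "P_Ca"), P_Na=_val(t, "P_Na"), P_Cs=_val(t, "P_Cs"),
        K_mAllo=_val(t, "K_mAllo"), K_mCao=_val(t, "K_mCao"),
        K_mCai=_val(t, "K_mCai"), K_mNao=_val(t, "K_mNao"),
        K_mNai=_val(t, "K_mNai"), V_max=_val(t, "V_max"),
        k_mpca=_val(t, "k_mpca") * 1e-3,          # uM -> mM
        I_PMCA_max=_val(t, "I_PMCA_max"),
        K_mcs=_val(t, "K_mcs") * 1e-3,            # uM -> mM
        K_mna=_val(t, "K_mna") * 1e-3,            # uM -> mM
        I_NaCs_max=_val(t, "I_NaCs_max"),
        G_Nab=_val(t, "G_Nab"),
        tau_tr=_val(t, "tau_tr") * 1e3,           # s -> ms
        tau_Na=_val(t, "tau_Na") * 1e3,
        tau_Cs=_val(t, "tau_Cs") * 1e3,
        P_ryr=_val(t, "P_ryr"),
        D_Ca=_val(t, "D_Ca") * 1e3,               # um^2/s -> nm^2/ms
        N_h=_val(t, "N_h"), N_l=_val(t, "N_l"),
        K_h=_val(t, "K_h"), K_l=_val(t, "K_l"),
        Mg_myo=_val(t, "Mg_myo"),
        fluo3_tot=_val(t, "fluo3_tot"),
        k_fluo3_on=_val(t, "k_fluo3_on") * _MS,
        k_fluo3_off=_val(t, "k_fluo3_off") * _MS,
    )

    def rate_dict(section: str) -> dict[str, float]:
        return {k: _val(raw[section], k) * _MS for k in raw[section]}

    sc = raw["scaling"]
    se = raw["serca"]
    serca = {
        "k12_PLB": _val(se, "k12_PLB") * _MS,
        "k21_PLB": _val(se, "k21_PLB") * _MS,
        "K_cyt_serca": _val(se, "K_cyt_serca") * _MS,
        "K_serca_sr": _val(se, "K_serca_sr") * _MS,
        "SERCA_tot": _val(se, "SERCA_tot"),
        "PSR": _val(se, "PSR"),
        "PKA_act": _val(se, "PKA_act"),
    }
    rates = RateTables(
        serca=serca,
        cam=rate_dict("cam_rates"),
        camkii={k: (_val(raw["camkii_rates"], k) * _MS
                    if k != "k_mPP1" else _val(raw["camkii_rates"], k))
                for k in raw["camkii_rates"]},
        can=rate_dict("can_rates"),
        luminal=rate_dict("luminal_sensor"),
        totals={k: _val(raw["signaling_totals"], k)
                for k in raw["signaling_totals"]},
        R_CaL=_val(sc, "R_CaL"), R_NaCa=_val(sc, "R_NaCa"),
        R_NaCs=_val(sc, "R_NaCs"), f_TT=_val(sc, "f_TT"),
    )

    n = raw["numerics"]
    numerics = NumericsParams(
        dt=_val(n, "dt"),
        rim_exchange_scale=_val(n, "rim_exchange_scale"),
        conserve_C6=bool(_val(n, "conserve_C6")),
        fura2_tot=_val(n, "fura2_tot"),
        fura2_kon=_val(n, "fura2_kon") * _MS,
        fura2_koff=_val(n, "fura2_koff") * _MS,
    )

    params = ModelParameters(
        geometry=geometry, transport=transport, rates=rates, numerics=numerics,
        metadata={"schema_version": raw["schema_version"],
                  "unit_system": "ms/mV/pA/nL/nm; mM compartments, uM signaling",
                  "conversions": {
                      "k_mpca": "uM->mM", "K_mcs": "uM->mM", "K_mna": "uM->mM",
                      "tau_*": "s->ms", "D_Ca": "um^2/s->nm^2/ms",
                      "all rate constants": "1/s->1/ms"}},
    )
    report = validate(params)
    if report:
        raise ValueError("invalid parameters: " + "; ".join(report))
    return params


def validate(params: ModelParameters) -> list[str]:
    """Return the list of violated invariants (empty on success)."""
    out: list[str] = []
    g, t, r = params.geometry, params.transport, params.rates

    for name in ("N_dyad", "V_myo", "V_LSR", "V_jSR_total", "V_cleft",
                 "d", "h", "dr", "dz"):
        if getattr(g, name) <= 0:
            out.append(f"geometry.{name}: must be positive")
    for fdata in dataclasses.fields(t):
        v = getattr(t, fdata.name)
        if isinstance(v, float) and v <= 0:
            out.append(f"transport.{fdata.name}: must be positive")

    radius = g.d / 2
    if abs(radius / g.dr - round(radius / g.dr)) > 1e-9:
        out.append(f"geometry.dr: {g.dr} nm does not tile the {radius} nm radius")
    if abs(g.h / g.dz - round(g.h / g.dz)) > 1e-9:
        out.append(f"geometry.dz: {g.dz} nm does not tile the {g.h} nm length")
    v_cyl = math.pi * radius**2 * g.h * 1e-24 * 1e9   # nm^3 -> nL
    if abs(v_cyl - g.V_cleft) / g.V_cleft > 0.01:
        out.append("geometry.V_cleft: differs from pi*(d/2)^2*h by more than 1%")

    for table_name in ("serca", "cam", "camkii", "can", "luminal", "totals"):
        for k, v in getattr(r, table_name).items():
            if v < 0:
                out.append(f"rates.{table_name}.{k}: negative rate")
    if not 0.0 <= r.f_TT <= 1.0:
        out.append("rates.f_TT: partition fraction outside [0, 1]")
    for k in ("R_CaL", "R_NaCa", "R_NaCs"):
        if getattr(r, k) < 0:
            out.append(f"rates.{k}: negative scaling")
    return out


# ---------------------------------------------------------------------------
def load_initial_state(params: ModelParameters | None = None) -> np.ndarray:
    """Packaged resting initial conditions as a flat state vector.

    Markov closure states (C5/C4/I4/B5/P2) are not stored; each is derived
    from its pool.  The cleft grid is initialized uniformly to the packaged
    resting dyadic Ca by the integrator.
    """
    raw = _read_yaml("initial_state.yaml")
    y = np.zeros(S.N_STATE)

    c = raw["concentrations"]
    y[S.CA_MYO] = _val(c, "Ca_myo"); y[S.CA_JSR] = _val(c, "Ca_jSR")
    y[S.CA_LSR] = _val(c, "Ca_LSR")
    y[S.NA_MYO] = _val(c, "Na_myo"); y[S.NA_DYAD] = _val(c, "Na_dyad")
    y[S.CS_MYO] = _val(c, "Cs_myo"); y[S.CS_DYAD] = _val(c, "Cs_dyad")

    b = raw["buffers"]
    y[S.O_C] = _val(b, "O_c"); y[S.O_TC] = _val(b, "O_tc")
    y[S.O_TMGC] = _val(b, "O_tmgc"); y[S.O_TMGMG] = _val(b, "O_tmgmg")
    y[S.CAF3] = _val(b, "CaF3")
    y[S.CAF2] = 0.0

    ry = raw["ryr"]
    y[S.RYR_C1] = _val(ry, "C1"); y[S.RYR_O2] = _val(ry, "O2")
    y[S.RYR_C3] = _val(ry, "C3")

    ls = raw["luminal_sensor"]
    y[S.LS_A1] = _val(ls, "A1"); y[S.LS_I2] = _val(ls, "I2")
    y[S.LS_I3] = _val(ls, "I3"); y[S.LS_B6] = _val(ls, "B6")

    sr = raw["serca"]
    y[S.CA_SERCA] = _val(sr, "Ca_serca"); y[S.PLB_DP] = _val(sr, "PLB_dp")

    dh = raw["dhpr"]
    for base in (S.TT_C1, S.SL_C1):
        y[base + 0] = _val(dh, "C1"); y[base + 1] = _val(dh, "O2")
        y[base + 2] = _val(dh, "O3"); y[base + 3] = _val(dh, "C4")
        y[base + 4] = _val(dh, "C6"); y[base + 5] = _val(dh, "S2")

    sg = raw["signaling"]
    order = ["Ca2CaM", "Ca4CaM", "CaMB", "Ca2CaMB", "Ca4CaMB",
             "P1", "P3", "P4", "P5", "P6",
             "Ca4CaN", "CaMCaN", "Ca2CaMCaN", "Ca4CaMCaN"]
    for base in (S.DY_CA2CAM, S.CY_CA2CAM):
        for j, key in enumerate(order):
            y[base + j] = _val(sg, key)

    _check_initial(y)
    return y


def resting_dyad_ca() -> float:
    """Uniform resting cleft Ca concentration (mM)."""
    raw = _read_yaml("initial_state.yaml")
    return _val(raw["concentrations"], "Ca_dyad")


def _check_initial(y: np.ndarray) -> None:
    occ = [S.O_C, S.O_TC, S.O_TMGC, S.O_TMGMG,
           S.RYR_C1, S.RYR_O2, S.RYR_C3,
           S.LS_A1, S.LS_I2, S.LS_I3, S.LS_B6,
           S.PLB_DP, S.TT_C1, S.TT_O2, S.TT_O3, S.TT_C4, S.TT_C6, S.TT_S2]
    for i in occ:
        if not 0.0 <= y[i] <= 1.0:
            raise ValueError(f"initial state {S.STATE_NAMES[i]} outside [0,1]")
    if y[S.O_TMGC] + y[S.O_TMGMG] > 1.0:
        raise ValueError("troponin-Mg occupancies exceed 1")
    for c4 in (1 - (y[S.RYR_C1] + y[S.RYR_O2] + y[S.RYR_C3]),
               1 - (y[S.LS_A1] + y[S.LS_I2] + y[S.LS_I3]),
               1 - (y[S.LS_I2] + y[S.LS_I3] + y[S.LS_B6]),
               1 - (y[S.TT_C1] + y[S.TT_O2] + y[S.TT_O3] + y[S.TT_C4])):
        if not 0.0 <= c4 <= 1.0:
            raise ValueError("derived closure state outside [0,1]")
    if np.any(y[[S.CA_MYO, S.CA_JSR, S.CA_LSR, S.NA_MYO, S.NA_DYAD,
                 S.CS_MYO, S.CS_DYAD, S.CAF3]] < 0):
        raise ValueError("negative initial concentration")


# ---------------------------------------------------------------------------
def pack_parameters(params: ModelParameters) -> np.ndarray:
    """Flatten a ModelParameters into the core's float64 vector."""
    g, t, r, n = params.geometry, params.transport, params.rates, params.numerics
    P = np.zeros(N_PARAM)
    P[P_NDYAD] = g.N_dyad
    P[P_VMYO] = g.V_myo; P[P_VLSR] = g.V_LSR; P[P_VJSR] = g.V_jSR
    P[P_VCLEFT] = g.V_cleft
    P[P_DR] = g.dr; P[P_DZ] = g.dz; P[P_NR] = g.nr; P[P_NZ] = g.nz
    P[P_F] = t.F; P[P_RT] = t.R * t.T
    P[P_CAO] = t.Ca_o; P[P_NAO] = t.Na_o; P[P_CSO] = t.Cs_o
    P[P_PCA] = t.P_Ca; P[P_PNA] = t.P_Na; P[P_PCS] = t.P_Cs
    P[P_KMALLO] = t.K_mAllo; P[P_KMCAO] = t.K_mCao; P[P_KMCAI] = t.K_mCai
    P[P_KMNAO] = t.K_mNao; P[P_KMNAI] = t.K_mNai; P[P_VMAXNCX] = t.V_max
    P[P_KMPCA] = t.k_mpca; P[P_IPMCA] = t.I_PMCA_max
    P[P_KMCS] = t.K_mcs; P[P_KMNA] = t.K_mna; P[P_INACS] = t.I_NaCs_max
    P[P_GNAB] = t.G_Nab
    P[P_TAUTR] = t.tau_tr; P[P_TAUNA] = t.tau_Na; P[P_TAUCS] = t.tau_Cs
    P[P_PRYR] = t.P_ryr; P[P_DCA] = t.D_Ca
    P[P_NH] = t.N_h; P[P_NL] = t.N_l; P[P_KH] = t.K_h; P[P_KL] = t.K_l
    P[P_MGMYO] = t.Mg_myo
    P[P_F3TOT] = t.fluo3_tot; P[P_F3ON] = t.k_fluo3_on; P[P_F3OFF] = t.k_fluo3_off
    P[P_K12PLB] = r.serca["k12_PLB"]; P[P_K21PLB] = r.serca["k21_PLB"]
    P[P_KCYT] = r.serca["K_cyt_serca"]; P[P_KSR] = r.serca["K_serca_sr"]
    P[P_SERCATOT] = r.serca["SERCA_tot"]; P[P_PSR] = r.serca["PSR"]
    P[P_PKA] = r.serca["PKA_act"]
    P[P_RCAL] = r.R_CaL; P[P_RNACA] = r.R_NaCa; P[P_RNACS] = r.R_NaCs
    P[P_FTT] = r.f_TT
    lum = r.luminal
    P[P_LS_K12] = lum["k12_ls"]; P[P_LS_K21] = lum["k21_ls"]
    P[P_LS_K14] = lum["k14_ls"]; P[P_LS_K41] = lum["k41_ls"]
    P[P_LS_K42] = lum["k42_ls"]; P[P_LS_K43] = lum["k43_ls"]
    P[P_LS_K34] = lum["k34_ls"]; P[P_LS_K23] = lum["k23_ls"]
    P[P_LS_K32] = lum["k32_ls"]; P[P_LS_K56] = lum["k56_ls"]
    P[P_LS_K65] = lum["k65_ls"]; P[P_LS_K24] = lum["k24_ls"]
    P[P_LS_K25] = lum["k25_ls"]
    tot = r.totals
    P[P_CAMTOT] = tot["CaM_tot"]; P[P_BTOT] = tot["B_tot"]
    P[P_CKTOT] = tot["CaMKII_tot"]; P[P_CNTOT] = tot["CaN_tot"]
    P[P_PP1TOT] = tot["PP1_tot"]
    cm = r.cam
    P[P_CM_K02] = cm["k02_CM"]; P[P_CM_K20] = cm["k20_CM"]
    P[P_CM_K24] = cm["k24_CM"]; P[P_CM_K42] = cm["k42_CM"]
    P[P_CM_K0BON] = cm["k0Bon_CM"]; P[P_CM_K0BOFF] = cm["k0Boff_CM"]
    ck = r.camkii
    P[P_CK_KPP1] = ck["k_PP1"]; P[P_CK_KMPP1] = ck["k_mPP1"]
    P[P_CK_K21] = ck["k21_CK"]; P[P_CK_K12] = ck["k12_CK"]
    P[P_CK_K13] = ck["k13_CK"]; P[P_CK_K31] = ck["k31_CK"]
    P[P_CK_K23] = ck["k23_CK"]; P[P_CK_K32] = ck["k32_CK"]
    P[P_CK_K45] = ck["k45_CK"]; P[P_CK_K54] = ck["k54_CK"]
    P[P_CK_K46] = ck["k46_CK"]; P[P_CK_K64] = ck["k64_CK"]
    P[P_CK_K56] = ck["k56_CK"]; P[P_CK_K65] = ck["k65_CK"]
    cn = r.can
    P[P_CN_KCAON] = cn["kCaon_CN"]; P[P_CN_KCAOFF] = cn["kCaoff_CN"]
    P[P_CN_K02] = cn["k02_CN"]; P[P_CN_K20] = cn["k20_CN"]
    P[P_CN_K24] = cn["k24_CN"]; P[P_CN_K42] = cn["k42_CN"]
    P[P_CN_K0ON] = cn["k0on_CN"]; P[P_CN_K0OFF] = cn["k0off_CN"]
    P[P_CN_K2ON] = cn["k2on_CN"]; P[P_CN_K2OFF] = cn["k2off_CN"]
    P[P_CN_K4ON] = cn["k4on_CN"]; P[P_CN_K4OFF] = cn["k4off_CN"]
    P[P_RIMSCALE] = n.rim_exchange_scale
    P[P_CONSC6] = 1.0 if n.conserve_C6 else 0.0
    P[P_F2TOT] = n.fura2_tot; P[P_F2ON] = n.fura2_kon; P[P_F2OFF] = n.fura2_koff
    P[P_CAMTOT_DY] = tot.get("CaM_tot_dyad", tot["CaM_tot"])
    return P
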