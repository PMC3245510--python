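"""Frozen state-vector registry.

The whole-cell state is a flat float64 vector with the layout below plus the
flattened dyadic-cleft concentration grid appended by the integrator.  The
name <-> index map is frozen here so results stay reproducible across
refactors; every module addresses states through these constants.

Units: compartment concentrations in mM, signaling species and SERCA-bound
Ca in uM, occupancies dimensionless.
"""

from __future__ import annotations

# concentrations (mM)
CA_MYO = 0
CA_JSR = 1
CA_LSR = 2
NA_MYO = 3
NA_DYAD = 4
CS_MYO = 5
CS_DYAD = 6
# cytosolic buffers
O_C = 7
O_TC = 8
O_TMGC = 9
O_TMGMG = 10
CAF3 = 11        # fluo-3:Ca complex (uM)
CAF2 = 12        # fura-2:Ca complex (uM); 0 unless dialysis enabled
# RyR release channel (4-state; C4 by closure)
RYR_C1 = 13
RYR_O2 = 14
RYR_C3 = 15
# jSR luminal sensor (6-state; I4, B5 by closure)
LS_A1 = 16
LS_I2 = 17
LS_I3 = 18
LS_B6 = 19
# SERCA
CA_SERCA = 20    # uM
PLB_DP = 21
# DHPR L-type channel, T-tubular (dyad-facing) instance
TT_C1 = 22
TT_O2 = 23
TT_O3 = 24
TT_C4 = 25
TT_C6 = 26
TT_S2 = 27
# DHPR L-type channel, free-sarcolemmal instance
SL_C1 = 28
SL_O2 = 29
SL_O3 = 30
SL_C4 = 31
SL_C6 = 32
SL_S2 = 33

# CaM/CaMKII/CaN network, dyadic instance (uM / fractions)
DY_CA2CAM = 34
DY_CA4CAM = 35
DY_CAMB = 36
DY_CA2CAMB = 37
DY_CA4CAMB = 38
DY_P1 = 39
DY_P3 = 40
DY_P4 = 41
DY_P5 = 42
DY_P6 = 43
DY_CA4CAN = 44
DY_CAMCAN = 45
DY_CA2CAMCAN = 46
DY_CA4CAMCAN = 47
# cytosolic instance
CY_CA2CAM = 48
CY_CA4CAM = 49
CY_CAMB = 50
CY_CA2CAMB = 51
CY_CA4CAMB = 52
CY_P1 = 53
CY_P3 = 54
CY_P4 = 55
CY_P5 = 56
CY_P6 = 57
CY_CA4CAN = 58
CY_CAMCAN = 59
CY_CA2CAMCAN = 60
CY_CA4CAMCAN = 61

N_STATE = 62

STATE_NAMES = [
    "Ca_myo", "Ca_jSR", "Ca_LSR", "Na_myo", "Na_dyad", "Cs_myo", "Cs_dyad",
    "O_c", "O_tc", "O_tmgc", "O_tmgmg", "CaF3", "CaF2",
    "C1_ryr", "O2_ryr", "C3_ryr",
    "A1_ls", "I2_ls", "I3_ls", "B6_ls",
    "Ca_serca", "PLB_dp",
    "C1_dhpr_TT", "O2_dhpr_TT", "O3_dhpr_TT", "C4_dhpr_TT", "C6_dhpr_TT",
    "S2_dhpr_TT",
    "C1_dhpr_SL", "O2_dhpr_SL", "O3_dhpr_SL", "C4_dhpr_SL", "C6_dhpr_SL",
    "S2_dhpr_SL",
    "Ca2CaM_dy", "Ca4CaM_dy", "CaMB_dy", "Ca2CaMB_dy", "Ca4CaMB_dy",
    "P1_dy", "P3_dy", "P4_dy", "P5_dy", "P6_dy",
    "Ca4CaN_dy", "CaMCaN_dy", "Ca2CaMCaN_dy", "Ca4CaMCaN_dy",
    "Ca2CaM_cy", "Ca4CaM_cy", "CaMB_cy", "Ca2CaMB_cy", "Ca4CaMB_cy",
    "P1_cy", "P3_cy", "P4_cy", "P5_cy", "P6_cy",
    "Ca4CaN_cy", "CaMCaN_cy", "Ca2CaMCaN_cy", "Ca4CaMCaN_cy",
]

assert len(STATE_NAMES) == N_STATE

STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}
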