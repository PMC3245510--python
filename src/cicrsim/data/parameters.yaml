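# Default parameter set for the rat ventricular myocyte voltage-clamp model.
# schema_version 1.  Every entry is [value, unit].  Units are the source units;
# the loader converts to the canonical internal system (mM, nL, pA, ms, mV, nm)
# and records the conversion in ModelParameters.metadata.
schema_version: 1

geometry:
  N_dyad: [10000, ""]                 # number of dyadic coupling units
  V_myo: [5.3581e-2, nL]              # myoplasmic volume
  V_LSR: [1.1776e-3, nL]              # longitudinal SR volume
  V_jSR_total: [1.104e-4, nL]         # total junctional SR volume (all dyads)
  V_cleft: [1.91e-9, nL]              # volume of one dyadic cleft
  d: [400.0, nm]                      # cleft diameter
  h: [15.2, nm]                       # cleft axial length
  dr: [10.0, nm]                      # radial grid step
  dz: [0.76, nm]                      # axial grid step
  A_ExtSL: [11.4e3, um^2]
  A_TT: [5.52e3, um^2]
  A_TotSL: [16.9e3, um^2]
  A_JunctExtSL: [0.846e3, um^2]
  A_JunctTT: [2.54e3, um^2]
  A_TotJunct: [3.39e3, um^2]
  A_JunctSR: [6.99e3, um^2]
  A_LongSR: [36.8e3, um^2]
  A_TotSR: [43.8e3, um^2]

transport:
  F: [96485.0, C/mol]
  R: [8314.0, mJ/mol/K]
  T: [290.0, K]
  Ca_o: [1.0, mM]
  Na_o: [140.0, mM]
  Cs_o: [3.0, mM]
  P_Ca: [6.7367e-9, uL/s]             # L-type channel Ca permeability
  P_Na: [8.0355e-11, uL/s]
  P_Cs: [6.2088e-11, uL/s]
  K_mAllo: [125.0e-6, mM]             # NCX allosteric Ca activation
  K_mCao: [1.14, mM]
  K_mCai: [0.0036, mM]
  K_mNao: [87.5, mM]
  K_mNai: [12.3, mM]
  V_max: [776.2392, pA]               # peak NCX current scale
  k_mpca: [0.5, uM]                   # PMCA half-saturation
  I_PMCA_max: [1.15, pA]
  K_mcs: [1.5e3, uM]                  # Na/Cs pump, extracellular Cs
  K_mna: [2.14e5, uM]                 # Na/Cs pump, intracellular Na
  I_NaCs_max: [147.3, pA]
  G_Nab: [0.00141, nS]
  tau_tr: [7.0e-3, s]                 # LSR -> jSR transfer
  tau_Na: [1.0e-3, s]                 # dyad <-> myo Na relaxation
  tau_Cs: [6.0e-3, s]
  P_ryr: [1.714e-7, uL/s]             # RyR channel permeability
  D_Ca: [100.0, um^2/s]               # cleft Ca diffusion constant
  N_h: [200.0, uM]                    # SL high-affinity binding-site density
  N_l: [16.0, uM]                     # SL low-affinity binding-site density
  K_h: [13.0, uM]
  K_l: [1100.0, uM]
  Mg_myo: [634.0, uM]
  fluo3_tot: [100.0, uM]
  k_fluo3_on: [80.0, 1/uM/s]
  k_fluo3_off: [90.0, 1/s]

serca:
  k12_PLB: [6800.0, 1/s]              # PLB dephosphorylation-state gain
  k21_PLB: [1000.0, 1/s]
  K_cyt_serca: [6250.0, 1/s]          # maximal cytosol<->SERCA rate
  K_serca_sr: [6.25, 1/s]             # maximal SERCA<->LSR rate
  SERCA_tot: [47.0, uM]
  PSR: [1.0, ""]                      # phospholamban:SERCA ratio
  PKA_act: [0.1, ""]                  # fixed relative PKA activity

scaling:
  # Whole-cell L-type scaling (not tabulated).  Calibrated once so the
  # dyadic trigger evoked by the standard +10 mV step peaks at 6.657 pA/pF
  # (the stated stimulus amplitude) with C_m = A_TotSL * 1 uF/cm^2 = 169 pF,
  # equivalently ~0.1 pA per dyadic unit.
  R_CaL: [27.1, ""]
  R_NaCa: [1.0, ""]
  R_NaCs: [1.0, ""]
  f_TT: [0.9, ""]                     # T-tubular fraction of I_CaL / I_NaCa / I_NaCs

cam_rates:       # Ca/CaM binding and CaM buffering
  k02_CM: [4.8387, 1/uM^2/s]
  k20_CM: [10.0, 1/s]
  k24_CM: [3.4722, 1/uM^2/s]
  k42_CM: [500.0, 1/s]
  k0Bon_CM: [3.5e-4, 1/uM/s]
  k0Boff_CM: [1.4e-6, 1/s]
  # derived per table: k02B=k02, k20B=k20/100, k24B=k24, k42B=k42,
  # k2Bon=k4Bon=k0Bon, k2Boff=k4Boff=k0Boff

camkii_rates:    # Ca/CaM/CaMKII interactions
  k_PP1: [1.72, 1/s]
  k_mPP1: [11.5, uM]
  k21_CK: [65.67164, 1/uM/s]
  k12_CK: [328.3582, 1/s]
  k13_CK: [3.4722, 1/uM^2/s]
  k31_CK: [3.35, 1/s]
  k23_CK: [65.67164, 1/uM/s]
  k32_CK: [2.2, 1/s]
  k45_CK: [3.35e-3, 1/s]
  k54_CK: [3.4722, 1/uM^2/s]
  k46_CK: [2.2e-3, 1/s]
  k64_CK: [65.67164, 1/uM/s]
  k56_CK: [328.3582, 1/s]
  k65_CK: [65.67164, 1/uM/s]

can_rates:       # Ca/CaM/CaN interactions
  kCaon_CN: [2.0, 1/uM^2/s]
  kCaoff_CN: [1.0, 1/s]
  k02_CN: [4.8387, 1/uM^2/s]
  k20_CN: [0.0606, 1/s]
  k24_CN: [3.4722, 1/uM^2/s]
  k42_CN: [0.199362, 1/s]
  k0on_CN: [46.0, 1/uM/s]
  k0off_CN: [537.966, 1/s]
  k2on_CN: [46.0, 1/uM/s]
  k2off_CN: [3.2604, 1/s]
  k4on_CN: [46.0, 1/uM/s]
  k4off_CN: [1.3e-3, 1/s]

luminal_sensor:
  k12_ls: [88.16, 1/s]
  k21_ls: [4.1, 1/s]
  k14_ls: [0.5, 1/s]
  k41_ls: [85.7, 1/s]
  k42_ls: [2.98, 1/s]
  k43_ls: [25.5, 1/s]
  k34_ls: [150.3, 1/s]
  k23_ls: [57.9, 1/s]
  k32_ls: [2.42, 1/s]
  k35_ls: [150.3, 1/s]     # tabulated but unused by the printed ODEs
  k53_ls: [25.5, 1/s]      # tabulated but unused by the printed ODEs
  k52_ls: [88.16, 1/s]     # tabulated but unused by the printed ODEs
  k56_ls: [1.2, 1/uM/s]    # Ca binding to calsequestrin (jSR Ca in uM)
  k65_ls: [401.7, 1/s]
  # Losses from the I2 state referenced by the ODEs but never tabulated.
  # Zero makes the packaged initial state a fixed point of the sensor ODEs.
  k24_ls: [0.0, 1/s]
  k25_ls: [0.0, 1/s]

signaling_totals:
  # Total pools of the signaling network; not tabulated in the source data.
  # Placeholder defaults chosen for consistency with the packaged initial
  # state (see docs/methods.md); override from config for sensitivity work.
  CaM_tot: [50.0, uM]          # cytosolic instance
  CaM_tot_dyad: [50.0, uM]     # uniform CaM across myoplasm and dyad
  B_tot: [24.2, uM]
  CaMKII_tot: [4.5, uM]
  CaN_tot: [3.64, uM]
  PP1_tot: [0.57, uM]

numerics:
  dt: [1.0e-3, ms]                    # fixed integration step
  rim_exchange_scale: [1.0, ""]       # scales the cleft-rim Robin coefficient
  conserve_C6: [0, ""]                # add symmetric O3->C6 loss (off = verbatim)
  fura2_tot: [2000.0, uM]             # only used when fura-2 dialysis is enabled
  fura2_kon: [80.0, 1/uM/s]           # implementer-chosen (same scheme as fluo-3)
  fura2_koff: [19.2, 1/s]             # gives Kd = 0.24 uM, typical for fura-2
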