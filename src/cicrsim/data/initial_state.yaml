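# Default initial conditions (resting state at -40 mV holding).
# schema_version 1.  [value, unit]; unit "" marks a dimensionless occupancy.
# The signaling-network block initializes both the dyadic and the cytosolic
# network instance.
schema_version: 1

concentrations:
  Ca_myo: [8.1027e-5, mM]
  Ca_jSR: [1.2677, mM]
  Ca_LSR: [1.3346, mM]
  Na_myo: [16.746, mM]
  Na_dyad: [16.321, mM]
  Cs_myo: [140.2154, mM]
  Cs_dyad: [140.2157, mM]
  Ca_dyad: [9.012e-5, mM]       # uniform over the cleft grid

buffers:
  O_c: [0.033091, ""]
  O_tc: [0.016049, ""]
  O_tmgc: [0.321764, ""]
  O_tmgmg: [0.598385, ""]
  CaF3: [21.88721, uM]

ryr:
  C1: [0.9990953, ""]
  O2: [1.03668e-9, ""]
  C3: [9.38711e-13, ""]

dhpr:
  C1: [0.1673614, ""]
  O2: [1.499173e-3, ""]
  O3: [3.300291e-3, ""]
  C4: [7.478058e-8, ""]
  C6: [7.478058e-8, ""]
  S2: [6.816729e-2, ""]

luminal_sensor:
  A1: [0.6709816, ""]
  I2: [0.155258, ""]
  I3: [0.0623695, ""]
  B6: [0.619346, ""]

serca:
  Ca_serca: [36.0637e-5, uM]
  PLB_dp: [7.684160e-2, ""]

signaling:
  Ca2CaM: [34.56529, uM]
  Ca4CaM: [8.635052e-2, uM]
  CaMB: [7.563836e-2, uM]
  Ca2CaMB: [2.035086, uM]
  Ca4CaMB: [1.288455e-6, uM]
  P1: [5.527608e-1, ""]
  P3: [3.661260e-1, ""]
  P4: [9.121920e-8, ""]
  P5: [6.277911e-7, ""]
  P6: [1.314410e-3, ""]
  Ca4CaN: [2.606246e-4, uM]
  CaMCaN: [4.348535e-3, uM]
  Ca2CaMCaN: [1.419613e-1, uM]
  Ca4CaMCaN: [3.473412, uM]
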