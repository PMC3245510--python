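# Model and methods

`cicrsim` is a deterministic, lumped whole-cell model of calcium-induced
calcium release (CICR) in a rat ventricular myocyte under voltage clamp.
This note records the model structure, the unit conventions, the numerical
schemes, and — because the model was reconstructed from printed equations
and tables with several ambiguities — the places where a reading had to be
chosen and why.

## Compartments and state

The cell is a set of well-mixed fluid compartments — cytosol, longitudinal
SR (LSR, the uptake compartment), junctional SR (jSR, the release
compartment) — plus one *dyadic coupling unit* (DCU) that represents the
lumped behaviour of 10,000 identical dyads.  The DCU couples one lumped
DHP-sensitive L-type channel on the T-tubular membrane to one lumped
Ry-sensitive release channel on the jSR face across a cylindrical cleft
(radius 200 nm, height 15.2 nm) in which Ca²⁺ diffuses as a 2-D
axisymmetric field (20 radial × 20 axial finite-volume cells, Δr = 10 nm,
Δz = 0.76 nm, D = 100 µm²/s).

The ODE state comprises: compartment concentrations (Ca in cytosol, jSR,
LSR; Na and Cs in cytosol and dyad), cytosolic buffers (fluo-3 — and
optionally fura-2 — troponin-Ca, troponin-Mg, calmodulin occupancy), a
6-state Markov L-type channel with a 2-state Ca₄CaM gate (instantiated
twice: a T-tubular copy facing the cleft and a free-sarcolemmal copy facing
the cytosol), a 4-state RyR channel, a 6-state luminal
triadin/calsequestrin sensor whose output `var` biases the RyR rates, SERCA
with a bound-Ca intermediate and phospholamban, and a 14-species
CaM/CaMKII/CaN signalling network instantiated per compartment (dyad and
cytosol).  Membrane transport: GHK fluxes (Ca/Na/Cs) through the open
L-type channels, an allosterically Ca-activated Na/Ca exchanger (NCX;
electrical sign convention: positive = reverse mode = Ca entry), PMCA, a
Na/Cs pump (Cs replaces K in the experimental solutions), and a background
Na current.  90% of the L-type, NCX and Na/Cs transport faces the dyad.

Units: ms, mV, pA, nL, nm; compartment concentrations in mM, signalling
species in µM.  All printed rate constants are converted once at load time
(`parameters.py` records each conversion).

## Numerical scheme

One fixed step (default dt = 1 µs; the packaged experiment harness uses
2 µs for single-beat protocols and 4 µs for trains — halving dt changes the
observables by < 0.5%) advances three sub-systems:

* **Concentrations** by a fixed-step Merson RK4, re-evaluating the
  concentration-dependent fluxes at every stage.
* **Gating and signalling states** by a locally exact exponential update:
  each state's ODE is frozen as dx/dt = a − b·x over the step and solved in
  closed form.  This is required, not cosmetic: the luminal-sensor feedback
  makes several RyR rates of order 10⁵–10⁶ s⁻¹ during the refractory
  period, which no explicit scheme survives at a practical step.
  Occupancy-type states are clamped to [0, 1].
* **The cleft PDE** by a Peaceman–Rachford ADI split (unconditionally
  stable), with the sarcolemmal binding sites entering as a rapid-buffer
  factor β(C) = 1 + Σᵢ NᵢKᵢ/(Kᵢ+C)² scaling ∂C/∂t (the printed product form
  of that term is dimensionally anomalous).  Boundary conditions: no-flux
  at both flat faces and the axis; a Robin exchange with the bulk cytosol
  at the outer rim with velocity g = D/Δr (sub-millisecond equilibration of
  the resting cleft; exposed as `numerics.rim_exchange_scale`).  The DHPR
  trigger enters as a source in the axis voxel at the sarcolemmal face, NCX
  uniformly over that face, and the RyR release **implicitly** as an
  exchange σ·([Ca]_jSR − C) at the jSR-face axis voxel — the open-channel
  coupling constant reaches ~7·10⁵ ms⁻¹ and oscillates violently as an
  explicit source.

Everything is deterministic; identical configurations give bit-identical
output.

## Choices forced by the source material

The printed equations contain transcription defects; each choice below is
also covered by a test where it is checkable.

* **Source-voxel conversion.**  The printed current→concentration factor is
  1000× smaller than Faraday's law in the stated units.  The physical
  1/(2F) conversion is used; it is the only reading that reproduces the
  stated no-release mouth concentration (~23 µM at +10 mV; this model: ~60
  µM).
* **RyR rate readings.**  The closing rate keeps its Ca-dependent dwell
  term (1 + 6/[Ca]) but not the trailing 1/var division, and the activation
  rate's sensor factor enters normalized to its reference value
  (var/100): with the raw factors and physical source coupling the
  *resting* dyad ignites regeneratively.  The recovery/repriming rates
  scale **with** var (2·var s⁻¹) — recovery is gated by luminal refilling,
  which is the stated termination/refractoriness mechanism; the reciprocal
  reading turns the inactivated↔open pair into a closed fast loop and
  produces a smoldering post-release leak instead of a refractory period.
* **Luminal sensor.**  The two loss rates from the I2 state that the ODEs
  reference but no table lists are zero by default — the only value for
  which the packaged initial occupancies are a fixed point of the sensor
  scheme (they are exposed as `luminal_sensor.k24_ls`/`k25_ls`).  jSR Ca
  enters the calsequestrin binding step in µM (verified against the same
  fixed point).  Calsequestrin buffers the jSR balance with 31 mM capacity.
* **SERCA.**  Two-step pump (cytosolic binding at EC50_fwd ≈ 1.6 µM, slow
  luminal release), forward rate per µM² following the Ca²-rate convention
  of the signalling tables.  The printed luminal backward affinity
  (~1.16 mM ≈ the resting SR content itself) would make the pump run net
  backward in every physiological state; it is replaced by a linear
  SR-content leak whose single coefficient is fixed so the packaged rest
  state is exactly flux-neutral.  The pump/PLB regulation is evaluated at
  the packaged (paced) operating point — the active-enzyme concentrations
  implied by the shipped initial state — because the reconstructed
  cytosolic kinase cascade decays within ~1 s of quiescence, which would
  silence uptake and contradict every long-time-scale balance the model is
  supposed to show.  Channel regulation (CDF/CDI, ξ) stays fully dynamic.
* **Initial conditions.**  The shipped state tables are a 4-Hz-pacing
  diastolic snapshot, not a quiescent rest state (their dye and channel
  occupancies are inconsistent with the resting fixed points of their own
  ODEs).  When a run starts from holding, the model therefore equilibrates
  the L-type occupancies to the stationary distribution at the holding
  potential (computed from the frozen generator's nullspace), sets the
  cytosolic buffers and the SERCA load to their fixed points, and relaxes
  the dyadic signalling instance at resting cleft Ca.  This is the default
  and can be disabled (`run(..., equilibrate_dhpr=False)`).
* **Un-tabulated totals.**  CaM_tot = 50 µM in both compartments (the
  model assumes CaM uniformly distributed), B_tot = 24.2 µM,
  CaMKII_tot = 4.5 µM and CaN_tot = 3.64 µM (both chosen so the shipped
  PLB and Ca₄CaN values are fixed points), PP1_tot = 0.57 µM.  All are
  config fields, flagged as placeholders.
* **Scalings.**  R_CaL = 27.1, calibrated once so the dyadic trigger
  evoked by the standard +10 mV step peaks at the stated 6.657 pA/pF
  (C_m = 169 pF from the total sarcolemmal area at 1 µF/cm²), equivalently
  ~0.1 pA per dyad.  R_NaCa = R_NaCs = 1.

## Protocols and observables

`protocols.py` declares the clamp waveforms (piecewise linear, 1 ms
transitions) and the named experiments; `experiments.py` wires them to the
analysis: CICR gain by the flux-ratio criterion (∫ΣiRyR/∫I_CaL,TT over the
release episode, window ending when both fluxes fall below 1% of peak) and
the transient-ratio criterion (baseline-subtracted peak Δ[Ca]_myo, control
vs ryanodine); per-cycle charge integrals with the NCX integral doubled
(one net charge per Ca); refractory periods from a paired-stimulus scan in
which a stored +10 mV trigger waveform is injected directly into the dyad;
inactivation-pathway shares from the time-integrated k24·O2 (Ca pathway)
and k25·O2 (voltage pathway) transition fluxes; sensor ablation by freezing
`var` at its steady 4-Hz cycle average.

Problem sizes used by the packaged reproductions (the full-length protocol
trains are available by passing larger counts): long-pulse balance 4
pulses (of 40), short-pulse staircase 12 pulses (of 40), 4-Hz ablation
train 10 pulses (2.5 s), refractory scan T2 ∈ {50…250} ms in 25 ms steps.

## What the model does and does not reproduce

With the defaults the model rests quietly at −40 mV, triggers graded,
high-gain release on depolarisation (flux-ratio gain ≈ 5.7), terminates
release through the luminal sensor, and recovers over hundreds of ms.
Known quantitative departures from the source behaviours, analysed in the
tests:

* The transient-ratio gain runs high (≈9 vs ≈5.75): the trigger-only
  (ryanodine) transient is small because the pump, held at its paced
  operating strength, collects the slow trigger influx before it peaks.
  Likewise the release leaves the calsequestrin occupancy at ~50% rather
  than ~37%, and the caffeine-evoked transient peaks at ~81 nM rather than
  ~110 nM (fura-2 kinetics are implementer-chosen).
* The Ca-pathway share of free-sarcolemmal L-type inactivation cannot fall
  to ~19%: the printed CaM-gate floor (ks12 ≥ 4·e^(−100/90)) pins S2 ≥
  0.068 and hence the Ca-pathway share ≥ ~79% at +10 mV for *any*
  parameter choice.
* The refractory periods run long (ARP ~200 ms vs 75 ms) because the dyadic
  NCX extrudes a large fraction of each release while the membrane is
  clamped at −40 mV, so full SR recovery needs net external Ca re-entry.
* The long-pulse per-cycle charge (~150 pC vs ~600 pC) reflects deeper
  L-type inactivation over 800 ms than the source's fits; the short-pulse
  train correspondingly lacks the negative staircase (the cell holds its
  Ca balance instead of losing ~40%).
* Sensor ablation at 4 Hz is directionally right but overshoots: freezing
  `var` at its steady end-diastolic 4-Hz level (the reading under which the
  clamped channel loses refractory protection but keeps its diastolic
  sensitisation) depletes diastolic jSR by ~84% rather than ~37%; the
  clamp level is genuinely ambiguous (freezing at the cycle *average*
  instead produces almost no depletion).

These are properties of the reconstruction, documented rather than tuned
away; the acceptance suite asserts the source values and is expected to be
red on the corresponding items.

## Limitations

No action potentials or Na/K currents (voltage-clamp only); one lumped DCU
(no inter-dyad variability or stochastic gating); well-mixed cytosolic
buffers; fura-2 kinetics are implementer-chosen (Kd 0.24 µM, same scheme
as fluo-3); no ATP/ADP energetics.
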