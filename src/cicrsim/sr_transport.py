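"""SERCA uptake with phospholamban/CaMKII/CaN regulation, the SERCA Ca
buffer, and diffusional LSR -> jSR refilling.

The pump is the two-step scheme: fast Ca binding on the cytosolic side
(capacity ``SERCA_tot``, affinity ``EC50_fwd``) followed by slow luminal
release, both scaled by the CaMKII factor (1.07 + 5500*[CaMKII_act]) with the
active-enzyme concentration expressed in mM.  The luminal backward branch of
the printed scheme has an affinity (~1.16 mM) at which the pump would run
net-backward in every physiological state; it is replaced by a linear
SR-content-proportional leak whose single coefficient is fixed so that the
packaged resting state is exactly flux-neutral (see docs/methods.md).

All fluxes in uM/ms referred to the cytosolic volume; rates per ms.
"""

from __future__ import annotations

from .dhpr import njit

# SR leak coefficient (1/ms): K_serca_sr * phi_rest * CaSERCA_rest / Ca_LSR_rest
K_SR_LEAK = 5.42532e-6


@njit(cache=True)
def activity_mm(act_percent, tot_um):
    """Active-enzyme concentration (mM) from a percent-scale activity."""
    return tot_um * (act_percent / 100.0) * 1e-3


@njit(cache=True)
def serca_regulation(ck_mm, plb_dp, psr):
    """(phi, EC50_fwd uM, EC50_bwd uM) for a given CaMKII level (mM) and
    dephosphorylated-PLB fraction."""
    g = 1.0 + 5500.0 * ck_mm
    phi = 0.07 + g
    ec50f = 15.0 * (1.0 + psr * plb_dp) * 1.027 / g
    ec50b = 1250.0 - 1110.0 * psr * plb_dp
    return phi, ec50f, ec50b


@njit(cache=True)
def serca_fluxes(ca_myo_mm, ca_lsr_mm, ca_serca_um, ck_mm, plb_dp,
                 k_cyt, k_sr, serca_tot, psr, thapsigargin):
    """(J_cyt_serca, J_serca_sr) in uM/ms (cytosolic-volume basis).

    J_cyt_serca > 0 loads the pump from the cytosol; J_serca_sr > 0 unloads
    it into the LSR.  ``thapsigargin`` zeroes both.
    """
    if thapsigargin:
        return 0.0, 0.0
    phi, ec50f, _ = serca_regulation(ck_mm, plb_dp, psr)
    ca_um = ca_myo_mm * 1e3
    # forward rate per uM^2 (Ca^2 cooperativity), reverse tied by EC50_fwd
    kf = k_cyt * phi * 1e-3
    kr = kf * ec50f * ec50f
    j_cyt = kf * ca_um * ca_um * (serca_tot - ca_serca_um) - kr * ca_serca_um
    j_sr = k_sr * phi * ca_serca_um - K_SR_LEAK * ca_lsr_mm * 1e3
    return j_cyt, j_sr


@njit(cache=True)
def serca_buffer_derivative(j_cyt_serca, j_serca_sr):
    """d[Ca_serca]/dt (uM/ms)."""
    return j_cyt_serca - j_serca_sr


@njit(cache=True)
def serca_buffer_ab(ca_myo_mm, ca_lsr_mm, ck_mm, plb_dp,
                    k_cyt, k_sr, serca_tot, psr, thapsigargin):
    """Production/loss split (a, b) of the SERCA-bound Ca ODE for the
    exponential update: dCaS/dt = a - b*CaS."""
    if thapsigargin:
        return 0.0, 0.0
    phi, ec50f, _ = serca_regulation(ck_mm, plb_dp, psr)
    ca_um = ca_myo_mm * 1e3
    kf = k_cyt * phi * 1e-3
    a = kf * ca_um * ca_um * serca_tot + K_SR_LEAK * ca_lsr_mm * 1e3
    b = kf * ca_um * ca_um + kf * ec50f * ec50f + k_sr * phi
    return a, b


@njit(cache=True)
def serca_currents(j_cyt, j_sr, faraday, v_myo):
    """(I_cyt_serca, I_serca_sr) in pA for J in uM/ms over the cytosolic
    volume (nL)."""
    conv = 2.0 * faraday * v_myo     # pA per (mM/ms); uM/ms adds 1e-3 * 1e3
    return j_cyt * conv, j_sr * conv


@njit(cache=True)
def plb_derivative(plb_dp, ck_mm, cn_mm, pka_act, k12, k21):
    """dPLB_dp/dt (1/ms); regulation activities as mM concentrations."""
    x = 5500.0 * ck_mm + 2.5 * cn_mm + pka_act
    return k12 * (1.0 - plb_dp) - k21 * x * x * plb_dp


@njit(cache=True)
def plb_ab(ck_mm, cn_mm, pka_act, k12, k21):
    x = 5500.0 * ck_mm + 2.5 * cn_mm + pka_act
    return k12, k12 + k21 * x * x


@njit(cache=True)
def transfer_current(ca_lsr_mm, ca_jsr_mm, tau_tr, v_jsr, faraday):
    """LSR -> jSR refilling current i_tr (pA) of one dyadic unit; positive
    down the concentration gradient (tau_tr in ms, V_jSR per dyad in nL)."""
    return (ca_lsr_mm - ca_jsr_mm) / tau_tr * 2.0 * faraday * v_jsr * 1e3
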