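"""Cytosolic Ca buffers: fluo-3 (and optional fura-2) indicator dye,
calmodulin occupancy, troponin-Ca and the Ca/Mg-competitive troponin site.

Rates per ms, Ca/Mg in uM; occupancies dimensionless, dye complexes in uM.
The weighted occupancy derivative dO/dt (weights 3.2/6.4/1.8 uM) feeds the
cytosolic Ca balance; the experimentally observed transient is the
dye-complex trace, not free Ca.
"""

from __future__ import annotations

import numpy as np

from .dhpr import njit

# association/dissociation constants of the occupancy ODEs (per uM per ms /
# per ms), as printed (1/s scale divided by 1e3)
KC_ON, KC_OFF = 200.0e-3, 476.0e-3       # calmodulin site
KTC_ON, KTC_OFF = 78.4e-3, 392.0e-3      # troponin-Ca site
KTMGC_ON, KTMGC_OFF = 200.0e-3, 6.6e-3   # troponin-Mg site, Ca binding
KTMGMG_ON, KTMGMG_OFF = 2.0e-3, 666.0e-3  # troponin-Mg site, Mg binding

W_TC, W_TMGC, W_C = 3.2, 6.4, 1.8        # uM weights of Eq.-style dO/dt


@njit(cache=True)
def buffer_derivatives(o_c, o_tc, o_tmgc, o_tmgmg, caf3,
                       ca_myo_um, mg_um, f3_tot, f3_on, f3_off):
    """(dO_c, dO_tc, dO_tmgc, dO_tmgmg, dCaF3) per ms."""
    free_tmg = 1.0 - o_tmgc - o_tmgmg
    d_oc = KC_ON * ca_myo_um * (1.0 - o_c) - KC_OFF * o_c
    d_otc = KTC_ON * ca_myo_um * (1.0 - o_tc) - KTC_OFF * o_tc
    d_otmgc = KTMGC_ON * ca_myo_um * free_tmg - KTMGC_OFF * o_tmgc
    d_otmgmg = KTMGMG_ON * mg_um * free_tmg - KTMGMG_OFF * o_tmgmg
    d_caf3 = f3_on * ca_myo_um * (f3_tot - caf3) - f3_off * caf3
    return d_oc, d_otc, d_otmgc, d_otmgmg, d_caf3


@njit(cache=True)
def occupancy_flux_to_balance(d_otc, d_otmgc, d_oc):
    """Weighted buffer-occupancy flux dO/dt (uM/ms) for the Ca balance."""
    return W_TC * d_otc + W_TMGC * d_otmgc + W_C * d_oc


@njit(cache=True)
def buffer_ab(o_tmgc, o_tmgmg, ca_myo_um, mg_um, f3_tot, f3_on, f3_off,
              a, b, base):
    """Production/loss split for the five buffer states, written to a/b at
    ``base`` in state order (O_c, O_tc, O_tmgc, O_tmgmg, CaF3, CaF2-slot
    untouched)."""
    a[base + 0] = KC_ON * ca_myo_um
    b[base + 0] = KC_ON * ca_myo_um + KC_OFF
    a[base + 1] = KTC_ON * ca_myo_um
    b[base + 1] = KTC_ON * ca_myo_um + KTC_OFF
    # competitive sites: the partner occupancy is frozen within the step
    a[base + 2] = KTMGC_ON * ca_myo_um * (1.0 - o_tmgmg)
    b[base + 2] = KTMGC_ON * ca_myo_um + KTMGC_OFF
    a[base + 3] = KTMGMG_ON * mg_um * (1.0 - o_tmgc)
    b[base + 3] = KTMGMG_ON * mg_um + KTMGMG_OFF
    a[base + 4] = f3_on * ca_myo_um * f3_tot
    b[base + 4] = f3_on * ca_myo_um + f3_off


def equilibrium_occupancies(ca_um: float, mg_um: float = 634.0) -> dict:
    """Steady-state occupancies at fixed Ca (uM); reference for tests."""
    oc = ca_um / (ca_um + KC_OFF / KC_ON)
    otc = ca_um / (ca_um + KTC_OFF / KTC_ON)
    rc = KTMGC_ON * ca_um / KTMGC_OFF
    rm = KTMGMG_ON * mg_um / KTMGMG_OFF
    free = 1.0 / (1.0 + rc + rm)
    return {"O_c": oc, "O_tc": otc,
            "O_tmgc": rc * free, "O_tmgmg": rm * free}
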