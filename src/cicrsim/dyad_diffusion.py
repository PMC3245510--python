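"""2-D axisymmetric Ca diffusion in the cylindrical dyadic cleft.

Finite-volume discretization on a cell-centered (r, z) lattice (defaults: 20
radial cells over the 200 nm radius, 20 axial cells over 15.2 nm), advanced
by an unconditionally stable Peaceman-Rachford ADI split so the PDE runs at
the ODE step.  Boundaries: no-flux at both flat faces (sources enter as voxel
terms), zero-flux at the axis by symmetry, and a Robin exchange with the bulk
cytosol at the outer rim (coefficient g = rim_scale * D/dr, giving sub-ms
equilibration of the resting cleft).

Sarcolemmal binding-site buffering enters as the rapid-buffer factor
beta(C) = 1 + Nh*Kh/(Kh+C)^2 + Nl*Kl/(Kl+C)^2 scaling dC/dt (the printed
product form is dimensionally anomalous; see docs/methods.md).

Units: nm, ms, mM; source fields in mM/ms of free Ca.
"""

from __future__ import annotations

import math

import numpy as np

from .dhpr import njit

#: pA per (mM * nm^3 / ms) of divalent flux: 2F * 1e-27 mol * 1e15
_PA_PER_MM_NM3_MS = 2.0 * 96485.0 * 1e-12


@njit(cache=True)
def beta_factor(c_mm, nh, nl, kh, kl):
    """Rapid-buffering factor at free Ca c (mM); site constants in uM."""
    c = c_mm * 1e3
    return (1.0 + nh * kh / ((kh + c) * (kh + c))
            + nl * kl / ((kl + c) * (kl + c)))


@njit(cache=True)
def _thomas(lo, di, up, rhs):
    """In-place tridiagonal solve; returns the solution in rhs."""
    n = rhs.shape[0]
    for i in range(1, n):
        w = lo[i] / di[i - 1]
        di[i] -= w * up[i - 1]
        rhs[i] -= w * rhs[i - 1]
    rhs[n - 1] /= di[n - 1]
    for i in range(n - 2, -1, -1):
        rhs[i] = (rhs[i] - up[i] * rhs[i + 1]) / di[i]
    return rhs


@njit(cache=True)
def adi_step(c, src, beta, dt, d_ca, dr, dz, g_rim, ca_myo,
             ryr_sigma=0.0, ca_jsr=0.0):
    """Advance the grid by one dt.  ``c`` (nr, nz) is updated in place.

    ``src``: free-Ca source field (mM/ms); ``beta``: buffering factor per
    cell (evaluated by the caller, lagged one step); ``g_rim``: rim exchange
    velocity (nm/ms); ``ca_myo``: bulk concentration seen beyond the rim.
    The RyR release enters implicitly as an exchange ryr_sigma*(Ca_jSR - C)
    at the jSR-face axis voxel — the open-channel coupling reaches ~1e6/ms
    and would oscillate violently as an explicit source.
    """
    nr, nz = c.shape
    dt2 = 0.5 * dt
    ar = d_ca / (dr * dr)
    az = d_ca / (dz * dz)
    jryr = nz - 1

    # --- half step 1: implicit in r, explicit in z ---
    cs = np.empty_like(c)
    lo = np.empty(nr); di = np.empty(nr); up = np.empty(nr); rhs = np.empty(nr)
    for j in range(nz):
        for i in range(nr):
            # explicit z part
            lz = 0.0
            if j > 0:
                lz += az * (c[i, j - 1] - c[i, j])
            if j < nz - 1:
                lz += az * (c[i, j + 1] - c[i, j])
            b = beta[i, j]
            rhs[i] = b / dt2 * c[i, j] + lz + src[i, j]
            # implicit r row
            ri = i + 0.5
            wm = ar * i / ri if i > 0 else 0.0
            wp = ar * (i + 1) / ri if i < nr - 1 else 0.0
            lo[i] = -wm
            up[i] = -wp
            di[i] = b / dt2 + wm + wp
            if i == nr - 1:
                wrim = g_rim * nr / (ri * dr)
                di[i] += wrim
                rhs[i] += wrim * ca_myo
            if i == 0 and j == jryr and ryr_sigma > 0.0:
                di[i] += ryr_sigma
                rhs[i] += ryr_sigma * ca_jsr
        sol = _thomas(lo, di, up, rhs)
        for i in range(nr):
            cs[i, j] = sol[i]

    # --- half step 2: implicit in z, explicit in r ---
    lo2 = np.empty(nz); di2 = np.empty(nz); up2 = np.empty(nz)
    rhs2 = np.empty(nz)
    for i in range(nr):
        ri = i + 0.5
        for j in range(nz):
            lr = 0.0
            if i > 0:
                lr += ar * i / ri * (cs[i - 1, j] - cs[i, j])
            if i < nr - 1:
                lr += ar * (i + 1) / ri * (cs[i + 1, j] - cs[i, j])
            if i == nr - 1:
                lr += g_rim * nr / (ri * dr) * (ca_myo - cs[i, j])
            b = beta[i, j]
            rhs2[j] = b / dt2 * cs[i, j] + lr + src[i, j]
            wm = az if j > 0 else 0.0
            wp = az if j < nz - 1 else 0.0
            lo2[j] = -wm
            up2[j] = -wp
            di2[j] = b / dt2 + wm + wp
            if i == 0 and j == jryr and ryr_sigma > 0.0:
                di2[j] += ryr_sigma
                rhs2[j] += ryr_sigma * ca_jsr
        sol = _thomas(lo2, di2, up2, rhs2)
        for j in range(nz):
            c[i, j] = sol[j]
        for j in range(nz):
            if c[i, j] < 0.0:
                c[i, j] = 0.0


@njit(cache=True)
def rim_efflux_current(c, g_rim, ca_myo, dr, dz):
    """Per-dyad Ca efflux through the rim into the cytosol, as a divalent
    current (pA); positive = cleft -> cytosol."""
    nr, nz = c.shape
    radius = nr * dr
    area = 2.0 * math.pi * radius * dz      # nm^2 per rim cell
    total = 0.0
    for j in range(nz):
        total += g_rim * (c[nr - 1, j] - ca_myo) * area
    return total * _PA_PER_MM_NM3_MS


@njit(cache=True)
def mean_concentration(c, dr):
    """Volume-weighted mean cleft Ca (mM)."""
    nr, nz = c.shape
    num = 0.0
    den = 0.0
    for i in range(nr):
        w = i + 0.5
        for j in range(nz):
            num += w * c[i, j]
            den += w
    return num / den


@njit(cache=True)
def face_mean_concentration(c, dr, j):
    """Area-weighted mean Ca (mM) over one flat face row j."""
    nr = c.shape[0]
    num = 0.0
    den = 0.0
    for i in range(nr):
        w = i + 0.5
        num += w * c[i, j]
        den += w
    return num / den


@njit(cache=True)
def total_mass(c, dr, dz):
    """Free Ca content of the cleft in mM*nm^3."""
    nr, nz = c.shape
    out = 0.0
    for i in range(nr):
        vol = math.pi * ((i + 1.0) ** 2 - i ** 2) * dr * dr * dz
        for j in range(nz):
            out += c[i, j] * vol
    return out


def diffusion_rhs(c: np.ndarray, src: np.ndarray, d_ca: float, dr: float,
                  dz: float, g_rim: float, ca_myo: float,
                  nh: float = 0.0, nl: float = 0.0,
                  kh: float = 13.0, kl: float = 1100.0) -> np.ndarray:
    """Explicit dC/dt field (mM/ms): cylindrical Laplacian with the boundary
    conditions of :func:`adi_step`, divided by the rapid-buffer factor.

    Reference form for tests and inspection; the integrator advances the
    same operator implicitly.
    """
    nr, nz = c.shape
    out = np.zeros_like(c)
    ar = d_ca / dr ** 2
    az = d_ca / dz ** 2
    for i in range(nr):
        ri = i + 0.5
        for j in range(nz):
            acc = 0.0
            if i > 0:
                acc += ar * i / ri * (c[i - 1, j] - c[i, j])
            if i < nr - 1:
                acc += ar * (i + 1) / ri * (c[i + 1, j] - c[i, j])
            if i == nr - 1:
                acc += g_rim * nr / (ri * dr) * (ca_myo - c[i, j])
            if j > 0:
                acc += az * (c[i, j - 1] - c[i, j])
            if j < nz - 1:
                acc += az * (c[i, j + 1] - c[i, j])
            out[i, j] = (acc + src[i, j]) / beta_factor(c[i, j], nh, nl,
                                                       kh, kl)
    return out


def make_grid(nr: int, nz: int, c0: float) -> np.ndarray:
    """Uniform initial cleft concentration field (mM)."""
    return np.full((nr, nz), float(c0))


def sample_mouth_concentrations(c: np.ndarray) -> tuple[float, float]:
    """(Ca_dhp, Ca_ryr): axis voxels at the SL face (j=0) and jSR face
    (j=nz-1)."""
    return float(c[0, 0]), float(c[0, -1])


@njit(cache=True)
def source_field(nr: int, nz: int, dr: float, dz: float,
                 i_cal_tt_unit: float, i_naca_tt_unit: float) -> np.ndarray:
    """Free-Ca source field (mM/ms): DHPR into the axis voxel at the SL
    face and NCX spread uniformly over the SL face (the RyR release couples
    implicitly inside :func:`adi_step`).  Inward (negative) electrical
    currents add Ca."""
    src = np.zeros((nr, nz))
    vvox = math.pi * dr * dr * dz
    conv2 = 1e12 / (2.0 * 96485.0)          # mM*nm^3/ms per pA, divalent
    src[0, 0] += -i_cal_tt_unit * conv2 / vvox
    v_face = math.pi * (nr * dr) ** 2 * dz
    # NCX positive = reverse mode = Ca entering the cleft
    src[:, 0] += i_naca_tt_unit * (2.0 * conv2) / v_face
    return src
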