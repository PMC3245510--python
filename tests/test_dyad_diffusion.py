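"""Cleft diffusion solver: conservation, steady states against an
independent direct solve, sampling and rim exchange."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from cicrsim.dyad_diffusion import (adi_step, beta_factor, make_grid,
                                    source_field, sample_mouth_concentrations,
                                    mean_concentration, total_mass,
                                    rim_efflux_current)

NR, NZ, DR, DZ, D = 20, 20, 10.0, 0.76, 1e5


def test_uniform_field_without_sources_stays_uniform():
    c = make_grid(NR, NZ, 1e-4)
    beta = np.ones((NR, NZ))
    src = np.zeros((NR, NZ))
    adi_step(c, src, beta, 1e-3, D, DR, DZ, 0.0, 0.0)
    assert np.allclose(c, 1e-4, rtol=1e-12)


def test_closed_box_mass_conservation():
    """No sources, no rim exchange, no buffering: total free Ca is
    conserved to machine precision over 1e4 steps."""
    rng = np.random.default_rng(1)
    c = 1e-4 * (1.0 + 0.5 * rng.random((NR, NZ)))
    beta = np.ones((NR, NZ))
    src = np.zeros((NR, NZ))
    m0 = total_mass(c, DR, DZ)
    for _ in range(10000):
        adi_step(c, src, beta, 2e-3, D, DR, DZ, 0.0, 0.0)
    assert total_mass(c, DR, DZ) == pytest.approx(m0, rel=1e-8)
    # and the field has homogenized
    assert np.ptp(c) < 1e-12


def _direct_steady(src, g_rim, ca_myo):
    n = NR * NZ

    def idx(i, j):
        return i * NZ + j

    a = sp.lil_matrix((n, n))
    b = np.zeros(n)
    ar, az = D / DR ** 2, D / DZ ** 2
    for i in range(NR):
        ri = i + 0.5
        for j in range(NZ):
            k = idx(i, j)
            diag = 0.0
            if i > 0:
                w = ar * i / ri
                a[k, idx(i - 1, j)] += w
                diag -= w
            if i < NR - 1:
                w = ar * (i + 1) / ri
                a[k, idx(i + 1, j)] += w
                diag -= w
            if i == NR - 1:
                w = g_rim * NR / (ri * DR)
                diag -= w
                b[k] -= w * ca_myo
            if j > 0:
                a[k, idx(i, j - 1)] += az
                diag -= az
            if j < NZ - 1:
                a[k, idx(i, j + 1)] += az
                diag -= az
            a[k, k] += diag
            b[k] -= src[i, j]
    return spla.spsolve(sp.csr_matrix(a), b).reshape(NR, NZ)


def test_point_source_steady_profile_matches_direct_solve():
    """Time-marching the ADI scheme to steady state reproduces the direct
    sparse solve of the same boundary-value problem within 0.1% at the
    sample sites (and 2% everywhere)."""
    g_rim = D / DR
    ca_myo = 1e-4
    src = source_field(NR, NZ, DR, DZ, -0.05, 0.0)
    c = make_grid(NR, NZ, ca_myo)
    beta = np.ones((NR, NZ))
    for _ in range(100000):
        adi_step(c, src, beta, 2e-3, D, DR, DZ, g_rim, ca_myo)
    ref = _direct_steady(src, g_rim, ca_myo)
    ca_dhp, ca_ryr = sample_mouth_concentrations(c)
    assert ca_dhp == pytest.approx(ref[0, 0], rel=1e-3)
    assert ca_ryr == pytest.approx(ref[0, -1], rel=1e-3)
    assert np.max(np.abs(c - ref) / ref) < 0.02


def test_sampling_and_gradient_direction():
    c = make_grid(NR, NZ, 2e-4)
    assert sample_mouth_concentrations(c) == (2e-4, 2e-4)
    # inward trigger current raises the SL-face mouth above the jSR face
    src = source_field(NR, NZ, DR, DZ, -0.1, 0.0)
    beta = np.ones((NR, NZ))
    for _ in range(2000):
        adi_step(c, src, beta, 2e-3, D, DR, DZ, D / DR, 2e-4)
    ca_dhp, ca_ryr = sample_mouth_concentrations(c)
    assert ca_dhp > ca_ryr


def test_rim_flux_zero_at_equilibrium_and_sign():
    c = make_grid(NR, NZ, 1e-4)
    assert rim_efflux_current(c, D / DR, 1e-4, DR, DZ) == 0.0
    assert rim_efflux_current(c, D / DR, 0.5e-4, DR, DZ) > 0.0
    assert rim_efflux_current(c, D / DR, 2e-4, DR, DZ) < 0.0


def test_buffering_factor_slows_but_preserves_steady_state():
    """beta rescales the transient only: the buffered and unbuffered steady
    profiles agree."""
    g_rim = D / DR
    src = source_field(NR, NZ, DR, DZ, -0.02, 0.0)
    c1 = make_grid(NR, NZ, 1e-4)
    c2 = make_grid(NR, NZ, 1e-4)
    b1 = np.ones((NR, NZ))
    for _ in range(60000):
        adi_step(c1, src, b1, 2e-3, D, DR, DZ, g_rim, 1e-4)
    for _ in range(60000):
        b2 = np.empty((NR, NZ))
        for i in range(NR):
            for j in range(NZ):
                b2[i, j] = beta_factor(c2[i, j], 200.0, 16.0, 13.0, 1100.0)
        adi_step(c2, src, b2, 2e-3, D, DR, DZ, g_rim, 1e-4)
    assert np.allclose(c1, c2, rtol=1e-3)


def test_grid_refinement_convergence():
    """Halving both grid steps changes the sampled mouth concentrations of
    a steady point-source problem by < 5%."""
    def steady(nr, nz, dr, dz):
        src = source_field(nr, nz, dr, dz, -0.05, 0.0)
        c = make_grid(nr, nz, 1e-4)
        beta = np.ones((nr, nz))
        for _ in range(120000):
            adi_step(c, src, beta, 1e-3, D, dr, dz, D / dr, 1e-4)
        return c

    c_coarse = steady(NR, NZ, DR, DZ)
    c_fine = steady(2 * NR, 2 * NZ, DR / 2, DZ / 2)
    # compare at matching physical locations away from the singular voxel
    coarse_mid = c_coarse[NR // 2, NZ // 2]
    fine_mid = c_fine[NR, NZ]
    assert fine_mid == pytest.approx(coarse_mid, rel=0.05)
    assert mean_concentration(c_fine, DR / 2) == pytest.approx(
        mean_concentration(c_coarse, DR), rel=0.05)


def test_explicit_rhs_zero_for_uniform_equilibrated_field():
    from cicrsim.dyad_diffusion import diffusion_rhs
    c = make_grid(NR, NZ, 1e-4)
    src = np.zeros((NR, NZ))
    rhs = diffusion_rhs(c, src, D, DR, DZ, D / DR, 1e-4)
    assert np.allclose(rhs, 0.0, atol=1e-18)
    # a source enters divided by the local buffering factor
    src[0, 0] = 1.0
    rhs = diffusion_rhs(c, src, D, DR, DZ, D / DR, 1e-4, nh=200.0, nl=16.0)
    from cicrsim.dyad_diffusion import beta_factor
    assert rhs[0, 0] == 1.0 / beta_factor(1e-4, 200.0, 16.0, 13.0, 1100.0)
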