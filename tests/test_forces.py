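"""Force terms: formulas, oracles, Hermitian symmetry, energy consistency."""

import math

import numpy as np
import pytest

from fsbdmc import (
    SimConfig,
    WallContactError,
    bending_energy,
    bending_force,
    build_grid,
    build_lattice,
    hermitian_deviation,
    linkage_energy,
    linkage_force,
    pressure_force,
    to_fourier,
    to_real,
    total_force,
    wall_force,
    wall_pressure,
)
from conftest import random_hermitian_field


class TestBendingForce:
    def test_zero_field(self, small_grid):
        z = np.zeros((small_grid.N, small_grid.N), dtype=complex)
        assert np.all(bending_force(z, small_grid, 20.0) == 0)

    def test_single_mode_formula(self, small_grid):
        h_q = np.zeros((small_grid.N, small_grid.N), dtype=complex)
        a = 7.0
        h_q[2, 1] = a
        F = bending_force(h_q, small_grid, 20.0)
        q0 = small_grid.q_mag[2, 1]
        assert F[2, 1] == pytest.approx(-20.0 * q0**4 * a)
        F[2, 1] = 0
        assert np.abs(F).max() == 0.0

    def test_zero_mode_contributes_nothing(self, small_grid):
        h_q = np.zeros((small_grid.N, small_grid.N), dtype=complex)
        h_q[0, 0] = 5.0 * small_grid.L**2
        assert np.all(bending_force(h_q, small_grid, 20.0) == 0)

    def test_matches_real_space_biharmonic(self, small_grid, rng):
        """-B grad^4 h applied with a periodic finite-difference stencil."""
        # band-limited random field so FD error is small
        h_q = np.zeros((small_grid.N, small_grid.N), dtype=complex)
        for idx in [(1, 0), (0, 2), (2, 1), (1, 2)]:
            v = rng.standard_normal() + 1j * rng.standard_normal()
            h_q[idx] = v * small_grid.L**2
            h_q[-idx[0], -idx[1]] = np.conj(v) * small_grid.L**2
        B = 20.0
        h = to_real(h_q, small_grid)
        a = small_grid.grid_spacing

        def lap(f):
            return (
                np.roll(f, 1, 0) + np.roll(f, -1, 0)
                + np.roll(f, 1, 1) + np.roll(f, -1, 1) - 4 * f
            ) / a**2

        P = -B * lap(lap(h))
        F_fd = to_fourier(P, small_grid)
        F = bending_force(h_q, small_grid, B)
        nz = np.abs(F) > 1e-6 * np.abs(F).max()
        # 5-point stencil error is O((qa)^2) ~ 5% for the modes kept here
        np.testing.assert_allclose(F_fd[nz], F[nz], rtol=0.06)


class TestLinkageForce:
    @pytest.fixture
    def setup(self, small_grid):
        cfg = SimConfig(L=240.0, alpha_max=12, Delta=20.0, Nb=12,
                        enable_linkage=True)
        lattice = build_lattice(cfg, small_grid)
        return cfg, lattice

    def test_all_open_gives_zero(self, small_grid, setup):
        cfg, lattice = setup
        h = np.full((small_grid.N, small_grid.N), 4.0)
        bonds = np.zeros((12, 12), dtype=np.int8)
        F = linkage_force(h, bonds, 10.0, cfg.h_L, lattice, small_grid)
        assert np.abs(F).max() == 0.0

    def test_zero_extension_gives_zero(self, small_grid, setup):
        cfg, lattice = setup
        h = np.full((small_grid.N, small_grid.N), cfg.h_L)
        bonds = np.ones((12, 12), dtype=np.int8)
        F = linkage_force(h, bonds, 10.0, cfg.h_L, lattice, small_grid)
        assert np.abs(F).max() == 0.0

    def test_point_force_at_origin_has_flat_spectrum(self, small_grid, setup):
        cfg, lattice = setup
        e, k = 2.0, 5.0
        h = np.full((small_grid.N, small_grid.N), cfg.h_L)
        h[0, 0] = cfg.h_L + e
        bonds = np.zeros((12, 12), dtype=np.int8)
        bonds[0, 0] = 1
        F = linkage_force(h, bonds, k, cfg.h_L, lattice, small_grid)
        np.testing.assert_allclose(F, -k * e, atol=1e-12)

    def test_matches_direct_summation(self, small_grid, setup, rng):
        cfg, lattice = setup
        h = rng.standard_normal((small_grid.N, small_grid.N))
        bonds = (rng.random((12, 12)) < 0.3).astype(np.int8)
        k = 7.0
        F = linkage_force(h, bonds, k, cfg.h_L, lattice, small_grid)
        # direct sum over closed bonds: F_q = -sum k (h - h_L) e^{-i q.x_mn}
        x, _ = small_grid.coordinates()
        qx = small_grid.qx
        F_direct = np.zeros_like(F)
        for m in range(12):
            for n in range(12):
                if not bonds[m, n]:
                    continue
                xm, yn = x[lattice.gx[m]], x[lattice.gy[n]]
                amp = -k * (h[lattice.gx[m], lattice.gy[n]] - cfg.h_L)
                F_direct += amp * np.exp(
                    -1j * (qx[:, None] * xm + qx[None, :] * yn)
                )
        np.testing.assert_allclose(F, F_direct, atol=1e-9 * np.abs(F_direct).max())


class TestWallForce:
    def test_truncated_above_h_sub(self, small_grid):
        h = np.full((small_grid.N, small_grid.N), 1.0)  # h > h_sub = 0
        F = wall_force(h, small_grid, sigma_w=4.0, eps_w=0.043)
        assert np.abs(F).max() == 0.0

    def test_uniform_contact_only_zero_mode(self, small_grid):
        h = np.zeros((small_grid.N, small_grid.N))  # h = h_sub exactly
        F = wall_force(h, small_grid, sigma_w=4.0, eps_w=0.043)
        expected = small_grid.L**2 * 8.0 * 0.043 / 4.0
        assert F[0, 0].real == pytest.approx(expected)
        F[0, 0] = 0
        assert np.abs(F).max() < 1e-9 * expected

    def test_pointwise_pressure_value(self):
        # sigma_w = 4 nm, eps_w = 0.043 pN/nm, h - h_sub = -2 nm:
        # 8*(0.043/4)*(4/2)^9 = 0.086 * 512 = 44.032 pN/nm^2
        P = wall_pressure(np.array([[-2.0]]), sigma_w=4.0, eps_w=0.043)
        assert P[0, 0] == pytest.approx(44.032)

    def test_pressure_is_repulsive_everywhere(self, small_grid, rng):
        h = rng.uniform(-2.0, 5.0, (small_grid.N, small_grid.N))
        P = wall_pressure(h, sigma_w=4.0, eps_w=0.043)
        assert np.all(P >= 0.0)

    def test_singularity_aborts(self, small_grid):
        h = np.full((small_grid.N, small_grid.N), 1.0)
        h[3, 4] = -4.0  # at h_sub - sigma_w
        with pytest.raises(WallContactError):
            wall_force(h, small_grid, sigma_w=4.0, eps_w=0.043)


class TestPressureForce:
    def test_zero_pressure(self, small_grid):
        assert np.abs(pressure_force(0.0, 240.0, small_grid)).max() == 0.0

    def test_reference_magnitude(self):
        grid = build_grid(800.0, 40)
        F = pressure_force(4e-5, 800.0, grid)
        assert F[0, 0].real == pytest.approx(-25.6)

    def test_only_zero_mode(self, small_grid):
        F = pressure_force(1e-3, 240.0, small_grid)
        F[0, 0] = 0
        assert np.abs(F).max() == 0.0


class TestTotalForce:
    def test_additivity(self, small_grid, hermitian_field, rng):
        cfg = SimConfig(
            L=240.0, alpha_max=12, Delta=20.0, Nb=12, p=1e-4,
            enable_bending=True, enable_wall=True, enable_linkage=True,
            enable_pressure=True,
        )
        lattice = build_lattice(cfg, small_grid)
        h_q = hermitian_field * 0.02 + 0  # small state
        h = np.asarray(np.real(np.fft.ifft2(h_q)) * (small_grid.N / cfg.L) ** 2)
        bonds = (rng.random((12, 12)) < 0.5).astype(np.int8)
        F = total_force(h_q, h, bonds, cfg, small_grid, lattice)
        F_sum = (
            bending_force(h_q, small_grid, cfg.B)
            + wall_force(h, small_grid, cfg.sigma_w, cfg.eps_w, cfg.h_sub)
            + linkage_force(h, bonds, cfg.k, cfg.h_L, lattice, small_grid)
            + pressure_force(cfg.p, cfg.L, small_grid)
        )
        np.testing.assert_allclose(F, F_sum, rtol=1e-12)

    def test_free_membrane_mode_is_bending_only(self, small_grid, hermitian_field):
        cfg = SimConfig(L=240.0, alpha_max=12)  # only bending enabled
        F = total_force(hermitian_field, None, None, cfg, small_grid)
        np.testing.assert_allclose(
            F, bending_force(hermitian_field, small_grid, cfg.B), rtol=1e-14
        )


class TestHermitianSymmetry:
    def test_all_terms_hermitian(self, small_grid, rng):
        cfg = SimConfig(L=240.0, alpha_max=12, Delta=20.0, Nb=12,
                        enable_linkage=True)
        lattice = build_lattice(cfg, small_grid)
        h_q = random_hermitian_field(small_grid, rng, scale=10.0)
        h = to_real(h_q, small_grid)
        bonds = (rng.random((12, 12)) < 0.5).astype(np.int8)
        for F in (
            bending_force(h_q, small_grid, 20.0),
            wall_force(h - h.max() - 0.5, small_grid, 4.0, 0.043),
            linkage_force(h, bonds, 5.0, -1.2, lattice, small_grid),
            pressure_force(1e-4, 240.0, small_grid),
        ):
            if np.abs(F).max() > 0:
                assert hermitian_deviation(F, small_grid) < 1e-10


class TestEnergyConsistency:
    """F = -dE/dh checked as a directional derivative on random states."""

    def _directional(self, energy, force_q, h, dh, grid):
        eps = 1e-5
        e_plus = energy(h + eps * dh)
        e_minus = energy(h - eps * dh)
        numeric = (e_plus - e_minus) / (2 * eps)
        P = to_real(force_q, grid)  # pressure field (pN/nm^2)
        analytic = -np.sum(P * dh) * grid.grid_spacing**2
        assert numeric == pytest.approx(analytic, rel=1e-5, abs=1e-8)

    def test_bending(self, small_grid, rng):
        B = 20.0
        h_q = random_hermitian_field(small_grid, rng, scale=100.0)
        h = to_real(h_q, small_grid)
        dh = to_real(random_hermitian_field(small_grid, rng), small_grid)
        self._directional(
            lambda hh: bending_energy(to_fourier(hh, small_grid), small_grid, B),
            bending_force(h_q, small_grid, B),
            h, dh, small_grid,
        )

    def test_linkage(self, small_grid, rng):
        cfg = SimConfig(L=240.0, alpha_max=12, Delta=20.0, Nb=12,
                        enable_linkage=True)
        lattice = build_lattice(cfg, small_grid)
        k, h_L = 5.0, -1.2
        h = rng.standard_normal((small_grid.N, small_grid.N))
        dh = rng.standard_normal((small_grid.N, small_grid.N))
        bonds = (rng.random((12, 12)) < 0.5).astype(np.int8)
        self._directional(
            lambda hh: linkage_energy(hh, bonds, k, h_L, lattice),
            linkage_force(h, bonds, k, h_L, lattice, small_grid),
            h, dh, small_grid,
        )
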