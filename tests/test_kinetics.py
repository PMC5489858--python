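"""Receptor lattice and Monte Carlo bond kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsbdmc import (
    SimConfig,
    attempt_binding,
    attempt_unbinding,
    bell_off_rate,
    bond_force,
    build_grid,
    build_lattice,
    equilibrium_constant,
    kinetic_sweep,
    two_state_occupancy,
)


@pytest.fixture
def kin_config():
    return SimConfig(
        L=240.0, alpha_max=12, Delta=20.0, Nb=12, dt=0.5,
        kon0=0.1, koff0=0.02, k=2.0, h_L=-1.2, R_RL=1.0, x_b=1.0,
        enable_linkage=True, enable_kinetics=True,
    )


@pytest.fixture
def kin_lattice(kin_config):
    return build_lattice(kin_config, build_grid(kin_config))


class TestLattice:
    def test_sites_on_collocation_points(self, kin_config, kin_lattice):
        grid = build_grid(kin_config)
        x, _ = grid.coordinates()
        np.testing.assert_allclose(x[kin_lattice.gx], np.arange(12) * 20.0)

    def test_off_grid_spacing_rejected(self):
        cfg = SimConfig(L=240.0, alpha_max=12)
        grid = build_grid(cfg)
        bad = SimConfig(L=240.0, alpha_max=12, Delta=15.0, Nb=4)
        with pytest.raises(ValueError, match="off-grid"):
            build_lattice(bad, grid)

    def test_oversized_lattice_rejected(self):
        cfg = SimConfig(L=240.0, alpha_max=12)
        grid = build_grid(cfg)
        with pytest.raises(ValueError, match="Nb"):
            build_lattice(SimConfig(L=240.0, alpha_max=12, Delta=30.0, Nb=12), grid)


class TestBondForce:
    def test_zero_extension(self):
        assert bond_force(-1.2, k=5.0, h_L=-1.2) == 0.0

    def test_linear_spring(self):
        assert bond_force(0.8, k=1.0, h_L=-1.2) == pytest.approx(2.0)

    def test_compression_carries_no_force(self):
        assert bond_force(-3.0, k=10.0, h_L=-1.2) == 0.0


class TestBellRate:
    def test_zero_force_is_koff0(self):
        assert bell_off_rate(0.0, koff0=1e-4, x_b=1.0, kBT=4.3) == pytest.approx(1e-4)

    def test_one_thermal_unit_multiplies_by_e(self):
        koff = bell_off_rate(4.3, koff0=1e-4, x_b=1.0, kBT=4.3)
        assert koff == pytest.approx(1e-4 * math.e)

    def test_zero_bell_length_is_force_independent(self):
        assert bell_off_rate(500.0, koff0=1e-4, x_b=0.0, kBT=4.3) == pytest.approx(1e-4)

    def test_equilibrium_constant_order_of_magnitude(self):
        # eps_b = 10 kBT -> kon0/koff0 ~ e^10 ~ 2.2e4
        K = equilibrium_constant(10 * 4.3, 4.3)
        assert math.floor(math.log10(K)) == 4


class TestAttempts:
    def test_binding_outside_encounter_distance_never_occurs(self, kin_config, rng):
        bonds = np.zeros((12, 12), dtype=np.int8)
        h_site = kin_config.h_L + 10 * kin_config.R_RL
        for _ in range(200):
            assert not attempt_binding(bonds, (0, 0), h_site, kin_config, rng)
        assert bonds[0, 0] == 0

    def test_binding_probability_one_always_binds(self, kin_config, rng):
        cfg = kin_config.replace(kon0=10.0)  # kon0*dt = 5, clamped to 1
        for _ in range(50):
            bonds = np.zeros((12, 12), dtype=np.int8)
            assert attempt_binding(bonds, (0, 0), cfg.h_L, cfg, rng)

    def test_binding_bernoulli_frequency(self, kin_config):
        cfg = kin_config.replace(kon0=0.1)  # p = 0.05 per attempt
        rng = np.random.default_rng(5)
        n, hits = 20000, 0
        for _ in range(n):
            bonds = np.zeros((12, 12), dtype=np.int8)
            hits += attempt_binding(bonds, (0, 0), cfg.h_L, cfg, rng)
        p = 0.05
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_unbinding_clamp_warns(self, kin_config, rng):
        cfg = kin_config.replace(k=100.0, koff0=0.5)  # koff*dt >> 1
        bonds = np.ones((12, 12), dtype=np.int8)
        with pytest.warns(UserWarning, match="clamped"):
            assert attempt_unbinding(bonds, (0, 0), cfg.h_L + 5.0, cfg, rng)

    def test_attempt_on_wrong_state_raises(self, kin_config, rng):
        bonds = np.zeros((12, 12), dtype=np.int8)
        with pytest.raises(ValueError):
            attempt_unbinding(bonds, (0, 0), 0.0, kin_config, rng)
        bonds[0, 0] = 1
        with pytest.raises(ValueError):
            attempt_binding(bonds, (0, 0), 0.0, kin_config, rng)


class TestSweep:
    def test_zero_rates_leave_state_unchanged(self, kin_config, kin_lattice, rng):
        cfg = kin_config.replace(kon0=0.0, koff0=0.0)
        bonds = (rng.random((12, 12)) < 0.5).astype(np.int8)
        before = bonds.copy()
        nb, nu = kinetic_sweep(bonds, np.zeros((24, 24)) + cfg.h_L, cfg,
                               kin_lattice, rng)
        assert (nb, nu) == (0, 0)
        np.testing.assert_array_equal(bonds, before)

    def test_clamped_off_rate_opens_all_in_one_sweep(self, kin_config, kin_lattice, rng):
        cfg = kin_config.replace(k=1000.0, koff0=10.0, kon0=0.0)
        bonds = np.ones((12, 12), dtype=np.int8)
        h = np.full((24, 24), cfg.h_L + 5.0)  # large tension everywhere
        _, nu = kinetic_sweep(bonds, h, cfg, kin_lattice, rng)
        assert nu == 144
        assert bonds.sum() == 0

    def test_sweep_equals_sequential_row_major_attempts(self, kin_config, kin_lattice):
        """The vectorised sweep reproduces per-site attempts on one stream."""
        h = np.full((24, 24), kin_config.h_L + 0.5)
        h[::3, ::2] = kin_config.h_L + 3.0  # some sites out of encounter range
        rng1 = np.random.default_rng(99)
        rng2 = np.random.default_rng(99)
        bonds1 = np.zeros((12, 12), dtype=np.int8)
        bonds1[::2, ::2] = 1
        bonds2 = bonds1.copy()
        kinetic_sweep(bonds1, h, kin_config, kin_lattice, rng1)
        hs = kin_lattice.site_heights(h)
        for m in range(12):
            for n in range(12):
                if bonds2[m, n]:
                    attempt_unbinding(bonds2, (m, n), hs[m, n], kin_config, rng2)
                else:
                    attempt_binding(bonds2, (m, n), hs[m, n], kin_config, rng2)
        np.testing.assert_array_equal(bonds1, bonds2)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_phi_stays_in_unit_interval(self, seed):
        cfg = SimConfig(
            L=240.0, alpha_max=12, Delta=20.0, Nb=12, dt=0.5,
            kon0=0.5, koff0=0.1, k=2.0, h_L=-1.2, R_RL=1.5,
            enable_linkage=True, enable_kinetics=True,
        )
        lattice = build_lattice(cfg, build_grid(cfg))
        rng = np.random.default_rng(seed)
        bonds = (rng.random((12, 12)) < rng.random()).astype(np.int8)
        h = rng.normal(cfg.h_L, 1.0, (24, 24))
        for _ in range(20):
            kinetic_sweep(bonds, h, cfg, lattice, rng)
            phi = bonds.mean()
            assert 0.0 <= phi <= 1.0
            assert bonds.sum() == np.count_nonzero(bonds == 1)
            assert set(np.unique(bonds)) <= {0, 1}

    def test_fixed_gap_detailed_balance_single_point(self, kin_config, kin_lattice):
        """Stationary phi equals kon0/(kon0 + koff(f)) for a frozen membrane."""
        cfg = kin_config
        gap = 0.5
        h = np.full((24, 24), cfg.h_L + gap)
        rng = np.random.default_rng(11)
        bonds = np.zeros((12, 12), dtype=np.int8)
        burn, n = 2000, 20000
        acc = 0.0
        for i in range(burn + n):
            kinetic_sweep(bonds, h, cfg, kin_lattice, rng)
            if i >= burn:
                acc += bonds.mean()
        phi = acc / n
        koff = bell_off_rate(bond_force(cfg.h_L + gap, cfg.k, cfg.h_L),
                             cfg.koff0, cfg.x_b, cfg.kBT)
        expected = two_state_occupancy(cfg.kon0, koff)
        assert phi == pytest.approx(expected, abs=0.01)
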