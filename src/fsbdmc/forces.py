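"""Deterministic forces on the membrane, assembled in Fourier space.

Four contributions act on the height field:

* bending (Canham-Helfrich), ``F_q^b = -B q^4 h_q``;
* membrane-substrate linkages: each closed receptor-ligand bond is a linear
  spring of stiffness ``k`` anchored at the ligand rest height ``h_L``,
  contributing a point force at its lattice site;
* a soft repulsive wall representing the substrate, a truncated inverse-power
  pressure ``8 (eps_w/sigma_w) (sigma_w/(h + sigma_w - h_sub))^9`` active only
  where ``h <= h_sub`` (pseudo-spectral: evaluated pointwise on the
  collocation grid and transformed);
* a uniform applied pressure ``p`` acting on the zero mode only,
  ``F_0^p = -L^2 p`` (positive p pushes the membrane toward the wall).

All force fields use the same transform convention as the height field:
``F_q = integral_A P(x) exp(-i q.x) dx`` with ``P = -dE/dh`` in pN/nm^2, so
``F_q`` carries units of pN.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import scipy.fft as _fft

from .core import RealField, SimConfig, SpectralField, WavevectorGrid

__all__ = [
    "WallContactError",
    "bending_force",
    "linkage_force",
    "wall_force",
    "wall_pressure",
    "pressure_force",
    "total_force",
    "bending_energy",
    "linkage_energy",
    "wall_energy",
    "pressure_energy",
]

#: Complex (N, N) array of force amplitudes F_q in FFT layout (pN).
ForceField = np.ndarray


class WallContactError(RuntimeError):
    """Membrane reached the wall singularity (h <= h_sub - sigma_w).

    The repulsive pressure diverges there; hitting it means the timestep is
    too large for the chosen wall stiffness (reduce ``dt`` or soften the
    wall by increasing ``sigma_w``).
    """


def bending_force(h_q: SpectralField, grid: WavevectorGrid, B: float) -> ForceField:
    """Helfrich bending restoring force, ``F_q = -B q^4 h_q``."""
    return -B * grid.q4 * h_q


def wall_pressure(
    h: RealField, sigma_w: float, eps_w: float, h_sub: float = 0.0
) -> RealField:
    """Pointwise repulsive wall pressure (pN/nm^2), truncated above ``h_sub``.

    Raises :class:`WallContactError` if the membrane touches or crosses the
    singular plane ``h_sub - sigma_w``.
    """
    g = h + sigma_w - h_sub
    active = h <= h_sub
    if np.any(g[active] <= 0.0):
        i, j = np.unravel_index(np.argmin(g), g.shape)
        raise WallContactError(
            f"membrane height {h[i, j]:.3g} nm at grid point ({i}, {j}) is at "
            f"or below the wall singularity h_sub - sigma_w = {h_sub - sigma_w:.3g} nm"
        )
    P = np.zeros_like(np.asarray(h, dtype=float))
    P[active] = 8.0 * (eps_w / sigma_w) * (sigma_w / g[active]) ** 9
    return P


def wall_force(
    h: RealField,
    grid: WavevectorGrid,
    sigma_w: float,
    eps_w: float,
    h_sub: float = 0.0,
) -> ForceField:
    """Soft-wall repulsion transformed to Fourier space (always upward)."""
    P = wall_pressure(h, sigma_w, eps_w, h_sub)
    return grid.grid_spacing**2 * _fft.fft2(P)


def linkage_force(
    h: RealField,
    bonds: np.ndarray,
    k: float,
    h_L: float,
    lattice,
    grid: WavevectorGrid,
) -> ForceField:
    """Point forces from closed membrane-substrate linkages.

    Each closed bond (``bonds[m, n] == 1``) pulls the membrane toward the
    ligand rest height with force ``-k (h(x_mn) - h_L)``; open bonds do not
    contribute.  In Fourier space,
    ``F_q = -sum_closed k (h(x_mn) - h_L) exp(-i q . x_mn)``,
    which is exactly the DFT of a grid field holding the point forces.
    """
    S = np.zeros((grid.N, grid.N))
    hs = h[np.ix_(lattice.gx, lattice.gy)]
    S[np.ix_(lattice.gx, lattice.gy)] = -k * (hs - h_L) * bonds
    return _fft.fft2(S)


def pressure_force(p: float, L: float, grid: WavevectorGrid) -> ForceField:
    """Uniform applied pressure: zero-mode force ``F_0 = -L^2 p`` only."""
    F = np.zeros((grid.N, grid.N), dtype=complex)
    F[0, 0] = -(L**2) * p
    return F


def total_force(
    h_q: SpectralField,
    h: RealField,
    bonds: Optional[np.ndarray],
    config: SimConfig,
    grid: WavevectorGrid,
    lattice=None,
) -> ForceField:
    """Sum of the enabled force terms for the current membrane state."""
    F = np.zeros((grid.N, grid.N), dtype=complex)
    if config.enable_bending:
        F += bending_force(h_q, grid, config.B)
    if config.enable_wall:
        F += wall_force(h, grid, config.sigma_w, config.eps_w, config.h_sub)
    if config.enable_linkage:
        if bonds is None or lattice is None:
            raise ValueError("linkage force requires bonds and a receptor lattice")
        F += linkage_force(h, bonds, config.k, config.h_L, lattice, grid)
    if config.enable_pressure:
        F += pressure_force(config.p, config.L, grid)
    return F


# -- energies (used for trajectory records and consistency tests) ----------


def bending_energy(h_q: SpectralField, grid: WavevectorGrid, B: float) -> float:
    """E_b = (B/2) integral (laplacian h)^2 dx = (B / 2 L^2) sum_q q^4 |h_q|^2."""
    return float(0.5 * B / grid.L**2 * np.sum(grid.q4 * np.abs(h_q) ** 2))


def linkage_energy(
    h: RealField, bonds: np.ndarray, k: float, h_L: float, lattice
) -> float:
    """Elastic energy stored in closed linkages, sum of (k/2)(h - h_L)^2."""
    hs = h[np.ix_(lattice.gx, lattice.gy)]
    return float(0.5 * k * np.sum(bonds * (hs - h_L) ** 2))


def wall_energy(
    h: RealField,
    grid: WavevectorGrid,
    sigma_w: float,
    eps_w: float,
    h_sub: float = 0.0,
) -> float:
    """Truncated soft-wall energy eps_w * integral (sigma_w/(h+sigma_w-h_sub))^8 dx."""
    g = np.asarray(h, dtype=float) + sigma_w - h_sub
    active = h <= h_sub
    if np.any(g[active] <= 0.0):
        raise WallContactError("membrane at or below the wall singularity")
    e = np.zeros_like(g)
    e[active] = eps_w * (sigma_w / g[active]) ** 8
    return float(np.sum(e) * grid.grid_spacing**2)


def pressure_energy(h_q: SpectralField, p: float, grid: WavevectorGrid) -> float:
    """E_p = p * integral h dx = p * h_0 (work against the applied pressure)."""
    return float(p * h_q[0, 0].real)
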