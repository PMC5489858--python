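"""Fixed-timestep Monte Carlo for receptor-ligand binding and unbinding.

Receptors sit immobile on a uniform ``Nb x Nb`` lattice with spacing
``Delta`` (sites ``x_mn = (m Delta, n Delta)`` coinciding with membrane
collocation points).  Each site carries a binary bond state: 1 (closed) or
0 (open).  Once per dynamics step, every site is visited in fixed row-major
order:

* an open pair may close with probability ``kon0 * dt``, but only while the
  vertical receptor-ligand separation is within the encounter distance,
  ``|h(x_mn) - h_L| <= R_RL``;
* a closed bond opens with probability ``koff * dt`` where
  ``koff = koff0 * exp(f x_b / kBT)`` (Bell's slip-bond law) and
  ``f = k * max(h(x_mn) - h_L, 0)`` is the tensile spring force; a compressed
  bond carries no rupture-accelerating force.

Unbound ligands retract to their rest height instantaneously (the substrate
is rigid compared to the membrane fluctuation timescale), so a reopened site
is immediately available for rebinding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import RealField, SimConfig, WavevectorGrid

__all__ = [
    "ReceptorLattice",
    "build_lattice",
    "bond_force",
    "bell_off_rate",
    "attempt_binding",
    "attempt_unbinding",
    "kinetic_sweep",
    "two_state_occupancy",
    "equilibrium_constant",
    "check_rate_validity",
]

_EXP_CLIP = 700.0  # exp argument cap; beyond this koff*dt clamps to 1 anyway


@dataclass(frozen=True)
class ReceptorLattice:
    """Receptor sites x_mn = (m*Delta, n*Delta) mapped to grid indices."""

    Nb: int
    Delta: float
    gx: np.ndarray  # (Nb,) collocation indices along x
    gy: np.ndarray  # (Nb,)

    @property
    def n_sites(self) -> int:
        return self.Nb**2

    def site_heights(self, h: RealField) -> np.ndarray:
        """Membrane heights at the receptor sites, shape (Nb, Nb)."""
        return h[np.ix_(self.gx, self.gy)]


def build_lattice(config: SimConfig, grid: WavevectorGrid) -> ReceptorLattice:
    """Build the receptor lattice; sites must fall on collocation points."""
    a = grid.grid_spacing
    ratio = config.Delta / a
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"receptor spacing Delta={config.Delta} nm is off-grid "
            f"(collocation spacing {a} nm)"
        )
    if config.Nb * config.Delta > grid.L * (1 + 1e-12):
        raise ValueError("receptor lattice exceeds the box: Nb*Delta > L")
    step = int(round(ratio))
    g = (np.arange(config.Nb) * step) % grid.N
    return ReceptorLattice(Nb=int(config.Nb), Delta=config.Delta, gx=g, gy=g.copy())


def bond_force(h_at_site, k: float, h_L: float):
    """Tensile force on a closed bond, ``f = k * max(h - h_L, 0)`` (pN).

    Only stretching (membrane pulled above the ligand rest height) loads the
    bond; compression leaves a slip bond unloaded.
    """
    return k * np.maximum(np.asarray(h_at_site, dtype=float) - h_L, 0.0)


def bell_off_rate(f, koff0: float, x_b: float, kBT: float):
    """Bell slip-bond unbinding rate ``koff0 * exp(f x_b / kBT)`` (1/ns)."""
    if x_b == 0.0:
        return koff0 * np.ones_like(np.asarray(f, dtype=float))
    return koff0 * np.exp(np.minimum(np.asarray(f, dtype=float) * x_b / kBT, _EXP_CLIP))


def two_state_occupancy(kon: float, koff) -> float:
    """Stationary closed probability of the open<->closed two-state process."""
    return kon / (kon + np.asarray(koff, dtype=float))


def equilibrium_constant(eps_b: float, kBT: float) -> float:
    """Intrinsic equilibrium constant kon0/koff0 ~ exp(eps_b/kBT)."""
    return math.exp(eps_b / kBT)


def check_rate_validity(config: SimConfig, f_max: float = 0.0) -> None:
    """Warn when the first-order MC probabilities per step are not small."""
    p_on = config.kon0 * config.dt
    p_off = float(bell_off_rate(f_max, config.koff0, config.x_b, config.kBT)) * config.dt
    if max(p_on, p_off) >= 0.1:
        warnings.warn(
            f"per-step reaction probability is large (kon0*dt={p_on:.3g}, "
            f"koff*dt={p_off:.3g}); the fixed-timestep MC assumes "
            "first-order kinetics per step",
            stacklevel=2,
        )


def attempt_binding(
    bonds: np.ndarray,
    site: tuple[int, int],
    h_site: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> bool:
    """Try to close one open bond; returns True if a binding event occurred."""
    m, n = site
    if bonds[m, n]:
        raise ValueError("attempt_binding called on a closed bond")
    u = rng.random()  # one draw per site visit, in or out of range
    if abs(h_site - config.h_L) > config.R_RL:
        return False
    if u < min(config.kon0 * config.dt, 1.0):
        bonds[m, n] = 1
        return True
    return False


def attempt_unbinding(
    bonds: np.ndarray,
    site: tuple[int, int],
    h_site: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> bool:
    """Try to open one closed bond; returns True if an unbinding occurred."""
    m, n = site
    if not bonds[m, n]:
        raise ValueError("attempt_unbinding called on an open bond")
    f = bond_force(h_site, config.k, config.h_L)
    p_off = float(bell_off_rate(f, config.koff0, config.x_b, config.kBT)) * config.dt
    if p_off > 1.0:
        warnings.warn("koff*dt > 1 clamped to 1; timestep too large for this bond force",
                      stacklevel=2)
        p_off = 1.0
    if rng.random() < p_off:
        bonds[m, n] = 0
        return True
    return False


def kinetic_sweep(
    bonds: np.ndarray,
    h: RealField,
    config: SimConfig,
    lattice: ReceptorLattice,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """One Monte Carlo pass over every receptor site (in place).

    Visits sites in fixed row-major order, drawing one uniform number per
    site.  All sites are mutually independent within a sweep (each update
    depends only on the frozen membrane heights), so the vectorised update
    below is exactly the sequential row-major sweep.

    Returns ``(n_bind, n_unbind)`` event counts for the sweep.
    """
    hs = lattice.site_heights(h)
    ext = hs - config.h_L
    u = rng.random((lattice.Nb, lattice.Nb))  # row-major draw order
    closed = bonds.astype(bool)

    f = config.k * np.maximum(ext, 0.0)
    p_off = np.minimum(
        bell_off_rate(f, config.koff0, config.x_b, config.kBT) * config.dt, 1.0
    )
    p_on = min(config.kon0 * config.dt, 1.0)

    bind = (~closed) & (np.abs(ext) <= config.R_RL) & (u < p_on)
    unbind = closed & (u < p_off)
    bonds[bind] = 1
    bonds[unbind] = 0
    return int(bind.sum()), int(unbind.sum())
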