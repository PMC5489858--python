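"""Euler-Maruyama integration of the membrane Langevin equation in Fourier space.

Each undulation mode obeys the overdamped equation

    d h_q / dt = Lambda_q [ F_q(t) + zeta_q(t) ]

with the Oseen-level hydrodynamic mobility ``Lambda_q = 1/(4 eta q)`` and
Gaussian thermal noise of covariance
``<zeta_q zeta_q'*> = 2 kBT L^2 Lambda_q^-1 delta_qq' delta(t-t')``, so that
the increment of ``h_q`` over a step has variance ``2 kBT L^2 Lambda_q dt``
(summed over real and imaginary parts, with conjugate pairs mirrored).

The q = 0 mode needs care: its mobility formally diverges, and it carries no
restoring bending force.  We regularise ``Lambda_0 = 1/(4 eta q_min)`` with
``q_min = 2 pi / L`` (the box size cuts off the hydrodynamic self-mobility)
and give the centre of mass a purely deterministic, force-driven drift — no
thermal kick — so that the mean height responds to the wall and applied
pressure but does not random-walk.

Noise draws are Hermitian by construction: an i.i.d. complex Gaussian array
``G`` is projected as ``(G + conj(G(-q)))/sqrt(2)``, which leaves unit
variance per mode (self-conjugate modes come out purely real with the same
total variance) and guarantees a real height field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    RealField,
    SimConfig,
    SpectralField,
    WavevectorGrid,
    build_grid,
)
from .forces import bending_energy
from .kinetics import ReceptorLattice, build_lattice, check_rate_validity

__all__ = [
    "SimulationError",
    "TrajectoryRecord",
    "mobility_spectrum",
    "noise_rms",
    "draw_noise",
    "step",
    "thermal_state",
    "flat_state",
    "run",
]

logger = logging.getLogger("fsbdmc")

_NOISE_CHUNK = 256  # steps of pre-generated noise per batch


class SimulationError(RuntimeError):
    """Integration failure; carries the partial trajectory for post-mortem."""

    def __init__(self, message: str, record: Optional["TrajectoryRecord"] = None):
        super().__init__(message)
        self.record = record


def mobility_spectrum(grid: WavevectorGrid, eta: float) -> np.ndarray:
    """Per-mode mobility Lambda_q = 1/(4 eta q), q=0 regularised at q_min."""
    q = grid.q_mag.copy()
    q[0, 0] = grid.q_min
    return 1.0 / (4.0 * eta * q)


def noise_rms(
    grid: WavevectorGrid, mobility: np.ndarray, kBT: float, dt: float
) -> np.ndarray:
    """Per-mode RMS of the h_q increment, sqrt(2 kBT L^2 Lambda_q dt).

    The zero mode gets no thermal kick (see module docstring).
    """
    s = np.sqrt(2.0 * kBT * grid.L**2 * mobility * dt)
    s[0, 0] = 0.0
    return s


class HermitianNoise:
    """Scaled Hermitian Gaussian mode increments, drawn with exact d.o.f.

    A real height field has exactly ``N^2`` independent Gaussian degrees of
    freedom: one real amplitude for each self-conjugate mode (both index
    components 0 or Nyquist) and a complex amplitude for one representative
    of every conjugate pair.  The builder precomputes the pair structure and
    scatters a flat block of standard normals into a Hermitian (N, N) array
    scaled by the per-mode RMS ``s`` (conjugate-symmetric itself), giving
    ``<|xi_q|^2> = s_q^2`` for every mode with pairs exactly mirrored.
    """

    def __init__(self, grid: WavevectorGrid, s: np.ndarray):
        N = grid.N
        flat = np.arange(N * N)
        partner = (grid.conj_index[flat // N] * N + grid.conj_index[flat % N])
        self._self_idx = flat[partner == flat]
        self._rep_idx = flat[flat < partner]
        self._conj_idx = partner[flat < partner]
        s_flat = np.asarray(s, dtype=float).ravel()
        self._s_self = s_flat[self._self_idx]
        self._s_rep = s_flat[self._rep_idx] * np.sqrt(0.5)
        self._N = N
        self._n_dof = len(self._self_idx) + 2 * len(self._rep_idx)

    def sample(
        self,
        rng: np.random.Generator,
        n: Optional[int] = None,
        out: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        squeeze = n is None
        n = 1 if squeeze else n
        z = rng.standard_normal((n, self._n_dof))
        ns, npair = len(self._self_idx), len(self._rep_idx)
        if out is None:
            out = np.zeros((n, self._N * self._N), dtype=complex)
        else:
            out = out.reshape(n, self._N * self._N)
        out[:, self._self_idx] = self._s_self * z[:, :ns]
        a = self._s_rep * (z[:, ns:ns + npair] + 1j * z[:, ns + npair:])
        out[:, self._rep_idx] = a
        out[:, self._conj_idx] = np.conj(a)
        out = out.reshape(n, self._N, self._N)
        return out[0] if squeeze else out


def draw_noise(
    rng: np.random.Generator,
    grid: WavevectorGrid,
    s: np.ndarray,
    n: Optional[int] = None,
) -> np.ndarray:
    """Draw Hermitian noise increment(s) xi_q with per-mode RMS ``s``."""
    return HermitianNoise(grid, s).sample(rng, n)


def _hermitian_unit_noise(
    rng: np.random.Generator, grid: WavevectorGrid, n: Optional[int] = None
) -> np.ndarray:
    """Hermitian complex Gaussian array(s) with unit variance per mode."""
    return HermitianNoise(grid, np.ones((grid.N, grid.N))).sample(rng, n)


def step(
    h_q: SpectralField,
    F_q: np.ndarray,
    mobility: np.ndarray,
    config: SimConfig,
    grid: WavevectorGrid,
    rng: np.random.Generator,
) -> SpectralField:
    """One explicit Euler-Maruyama update of the mode amplitudes.

    ``h_q(t+dt) = h_q(t) + dt * Lambda_q * F_q + xi_q`` with the thermal
    increment variance stated in the module docstring.  Raises
    :class:`SimulationError` naming the offending mode if the state leaves
    the finite range.
    """
    s = noise_rms(grid, mobility, config.kBT, config.dt)
    out = h_q + config.dt * mobility * F_q + draw_noise(rng, grid, s)
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))[0]
        raise SimulationError(
            f"non-finite amplitude at mode (alpha, beta) index {tuple(bad)}; "
            "the timestep is too large for the acting forces"
        )
    return out


def thermal_state(
    config: SimConfig, grid: WavevectorGrid, rng: np.random.Generator
) -> SpectralField:
    """Draw h_q from the free-membrane equilibrium, <|h_q|^2> = kBT L^2/(B q^4).

    The zero mode is set to ``config.h_init`` (or 0) times L^2.
    """
    amp = np.zeros((grid.N, grid.N))
    nz = grid.q_mag > 0
    amp[nz] = np.sqrt(config.kBT * grid.L**2 / (config.B * grid.q4[nz]))
    h_q = amp * _hermitian_unit_noise(rng, grid)
    h_q[0, 0] = (config.h_init or 0.0) * grid.L**2
    return h_q


def flat_state(config: SimConfig, grid: WavevectorGrid, height: float) -> SpectralField:
    """Uniform membrane at the given height: only the zero mode is set."""
    h_q = np.zeros((grid.N, grid.N), dtype=complex)
    h_q[0, 0] = height * grid.L**2
    return h_q


@dataclass
class TrajectoryRecord:
    """Sampled observables of one simulation run.

    Columns follow the trajectory-table contract: time (ns), mean and RMS
    height (nm), closed bond ratio phi, closed bond count, bending and
    linkage energies (pN*nm).  ``spectrum_power`` optionally holds per-sample
    |h_q|^2 fields for spectrum estimation.
    """

    config: SimConfig
    time: np.ndarray
    mean_height: np.ndarray
    rms_height: np.ndarray
    phi: np.ndarray
    n_closed: np.ndarray
    E_bend: np.ndarray
    E_link: np.ndarray
    n_bind_events: int
    n_unbind_events: int
    final_h_q: SpectralField
    final_bonds: Optional[np.ndarray]
    grid: WavevectorGrid = field(repr=False)
    spectrum_power: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def sample_interval(self) -> float:
        """Time between recorded samples (ns)."""
        return self.config.sample_stride * self.config.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.time,
                "mean_height_nm": self.mean_height,
                "rms_height_nm": self.rms_height,
                "phi": self.phi,
                "n_closed": self.n_closed,
                "E_bend": self.E_bend,
                "E_link": self.E_link,
            }
        )

    def save(self, path) -> None:
        """Write the trajectory as TSV with the full config as '#' header."""
        with open(path, "w") as fh:
            fh.write("\n".join(self.config.header_comments()) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def run(
    config: SimConfig,
    initial_state: Optional[SpectralField] = None,
    initial_bonds: Optional[np.ndarray] = None,
    callbacks: Sequence[Callable] = (),
    record_spectrum: bool = False,
    log_interval: Optional[int] = None,
) -> TrajectoryRecord:
    """Integrate the membrane (and optionally the bond kinetics) forward.

    Runs ``t_total/dt`` steps from the configured or supplied initial state,
    sampling observables every ``config.sample_stride`` steps.  The run is a
    pure function of ``(config, initial conditions)``: the seed feeds one
    deterministic random stream split between membrane noise and Monte Carlo
    kinetics, so identical inputs give bit-identical trajectories.

    ``callbacks`` are invoked at every sample with
    ``(step_index, time, h_q, h, bonds)``.

    The kinetic sweep runs once at the end of each dynamics step, on the
    freshly updated membrane heights.
    """
    grid = build_grid(config)
    N, L, dt = grid.N, config.L, config.dt
    dyn_ss, kin_ss = np.random.SeedSequence(config.seed).spawn(2)
    dyn_rng = np.random.Generator(np.random.SFC64(dyn_ss))
    kin_rng = np.random.Generator(np.random.SFC64(kin_ss))

    use_wall = config.enable_wall
    use_link = config.enable_linkage
    use_kin = config.enable_kinetics
    need_real = use_wall or use_link or use_kin

    lattice: Optional[ReceptorLattice] = None
    bonds: Optional[np.ndarray] = None
    if use_link or use_kin:
        lattice = build_lattice(config, grid)
        bonds = (
            np.zeros((lattice.Nb, lattice.Nb), dtype=np.int8)
            if initial_bonds is None
            else np.array(initial_bonds, dtype=np.int8)
        )
        if bonds.shape != (lattice.Nb, lattice.Nb):
            raise ValueError("initial bond state does not match the receptor lattice")
    if use_kin:
        check_rate_validity(config)

    if initial_state is not None:
        h_q = np.array(initial_state, dtype=complex)
    elif config.h_init is not None:
        h_q = flat_state(config, grid, config.h_init)
    elif use_link or use_wall or use_kin:
        h_q = flat_state(config, grid, config.h_L + config.R_RL)
    else:
        h_q = thermal_state(config, grid, dyn_rng)

    mobility = mobility_spectrum(grid, config.eta)
    dt_lam = dt * mobility
    s_noise = noise_rms(grid, mobility, config.kBT, dt)
    noise = HermitianNoise(grid, s_noise)
    bend_coef = -config.B * grid.q4 if config.enable_bending else None
    F_press = -(L**2) * config.p if config.enable_pressure else 0.0
    a2 = grid.grid_spacing**2  # collocation cell area
    inv_a2_over_L2 = (N / L) ** 2
    wall_pref = 8.0 * config.eps_w / config.sigma_w if use_wall else 0.0
    lat_ix = np.ix_(lattice.gx, lattice.gy) if lattice is not None else None

    # Per-step transforms as cached-DFT-matrix products: at these grid sizes
    # two small matmuls beat the FFT call overhead, and agree with the FFT
    # to rounding error.
    _w = np.exp(-2j * np.pi * np.outer(np.arange(N), np.arange(N)) / N)
    _wi = np.conj(_w) / N

    def ifft2(a):
        return _wi @ (a @ _wi)

    def fft2(a):
        return _w @ (a @ _w)

    n_steps = config.n_steps
    stride = config.sample_stride
    noiseless = config.kBT == 0.0

    t_list: list = []
    obs: dict[str, list] = {k: [] for k in
                            ("mean", "rms", "phi", "ncl", "eb", "el")}
    spec_samples: list = []
    n_bind = n_unbind = 0
    clamp_warned = False

    def sample(i: int, h: Optional[np.ndarray]) -> None:
        nonlocal clamp_warned
        if h is None:
            h = inv_a2_over_L2 * ifft2(h_q).real
        mean_h = float(h_q[0, 0].real) / L**2
        if not np.isfinite(mean_h):
            raise SimulationError(
                f"non-finite membrane state at step {i}",
                _make_record(i),
            )
        t_list.append(i * dt)
        obs["mean"].append(mean_h)
        obs["rms"].append(float(np.sqrt(np.mean(h * h))))
        if bonds is not None:
            obs["phi"].append(float(bonds.mean()))
            obs["ncl"].append(int(bonds.sum()))
            ext = h[lat_ix] - config.h_L
            obs["el"].append(float(0.5 * config.k * np.sum(bonds * ext * ext)))
        else:
            obs["phi"].append(0.0)
            obs["ncl"].append(0)
            obs["el"].append(0.0)
        obs["eb"].append(bending_energy(h_q, grid, config.B))
        if record_spectrum:
            spec_samples.append(np.abs(h_q) ** 2)
        for cb in callbacks:
            cb(i, i * dt, h_q, h, bonds)

    def _make_record(upto_step: int) -> "TrajectoryRecord":
        return TrajectoryRecord(
            config=config,
            time=np.asarray(t_list),
            mean_height=np.asarray(obs["mean"]),
            rms_height=np.asarray(obs["rms"]),
            phi=np.asarray(obs["phi"]),
            n_closed=np.asarray(obs["ncl"], dtype=int),
            E_bend=np.asarray(obs["eb"]),
            E_link=np.asarray(obs["el"]),
            n_bind_events=n_bind,
            n_unbind_events=n_unbind,
            final_h_q=h_q,
            final_bonds=None if bonds is None else bonds.copy(),
            grid=grid,
            spectrum_power=np.asarray(spec_samples) if spec_samples else None,
        )

    xi = None
    j = _NOISE_CHUNK  # force a draw on the first step
    for i in range(n_steps):
        h = inv_a2_over_L2 * ifft2(h_q).real if need_real else None

        # kinetics for the *previous* step act on the freshly updated heights
        if use_kin and i > 0:
            nb, nu, clamped = _sweep_inline(bonds, h, config, lat_ix, kin_rng)
            if clamped and not clamp_warned:
                logger.warning("koff*dt > 1 clamped to 1 (stiff bond force)")
                clamp_warned = True
            n_bind += nb
            n_unbind += nu

        if i % stride == 0:
            sample(i, h)
        if log_interval and i % log_interval == 0 and i:
            logger.info("step %d / %d (t = %.4g ns)", i, n_steps, i * dt)

        # assemble forces
        F = bend_coef * h_q if bend_coef is not None else 0.0
        if use_wall or use_link:
            if use_wall:
                g = h + config.sigma_w - config.h_sub
                if g.min() <= 0.0:
                    raise SimulationError(
                        f"membrane crossed the wall singularity at step {i} "
                        "(reduce dt or increase sigma_w)",
                        _make_record(i),
                    )
                S = np.where(
                    h <= config.h_sub,
                    (a2 * wall_pref) * (config.sigma_w / g) ** 9,
                    0.0,
                )
            else:
                S = np.zeros((N, N))
            if use_link:
                S[lat_ix] += -config.k * (h[lat_ix] - config.h_L) * bonds
            F = F + fft2(S)

        if noiseless:
            h_q = h_q + dt_lam * F
            if config.enable_pressure:
                h_q[0, 0] += dt_lam[0, 0] * F_press
        else:
            if j >= _NOISE_CHUNK:
                xi = noise.sample(dyn_rng, _NOISE_CHUNK, out=xi)
                j = 0
            if config.enable_pressure:
                h_q = h_q + dt_lam * F + xi[j]
                h_q[0, 0] += dt_lam[0, 0] * F_press
            else:
                h_q = h_q + dt_lam * F + xi[j]
            j += 1

    # close out: final heights, final kinetic sweep, final sample
    h = inv_a2_over_L2 * ifft2(h_q).real if need_real else None
    if use_kin and n_steps > 0:
        nb, nu, _ = _sweep_inline(bonds, h, config, lat_ix, kin_rng)
        n_bind += nb
        n_unbind += nu
    if n_steps % stride == 0:
        sample(n_steps, h)

    return _make_record(n_steps)


def _sweep_inline(bonds, h, config, lat_ix, rng):
    """Vectorised kinetic sweep used by the hot loop.

    Equivalent to :func:`fsbdmc.kinetics.kinetic_sweep` (row-major site
    order, one uniform draw per site); additionally reports whether a
    ``koff*dt`` clamp occurred so the caller can log it once.
    """
    hs = h[lat_ix]
    ext = hs - config.h_L
    u = rng.random(hs.shape)
    closed = bonds.astype(bool)
    f = config.k * np.maximum(ext, 0.0)
    arg = np.minimum(f * config.x_b / config.kBT, 700.0)
    p_off_raw = config.koff0 * np.exp(arg) * config.dt
    clamped = bool(np.any(p_off_raw[closed] > 1.0)) if closed.any() else False
    p_off = np.minimum(p_off_raw, 1.0)
    bind = (~closed) & (np.abs(ext) <= config.R_RL) & (u < min(config.kon0 * config.dt, 1.0))
    unbind = closed & (u < p_off)
    bonds[bind] = 1
    bonds[unbind] = 0
    return int(bind.sum()), int(unbind.sum()), clamped
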