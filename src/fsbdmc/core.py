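"""Parameters, wavevector grids, and real/Fourier membrane fields.

The membrane is described in the Monge gauge by a height field ``h(x)`` over
a periodic square box of side ``L``, represented either on an ``N x N``
collocation grid (a :data:`RealField`, nm) or by complex mode amplitudes
``h_q`` (a :data:`SpectralField`).  The transform pair follows the continuum
convention

    h_q  = integral_A h(x) exp(-i q.x) dx      (nm^3)
    h(x) = L^-2 sum_q h_q exp(+i q.x)          (nm)

discretised as ``h_q = (L/N)^2 * FFT2(h)`` and ``h = (N/L)^2 * IFFT2(h_q)``,
so that closed-form mode expressions (bending force, noise covariance) carry
their ``L^2`` factors verbatim.

Unit system (fixed throughout the package): lengths in nm, times in ns,
forces in pN, energies in pN*nm.  Viscosities are stored in pN*ns/nm^2;
1 Poise = 100 pN*ns/nm^2 (1 Pa*s = 1e3 pN*ns/nm^2), so water-like
0.06 Poise is ``eta = 6``.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import scipy.fft as _fft

__all__ = [
    "POISE",
    "SimConfig",
    "WavevectorGrid",
    "UnknownConfigKeyError",
    "build_grid",
    "to_real",
    "to_fourier",
    "hermitize",
    "hermitian_deviation",
]

#: Conversion factor: viscosity in Poise -> pN*ns/nm^2.
POISE = 100.0

#: A complex (N, N) array of mode amplitudes h_q in FFT layout (nm^3).
SpectralField = np.ndarray

#: A real (N, N) array of membrane heights h(x) on the collocation grid (nm).
RealField = np.ndarray


class UnknownConfigKeyError(ValueError):
    """Raised when a config file or CLI override names a non-existent key."""

    def __init__(self, key: str):
        self.key = key
        super().__init__(f"unknown configuration key: {key!r}")


@dataclass
class SimConfig:
    """All physical, numerical and kinetic parameters of a simulation.

    Defaults reproduce the reference free-membrane / adhesion conditions
    (square box of 800 nm, bending rigidity 20 pN*nm ~ 5 kBT at
    kBT = 4.3 pN*nm, water-like viscosity, 0.5 ns timestep).

    Parameters
    ----------
    L : float
        Box side length (nm).  The membrane is periodic in both directions.
    alpha_max : int
        Mode cutoff: integer wavenumbers run up to ``alpha_max`` per axis,
        giving wavelength cutoffs ``lambda_min = L/alpha_max`` and
        ``lambda_max = L`` on an ``N = 2*alpha_max`` collocation grid.
    B : float
        Bending rigidity (pN*nm).
    eta : float
        Viscosity of the surrounding fluid (pN*ns/nm^2; multiply Poise
        by :data:`POISE`).
    kBT : float
        Thermal energy (pN*nm).  May be 0 for deterministic relaxation runs.
    dt : float
        Integration timestep (ns).
    t_total : float
        Total simulated time (ns).
    seed : int
        Seed for the single pseudo-random stream of the run.
    sigma_w, eps_w, h_sub : float
        Soft-wall repulsion length scale (nm), strength (pN/nm, i.e. energy
        per area) and truncation height (nm; the wall is inactive for
        ``h > h_sub``).
    k : float
        Membrane-substrate linkage (MSL) spring constant (pN/nm), lumping
        bilayer shear stiffness, receptor-ligand complex stiffness and
        substrate elasticity.
    h_L : float
        Height of the rest (unbound) ligand tips (nm).
    Delta : float
        Receptor lattice spacing (nm); must be a multiple of the collocation
        spacing ``L/N`` so receptors sit exactly on grid points.
    Nb : int
        Receptors per side; total receptor count is ``Nb**2`` and the lattice
        must fit in the box (``Nb*Delta <= L``).
    R_RL : float
        Encounter distance (nm): an open pair can react only while
        ``|h(x_mn) - h_L| <= R_RL``.
    kon0, koff0 : float
        Intrinsic binding rate and zero-force unbinding rate (1/ns).
    x_b : float
        Bell length (nm) governing force-accelerated unbinding,
        ``koff = koff0*exp(f*x_b/kBT)``.
    p : float
        Uniform applied pressure (pN/nm^2); positive pushes the membrane
        down toward the wall.
    enable_bending, enable_wall, enable_linkage, enable_pressure,
    enable_kinetics : bool
        Force/kinetics term toggles (the validation experiments switch
        subsets on).
    h_init : float or None
        Initial flat membrane height (nm).  ``None`` selects a thermal
        equilibrium draw for free-membrane runs and ``h_L + R_RL``
        (binding can nucleate) when the linkage is enabled.
    sample_stride : int
        Observable sampling interval in steps.
    discard_fraction : float
        Leading fraction of each trajectory discarded as equilibration when
        averaging observables.
    """

    L: float = 800.0
    alpha_max: int = 40
    B: float = 20.0
    eta: float = 0.06 * POISE
    kBT: float = 4.3
    dt: float = 0.5
    t_total: float = 1e5
    seed: int = 0
    sigma_w: float = 4.0
    eps_w: float = 0.043
    h_sub: float = 0.0
    k: float = 10.0
    h_L: float = -1.2
    Delta: float = 20.0
    Nb: int = 40
    R_RL: float = 1.0
    kon0: float = 1.0
    koff0: float = 1e-4
    x_b: float = 1.0
    p: float = 0.0
    enable_bending: bool = True
    enable_wall: bool = False
    enable_linkage: bool = False
    enable_pressure: bool = False
    enable_kinetics: bool = False
    h_init: Optional[float] = None
    sample_stride: int = 100
    discard_fraction: float = 0.2

    # -- derived quantities -------------------------------------------------

    @property
    def N(self) -> int:
        """Collocation points per side (= 2*alpha_max)."""
        return 2 * int(self.alpha_max)

    @property
    def grid_spacing(self) -> float:
        """Collocation spacing L/N (nm)."""
        return self.L / self.N

    @property
    def lambda_min(self) -> float:
        """Shortest represented wavelength L/alpha_max (nm)."""
        return self.L / self.alpha_max

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if int(self.alpha_max) != self.alpha_max or self.alpha_max < 1:
            raise ValueError("alpha_max must be a positive integer")
        if self.alpha_max % 2:
            raise ValueError("alpha_max must be even (odd cutoffs are rejected)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.B <= 0 or self.eta <= 0:
            raise ValueError("B and eta must be positive")
        if self.kBT < 0:
            raise ValueError("kBT must be non-negative")
        if min(self.kon0, self.koff0) < 0:
            raise ValueError("rates must be non-negative")
        if self.sigma_w <= 0 or self.eps_w < 0:
            raise ValueError("sigma_w must be positive and eps_w non-negative")
        if self.t_total < 0:
            raise ValueError("t_total must be non-negative")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")
        if not 0.0 <= self.discard_fraction < 1.0:
            raise ValueError("discard_fraction must be in [0, 1)")
        if self.enable_linkage or self.enable_kinetics:
            a = self.grid_spacing
            ratio = self.Delta / a
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"Delta={self.Delta} is not a multiple of the grid "
                    f"spacing L/N={a}; receptors must sit on collocation points"
                )
            if self.Nb < 1:
                raise ValueError("Nb must be >= 1")
            if self.Nb * self.Delta > self.L * (1 + 1e-12):
                raise ValueError("receptor lattice exceeds the box: Nb*Delta > L")

    def replace(self, **changes) -> "SimConfig":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- flat key=value config files ---------------------------------------

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def _coerce(cls, name: str, raw: str):
        hints = {f.name: f.type for f in dataclasses.fields(cls)}
        if name not in hints:
            raise UnknownConfigKeyError(name)
        raw = raw.strip()
        if name == "h_init":
            return None if raw.lower() in ("none", "") else float(raw)
        if name in ("alpha_max", "Nb", "seed", "sample_stride"):
            return int(raw)
        if name.startswith("enable_"):
            if raw.lower() in ("1", "true", "yes", "on"):
                return True
            if raw.lower() in ("0", "false", "no", "off"):
                return False
            raise ValueError(f"cannot parse boolean value {raw!r} for key {name!r}")
        return float(raw)

    @classmethod
    def from_file(cls, path: Union[str, Path], overrides: Optional[dict] = None) -> "SimConfig":
        """Read a flat ``key = value`` text file ('#' starts a comment)."""
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = (s.strip() for s in line.split("=", 1))
            values[key] = cls._coerce(key, raw)
        for key, raw in (overrides or {}).items():
            values[key] = cls._coerce(key, raw) if isinstance(raw, str) else raw
        return cls(**values)

    def to_file(self, path: Union[str, Path]) -> None:
        lines = ["# fsbdmc configuration (units: nm, ns, pN, pN*nm)"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    def header_comments(self) -> list[str]:
        """Full parameter set as '#'-prefixed lines for output provenance."""
        return [f"# {f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]


@dataclass(frozen=True)
class WavevectorGrid:
    """Square FFT wavevector grid with Hermitian-symmetry bookkeeping.

    Mode indices alpha, beta run over the standard DFT set
    {-alpha_max, ..., alpha_max - 1} per axis (N = 2*alpha_max), the full
    conjugate-symmetric set required for a real height field; the wavelength
    cutoffs lambda_min = L/alpha_max and lambda_max = L are preserved.
    """

    L: float
    alpha_max: int
    N: int
    qx: np.ndarray          # (N,) wavevector components, FFT order (1/nm)
    qy: np.ndarray          # (N,)
    q_mag: np.ndarray       # (N, N) |q|
    q4: np.ndarray          # (N, N) |q|^4, cached for the bending force
    conj_index: np.ndarray  # (N,) axis index map i -> -i mod N
    self_conjugate: np.ndarray  # (N, N) bool: modes equal to their conjugate

    @property
    def grid_spacing(self) -> float:
        return self.L / self.N

    @property
    def lambda_min(self) -> float:
        return self.L / self.alpha_max

    @property
    def q_min(self) -> float:
        """Smallest nonzero wavevector magnitude 2*pi/L."""
        return 2.0 * math.pi / self.L

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Collocation point coordinates (x_i, y_j), each (N,) in nm."""
        x = np.arange(self.N) * self.grid_spacing
        return x, x.copy()

    def conjugate_modes(self, a: np.ndarray) -> np.ndarray:
        """Return ``a`` evaluated at -q (works on trailing two axes)."""
        ci = self.conj_index
        return a[..., ci, :][..., :, ci]


def build_grid(config_or_L: Union[SimConfig, float], alpha_max: Optional[int] = None) -> WavevectorGrid:
    """Construct the wavevector grid, ``q = 2*pi*(alpha, beta)/L``.

    Accepts either a :class:`SimConfig` or an explicit ``(L, alpha_max)``
    pair.  The grid has ``N = 2*alpha_max`` points per side and exactly one
    zero mode.
    """
    if isinstance(config_or_L, SimConfig):
        L, alpha_max = config_or_L.L, config_or_L.alpha_max
    else:
        L = float(config_or_L)
        if alpha_max is None:
            raise TypeError("alpha_max required when not passing a SimConfig")
    if int(alpha_max) != alpha_max or alpha_max < 1:
        raise ValueError("alpha_max must be a positive integer")
    if alpha_max % 2:
        raise ValueError("alpha_max must be even (odd cutoffs are rejected)")
    if L <= 0:
        raise ValueError("L must be positive")
    alpha_max = int(alpha_max)
    N = 2 * alpha_max
    q1 = 2.0 * math.pi * np.fft.fftfreq(N, d=L / N)  # = 2*pi*alpha/L
    qx, qy = np.meshgrid(q1, q1, indexing="ij")
    q_mag = np.hypot(qx, qy)
    conj_index = (-np.arange(N)) % N
    # self-conjugate (purely real) modes: both components 0 or Nyquist
    axis_self = np.isin(np.arange(N), [0, N // 2])
    self_conj = np.logical_and.outer(axis_self, axis_self)
    return WavevectorGrid(
        L=L, alpha_max=alpha_max, N=N,
        qx=q1, qy=q1.copy(), q_mag=q_mag, q4=q_mag**4,
        conj_index=conj_index, self_conjugate=self_conj,
    )


def hermitian_deviation(h_q: SpectralField, grid: WavevectorGrid) -> float:
    """Max absolute deviation from h_{-q} = conj(h_q), relative to the scale."""
    dev = np.abs(h_q - np.conj(grid.conjugate_modes(h_q))).max()
    scale = np.abs(h_q).max()
    return float(dev / scale) if scale > 0 else float(dev)


def hermitize(h_q: SpectralField, grid: WavevectorGrid) -> SpectralField:
    """Project onto the Hermitian-symmetric subspace (real h(x))."""
    return 0.5 * (h_q + np.conj(grid.conjugate_modes(h_q)))


def to_fourier(h: RealField, grid: WavevectorGrid) -> SpectralField:
    """Forward transform, ``h_q = (L/N)^2 * DFT2(h)`` (continuum convention)."""
    h = np.asarray(h, dtype=float)
    if h.shape != (grid.N, grid.N):
        raise ValueError(f"field shape {h.shape} does not match grid N={grid.N}")
    return grid.grid_spacing**2 * _fft.fft2(h)


def to_real(
    h_q: SpectralField,
    grid: WavevectorGrid,
    nonhermitian: str = "raise",
    tol: float = 1e-8,
) -> RealField:
    """Inverse transform, ``h(x) = (N/L)^2 * IDFT2(h_q)``.

    ``nonhermitian`` controls what happens when the input is not
    conjugate-symmetric within ``tol``: ``"raise"`` (default) or
    ``"symmetrize"`` (project and warn).
    """
    h_q = np.asarray(h_q, dtype=complex)
    if h_q.shape != (grid.N, grid.N):
        raise ValueError(f"field shape {h_q.shape} does not match grid N={grid.N}")
    if hermitian_deviation(h_q, grid) > tol:
        if nonhermitian == "symmetrize":
            warnings.warn("non-Hermitian spectral field symmetrized", stacklevel=2)
            h_q = hermitize(h_q, grid)
        else:
            raise ValueError(
                "spectral field is not Hermitian-symmetric; the height field "
                "would be complex (pass nonhermitian='symmetrize' to project)"
            )
    return (grid.N / grid.L) ** 2 * _fft.ifft2(h_q).real
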