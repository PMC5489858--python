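"""Scripted validation and adhesion experiments.

Three studies exercise the simulator end to end:

* **free membrane** — bending force only; validates the equipartition
  spectrum and the analytic roughness;
* **entropic pressure** — bending + soft wall + swept uniform pressure;
  measures the equilibrium gap d(p) and fits the confinement-pressure
  coefficient c in ``p = c (kBT)^2/(B d^3)``;
* **adhesion sweeps** — full force set with Monte Carlo bond kinetics;
  maps the closed bond ratio phi against linkage stiffness k (substrate
  rigidity) and receptor spacing Delta (receptor density).

Two presets are provided.  ``"reference"`` keeps the reference conditions
(L = 800 nm, millisecond totals: ~2e6 steps at dt = 0.5 ns) and is intended
for workstation runs.  ``"quick"`` shrinks the box to L = 240 nm at the same
lambda_min = 20 nm — a change the pressure-distance relation is insensitive
to — and shortens the totals so the full validation battery runs in minutes;
precision is correspondingly lower (fewer modes, fewer decorrelation times).

Every experiment is a pure function of (config, seed): per-point seeds are
derived arithmetically from the base seed, and rerunning reproduces output
tables bit-identically.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import SimConfig, build_grid
from .integrator import run
from .kinetics import bell_off_rate, bond_force, build_lattice, kinetic_sweep, two_state_occupancy
from .observables import (
    block_standard_error,
    closed_bond_ratio_series,
    fit_entropic_coefficient,
    fluctuation_spectrum,
    mean_gap,
    rms_height_analytic,
)

__all__ = [
    "free_membrane_config",
    "entropic_pressure_config",
    "adhesion_config",
    "DEFAULT_PRESSURES",
    "DEFAULT_K_VALUES",
    "DEFAULT_DELTAS",
    "run_free_membrane",
    "run_entropic_pressure_sweep",
    "run_stiffness_sweep",
    "run_density_sweep",
    "run_fixed_gap_control",
    "write_table",
]

logger = logging.getLogger("fsbdmc")

#: Applied-pressure sweep (pN/nm^2) for the entropic-pressure study; spans
#: equilibrium gaps of roughly 3.5-7 nm, well inside the confined regime of
#: the quick box (free roughness ~10 nm) and well above sigma_w.
DEFAULT_PRESSURES = (2e-4, 3.5e-4, 6e-4, 1e-3, 1.7e-3)

#: Linkage stiffness sweep (pN/nm): two decades bracketing the crossover of
#: the closed bond ratio.  With the default encounter distance and Bell
#: length (1 nm each) the mean bond force at strong pinning approaches the
#: wall load per receptor, so adhesion collapses for k well above ~3 pN/nm;
#: the sweep stays on the adhered branch where the gap d(k) is monotone.
DEFAULT_K_VALUES = (0.03, 0.1, 0.3, 1.0, 3.0)

#: Receptor spacing sweep (nm); each must be a multiple of the grid spacing.
DEFAULT_DELTAS = (10.0, 20.0, 40.0, 60.0)


def _derive_seed(seed: int, index: int) -> int:
    """Deterministic per-run seed below 2^31."""
    return (1009 * (seed + 1) + 7919 * index) % (2**31)


def free_membrane_config(preset: str = "quick", **overrides) -> SimConfig:
    """Bending-only configuration (thermal initial state, spectrum sampling)."""
    base = dict(
        B=20.0, kBT=4.3, eta=6.0, dt=0.5,
        enable_bending=True, enable_wall=False, enable_linkage=False,
        enable_pressure=False, enable_kinetics=False,
        h_init=None, sample_stride=100,
    )
    if preset == "reference":
        base.update(L=800.0, alpha_max=40, t_total=1e6)
    elif preset == "quick":
        base.update(L=240.0, alpha_max=12, t_total=1e5)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    base.update(overrides)
    return SimConfig(**base)


def entropic_pressure_config(preset: str = "quick", **overrides) -> SimConfig:
    """Bending + soft wall + uniform pressure; near-hard-wall sigma_w."""
    base = dict(
        B=20.0, kBT=4.3, eta=6.0, dt=0.5,
        sigma_w=1.0, eps_w=0.043, h_sub=0.0,
        enable_bending=True, enable_wall=True, enable_linkage=False,
        enable_pressure=True, enable_kinetics=False,
        sample_stride=50,
    )
    if preset == "reference":
        base.update(L=800.0, alpha_max=40, t_total=6e5)
    elif preset == "quick":
        base.update(L=240.0, alpha_max=12, t_total=5e5)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    base.update(overrides)
    return SimConfig(**base)


def adhesion_config(preset: str = "quick", **overrides) -> SimConfig:
    """Full force set + kinetics with the reference adhesion parameters
    (p = 4e-5 pN/nm^2 holding pressure, h_L = -1.2 nm, sigma_w = 4 nm,
    eps_w = 0.01 kBT/nm^2, kon0 = 1/ns and koff0 = 1e-4/ns at their upper
    bounds)."""
    base = dict(
        B=20.0, kBT=4.3, eta=6.0, dt=0.5,
        sigma_w=4.0, eps_w=0.043, h_sub=0.0,
        k=1.0, h_L=-1.2, R_RL=1.0,
        kon0=1.0, koff0=1e-4, x_b=1.0,
        p=4e-5,
        enable_bending=True, enable_wall=True, enable_linkage=True,
        enable_pressure=True, enable_kinetics=True,
        sample_stride=200,
    )
    if preset == "reference":
        base.update(L=800.0, alpha_max=40, Delta=20.0, Nb=40, t_total=1e6)
    elif preset == "quick":
        base.update(L=240.0, alpha_max=12, Delta=20.0, Nb=12, t_total=1.5e5)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    base.update(overrides)
    return SimConfig(**base)


def write_table(df: pd.DataFrame, path, config: Optional[SimConfig] = None,
                extra: Sequence[str] = ()) -> None:
    """Write a TSV table with the full parameter set as '#' header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write("\n".join(config.header_comments()) + "\n")
        for line in extra:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_free_membrane(
    config: Optional[SimConfig] = None,
    seed: Optional[int] = None,
    out_dir=None,
    preset: str = "quick",
) -> dict:
    """Free-membrane validation: fluctuation spectrum and spatial roughness.

    Integrates the bending-only dynamics from a thermal-equilibrium initial
    state, estimates the radially binned spectrum with its equipartition
    reference, and compares the simulated spatial RMS height with the
    closed-form prediction.

    Returns a dict with keys ``record``, ``spectrum``, ``rms_simulated``,
    ``rms_analytic``, ``rms_ratio``; writes ``spectrum.tsv`` and
    ``summary.tsv`` when ``out_dir`` is given.
    """
    config = free_membrane_config(preset) if config is None else config
    if seed is not None:
        config = config.replace(seed=seed)
    record = run(config, record_spectrum=True)
    grid = record.grid
    n0 = int(len(record.time) * config.discard_fraction)
    spectrum = fluctuation_spectrum(
        record.spectrum_power[n0:], grid,
        config=config, sample_interval=record.sample_interval,
        min_samples=min(100, record.spectrum_power.shape[0] - n0),
    )
    rms_sim = float(np.sqrt(np.mean(record.rms_height[n0:] ** 2)))
    rms_th = rms_height_analytic(config.L, config.B, config.kBT)
    result = {
        "record": record,
        "spectrum": spectrum,
        "rms_simulated": rms_sim,
        "rms_analytic": rms_th,
        "rms_ratio": rms_sim / rms_th if rms_th > 0 else math.nan,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spectrum.save(out / "spectrum.tsv", config)
        summary = pd.DataFrame(
            [{"rms_simulated_nm": rms_sim, "rms_analytic_nm": rms_th,
              "ratio": result["rms_ratio"]}]
        )
        write_table(summary, out / "summary.tsv", config)
        record.save(out / "trajectory.tsv")
    return result


def run_entropic_pressure_sweep(
    pressures: Sequence[float] = DEFAULT_PRESSURES,
    config: Optional[SimConfig] = None,
    seed: int = 0,
    out_dir=None,
    preset: str = "quick",
    c_guess: float = 0.08,
) -> dict:
    """Entropic-pressure study: equilibrium gap versus applied pressure.

    For each pressure the membrane (bending + soft wall) is pushed against
    the substrate and the equilibrium mean gap d is measured; the
    confinement coefficient c of ``p = c (kBT)^2/(B d^3)`` is then fitted
    with the exponent fixed at -3.  Each run starts flat at the gap the law
    itself predicts for ``c_guess`` (a starting point only; the leading
    fraction of every trajectory is discarded before averaging).

    Returns a dict with the pressure-distance ``curve`` DataFrame
    (p, d, se), the fitted ``c``, and per-pressure records.  An
    unequilibrated run — first- and second-half gap averages differing by
    more than 5 combined SE — is flagged in the ``drift_flags`` column.
    """
    base = entropic_pressure_config(preset) if config is None else config
    rows, records = [], []
    for i, p in enumerate(sorted(pressures)):
        d_guess = (c_guess * base.kBT**2 / (base.B * p)) ** (1.0 / 3.0)
        cfg = base.replace(p=p, seed=_derive_seed(seed, i),
                           h_init=float(np.clip(d_guess, 2 * base.sigma_w, base.L / 4)))
        rec = run(cfg)
        d, se = mean_gap(rec)
        n0 = int(len(rec.mean_height) * cfg.discard_fraction)
        seg = rec.mean_height[n0:]
        half = len(seg) // 2
        d1, d2 = seg[:half].mean(), seg[half:].mean()
        se_drift = math.hypot(
            block_standard_error(seg[:half]), block_standard_error(seg[half:])
        )
        drift = abs(d1 - d2) > 5 * max(se_drift, 1e-12)
        if drift:
            logger.warning("pressure %.3g: drift between trajectory halves "
                           "(%.3g vs %.3g nm); run may be unequilibrated", p, d1, d2)
        rows.append({"p_pN_nm2": p, "d_nm": d, "se": se, "drift_flag": drift})
        records.append(rec)
    curve = pd.DataFrame(rows)
    c_fit = fit_entropic_coefficient(
        curve["p_pN_nm2"], curve["d_nm"], base.B, base.kBT
    )
    curve["c_pointwise"] = (
        curve["p_pN_nm2"] * curve["d_nm"] ** 3 * base.B / base.kBT**2
    )
    result = {"curve": curve, "c": c_fit, "records": records, "config": base}
    if out_dir is not None:
        write_table(curve, Path(out_dir) / "pressure_distance.tsv", base,
                    extra=[f"fitted_c = {c_fit}"])
    return result


def _adhesion_point(cfg: SimConfig) -> dict:
    rec = run(cfg)
    phi, phi_se = closed_bond_ratio_series(rec)
    d, d_se = mean_gap(rec)
    return {"phi": phi, "phi_se": phi_se, "d_nm": d, "d_se": d_se,
            "n_bind": rec.n_bind_events, "n_unbind": rec.n_unbind_events}


def run_stiffness_sweep(
    k_values: Sequence[float] = DEFAULT_K_VALUES,
    config: Optional[SimConfig] = None,
    seed: int = 0,
    out_dir=None,
    preset: str = "quick",
    rate_scale: float = 1.0,
) -> dict:
    """Closed bond ratio and gap versus linkage stiffness k.

    ``rate_scale`` multiplies both intrinsic rates (kon0, koff0), preserving
    the equilibrium constant; reducing it probes the regime where membrane
    fluctuation, not bond chemistry, limits the reaction.

    Returns ``table`` (k, phi, phi_se, d_nm, d_se, ...) and ``k_argmax``.
    """
    base = adhesion_config(preset) if config is None else config
    if rate_scale != 1.0:
        base = base.replace(kon0=base.kon0 * rate_scale,
                            koff0=base.koff0 * rate_scale)
    rows = []
    for i, k in enumerate(k_values):
        cfg = base.replace(k=float(k), seed=_derive_seed(seed, i))
        point = _adhesion_point(cfg)
        point["k_pN_nm"] = float(k)
        rows.append(point)
        logger.info("k = %g: phi = %.3f +/- %.3f, d = %.2f nm",
                    k, point["phi"], point["phi_se"], point["d_nm"])
    table = pd.DataFrame(rows)[
        ["k_pN_nm", "phi", "phi_se", "d_nm", "d_se", "n_bind", "n_unbind"]
    ]
    k_argmax = float(table.loc[table["phi"].idxmax(), "k_pN_nm"])
    result = {"table": table, "k_argmax": k_argmax, "config": base}
    if out_dir is not None:
        write_table(table, Path(out_dir) / "stiffness_sweep.tsv", base,
                    extra=[f"rate_scale = {rate_scale}", f"k_argmax = {k_argmax}"])
    return result


def run_density_sweep(
    deltas: Sequence[float] = DEFAULT_DELTAS,
    config: Optional[SimConfig] = None,
    seed: int = 0,
    out_dir=None,
    preset: str = "quick",
) -> dict:
    """Closed bond ratio versus receptor spacing Delta (density 1/Delta^2).

    The lattice always tiles the box (``Nb = L/Delta``), so each spacing
    must divide the box side and be a multiple of the collocation spacing.
    """
    base = adhesion_config(preset) if config is None else config
    rows = []
    for i, delta in enumerate(deltas):
        nb = int(round(base.L / delta))
        cfg = base.replace(Delta=float(delta), Nb=nb, seed=_derive_seed(seed, i))
        point = _adhesion_point(cfg)
        point.update({"Delta_nm": float(delta), "Nb": nb})
        rows.append(point)
        logger.info("Delta = %g: phi = %.3f +/- %.3f",
                    delta, point["phi"], point["phi_se"])
    table = pd.DataFrame(rows)[
        ["Delta_nm", "Nb", "phi", "phi_se", "d_nm", "d_se", "n_bind", "n_unbind"]
    ]
    result = {"table": table, "config": base}
    if out_dir is not None:
        write_table(table, Path(out_dir) / "density_sweep.tsv", base)
    return result


def run_fixed_gap_control(
    gaps: Sequence[float],
    k_values: Sequence[float],
    config: Optional[SimConfig] = None,
    seed: int = 0,
    n_steps: int = 80_000,
    out_dir=None,
) -> pd.DataFrame:
    """Detailed-balance control: kinetics on a frozen flat membrane.

    For each (gap, k) combination the membrane is pinned at
    ``h = h_L + gap`` and only the Monte Carlo kinetics run.  The stationary
    closed bond ratio must match the two-state occupancy
    ``kon0 / (kon0 + koff(f))`` with ``f = k * max(gap, 0)``.

    Returns a table with columns (gap_nm, k_pN_nm, phi, phi_se,
    phi_analytic).  Gaps must lie within the encounter distance, otherwise
    binding never occurs and the control is vacuous.
    """
    base = (adhesion_config("quick") if config is None else config).replace(
        kon0=0.1, koff0=0.02, t_total=0.0
    )
    rows = []
    grid = build_grid(base)
    for j, (gap, k) in enumerate((g, k) for g in gaps for k in k_values):
        cfg = base.replace(k=float(k), seed=_derive_seed(seed, j))
        lattice = build_lattice(cfg, grid)
        h = np.full((grid.N, grid.N), cfg.h_L + gap)
        bonds = np.zeros((lattice.Nb, lattice.Nb), dtype=np.int8)
        rng = np.random.default_rng(cfg.seed)
        burn = n_steps // 5
        phis = np.empty(n_steps - burn)
        for i in range(n_steps):
            kinetic_sweep(bonds, h, cfg, lattice, rng)
            if i >= burn:
                phis[i - burn] = bonds.mean()
        f = bond_force(cfg.h_L + gap, cfg.k, cfg.h_L)
        koff = float(bell_off_rate(f, cfg.koff0, cfg.x_b, cfg.kBT))
        rows.append({
            "gap_nm": gap, "k_pN_nm": k,
            "phi": float(phis.mean()),
            "phi_se": block_standard_error(phis),
            "phi_analytic": float(two_state_occupancy(cfg.kon0, koff)),
        })
    table = pd.DataFrame(rows)
    if out_dir is not None:
        write_table(table, Path(out_dir) / "fixed_gap_control.tsv", base)
    return table
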