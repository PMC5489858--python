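# Methods

## Model

The membrane is a nearly-flat fluid sheet in the Monge gauge: a height field
`h(x)` over a periodic square box of side `L`, governed by the
Canham–Helfrich bending energy `E_b = (B/2) ∫ (∇²h)² dA` with bending
rigidity `B`.  Its overdamped Brownian dynamics are integrated in Fourier
space — each mode amplitude `h_q` is a degree of freedom obeying

    ∂h_q/∂t = Λ_q [F_q(t) + ζ_q(t)],      Λ_q = 1/(4ηq),

where `η` is the viscosity of the surrounding fluid, `F_q` the deterministic
force, and `ζ_q` Gaussian thermal noise with
`⟨ζ_q ζ_q'*⟩ = 2 kBT L² Λ_q⁻¹ δ_qq' δ(t−t')`.  The mode-dependent
(Oseen-level) mobility makes long wavelengths relax slowly,
`τ(λ) = 4ηλ³/(B(2π)³)`.

Four forces act on the membrane:

* bending, `F_q^b = −B q⁴ h_q`;
* membrane–substrate linkages (MSL): each *closed* receptor–ligand bond is
  a linear spring of stiffness `k` (lumping bilayer shear stiffness,
  receptor–ligand complex stiffness, and substrate elasticity) anchored at
  the ligand rest height `h_L`, contributing a point force
  `−k(h(x_mn) − h_L)` at its lattice site `x_mn = (mΔ, nΔ)`;
* a truncated soft-wall repulsion for the substrate, with pointwise pressure
  `8(ε_w/σ_w)(σ_w/(h+σ_w−h_sub))⁹` active only where `h ≤ h_sub`
  (`h_sub = 0` throughout);
* a uniform applied pressure `p` on the zero mode only, `F_0^p = −L²p`
  (positive `p` pushes the membrane toward the wall).

Receptor–ligand kinetics follow a two-step picture: membrane fluctuation
brings a receptor within the encounter distance `R_RL` of its ligand, after
which the intrinsic reaction closes the bond at rate `kon0`; closed bonds
open at the Bell slip-bond rate `koff = koff0·exp(f·x_b/kBT)` with the
tensile spring force `f = k·max(h(x_mn) − h_L, 0)`.  Binding and unbinding
are realised by a fixed-timestep Monte Carlo sweep over all `Nb²` receptor
sites once per dynamics step: per-site probabilities `kon0·Δt` (when in
range) and `koff·Δt` are compared against one uniform draw per site.  The
adhesion observable is the closed bond ratio `φ` = closed bonds / `Nb²`.

## Discretisation and numerics

**Mode set.**  "Integer wavenumbers up to `α_max`" per axis is realised as
the full Hermitian-symmetric DFT set `α, β ∈ {−α_max, …, α_max−1}` on an
`N = 2α_max` collocation grid — a real height field requires the conjugate
modes.  The wavelength cutoffs `λ_min = L/α_max` and `λ_max = L` are
preserved.  Transforms use the continuum convention
`h_q = (L/N)²·DFT(h)`, `h = (N/L)²·IDFT(h_q)`, so mode-space formulas carry
their `L²` factors verbatim.  Receptor spacing `Δ` must be a multiple of
`L/N`; receptors sit exactly on collocation points and no interpolation is
ever needed.

**Integrator.**  Explicit Euler–Maruyama with the default `Δt = 0.5 ns`,
roughly two orders of magnitude below `τ(λ_min) ≈ 39 ns` at the reference
parameters.  The noise increment has per-mode variance `2 kBT L² Λ_q Δt`;
it is generated with exactly the `N²` independent Gaussian degrees of
freedom a real field has (real amplitudes on the four self-conjugate
DC/Nyquist modes, one complex amplitude per conjugate pair, mirrored), so
Hermitian symmetry is exact by construction.  One caveat worth knowing: the
explicit chain equilibrates to the continuum variance inflated by
`1/(1 − a_q Δt/2)` with `a_q = Bq³/(4η)` — at `Δt = 0.5 ns` a ≤2% effect
confined to the fastest modes.  `fluctuation_spectrum` can attach either
the continuum equipartition reference or this exact discrete-chain value
(`discrete_correction=True`); high-precision validation runs should use the
latter, since their statistical errors resolve below the bias.

**Zero mode.**  `Λ_q` diverges as `q → 0`; the centre-of-mass mobility is
regularised at the box scale, `Λ_0 = 1/(4η·2π/L)`, and the zero mode gets a
purely deterministic, force-driven drift (no thermal kick).  The mean
height therefore responds to the wall and applied pressure but does not
random-walk; its equilibrium value is set by force balance, which is
exactly the quantity the entropic-pressure experiment measures.

**Wall.**  The repulsive pressure is evaluated pointwise on the collocation
grid and transformed (pseudo-spectral treatment of the nonlinearity).  The
truncation at `h_sub` follows the energy definition literally, so the force
drops discontinuously from `8ε_w/σ_w` to zero there; `ε_w` is small enough
that the jump is mild.  If any grid point reaches the singular plane
`h_sub − σ_w` the run aborts with a timestep-stability error.  `ε_w` is
stored as energy per area (pN/nm); 0.043 pN/nm equals 0.01 kBT/nm² at
kBT = 4.3 pN·nm.

**Kinetics details.**  Site visits are in fixed row-major order with one
uniform draw per site; since per-step probabilities are small and sites are
mutually independent within a sweep, the vectorised update is exactly the
sequential one (tested).  `koff·Δt > 1` is clamped to 1 with a logged
warning.  A bond under compression carries zero Bell force — "pulling"
loads a slip bond; compression accelerating rupture would be unphysical.
Reopened ligands retract instantly (rigid substrate), so sites are
immediately rebindable.  The encounter criterion uses the vertical distance
`|h(x_mn) − h_L| ≤ R_RL`.

**Random numbers.**  One seed per run feeds a `SeedSequence` that is split
deterministically into a membrane-noise stream and a kinetics stream (SFC64
generators).  Trajectories are bit-reproducible for a given
`(config, seed)`; noise is pre-generated in chunks of 256 steps for
throughput without affecting reproducibility.

## Parameters

Defaults reproduce the reference conditions:

| parameter | default | meaning |
|---|---|---|
| `L` | 800 nm (240 nm quick) | box side |
| `α_max` | 40 (12 quick) | mode cutoff, λ_min = 20 nm |
| `B` | 20 pN·nm (≈5 kBT) | bending rigidity |
| `kBT` | 4.3 pN·nm | thermal energy (T ≈ 310 K) |
| `η` | 6 pN·ns/nm² (0.06 Poise) | fluid viscosity |
| `Δt` | 0.5 ns | timestep |
| `σ_w`, `ε_w` | 4 nm, 0.043 pN/nm | wall range and strength (1 nm wall for the hard-wall entropic study) |
| `k` | 1 pN/nm | MSL stiffness (swept 0.03–3) |
| `h_L` | −1.2 nm | ligand rest height |
| `Δ`, `Nb` | 20 nm, L/Δ | receptor spacing / count per side |
| `R_RL` | 1 nm | encounter distance (molecular contact scale; not fixed by the model, exposed as a config key) |
| `x_b` | 1 nm | Bell length (conventional slip-bond scale; configurable) |
| `kon0`, `koff0` | 1 /ns, 1e-4 /ns | intrinsic rates at their upper bounds, ratio e^(ε_b/kBT) ≈ 1e4 at ε_b = 10 kBT |
| `p` | 4e-5 pN/nm² | weak holding pressure for adhesion runs |

Viscosity unit conversion: 1 Poise = 100 pN·ns/nm².

## Experiments and the problem sizes used

All scripted experiments come in a `"reference"` preset (L = 800 nm,
millisecond totals, workstation scale) and a `"quick"` preset used by the
test battery: the box is shrunk to L = 240 nm at the same λ_min = 20 nm — a
change the pressure–distance relation is verified to be insensitive to —
with totals of 1e5 ns (free membrane), 5e5 ns per pressure (entropic sweep)
and 1.5e5 ns per adhesion point.  Precision falls accordingly (fewer modes
per radial bin, fewer decorrelation times per run); every statistical
comparison in the tests carries a standard error estimated for the actual
run, so the quick preset trades tighter error bars, not correctness.

**Free membrane** (bending only, thermal-equilibrium initial state): the
radially binned time average of `|h_q|²` is compared with equipartition,
`kBT L²/(B q⁴)`.  Standard errors per bin come from sampling theory —
`|h_q|²` of a Gaussian mode is exponentially distributed and decorrelates
over `τ_q/2` — because the slowest modes decorrelate on the run timescale,
where block averaging would underestimate the error badly.

A note on the closed-form roughness: the textbook estimate
`⟨h²⟩ ≈ A·kBT/(4π³B)` (≈33 nm at the reference parameters) corresponds to a
continuum integral with an infrared cutoff at `π/L`.  The exact equipartition
sum over the discrete periodic mode set is smaller by a factor
`4π³·S/(16π⁴) ≈ 0.48` in `⟨h²⟩` (`S = Σ'(α²+β²)⁻² ≈ 6.03`), i.e. ≈23 nm of
RMS at L = 800 nm.  Both are implemented (`rms_height_analytic`,
`rms_height_modesum`); simulations are validated against the mode sum, which
is the quantity a periodic-box simulation actually realises.

**Entropic pressure** (bending + wall + pressure): a confined fluctuating
membrane pushes back with pressure `p = c(kBT)²/(B d³)`.  Five applied
pressures (2e-4 … 1.7e-3 pN/nm²) span equilibrium gaps `d ≈ 3.5–7 nm` —
inside the confined regime (free roughness ≈10 nm at L = 240 nm) and well
above `σ_w = 1 nm`.  Each run starts flat at the gap predicted with a prior
`c = 0.08` (a starting point only; the first 20% of every trajectory is
discarded), and `c` is fitted on `log p` vs `log d` with the exponent fixed
at −3.  The gap `d` is measured from `h_sub = 0` to the mean membrane
height.  Known sensitivities: softer walls (larger `σ_w`) shift the
effective wall plane and bias `c`; `λ_min` changes the relation strongly;
the box size barely matters.

**Adhesion sweeps** (all forces + kinetics): closed bond ratio versus
linkage stiffness `k` and receptor spacing `Δ`.  With the defaults above,
the mean bond force at strong pinning approaches the wall load per receptor
(`≈ P_w·Δ²`), so adhesion collapses for `k ≳ 5 pN/nm`: the default sweep
(0.03–3 pN/nm, two decades) brackets the interior maximum of `φ(k)` while
staying on the adhered branch, where the gap `d(k)` decreases monotonically.
Beyond the collapse the membrane unbinds and `d` reverts to the free
entropic level — the monotone-`d` statement applies to the adhered branch.
The rate-reduction comparison (both intrinsic rates ×0.01 at a fixed
equilibrium constant) is run over k ∈ {0.1, 1, 10}, where the collapse side
separates the two regimes sharply; at reduced rates the bond chemistry, not
the membrane fluctuation, limits the reaction and the stiffness dependence
of `φ` weakens.  Adhesion runs start flat at `h_L + R_RL` with all bonds
open, so binding can nucleate immediately.

**Fixed-gap control**: with the membrane frozen flat at `h_L + gap`, the
Monte Carlo kinetics must reach the two-state occupancy
`φ = kon0/(kon0 + koff(f))`, `f = k·max(gap, 0)` — checked for several
(gap, k) combinations as a detailed-balance test decoupled from the
dynamics.

## What the quick-preset validations do and do not show

They verify the integrator's stationary statistics, the force
implementations, detailed balance of the kinetics, and the qualitative
adhesion phenomenology on a 240 nm box.  They do not probe wavelengths
above 240 nm, receptor counts beyond 24², in-plane receptor diffusion
(receptors are immobile by construction), nonlinear linkage mechanics,
membrane tension, or hydrodynamics beyond the `1/(4ηq)` mobility — all
outside the model's scope.  Real adhesion data additionally involve
receptor clustering and cytoskeletal remodelling, which this early-stage
model deliberately omits.

## Known limitations

* Explicit Euler–Maruyama: O(Δt) weak bias (documented above); no implicit
  or higher-order scheme is provided.
* The wall-force truncation is discontinuous (by construction of the
  truncated energy).
* `koff·Δt` clamping distorts the unbinding statistics of extremely loaded
  bonds; such bonds rupture within a step or two either way.
* The fitted `c` inherits a small downward bias at the highest pressures,
  where the gap approaches `σ_w` and the soft wall admits slight
  penetration; the fitting window was chosen to keep this within the
  documented band.
* `φ` at 100×-reduced rates equilibrates on the `1/koff0` timescale, which
  exceeds the quick-preset run length; the reduced-rate curves are
  finite-time observations under the same protocol as the reference
  conditions, not equilibrium values.
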