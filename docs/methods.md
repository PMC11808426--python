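# Methods

## Scope and model chain

`shakeflask` characterizes one orbital-shaking operating point
(n, d, d0, V_L, fluid) and post-processes single two-phase flow snapshots.
It does **not** solve flow: the volume-of-fluid Navier–Stokes solve and
the k-ω SST transport equations are upstream of this package; their output
fields are inputs here. Temporal averaging across snapshot sequences is
likewise out of scope (loop over snapshots externally).

The correlation chain is:

1. `Re = ρ n d² / η` and the film Reynolds number
   `Re_film = Re (π/2) [1 − √(1 − (4/π)(V_L^{1/3}/d)²)]²`. The bracket in
   the film Reynolds expression is squared as a whole; this reading is the
   one that reproduces the published phase numbers (1.21 and 1.44 for the
   reference 250 mL conditions) and the CLI logs the convention once per
   run so reports are auditable.
2. Phase number `Ph = (d0/d)(1 + 3 log₁₀ Re_film)`; regimes: in-phase for
   `Ph ≥ 1.26`, transition for `0.91 ≤ Ph < 1.26`, out-of-phase below.
   The sources state the thresholds without a boundary convention; we
   close the in-phase interval at 1.26 and include 0.91 in the transition
   band.
3. In-phase power input `P/V_L = Ne′(Re) ρ n³ d⁴ V_L^{−2/3}` with
   `Ne′ = 70 Re⁻¹ + 25 Re⁻⁰·⁶ + 1.5 Re⁻⁰·²` (derived from in-phase
   experiments only), and the empirical out-of-phase quotient
   `y(Ph) = 1 − a e^{−b Ph}` with fitted defaults a = 3.43, b = 2.02.
   Below `Ph = ln(a)/b ≈ 0.610` the quotient goes negative — an
   extrapolation artifact outside the fitted data cloud — so the corrected
   power clamps at zero and carries a warning flag.
4. Henzler–Schedel
   `k_L a = 0.5 d^{73/36} n d0^{1/4} V_L^{−8/9} ν^{−13/54} g^{−7/54} D_L^{1/2}`;
   the exponents sum to a dimensionless group, which the tests verify by
   evaluating in rescaled unit systems (mm/min/g, cm/min/g, ft/h/lb) and
   recovering SI values to ten significant digits.
5. Diffusion coefficient via Stokes–Einstein–Gierer–Wirtz:
   `D_L = k_B T / (6π η r_solute f_GW)`, hard-sphere radii
   `r = (3·MW/(4π ρ_eff N_A))^{1/3}` with ρ_eff = 619 kg/m³, and
   `f_GW = (3β/2 + 1/(1+β))⁻¹`. The radius-ratio orientation is
   `β = (MW_solute/MW_solvent)^{1/3}`; with it O₂-in-water at 20 °C comes
   out at 1.78×10⁻⁹ m²/s, the physically expected magnitude. β is exposed
   through `SolutePair` should a user need the opposite orientation.
6. Giese effective shear rate
   `γ = [2.06 (P/V_L)/K (V_L^{1/3}/d)^{−0.33}]^{1/(m+1)}` and the power
   law `η_eff = K γ^{m−1}`.

### Effective-viscosity fixed point

For a power-law fluid the loop η → Re → Ne′ → P/V_L → γ → η = K γ^{m−1}
is iterated to a relative change below 1e−10 (cap 500, under-relaxation
0.5 engaged only when the update direction flips; the map is a mild
contraction near m = 1). The loop uses the **uncorrected** in-phase power
input by default: the Giese correlation was derived under in-phase
conditions, so feeding it the out-of-phase-corrected power would mix
calibrations. A `use_correction` flag enables the corrected variant; for
the reference PVP condition both round to the same 80 mPa·s. Convergence
is initialization-independent (tested from η₀ = K and η₀ = 1 mPa·s);
m = 1 terminates in one iteration with η_eff = K exactly.

### Bundled flask preset

The largest inner diameter of the reference 250 mL narrow-neck Erlenmeyer
is fixed at d = 81.3 mm — a plausible nominal value calibrated so the
dimensionless groups reproduce the published phase numbers — and is
always user-overridable. Model-fluid density defaults to 1000 kg/m³.
Interface units (rpm, mm, mL, mPa·s, °C, g/mol) are converted exactly
once at the boundary; all computation is SI.

## Snapshot post-processing

* **Derivatives.** Second-order central differences in the interior,
  first-order one-sided at boundaries (`np.gradient`, `edge_order=1`).
  Convergence claims are asserted on interior cells only; the observed
  error ratio under spacing halving is ~4.
* **Strain rate.** `S = sym ∇U`; scalar measure `‖S‖ = √(2 S:S)` (equals
  γ₀ for planar Couette flow); λ₁ from the closed-form trigonometric
  eigensolver for symmetric 3×3 tensors, arccos argument clamped to
  [−1, 1], result floored at 0. For traceless S, `‖S‖ ≥ √3 λ₁` with
  equality on the (λ, −λ/2, −λ/2) spectrum — both verified against a
  characteristic-polynomial root oracle.
* **Dissipation.** `ε_i = (η/ρ)‖S‖² + β* ω k` per cell (β* = 0.09, the
  k-ω SST closure constant; the turbulence term drops when k/ω are
  absent). The first factor is read as kinematic viscosity times ‖S‖² so
  the integrand is W/kg. Liquid averages are α-weighted — no hard phase
  threshold — because volume-of-fluid interfaces are diffuse and the
  liquid-mean definition carries α explicitly. `P/V_L = ε ρ` holds by
  construction for every snapshot.
* **Eddy-cell k_L a.** `k_L = 0.4 √D_L (ε_i/ν)^{1/4}` with the **local**
  per-cell dissipation (the integral is per-cell, so the local value is
  the consistent choice). The integral `Σ k_L a_i V_cell` is normalized by
  the total domain volume as the model is written; a liquid-volume
  normalization is co-reported because the experimental correlations it
  is compared against are liquid-referenced.
* **Shear estimators.** `γ = ‖S‖` (the scheme general-purpose CFD codes
  ship) or `γ = 2.5 λ₁` (from the laminar average-shear-stress estimate
  `τ = 2.5 η λ₁`). For power-law fluids the stress route requires the
  per-cell iteration `γ ← (2.5 γ^{m−1} λ₁)^{1/m}`, whose closed-form
  fixed point is γ = 2.5 λ₁ independent of K; the iteration contracts
  with factor |(m−1)/m| and is therefore rejected for m ≤ 0.5. Gas cells
  are always excluded from mean shear rates by α-weighting.
* **Contact lines.** α is sampled by trilinear interpolation on cylinders
  of radius R − δ (1° azimuth bins, every grid z level); the contact
  height is the **topmost** crossing of α through the iso level (default
  0.5), linearly interpolated, so a wall film reports the film's upper
  rim — the behavior needed to separate film from bulk by sweeping δ.
  Azimuths with no crossing carry NaN; a profile that is liquid up to the
  domain top reports the top.

## Synthetic fields

The generator emulates the geometric content of volume-of-fluid output,
not its dynamics: planar Couette shear and rigid rotation (exact
strain-rate references), slab and spherical diffuse interfaces (exact
areas: the integral of |∇α| across any monotone ramp telescopes to the
geometric area regardless of profile shape, so a clipped-linear ramp of
prescribed thickness ≥ 4 cell spacings suffices), and an annulus mimicking
the rotating liquid body in a flask — a liquid ring against a cylindrical
wall with an optional thinner, higher wall film and rigid-rotation
velocity. Requested liquid volumes are honored by solving the ring height
against the realized discrete ring cross-section (within 1 %). Snapshots
are bit-identical for a given seed.

Passing these tests therefore demonstrates the **operators** are correct
on resolved, smooth fields; it says nothing about turbulence modeling,
interface capturing, or mesh quality of any particular CFD run, and
free-surface shapes of real out-of-phase sloshing are not emulated.

## Problem sizes and numerical choices

Test grids are 16³–64³ cells — large enough for the diffuse-interface
(≥ 4 cells) and convergence (≥ 16 cells/axis) requirements, small enough
that the whole suite runs in seconds. Eigen-oracle comparisons use 10³
random tensors at 1e−10 relative tolerance. The correction fit seeds its
Levenberg–Marquardt-type least squares from a log-linear regression of
1 − y and flags all-quotients-≈1 data as unidentifiable (a ≈ 0 leaves b
unconstrained). The characterization report computes D_L for O₂ in water
at the row temperature and the resolved effective viscosity, the same
convention the k_L a comparisons it supports use.

## Known limitations

* Only power-law rheology (no Carreau or Herschel–Bulkley) and only the
  250 mL flask preset; any other geometry must supply d explicitly.
* The out-of-phase correction is an empirical fit; below Ph ≈ 0.61 it is
  extrapolation and the package clamps rather than predicts.
* Structured uniform grids only; no unstructured-mesh support.
* The SEGW estimate carries no electrolyte or mixed-solvent corrections;
  evaluation temperature is an explicit input, never inferred.
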