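# Methods

## Model

A swimming bacterium with a rotary flagellar motor is torque-free: the motor
torque Γ_M spins the flagellar bundle one way and the counter-torque spins
the body the other way. In the far field the cell is a torque dipole — point
torques +Γ_M x̂ (leading pole) and −Γ_M x̂ (trailing pole) separated by
ℓ_D = α ℓ_B along the swimming axis x̂, with ℓ_B the body length and α an
order-one geometric ratio. The force dipole, though present, drives no net
vertical torque for a cell aligned with the channel axis (by symmetry) and
is omitted.

Confined in a square duct (cross-section |y| ≤ W, |z| ≤ W) cut into the
underside of a microdisc, the flow of a single rotlet at axial position x₁
exerts a viscous traction on the top wall z = +W (the disc's underside; the
bottom wall is the fixed substrate). The transmitted vertical torque about
the disc centre x_C is linear in the offset,

    Γ₁ = −Λ (x₁ − x_C)/W · Γ_M,

with Λ a positive dimensionless constant, independent of every parameter
including W. The dipole therefore transmits Γ = −Λ (ℓ_D/W) Γ_M whenever both
rotlets are under the disc — independent of the cell's position and heading.
The disc responds with dΘ/dt = M_Θ Γ, where the rotational mobility follows
Stokes–Einstein, M_Θ = D_Θ/k_B T, from the independently measured thermal
diffusivity (default D_Θ = 6×10⁻⁵ rad²/s at 298.15 K, M_Θ = 1.46×10⁻²
rad s⁻¹ (pN·μm)⁻¹).

For a single crossing at constant speed U_s (position X_B = U_s t from the
channel entrance), eliminating time gives the piecewise profile

    ΔΘ(X_B) = −Λ (ℓ_D/W)(M_Θ/U_s) Γ_M X_B                      X_B ≤ X*,
    ΔΘ(X_B) = (Λ/W)(M_Θ/U_s) Γ_M [X_B²/2 + X_B(ℓ_B − ℓ_D − R)
               + ℓ_B(ℓ_B − 2R)/2]                               X_B > X*,

whose two branches are *exactly* continuous at X* = 2R − ℓ_B — the observed
reversal point of the "down–up" dip, with depth
ΔΘ_max = Λ (ℓ_D/W)(M_Θ/U_s) Γ_M (2R − ℓ_B). The angle freezes once the
trailing rotlet clears the exit (X_B = 2R + ℓ_D − ℓ_B); beyond it the torque
is zero. A `reversal_convention="naive"` switch instead places the reversal
at 2R (body centre exiting) with the quadratic branch continued continuously
from there; the observed convention is the default because it is where the
two printed branches meet identically.

Sign conventions: Θ is positive anticlockwise about +ẑ viewed from above;
clockwise means dΘ/dt < 0. The traction on the disc is −σ·n̂ with n̂ = +ẑ the
fluid's outward normal (the force the fluid exerts on the wall). With the
+Γ_M rotlet leading, the transmitted dipole torque is negative — clockwise —
matching the observed chirality for the wild-type motor handedness, and
flipping sign with Γ_M.

### Speed invariance

ΔΘ(X_B) carries the prefactor Γ_M/U_s. Both Γ_M and U_s are proportional to
the motor rotation rate (all loads are viscous), so their ratio is a
property of the cell geometry: cells of the same size but different motor
rates trace the same ΔΘ(X_B). This, not a literal independence from U_s at
fixed Γ_M, is the content of the experimental velocity collapse, and it is
how the package varies swim speed (`TorqueDipoleSpec.with_swim_speed`
co-scales the motor torque).

## Boundary-element solver

`channel_hydro` discretizes the four duct walls (axial truncation L,
default 40 W, panel-free open ends justified by the exponential axial
screening of duct Stokes flow) into flat square panels of size h ≤ W/4
carrying piecewise-constant force densities, and collocates the no-slip
condition at panel centres using the regularized-Stokeslet kernel

    G_ε(r) = [(r² + 2ε²) I + r r] / (r² + ε²)^{3/2},   ε = h/2,

with one-point quadrature. The dense system is LU-factored with a
reciprocal-condition estimate (refused above 10¹²; typical values are a few
hundred). The panel density f is the force per area the wall exerts on the
fluid; the traction on the disc is −f, so the top-wall torque integral needs
no numerical differentiation. A finite-difference traction variant (one-sided
differencing of the velocity evaluator at step h/4) is retained as a
diagnostic only: its probe sits inside the regularization layer and
underestimates the traction integral by ~30% at the default step, so the
panel-density route is the default.

`compute_lambda` places a unit axial rotlet on the centerline, evaluates
Λ = −W F_y(top)/Γ_M at two or more panel sizes (default W/4, W/5, W/6 on an
L = 20 W duct) and extrapolates linearly in h — the observed convergence
order of the regularized single layer with ε tied to h. The reported
uncertainty combines the extrapolation distance from the finest level with
the fit scatter. The refinement sequence is required to contract; a
non-converging sequence raises with the per-level values.

### Value of Λ and cross-checks

The solver converges from above (0.2146, 0.2090, 0.2062, 0.2044, 0.2031 at
h = W/2 … W/6, L = 20 W) and extrapolates to **Λ ≈ 0.196–0.197**. Two
independent routes confirm this:

* a staggered-grid (MAC) finite-difference Stokes solve with regularized
  point-torque forcing (`tests/stokes_fd_oracle.py`) gives 0.1965–0.1956 at
  increasing resolution;
* a Lorentz-reciprocal-theorem reduction gives the exact identity
  Λ = (W/2)|ω'_x| with ω'_x the x-vorticity at the rotlet location of the 2D
  Stokes lid-driven-cavity flow in the duct cross-section (top lid sliding in
  y); a converged biharmonic solve yields Λ = 0.19528.

The value ≈ 0.17 quoted with the experimental study this pipeline models is
~13% below all three routes; it is consistent with a modestly under-resolved
panel calculation (our own h = W/2 level with a coarser traction rule passes
through that value). The package reports its converged number and makes no
adjustment toward 0.17. Off-centre rotlet placement does not bridge the gap:
Λ(z_src) falls steeply below the centerline (0.17 is crossed only ~0.04 W
below it), and the cross-sectional placement is exposed as a parameter with
the centerline as default. Side-wall tractions transmit zero net vertical
torque (verified numerically to quadrature precision), confirming that only
the top wall contributes.

### Closed chambers

A dead-end wall at x_w is modelled by augmenting every rotlet with its
mirror image through the plane (position reflected; the torque pseudovector
keeps its axial component). The combined flow is reflection-symmetric, so
the normal velocity on the plane vanishes (measured ≲ 10⁻⁵ of the rotlet
scale); tangential slip on the plane is the approximation made. The torque
is then integrated over the *physical* side of the top wall only. An
explicit end-wall panel solve agrees with the image construction to well
within 20%. For the analytic layer the chamber effect is cached as a single
dimensionless multiplier κ on the open-channel dipole torque
(`closed_chamber_correction`; κ ≈ 1.06 for a 5 μm cell parked half a body
length from the dead end of a 2×2 μm chamber), keeping multi-chamber rates
additive: ω = Σᵢ M_Θ κ Γ(ℓ_D^i) ∝ Σᵢ ℓ_B^i — the total-length collapse.

## Chiral bath model

Plain discs in a dilute bath rotate because near a no-slip floor the
swimmers circle clockwise (radius R_c ≈ 50 μm), making rim collisions
slightly asymmetric. The minimal model takes Poisson collisions at rate
ν·2πR (ν per unit perimeter, defaulting to the kinetic estimate
ρ_B U_s ℓ_B ≈ 0.06 s⁻¹μm⁻¹ at 6×10⁸ cells/mL), each transferring a
tangential impulse of scale F R τ_c with rectified fraction c·ℓ_B/R_c and a
zero-mean unrectified part. The mean torque is then

    Γ̄ = χ c F (ℓ_B/R_c)(ν 2πR) R τ_c,     χ = −1 (clockwise swimmers),

scaling as R², so with the thin-disc mobility M ∝ R⁻³ the rate obeys
ω ∝ 1/R and the thermal diffusivity D_Θ = k_B T M ∝ R⁻³. The contact time
defaults to τ_c = ℓ_B/U_s = 0.25 s and c = 1; with the per-collision force
F = 0.2 pN this gives ω(R = 10 μm) ≈ 2.7×10⁻³ rad/s, inside the measured
10⁻³–10⁻² rad/s decade. These two constants are exposed in the config; the
model is scaling-complete rather than collision-resolved (no swimmer–swimmer
interactions, no disc translation).

## Synthetic data

Generators mirror the acquisition: dt = 0.1 s (10 frames/s), angles stored
unwrapped. Crossings superpose the analytic profile at the true position
X_B = U_s t, Euler–Maruyama rotational diffusion (valid since dt ≪ 1/model
rates), and additive measurement noise on the reported angle (0.01 rad) and
position (0.2 μm) — detector magnitudes that were not published and are
config defaults, not claims. Occupancy series drive the additive chamber
rate through Poisson entry events (no exits by default; the chambers are too
narrow to turn around in). All randomness flows through numpy's PCG64
generator, so a seed pins every trace across platforms. What passing tests
on these data do *not* show: robustness to tracking artefacts (non-monotone
X_B is refused, not repaired), to cell wobble or off-axis alignment, or to
the near-field effects at the channel exit.

## Inference

* **Rates**: OLS slope of Θ(t), offset- and time-origin-invariant.
* **D_Θ**: MSAD over overlapping windows, lags in [dt, duration/4] (up to
  200 lag values), weighted by the number of window pairs, fitted through
  the origin; D_Θ = slope/2. A quadratic term is co-fitted as a drift
  diagnostic (pure drift has MSAD = (ωτ)²) and flags non-diffusive series.
  Single-trace estimates carry ~50% scatter because long lags dominate the
  default range; ensemble means are used everywhere a tolerance matters.
* **Collapse / reversal**: traces re-parameterized by X_B and interpolated
  to a common grid; the reversal is the interior minimum of the
  Gaussian-smoothed mean curve (bandwidth 1 μm default, ties toward smaller
  X_B).
* **α**: fitted on the pre-reversal branch only, as a through-origin
  regression of ΔΘ on the known prefactor times X_B. Default is a pooled
  fit over traces; a per-trace mode averages individual estimates. Standard
  errors are cluster-robust (between-trace scatter): rotational diffusion
  makes within-trace residuals strongly correlated, and the naive pointwise
  OLS error underestimates the sampling scatter ~3–4×. Monte-Carlo over
  ensembles shows a small (+1–2%) finite-noise bias and 95% CI coverage at
  or above nominal. Γ_M and α are not jointly identifiable from a single
  trace (the slope depends on their product); Γ_M must be supplied.

## Problem sizes

The test suite solves the duct problem at h = W/4 on L = 10–20 W
(≈ 1300–2600 panels; seconds each), cross-checks against a 48×12×12 MAC
grid, and runs the convergence pair (W/4, W/5) on L = 20 W once. The
acceptance script uses three panel levels up to W/6 on L = 20 W (≈ 5800
panels, ~2.4 GB dense matrix) and stochastic ensembles of 192 bath runs and
100 passive traces per radius — sizes chosen so the standard error of each
reported slope is well below its tolerance.

## Known limitations

* Far-field rotlet description only: no flagellar-bundle mechanics, no
  near-field corrections where the cell enters or exits the channel (the
  main unexplained offset in the reversal location is absorbed by adopting
  X* = 2R − ℓ_B as the observed convention).
* The channel walls are truncated infinite planes; the disc is never
  resolved as a finite body.
* The bath model is a scaling argument with two calibrated order-one
  constants, not a collision-resolved simulation.
* Λ's ~13% disagreement with the earlier quoted value is documented above
  and deliberately not reconciled by tuning.
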