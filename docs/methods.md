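# Methods

This note documents the models implemented in `ldbridges`, the choices made
where the underlying procedures left the design open, and what the
synthetic-data generators do and do not emulate.

## Colocalization against a binomial random-placement null

**Model.** Foci and droplets are reduced to centroids and equivalent-circle
radii. A focus of radius `rA` *overlaps* a droplet of radius `rLD` when the
center distance is ≤ `rLD + rA`; the per-focus signed distance
`min_LD(‖c_focus − c_LD‖ − (rLD + rA))` is negative exactly on overlap (the
boundary-contact case counts as overlap). If foci fall uniformly at random
on the field, the single-focus overlap probability equals the fraction `s`
of the field covered by droplets dilated by `rA`, and the colocalized count
is `Binomial(nA, s)`.

**Union versus sum.** The textbook expression `s = Σ π(rLD + rA)² / area_f`
double-counts where dilated disks overlap and can exceed 1 in crowded
fields. The implementation computes the *geometric union* of the dilated
disks (shapely polygonal buffers, 256 segments per circle, relative area
error ~1e-4), clipped to the field rectangle, so `s` is always a valid
probability; the naive sum is also reported (`s_sum`) for comparison. The
two coincide for sparse droplets.

**Verdict.** Rather than an informal `n_exp ≫ n_s` comparison, verdicts use
exact binomial tails: *enriched* if `P(X ≥ n_exp) ≤ α`, *excluded* if
`P(X ≤ n_exp) ≤ α`, else *random-consistent*; default `α = 0.01`. The null
mode `n_s = argmax P(n)` breaks ties toward smaller `n`, which is
conservative for enrichment calls. Condition-level inference is a two-sided
paired t test of `n_exp/nA` against `n_s/nA` across fields; identical
differences across all fields (zero variance) are refused explicitly.

**Calibration.** Because the binomial test is discrete, the realized
false-enrichment rate at α = 0.01 on uniform-placement fields sits well
below α (measured ≈ 0.006–0.009 over 1000 fields); power at planted
enrichment 0.5 with nA = 50 is ≈ 1.0.

## Bridge kinetics and connection counting

**Model.** With constant ER concentration `C0`, droplet surface
`S = 4πR²`, bridge permeability `k = D/l` and section width `L`, the amount
on the droplet follows `dN/dt = n_c·kL·(C0 − N/S)`, hence
`N(t) = C0·S·(1 − e^{−t/τ})` with `τ = lS/(n_c·D·L)`. Reservoir depletion
is out of scope (`C0` constant). Only the ratio `l/L` enters; its default
is 2, configurable within the observed 1.5–3 range. The single-bridge bulk
time is `τ_bulk = (l/L)·4πR²/D` (= `8πR²/D` at the default), and the
inferred bridge count is `n_c = τ_bulk / τ_fit`. `τ_bulk` depends on the
droplet radius `R`, which varies between experiments; the package exposes
`R` as a parameter and also accepts `τ_bulk` bounds directly (e.g. 21–31
min), propagating them into an `n_c` range. With `τ_fit = 3.6` min those
bounds give `n_c ∈ [5.8, 8.6]`.

**Lag handling.** Measured targeting curves show a variable delay (1–25
min) before the rise, reflecting bridge formation. The lag is a free
parameter of the fitted model `N(t) = plateau·(1 − e^{−(t−lag)/τ})` for
`t > lag`, 0 before — no manual onset calls. Fits are plain nonlinear least
squares (trust-region reflective, bounds `τ > 0`, `lag ∈ [0, t_max]`,
`plateau > 0`), initialized from the first 5%-of-plateau crossing (lag),
the 63% crossing (τ) and the maximum (plateau). Standard errors come from
the Jacobian-based covariance. Connection estimates are refused when
`SE(τ) > τ` (unidentifiable).

**Units.** Time is carried in minutes, lengths in μm, `D` in μm²/s; the
s↔min conversion is confined to `bridge_kinetics` so the formulas cannot
mix units.

**Self-consistency oracle.** The module's primary internal check is that
numerical integration of the flux ODE reproduces the closed form to rtol
1e-6 across random parameter sets, and that a particle-mode simulation —
independent walkers whose bridge-crossing times are exponential at the
well-mixed first-order rate `1/τ` — matches the ODE mean within Monte-Carlo
error. The particle mode is the well-mixed (Markovian) limit of explicit
random walkers, which is exactly the regime the flux balance assumes.

## FRAP on ER tubules

ER tubules are quasi-one-dimensional, so the model is pure 1-D diffusion on
an infinite line with a rectangular bleach of width `w` and depth `β`:
heat-kernel convolution of the initial deficit gives the center intensity
`F(t) = 1 − β·erf(w/(4√(Dt)))`, with `F(0) = 1 − β` and full recovery at
long times. `D` obeys diffusive scaling (`w → cw`, `t → c²t` leaves it
unchanged), which the tests verify. The closed form is validated against an
independent Crank–Nicolson finite-difference integration, and `D` fitted
from those PDE-simulated curves agrees with the simulation's `D` within 5%
across 0.01–0.1 μm²/s. Bleach geometry (`w`, `β`) is treated as measured
metadata, not fitted; an optional immobile fraction caps recovery at
`1 − φβ` and defaults to 0 (near-complete recovery is the observed
behaviour). Fits refuse traces recovering less than 10% of the bleached
deficit. Reaction–diffusion (binding) models and 2-D spot geometries are
out of scope.

## Drop-weight tensiometry

Per drop, `γ = mg/(πdf)` with `m = vΔρ`. The geometric correction `f` is
interpolated (shape-preserving PCHIP) from the classical Harkins–Brown
calibration, tabulated against `x = r_tube/V^{1/3}`; the tube/drop radius
ratio is converted to `x` assuming a spherical detached drop. The table's
empirical nodes span `x ∈ [0.30, 1.20]`; below 0.30 the curve is bridged
smoothly to the thin-tip (Tate) limit `f → 1` at `x = 0`. That bridge is an
interpolation, not calibration data — for the small density contrasts and
low tensions typical of phospholipid-covered oil/water interfaces the
working point lies in this region, so absolute accuracy there inherits the
interpolation's uncertainty; generator→analyzer round trips are exact by
construction regardless. On the analysis side `f` follows directly from
each measured volume; only the *generator* needs the self-consistent
inversion `vΔρg = γπd·f(v)`, solved by damped fixed-point iteration
(tolerance 1e-10, converges in a handful of steps everywhere in the table
range). Results are the mean ± SD over drops, mirroring the
minimum-15-drops practice. Pendant-drop shape analysis and dynamic tension
are out of scope.

## Size distributions

Diameter samples (the module works in diameters, μm) are summarized by a
Gaussian KDE with Silverman's rule by default, renormalized to integrate to
1 on the evaluation grid (which extends 3 bandwidth-scaled SDs past the
sample). Modes are local maxima with prominence ≥ 5% of the global density
maximum — the floor suppresses noise wiggles without hiding genuinely
separated components. A constant sample short-circuits to a single mode at
the constant (the KDE is degenerate there). Formal bimodality tests and 3-D
volume back-computation are out of scope.

## Synthetic data: what it emulates and what it does not

The generators realize precisely the assumptions the analyses make, with
planted ground truth:

- **Fields.** Droplets are anti-aliased disks (radii from a configurable
  lognormal/mixture law), foci are small disks; both are rejected-and-
  resampled to lie fully inside the field (no periodic boundary), with a
  bounded-retry placement error for overcrowded fields. A focus planted as
  colocalized (probability = `enrichment`) is centered uniformly within
  `rLD + rA` of a random droplet center — the same overlap rule the
  analysis applies, so planted truth and analysis agree by construction.
  The remaining foci are uniform over the field. Noise is additive
  zero-mean Gaussian — the simplest model consistent with fluorescence
  readout at the relevant SNR; Poisson shot noise, PSF blur, uneven
  illumination and 3-D stacks are *not* modelled, so segmentation
  performance on these fields (precision/recall 1 at SNR ≥ 10) is an upper
  bound, not a claim about real micrographs. Focus intensity and size are
  free parameters, not measured quantities.
- **Curves.** Targeting curves and FRAP traces satisfy their closed forms
  exactly at zero noise (defaults τ = 3.6 min, lag ∈ 1–25 min,
  D = 0.035 μm²/s); drop series invert the tensiometry equation
  self-consistently (defaults: d = 250 μm tube, Δρ = 90 kg/m³ oil/buffer
  contrast, γ of a few mN/m for a phospholipid-covered triglyceride/buffer
  interface, 15 drops, 1% volume noise).
- **Size populations.** `bimodal` mixes many small (median 0.5 μm) with few
  large (median 3 μm) droplets; `monodisperse` is a narrow lognormal with
  arithmetic mean 1.3 μm; `giant` is a broad heavy-tailed law. These are
  phenomenological stand-ins chosen to reproduce the qualitative phenotypes
  (two KDE modes / one / right-shifted), not fits to measured histograms.

All randomness flows through `numpy.random.default_rng(seed)`; seeded runs
are bit-reproducible. Consequently, passing tests demonstrate correctness
of the statistics and fits *under the stated generative assumptions*; they
do not certify performance on real images with correlated noise or
non-disk morphologies.

## Numerical choices

- Binomial pmfs/tails via scipy's exact implementations; pmf normalization
  holds to 1e-12 up to nA = 10⁴.
- ODE integration: RK45 at rtol 1e-10 (checked against the closed form at
  rtol 1e-6).
- Curve fits: `scipy.optimize.curve_fit` with physical bounds; convergence
  failures raise a diagnostic error carrying residuals rather than
  returning silently bad parameters.
- Area fractions: shapely unions at 256 segments/circle (relative error
  ~1e-4), clipped to the field; `s` is capped at 1.
- Problem sizes in the self-checks (1000 null fields + 200 power fields,
  9 fusion-like curves, 200×500 particle-mode walkers, 15 drops) match the
  study designs they emulate while keeping a full run in tens of seconds.

## Known limitations

- The bridge model treats bridges as identical, independent and permanent;
  formation/closure dynamics, cargo selectivity and spatially resolved ER
  diffusion are not modelled.
- `τ_bulk` requires the droplet radius `R` (or explicit bounds); the
  package reports `τ_bulk(R)` rather than asserting a universal value.
- The Harkins–Brown bridge below `x = 0.30` is smooth interpolation toward
  the Tate limit (see above).
- The colocalization null assumes circular objects and ignores the slight
  edge bias introduced by keeping foci fully inside the field (< 1%
  relative on `s` for the default geometry, far below the Monte-Carlo
  tolerance used to validate it).
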