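# Methods

This note documents the models implemented in `icespec`, the defaults
and their rationale, the synthetic-data generator's scope, and the
numerical choices that matter for reproducing results. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Droplet-freezing assay statistics (`icespec.assay`)

A droplet assay is an event table (droplet id, cycle, freezing
temperature, frozen flag) plus protocol metadata: droplet volume *V*
(default 3 µL), solute mass concentration *C*m (default
10 mg mL⁻¹), cooling from 0 to −30 °C at 1 °C min⁻¹. Temperatures are
signed Celsius throughout and "increasing" always means in the cooling
direction.

Conventions, chosen once for determinism:

* `f_ice(T)` counts droplets frozen **at or above** `T` (closed at the
  warm end); ties at a grid temperature count as frozen. The curve is
  then right-continuous in cooling order and invariant to grid
  refinement at shared points.
* The default grid steps 0.5 °C — finer than the ±0.2 °C temperature
  uncertainty of typical IR-camera droplet instruments, so the grid
  never limits precision.
* `T50` interpolates linearly between the two grid points bracketing
  `f_ice = 0.5`; if the curve sits at exactly 0.5 over a plateau the
  warmest plateau point is reported. A curve that never reaches 0.5
  raises a dedicated exception rather than returning a sentinel value.
* The Vali inversion `N_m = -ln(1 - f_ice)/(V C_m)` assumes sites are
  Poisson-distributed over droplets. Saturated grid points
  (`f_ice = 1`) are excluded from the spectrum, with a log note: the
  inversion diverges there and a finite assay cannot constrain it.
* The differential spectrum interpolates `N_m(T)` with a cubic
  B-spline, differentiates analytically with respect to decreasing
  temperature, and smooths with a Savitzky–Golay filter of polynomial
  order 1 over a 3-point window. `n_m` is a density, so negative
  filter output is clipped to zero and counted; more than 10 % clipped
  points triggers a warning that the input is too noisy for the
  window. The first-order filter preserves linear trends exactly but
  slightly broadens sharp peaks (a few percent at the shoulders of a
  1.5 °C-wide Gaussian); peak locations are preserved to well under
  the 0.2 °C tolerance used in the tests.
* Freeze–thaw cycle comparisons pair droplets frozen in both cycles
  and report the mean temperature shift, the Spearman rank correlation
  (persistence of per-droplet freezing order), and the mean shift
  restricted to the warmest and coldest quartiles of first-cycle
  temperatures. The quartile-resolved shifts are this package's
  reconstruction of per-droplet freeze–thaw statistics; the exact
  statistic used in published per-droplet analyses varies.

## Mixture deconvolution (`icespec.hub`)

The underlying distribution of site characteristic temperatures is a
Gaussian mixture: components (weight `c_i`, mode `T_mode,i`, spread
`s_i`), weights summing to 1, plus a total site density `n_tot`
(sites per mg). The forward model couples it to the observable through
Poisson statistics:

```
F_u(T)   = Σ_i c_i · Φ((T_mode,i − T)/s_i)        (site survival)
f_ice(T) = 1 − exp(−V · C_m · n_tot · F_u(T))
```

Fitting minimizes the squared mismatch between this forward curve and
the measured curve on its own grid, in `f_ice` space (differentiating
first into `n_m` space would amplify counting noise). The optimizer is
seeded differential evolution (population 15×dim, Sobol
initialization, up to 400 generations, L-BFGS-B polish) with 5
restarts by default; the best restart wins and components are reported
warmest first. Bounds: modes in [−38, 0] °C (homogeneous limit to
melting), spreads in [0.05, 5] °C, weights through a stick-breaking
parameterization that keeps the simplex constraint exact, and
`log10 n_tot` in [−2, 8] unless `fixed_n_tot` pins it (useful when the
plateau of `N_m` is measured independently). Model selection over
p = 1–3 components takes the lowest mean squared error with a
parsimony tie-break (smaller p, then lower seed).

Two estimator details matter and were validated by parameter-recovery
simulation against the generator (not against any external value):

* **Weighting.** The binomial sampling variance of an empirical
  frozen fraction collapses near 0 and 1, so the default objective
  weights each grid point by the inverse of its estimated variance
  (with a +1/+2 pseudocount keeping weights finite). This sharpens
  recovery of minority modes whose signature lives in the nearly
  saturated part of the curve. The plain unweighted objective remains
  available (`weighting="uniform"`), and the `mse` reported in a fit
  result is always the unweighted one.
* **Background guard.** The mixture model does not describe
  instrument-background (pure water) freezing. When a measurable
  fraction of droplets freezes near the background temperature,
  `FitSettings.t_min` excludes the cold end of the grid from the
  objective; otherwise the coldest component chases the background
  rise.

**Identifiability.** The warm flank of each well-populated mode is
sharply identified. Modes that only a small minority of droplets
report are intrinsically soft: with λ expected sites per droplet and
equal weights, only ~exp(−λ/2) of droplets lack all warm sites and
freeze through the cold pathway (λ = 10 leaves ~5 droplets in 768).
A per-droplet maximum-likelihood estimator — the information-theoretic
bound — was simulated for these conditions and still shows
several-tenths-of-a-degree scatter for such modes, so this is a limit
of the study design (a single saturated assay), not of the optimizer;
real campaigns resolve it by serial dilution. The parameter-recovery
tests at reference conditions reflect exactly this: warm modes recover
within ±0.3 °C across seeds, cold modes do not.

## Classical nucleation theory for finite patches (`icespec.hint`)

The nucleus is a spherical cap on a square ice-binding patch of side
`L`, mapped to an equivalent-area circular footprint
(`R = L/√π`) so the cap geometry stays closed-form. Binding strength
enters as the interfacial free-energy reduction Δγ_bind through

```
cos θ = 2·Δγ_bind/γ(T) − 1,
```

an affine map chosen so that zero binding gives θ = 180° and exactly
the homogeneous barrier `16πγ³/(3Δμ_v²)`, and maximal binding
(Δγ_bind = γ) gives perfect wetting. Binding may be specified
absolutely (J m⁻²) or as a fraction of the temperature-dependent γ;
"strong" binding is the 0.95 fraction.

The barrier on a finite patch is the maximum over the growth path:

* while the cap footprint fits (`R ≥ r*`, with critical radius
  `r* = 2γ/Δμ_v`), the classical heterogeneous barrier
  `f(θ)·16πγ³/(3Δμ_v²)` applies;
* on smaller patches the contact line pins at the patch edge and the
  nucleus must bulge through a pinned spherical-cap saddle with
  curvature radius `r*` and apparent angle `ψ* = π − arcsin(R/r*)`,
  whose closed-form energy rises continuously toward the homogeneous
  (full-sphere) barrier as `R → 0`.

The implementation takes the larger of the two saddles; the tests
cross-check it against a brute-force scan of the free energy over
nucleus height on the fixed footprint. The rate is
`J(T) = A₀ · D(T)/D(0 °C) · exp(−ΔG*/k_B T)` and `T_het` solves
`J = J_exp` by bisection to 0.01 °C (verified against a 0.005 °C
temperature scan). `J_exp` defaults to 10⁵ cm⁻³ s⁻¹, the detection
condition of a ~1 °C min⁻¹ ramp; both it and `A₀` (default
10³⁷ cm⁻³ s⁻¹) only enter logarithmically — a tenfold change moves
`T_het` by roughly a degree.

Water property parameterizations (all overridable per model object):

| quantity | form | defaults | basis |
|---|---|---|---|
| Δμ(T) | ΔH_m(1−T/T_m) − Δc_p[(T_m−T) − T ln(T_m/T)] | ΔH_m = 6010 J mol⁻¹, Δc_p = 37.7 J mol⁻¹ K⁻¹ | integrated heat-capacity difference; within 10 % of the dilute limit ΔH_m·ΔT/T_m at −12 °C |
| D(T) | Vogel–Fulcher–Tammann D₀ exp(−B/(T−T₀)) | D₀ = 4.14×10⁻⁸ m² s⁻¹, B = 347 K, T₀ = 177 K | reproduces ~2.3×10⁻⁹ m² s⁻¹ at 25 °C and the steep supercooled slowdown |
| γ(T) | γ₀ + slope·T_C | γ₀ = 29.5 mJ m⁻², slope = 0.09 mJ m⁻² K⁻¹ | anchored near 30 mJ m⁻² at 0 °C; slope set so the zero-binding limit of the solver lands at −36.5 °C, inside the expected homogeneous band (−35 to −38 °C) for 3 µL-scale detection |

These coefficient sets are this package's calibration choice; no
single published set is canonical for all three quantities, which is
why they live in config. With them, a strongly binding patch reaches
−12 °C at L ≈ 6.5 nm, the size-activity curve rises steeply below
~18 nm, and patches ≥ 30 nm are indistinguishable from unbounded
surfaces (< 0.1 °C).

## Solubility and regimes (`icespec.solubility`)

The van't Hoff fit is exact linear least squares of ln S on 1/T
(slope −ΔH_sol/R, intercept ln S₀): closed-form, reproducible, and
exact on noiseless data, with residuals orthogonal to the design.
Conversion to mg mL⁻¹ is `C = S·10·ρ` with ρ = 1 g mL⁻¹ for water.
Regime classification over a freezing range (default 0 to −22.5 °C,
ramp start to pure-water background; an assay's empirical span can be
substituted): supersaturated if C exceeds saturation at the warm end,
solubility-critical if the saturation curve crosses C inside the range
(crossing located by Brent root-finding far below the 0.01 °C
requirement), undersaturated otherwise.

The shipped reference fit for phloroglucinol (S₀ = 7×10⁷ wt%,
ΔH_sol = 42 460 J mol⁻¹ ≈ 10.15 kcal mol⁻¹) gives ~2.5 wt% ≈
25 mg mL⁻¹ at 25 °C, noticeably above the ~12 mg mL⁻¹ sometimes quoted
for room temperature; the package treats the van't Hoff parameters as
authoritative for all computations and leaves the discrepancy to the
data source rather than reconciling it. Near the cold end the 1 mg
mL⁻¹ case is numerically marginal (saturation ≈ 0.99 mg mL⁻¹ at
−22.5 °C), so regime statements in the tests are made for ≥ 5 mg mL⁻¹.

## Synthetic assays (`icespec.simulate`)

Each droplet draws `K ~ Poisson(λ)`, `λ = n_tot·C_m·V`, site
temperatures from the mixture, and freezes at max(warmest site,
background), where the background is normal(−22.5, 0.4 °C) truncated
to the ramp — the 0.4 °C spread is a modeling choice (instrument
background width is rarely reported). λ above 10⁷ is rejected as an
unphysical load. Freezing temperatures are recorded continuously;
`bin_to` optionally rounds to a detection granularity. The generated
maxima follow `P(freeze ≥ T) = 1 − exp(−λ F_u(T))` within
Kolmogorov–Smirnov distance 0.05 at 768 droplets (tested over seeds).

The default population — equal-weight modes at −7.8 and −12 °C with
1 °C spreads and λ = 10 at 3 µL / 10 mg mL⁻¹ — represents a fresh
solubility-critical solution with coexisting crystal-surface (warm)
and aggregate (cold) nucleator classes. Transforms:

* **aging** (default shifts −1.1 / −3.2 °C, retained fractions
  0.44 / 1.0): modes move colder and the warm subpopulation loses 56 %
  of its site density;
* **freeze–thaw**: removes a fraction of the warmest component's
  density and boosts the coldest component's;
* **recovery**: adds back a fraction (default 19 %) of the warm
  component, *relative to its current density* — the reference
  amplitude for "restored" activity is a convention this package fixes
  explicitly.

After any transform, component site densities stay non-negative and
sum to the declared total; weights are renormalized exactly. With
`memory=True` (default) droplets keep their site sets across cycles
and transforms act per site (Bernoulli thinning, temperature shifts,
Poisson additions with the matching marginal), which produces the
rank-correlated paired statistics a real freeze–thaw series shows;
`memory=False` redraws sites each cycle.

What the generator does **not** emulate: droplet-volume
polydispersity, spatial plate effects, freezing-point depression of
the solution, detection dead time, and any chemistry (pH, tautomerism,
oxidation kinetics) beyond its parameterized population shifts.
Passing tests therefore demonstrate the statistical chain is correct
under Poisson site sampling — not that any particular real substance
follows these population dynamics.

## Problem sizes and reproducibility

All stochastic components (generator, optimizer restarts) are seeded;
identical configurations reproduce outputs bit-for-bit. The recovery
studies in the tests and the acceptance script use 768-droplet assays,
10 seeded replicates per population state, and 5 optimizer restarts
per fit — sizes chosen to match the reference freeze–thaw assay layout
(two 384-well plates) while keeping a full study in the minutes range
on one CPU. `scripts/acceptance.py --seed N --out results.json`
derives every internal seed from `N`.

## Known limitations

* Mixture components are Gaussian only; no posterior uncertainty is
  attached to fitted parameters (seed-to-seed scatter across restarts
  and replicates is the provided proxy).
* Minority-mode locations from a single saturated assay carry
  several-tenths-of-a-degree uncertainty regardless of optimizer (see
  Identifiability above); dilution series are the experimental remedy
  and can be emulated by varying `mass_concentration`.
* The pinned-cap CNT model treats one circular patch on a flat
  surface; wedges, pores and multi-patch cooperativity are out of
  scope.
* The van't Hoff model ignores activity coefficients and hydrate
  phases; regime boundaries near a solution's own saturation point
  inherit the fit's uncertainty.
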