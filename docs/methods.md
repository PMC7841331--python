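# Methods

## Model and assumptions

The package implements a bilinear compartment model of tumor growth under
chemotherapy, coupled to a one-equation pharmacokinetic (PK) model and a
static pharmacodynamic (PD) effect function:

    dN/dt = [A + s(c) B] N          N(0) = N0
    dc/dt = -(k1 + k2 u) c + h u    c(0) = 0

`N` is the vector of cell counts per cell-cycle compartment, `A` the
intrinsic flow/growth matrix (1/time), `B` the drug-effect coupling
(1/(time·effect)), `u(t)` the non-negative dose, `c(t)` the plasma
concentration. The PK equation has first-order clearance `k1 > 0`, infusion
gain `h > 0`, and a dose-dependent clearance coupling `k2` of unrestricted
sign: positive `k2` saturates the concentration, negative `k2` models drugs
whose elimination weakens as dosing continues, producing a growing
concentration regime. The effect function is either the Emax model
(`hill_k` forced to 1) or the sigmoid Hill form; both are
`s(c) = E0 + Emax c^k / (EC50^k + c^k)`.

Two structural facts drive much of the analysis and are worth stating
explicitly:

* the concentration equation is autonomous from `N`: nothing downstream of
  `c` (A, B, E0, Emax, EC50, hill exponent) can influence `c(t)`;
* the tumor equation is linear in `N` at fixed `c`, so trajectories scale
  with `N0`. `N0` defaults to 1 per compartment (arbitrary units) since the
  reference configuration does not pin it down.

The effect scale is used exactly as configured: with `Emax = 100` the effect
feeding `s(c)B` ranges over `[0, 100)`, not `[0, 1]`. A normalized-effect
convention exists in the literature; the package follows the configured
magnitudes and leaves any rescaling to the user, since `B` and `s` only
enter through their product.

## Numerical choices

Integration uses SciPy's adaptive explicit Runge-Kutta 4(5) with
`rtol = 1e-8`, `atol = 1e-10`; the system is non-stiff at the reference
parameters. Trajectory rows live on a uniform reporting grid (default
spacing 1 time unit over `[0, 500]`), decoupled from solver steps. A guard
event aborts with a diagnostic naming the divergent state if any variable
exceeds `1e12` in magnitude (reachable with strongly negative `k2`). The
horizon default of 500 time units matches the reference experiments; the
oscillation-to-plateau transition of the baseline is complete well within
it.

The LTI oracle `closed_form_lti` evaluates
`x(t) = e^{At}[x0 + ∫ e^{-Aτ}B u(τ) dτ]` with the matrix exponential and
adaptive quadrature; it independently cross-checks the simulator wherever
the dynamics are linear (e.g. `k2 = 0`).

The objective is evaluated by composite trapezoid on the reporting grid
(the integrand is smooth and the grid uniform), with composite Simpson
available as a cross-check; the two agree to ~1e-5 relative on reference
trajectories, and a 10× finer trapezoid oracle to 1e-3. Weights enter
linearly, so term-wise evaluation is exact by construction.

Numerical rank in the Kalman test uses the standard singular-value
threshold `max(dim) · eps · σ_max` unless overridden. The bilinear model is
not LTI; `linearize` produces the Jacobian system about a reference
`(N*, c*, u*)` — a package-added convenience, validated against finite
differences, and explicitly a local approximation.

## Sensitivity analysis

Latin hypercube sampling (`scipy.stats.qmc.LatinHypercube`) draws one point
per equal-width stratum per parameter, uniformly within strata,
deterministically per seed. Default ranges for the six varied parameters:
`k1 ∈ [0.001, 0.01]`, `k2 ∈ [0, 0.01]`, `h ∈ [0.001, 0.01]`,
`hill_k ∈ [1, 5]` (rounded to integer), `A, B ∈ [0.001, 0.01]`;
`n_samples` defaults to 100. The output variable is `c(t)`; because it is
autonomous from `N`, it is integrated alone, which both halves the cost and
makes the insensitivity of `A`, `B` and the Hill exponent exact rather than
approximate: identical solver inputs give identical output, so their
envelope widths are identically zero.

No named summary statistic was prescribed for ranking, so the package
defines the one-at-a-time score as the time-integrated envelope width
(max − min across draws) divided by the time-integrated baseline curve — a
direct numerical transcription of comparing band widths in an envelope
plot. Envelope bands report pointwise min, 5%/95% quantiles, mean, median,
max; 5%/95% were chosen as conventional robust band edges. For the joint
three-parameter envelope the parameters `k1, k2, h` are varied together;
for ranking, one at a time. Individual simulation failures under extreme
draws are excluded with a warning and counted, not fatal.

## Scenarios and their recorded assertions

Five registered scenarios regenerate all inputs internally and write
CSV + JSON summaries; their qualitative assertions are recorded in the
summary rather than raised, so runs always leave inspectable output.
The `k2` sweep grid (25 points, log-spaced over `[1e-4, 1e-2]`) was chosen
to span the sensitivity range's upper bound from a decade below the
reference value.

Two recorded diagnostics deserve caveats:

* **Plateau ratio.** The detector compares the sd of `c` over the last 20%
  of the horizon with the first 20% and flags a plateau below 0.1. At the
  reference parameters the measured ratio is ≈ 0.20 at every horizon
  (minimum ≈ 0.14 near t_end ≈ 2000): the periodic dose sustains a forced
  oscillation of sd ≈ 0.04 about the plateau level ≈ 1.09 that never decays,
  so the late curve is flat only relative to the initial rise, not
  absolutely. The summary records the measured ratio either way.
* **Late monotone increase (negative k2).** The dose vanishes exactly at
  every trough of the cosine schedule, where `dc/dt = -k1 c < 0` regardless
  of `k2`; the growing-concentration regime therefore always retains small
  dips (≈ −0.02 per time unit against a mean rise of ≈ +0.03). Strict
  non-decrease on the late half of the grid is thus unattainable by
  construction; the recorded value is the most negative late increment, and
  the robust statement — the negative-`k2` final concentration exceeds the
  positive-`k2` one by ≈ 2.8 — is asserted separately.

The dose-synchrony diagnostic cross-correlates detrended `c` and `u` over
the first 100 time units; the peak lag is accepted when non-negative and at
most a quarter dose period (≈ 16 time units), the maximum phase lag a
first-order system can exhibit.

## What the generator does and does not emulate

All inputs are synthetic by design: the study conditions are parameter sets
and schedule forms, not measured data. The generator reproduces those
conditions exactly (parameter values, cosine dosing, unit weights, ranges,
100-sample LHS). It does not emulate measurement noise, inter-individual PK
variability, delayed or saturable drug effects, or resistant subclones —
passing tests therefore validate the mathematics and the implementation,
not the biological adequacy of this model class, whose insensitivity to the
compartment parameters is itself a documented limitation of the model
family.

## Known limitations

* Single-drug control only; the multi-drug bilinear form with per-drug
  coupling matrices is out of scope.
* No optimal-control synthesis: the objective is evaluated on given
  schedules, never minimized.
* Controllability is assessed on linearizations only; no time-varying
  Gramians, no observability analysis.
* Sensitivity is range/envelope based; no variance-based (Sobol) indices.
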