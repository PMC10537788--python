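# Methods

This note documents the models, estimators and design choices behind
`sprintmech`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Sprint velocity model and profile estimation

Sprint acceleration is modelled as mono-exponential with a free trigger
delay,

    v(t) = vmax (1 − exp(−(t − t0)/τ)),  t ≥ t0;  v = 0 before t0,

the de-facto model beneath field force–velocity methods. `vmax` (m/s) is
the asymptotic speed, `τ` (s) the acceleration time constant, `t0` (s) the
delay between the radar trigger and first movement (instrument artifact,
typically 0–0.4 s). The fit uses trust-region nonlinear least squares with
an analytic Jacobian and a multi-start grid (τ ∈ {0.8, 1.2, 1.6} s,
t0 ∈ {0, 0.1, 0.2} s relative to the first sample, plus a data-driven
start at the 63.2%-of-peak time) to avoid local minima; tolerances are set
to 1e−14 so noise-free traces are recovered to ≲1e−6 relative. Times are
internally re-zeroed at the first sample, so adding a constant to all time
stamps only shifts the reported `t0`. Degenerate traces (near-zero speeds)
and non-convergent fits raise a fit-failure error carrying the best
residual sum of squares seen.

Forces are evaluated on the *analytic* model at 1 kHz from motion onset
until the speed reaches 99.9% of `vmax`, rather than by differentiating
noisy samples: `aH(t) = (vmax − v)/τ`, `FH = m aH + k (v − vw)²`,
`FV = m g`, `FRes = √(FH² + FV²)`. The ratio of force
`RF = 100 FH / FRes` and its slope against speed (DRF) are restricted to
t > 0.3 s after onset, excluding the start-push phase where the ratio is
not meaningful.

The aerodynamic coefficient uses the Du Bois body-surface scaling:
`ρ = 1.293 (P/760)(273/(273+T))` kg/m³, frontal area
`Af = 0.266 (0.2025 h^0.725 m^0.425)` m², drag coefficient `Cd = 0.9`,
`k = ½ ρ Af Cd`. Every component is overridable and `k = 0` is supported
(it makes the F–v relation exactly linear, the closed-form limit used
throughout the tests: F0 = vmax/τ, V0 = vmax, Pmax = vmax²/(4τ)).

The F–v line is fitted by least squares over modelled samples with speed
between 30% and 95% of the peak and t > 0.3 s — below 30% the start-push
exclusion dominates, above 95% the near-asymptotic tail (aH ≈ 0) would
swamp the line with zero-information points. With drag, the relation is
slightly convex and `V0` exceeds the asymptote `vmax` by roughly
`k vmax²/(m |Sfv|)` (~0.3–0.4 m/s for these athletes); both `V0` and the
measured peak speed are reported and kept distinct, since squad means of
the two differ by just this offset.

Split times invert the closed-form position
`x(s) = vmax s − vmax τ (1 − e^(−s/τ))` by bisection to |Δx| < 1e−6 m and
are reported relative to motion onset `t0`, not the radar trigger: athletes
start from a standing start, and the trigger delay is instrument artifact.
Wind defaults to 0 m/s (indoor testing).

## Deceleration phase

In a sprint-then-maximal-stop trial the deceleration phase starts
immediately after peak speed and ends at the lowest speed that follows.
The early-deceleration metric is the secant slope from the peak to the
instant speed first reaches 50% of the peak; decelerations are negative
internally, and the report layer prints magnitudes (the convention used in
reference tables).

Landmark detection on noisy radar data needs care. The trace is smoothed
with a centered moving average (default window 5 samples; 'valid' mode so
edges are not biased). The smoothed maximum gives the peak *level*. The
peak *time*, however, cannot be the smoothed argmax: near the end of a
30 m sprint the speed curve rises only ~0.15 m/s² while smoothed noise has
sd ~0.2 m/s, so the argmax of a noisy trace scatters hundreds of
milliseconds before deceleration actually begins and the secant
denominator inflates, under-reporting |deceleration| by 20–30%. Instead,
the least-squares line of the smoothed deceleration limb (samples between
55% and 92% of the peak level) is extended back to the peak level; its
crossing is the peak time. A second pass refits the line excluding samples
within one smoothing window of the estimated corner, because the moving
average smears the corner and flattens the first few limb samples (a bias
that grows with the deceleration rate). Since both secant endpoints then
sit on the deceleration line, over-estimation of the peak level by the
noise maximum cancels, and planted constant decelerations of −2 to
−5 m/s² are recovered with median bias ≤ ~2.5% at instrument noise. The
50% crossing is linearly interpolated between the straddling smoothed
samples. A regression-slope variant (`method="regression"`, the limb
line's own slope) is available; for a constant deceleration both
definitions coincide.

## Determinant analysis

The feature table holds twelve mechanical predictors per athlete —
relative and absolute F0, measured peak speed, theoretical V0, relative
and absolute Pmax, F–v slope, RFmax, DRF, early deceleration, body mass,
stature — and one target (5/15/30 m split or change-of-direction time).
The predictor order deliberately places relative F0 and measured peak
speed first: the collinearity filter scans columns in declared order and
removes the *later* member of any pair with |Pearson r| > 0.8 (iterating
until clean, constant columns dropped with a warning), so the predictors
of primary interest survive when their absolute/theoretical variants are
near-duplicates.

The fitting pipeline is: filter → single seeded 80/20 train/test split →
standardize on training rows only (population-sd convention) → fit OLS,
Ridge and Lasso. Ridge/Lasso penalties are chosen by five-fold
cross-validation *inside the training rows* over
[0.0001, 0.001, 0.01, 0.1, 1, 10], minimizing mean validation squared
error, with scaling refit inside every fold (no leakage; the test rows
never influence any fitted quantity, which the suite verifies by
perturbing held-out rows). All families are refit on the full training set
and scored on the held-out rows (R², MAE, MSE, RMSE); the candidate with
the highest test R² is flagged selected, ties broken by fewer nonzero
coefficients and then by preferring the penalized families over OLS.
Coefficients are reported on both the standardized and the raw scale,
because published equations in this literature mix the two. Residual
diagnostics are Shapiro–Wilk (normality) and Breusch–Pagan
(homoscedasticity, squared residuals on predictors) at the 0.05 level.

A caution on small-squad test R²: with 26 athletes the held-out set has
~6 rows, and R² = 1 − SSres/SStot divides by the test-set variance, a
χ²₅-scale random quantity. Under a null (feature-independent) outcome the
selected-model test R² therefore has a heavy left tail — single splits
can produce R² below −2 — so its *mean* across replicates is unstable and
systematically well below zero (≈ −0.4 across 100-seed batches), while
its *median* is a stable ≈ −0.1. Median or large-test-set summaries should
be preferred when characterizing null behaviour at this sample size.

## Synthetic-data generator

The generator emulates one testing session of an elite female
field-hockey squad. Defaults, chosen once from published squad
descriptives: n = 26 athletes; asymptotic speed 7.93 ± 0.47 m/s; time
constant 1.39 ± 0.09 s (mean set to V0 over relative F0, 7.93/5.72; sd
set so the induced F0 = vmax/τ spread matches the published 8.6% relative
sd given vmax's 5.9%); trigger delay 0.2 ± 0.05 s; body mass
63.1 ± 5.3 kg; stature 1.662 ± 0.041 m; deceleration −3.37 ± 0.87 m/s².
Parameters are drawn independently per athlete and truncated at
physiological floors (vmax ≥ 4 m/s, τ ≥ 0.5 s, deceleration ≤ −0.5 m/s²,
…) by resampling rather than clipping, keeping distributions smooth.
Change-of-direction times are drawn at 9.28 ± 0.30 s independent of the
mechanical parameters (the null design).

Radar acquisition is emulated as uniform sampling at 46.9 Hz with i.i.d.
zero-mean Gaussian speed noise of sd 1.61/3.6 ≈ 0.447 m/s (the
instrument's stated accuracy converted from km/h), clipped at zero. The
deceleration trial runs the sprint model to the 30 m mark (located on the
noise-free position function) and then decays speed linearly at the
planted rate to a floor. Outcome vectors are planted as
`y = intercept + Σ w·feature + N(0, σ)`; an empty weight map gives the
pure-noise null. Every generator is a pure function of its spec and seed.

What the generator does *not* emulate — and therefore what passing
recovery tests cannot show about real data: step-to-step speed
oscillations and gait events, radar panning/aiming error and dropouts,
deviation of real braking from a constant rate, wind, fatigue across
trials, and any true mechanical coupling between change-of-direction
ability and the sprint profile.

## Problem sizes and numerical choices

Recovery studies use 200 seeded traces (noise robustness, deceleration),
100 replicate cohorts of n = 26 (planted-coefficient and null regression
studies; features derived through the analytic noise-free profile path,
which isolates the regression stage from trace-fitting noise), and 5×5
parameter grids spanning the published inter-quartile ranges for the
closed-form and split-time checks. Bisection tolerances are 1e−6 m in
position; profile grids run at 1 kHz; fit tolerances at 1e−14. Quantiles
use linear (type-7) interpolation; descriptive SDs use the n−1
denominator, standardization the population convention. Ties in
`best_of` go to the earliest attempt.

## Known limitations

* The mono-exponential model ignores the very first push and any
  speed decay at the end of long sprints; split times assume it holds
  exactly beyond the fitted range.
* The aerodynamic model is a rough static estimate (fixed Cd, frontal
  area from mass and stature); errors in k fold directly into F0 at high
  speeds, though their effect at these speeds is small (~0.25 N/kg).
* Early deceleration summarizes the stop as one secant; real braking is
  not constant-rate, and the regression variant will differ on curved
  decays.
* With 26 athletes the determinant analysis is descriptive, not
  inferential: test-set R² on ~6 rows is noisy (see above), and no
  multiple-testing correction is applied across targets.
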