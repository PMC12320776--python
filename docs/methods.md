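# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `sharkescape`. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
acceptance script, not asserted from elsewhere.

## Respirometry and aerobic scope

Intermittent-flow respirometry records dissolved oxygen (DO, mg l⁻¹) in a
closed chamber every 2 s during 5-min measurement phases separated by 10-min
flushes, for 24 h post-exercise: 96 measurement windows × 150 samples =
14 400 readings. Each window's OLS decline slope *b* (mg l⁻¹ s⁻¹) converts
to a whole-animal uptake rate

    MO2 = −b · V_eff · 3600        [mg O₂ h⁻¹]

where `V_eff = chamber volume − body mass / ρ` is the effective water volume
(ρ = 1 kg l⁻¹; the subtraction is standard practice and configurable —
background microbial respiration is assumed zero, with a blank-correction
hook left to the caller). Rates are allometrically standardized to a 1-kg
animal with mass exponent 0.89 (mg O₂ h⁻¹ kg⁻⁰·⁸⁹); because a trial involves
one animal, scaling before or after any extremum search is equivalent, and
it is applied last.

* **MO2Min** — mean of the `ceil(0.10 n)` smallest per-window determinations
  (ties broken by window order; at least 10 determinations required, since
  the lowest-10% rule is undefined for tiny trials).
* **MO2Max** — steepest OLS slope over every 30-s sub-window (15 samples at
  2 s), advancing one sample at a time, confined to single measurement
  windows (a slope spanning a flush is physically meaningless) and to the
  first four windows, i.e. the first hour post-exercise.
* **AAS** = MO2Max − MO2Min. A negative scope is flagged, never dropped.

Exclusions: sharks flagged for bent posture, equilibrium loss or death are
removed before analysis; the filter reports per-group retained counts and
trusts per-shark flags rather than reconciling any aggregate bookkeeping.

## Thermal performance curves

AAS as a function of test temperature is fitted with two families:

* Gaussian: `f(T) = a·exp(−½((T − T_opt)/σ)²)`
* Quadratic: `f(T) = c0 + c1·T + c2·T²`

by nonlinear least squares from 64 starting vectors drawn uniformly from
data-informed bounds (`a ∈ [0.5, 1.5]·max AAS`, `T_opt ∈ [min T − 2,
max T + 2]`, `σ ∈ (0.1, 10]`; the optimizer itself is allowed slightly wider
box bounds so the best fit is not clipped to the start region). The lowest
converged RSS wins; the draw is deterministic per seed. Model comparison
uses the least-squares AICc convention

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1),  k = #curve params + 1,

counting the error variance in *k*; both families have k = 4 here, so the
AICc difference reduces to `n·ln(RSS ratio)`. Ties go to the first-listed
model. With only three distinct test temperatures the optimum is exactly
identified but fragile; the fit succeeds with an explicit warning. A
further consequence of that design: any three-parameter family that can
pass through the three group means attains the same minimal RSS, so at
exactly three temperatures the Gaussian and quadratic AICc values coincide
up to optimizer tolerance and selection rests on the tie rule (the Gaussian
is listed first as the mechanistically sensible family). Distinguishing the
families by information criteria requires four or more test temperatures.

Derived parameters: peak AAS, its temperature, and the performance breadth —
the width of the interval where the curve stays ≥ 80 % of its peak (the
fraction is a parameter). For the Gaussian the crossings are closed-form,
`T_opt ± σ·√(2 ln(1/0.8))`; a bracketed Brent root-finder provides an
independent check (agreement < 10⁻⁸ °C, asserted in tests).

Uncertainty comes from a residual bootstrap: replicates `y* = ŷ + resampled
residuals`, each refitted from the point estimate as single start (999
replicates by default; an error is raised if more than 20 % fail). Intervals
are bias-corrected and accelerated (BCa): the bias term z₀ is the normal
quantile of the fraction of draws below the point estimate, the acceleration
is estimated by a delete-one jackknife over observations. With zero
residuals the interval collapses to the point estimate; with symmetric draws
and z₀ = a = 0 it reduces to the percentile interval (both asserted).
Because each shark contributes one AAS value, per-observation and per-shark
residual resampling coincide.

Group contrasts use Welch two-sample t-tests (variance homogeneity is not
assumed) with Holm–Šidák step-down adjustment, `p'₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^(m−i+1)`
with running-maximum monotonicity, and a compact-letter display built from
maximal cliques of the not-significantly-different graph.

## Escape kinematics

Tracks are frame-indexed head and centre-of-mass coordinates plus body-axis
angle at 240 fps. Choices that the raw definitions leave open:

* **Movement onset** — first post-stimulus frame whose head displacement
  from the median pre-stimulus position exceeds 3× the pre-stimulus jitter
  SD, floored at 1 mm (deterministic and noise-adaptive). Latency is
  `(onset − stimulus)·1000/fps`, truncated to 2 decimals (one frame at
  240 fps → 4.16 ms), hence always a frame multiple.
* **Derivatives** — Savitzky–Golay local quadratic over a 5-frame window
  (window exposed in config). Raw finite differences scale tracking noise by
  fps² in the second derivative and make acceleration maxima meaningless.
* **Stage boundaries** — Stage 1 ends at the first sign reversal of smoothed
  angular velocity sustained ≥ 2 frames; a subsequent contralateral
  excursion ≥ 10° marks a double-bend, otherwise the response is a
  single-bend. Single-bends are excluded from temperature regressions.
* **Maximal performance** — per-variable extremum over the three
  stimulations (minimum latency; maximum ω_S1, U_MAX, A_MAX), so variables
  may come from different trials.

Temperature effects are simple OLS regressions with temperature continuous;
latency is natural-log transformed (slope sign and F are base-invariant).
QC helpers: two-sided Grubbs test (at most one outlier per call; degenerate
zero-variance input is an error) and Bartlett's variance-homogeneity test.

## Submergence depth index

SDI = z/B (habitat water depth over caudal-fin height); below SDI = 3,
surface-wave drag takes a significant bite out of fast-start thrust. z is
habitat water depth (bottom-swimming assumption). Per-individual SDI is
evaluated on a 0.1–1.5 m depth grid in 0.01-m steps and fitted per life
stage by OLS with the intercept constrained to zero (SDI is identically 0 at
z = 0); the zero-intercept slope is then exactly the stage mean of 1/B, so
the critical depth is `3 / mean(1/B)` — slightly below `3·mean(B)` by the
harmonic-mean inequality, which is why a critical depth of 0.33 m is
consistent with a 0.1166-m mean fin height. An unconstrained-intercept
option is provided. The slope difference between stages is a partial F-test
of stage-specific against common slopes. The advantage band is the interval
between the newborn and adult critical depths; it errors rather than
returning an empty band when the ordering is violated.

## Diel thermal regime

Per site and month, hourly logger readings are averaged across loggers per
timestamp and pooled across years by hour-of-day. The 24-h cycle is a LOESS
smooth — tricube-weighted local polynomials with nearest-neighbour
bandwidth — fitted to the pooled raw records (pooling preserves the
dispersion structure the volatility index needs). Span and degree are chosen
by 5-fold cross-validated squared error over span ∈ {0.2, …, 0.9} × degree
∈ {1, 2}; candidates whose span cannot support a local fit are skipped and
logged. Hour-of-day is circular, so records within 6 h of the day boundary
are replicated ±24 h before fitting. The smoother is hand-rolled because the
CV grid requires degree-2 local fits; the degree-1 case is cross-checked
against an established lowess implementation in the tests.

Cycle parameters (mean, extrema, their hour-rounded times, range) come from
the smoothed curve on a 0.1-h grid. The volatility index is, per hour of
day, the SD of raw-minus-smoothed residuals signed by the mean residual
(positive = warming pressure). A standard deviation is non-negative, so any
signed construction is a convention; hours where the mean residual is within
2 SE of zero are flagged low-confidence rather than trusted. Overlap with
the aerobic-scope window is the fraction of the 24-h grid where the smoothed
cycle lies inside [lower, upper] 80 %-breadth crossings.

## Synthetic data: what it emulates, and what it does not

All generators are seeded and bit-reproducible; all noise is Gaussian (the
simplest testable choice — real optode drift, autocorrelated tracking error
and heavy-tailed temperature excursions are *not* modelled).

* **DO traces** — whole-animal uptake decays exponentially from a
  post-exercise maximum to a resting minimum, `MO2(t) = min + (max −
  min)·e^(−t/τ)`; within each window DO falls linearly at the
  window-averaged rate (matching the per-window linear-slope analysis), and
  each flush resets DO to ambient. Defaults — chamber 30 l, mass 0.85 kg,
  MO2 150→450 mg O₂ h⁻¹, τ = 1.5 h, noise 0.005 mg l⁻¹, ambient 6.8
  mg l⁻¹ — are chosen so the steepest window depletes ≤ ~1.3 mg l⁻¹, i.e.
  physiologically sane for a newborn reef shark; the noise magnitudes are
  placeholders, not measured values.
* **Escape tracks** — the centre of mass accelerates along a fixed heading
  at `accel` up to cruise `speed` while the body axis turns at a constant
  Stage-1 rate, optionally reversing through Stage 2; the first moved
  position appears exactly `latency_frames` after the stimulus so latency
  round-trips. Tracks are generated directly in corrected planar
  coordinates — no lens distortion, parallax or midline tracking.
* **Fin heights** — positive-truncated Gaussians; dispersion defaults are
  reconstructed from printed standard errors (SE·√n).
* **Temperature logs** — a time-warped cosine (dawn trough, mid-afternoon
  peak; the warp keeps the daily mean exact while placing both extrema at
  their observed hours), hour-wise Gaussian noise (default SD 0.4 °C), and
  warm spikes of fixed magnitude at a small per-record probability. Field
  cycles are asymmetric about the mean, so row-driven simulations
  parameterize amplitude as the peak excursion (max − mean): the simulated
  minimum is then symmetric rather than the observed one — acceptable
  because downstream recovery checks target mean, maximum and peak time.
* **AAS datasets** — Gaussian TPC truth (peak 317.10 at 29.15 °C, 80 %
  breadth 3.30 °C → σ ≈ 2.47 °C) at the 27/29/31 °C design with n = 9/8/8
  and observation noise SD 40, truncated at ≥ 0.

Passing tests on these data demonstrate correctness of the *procedures*
(windowing arithmetic, rolling-regression search, fit/bootstrap/selection
machinery, geometric identities) and statistical calibration under the
stated generative assumptions. They do not demonstrate robustness to the
messiness of real recordings (drift, missed frames, logger dropouts).

## Problem sizes and runtime choices

The heavier statistical checks use: 100 seeds for optimum recovery
(64 multistarts each), 200 simulated datasets for BCa coverage with 299
bootstrap replicates per dataset, 50 seeds for the kinematics round-trip,
20 traces for the rolling-regression oracle, and all 16 site × month rows
for diel-cycle recovery. These sizes resolve the tested proportions well
(e.g. a 90–99 % coverage band at n = 200 has Monte-Carlo SE ≈ 1.5 %) while
keeping the full suite to a few minutes on one core.

## Known limitations

* Three test temperatures identify the Gaussian optimum exactly but leave
  curvature poorly constrained; the fit warns accordingly, and bootstrap
  breadth intervals are wide.
* The BCa acceleration uses a jackknife over observations; with n = 25 the
  estimate is itself noisy.
* The volatility sign convention is one reading of "warming vs cooling"
  dispersion; alternative constructions (e.g. signed semi-deviations) would
  differ at low signal.
* Critical depths inherit the zero-intercept assumption; with an
  unconstrained intercept they become `(3 − intercept)/slope` and are no
  longer exactly `3/mean(1/B)`.
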