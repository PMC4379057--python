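# Methods

This note documents the models, estimators, numerical choices and
known limitations behind `plategrowth`.  It is written for users who
need to judge whether the defaults fit their instrument and organism,
and for maintainers who need to know why the pipeline is built the way
it is.

## Data model and preprocessing

A plate export is parsed into one OD time series per well, all on a
common time grid with times in hours from the first reading.  Wells
carry `Sample_Condition` labels split at the *first* underscore, so
samples may not contain underscores but conditions may
(`FY4_YPD_2%NaCl` → sample `FY4`, condition `YPD_2%NaCl`).  Medium-only
wells carry the reserved sample label `blank` (configurable) with the
condition naming their medium; this makes the background-reference set
W(blank, condition) computable from labels alone.  Temperature columns
are parsed and stored for provenance but never used in computation.

**Background correction.**  For each condition, the pointwise
arithmetic mean of its blank wells is subtracted from every well of
that condition, blanks included (so corrected blanks average exactly
zero at every time point).  Negative corrected values are retained —
clipping would bias blanks and early time points — but the fitting
machinery treats non-positive values as unusable.

**High-density correction.**  Plate-reader detectors saturate at high
cell density, so measured OD under-reports true OD.  A zero-intercept
cubic `f(x) = c1·x + c2·x² + c3·x³` is least-squares fitted to serial
dilution data (measured OD → dilution-inferred OD); the zero intercept
reflects that a blank-corrected reading of zero means no cells.  The
fit is rejected unless f is strictly increasing on [0, max measured];
the fitted-range maximum is stored and corrections beyond it are
flagged rather than refused.  Order of operations is fixed:
background-correct first, then calibrate, then smooth/fit.  The
simulation module inverts f numerically (bisection on the monotone
cubic) to emulate the detector, which makes the round trip
distort → calibrate testable to better than 1%.

## Growth-parameter extraction

**Windowed exponential fits.**  For every admissible window of
`window_omega + 1` consecutive points, `OD(0)·exp(μ·T)` is fitted by
least squares *in OD space* (Levenberg–Marquardt on the residuals with
an analytic Jacobian, parametrised as `exp(a + μ·(T − T₀))` so the
amplitude stays positive and well-scaled; a log-linear regression
provides the starting point).  Fitting in OD space rather than on log
OD matters: additive detector noise is homoscedastic in OD, and log
transformation would overweight the noisiest, lowest-OD points.  T is
absolute plate time, so the fitted OD(0) is the back-extrapolated OD
at time zero and the lag follows directly.

**Admissibility and sanity checks.**  A window is a candidate for
μ_max when all its values are positive, its midpoint OD is at least
`min_od_at_mu` (default 0.03 OD: below that, additive noise dominates
and local fits become unreliable) and its midpoint time lies inside
`mu_time_interval` when one is given.  μ_max is the maximum fitted μ
over candidates, ties broken by earliest midpoint; the implementation
enumerates every window, so it is definitionally identical to a brute
force.  The result is invalidated when μ_max ≤ 0, the fitted OD(0) is
non-positive, no window clears the OD threshold, or the winning window
sits at an endpoint of the time interval (no interior local maximum);
the last check can be demoted to a warning with `allow_at_cutoff`.

**Lag, doubling time, yield.**  The lag is where the winning
exponential crosses a baseline OD.  By default the baseline is the
median of the curve's first three processed values — with equal
inoculation volumes, starting ODs are nearly identical across wells
and are the natural baseline — and a fixed value can be configured.
Doubling time is ln 2 / μ_max.  The yield is the maximum OD among
points belonging to any window of `yield_window` hours (default 5)
whose regression slope is within `yield_slope_tol` (default
0.005 OD/h) of zero; "compatible with zero" is implemented as this
absolute threshold (a confidence-interval test would be the natural
alternative; the absolute threshold is transparent and deterministic).
Trailing window stubs shorter than half the requested duration are
ignored.  If no window qualifies the yield is undefined and flagged,
which does not invalidate the rate estimates.

**Smoothing.**  An optional centred moving average (window
`2·half_width + 1`, shrinking at the edges) is applied before fitting.
The default half-width is 2 (≈ 50 min at a 10–15-min cycle).  A moving
average multiplies a pure exponential by a constant, so it does not
bias fitted rates in exponential phase; what it does is damp the
low-OD noise that otherwise inflates the *maximum* over many noisy
windows — without it, slow growers (μ ≈ 0.2/h) acquire a selection
bias of up to +15–20% under realistic noise, and the recovery suite
fails its 10% band for several percent of wells.

**Replicates.**  Parameters are extracted per well; replicate groups
(same sample and condition) are then summarised by arithmetic mean and
unbiased (n−1) sample variance, with blacklisted and invalid wells
excluded and counted.  Fitness ratios divide each condition's mean
μ_max by the reference condition's, per sample.

## Chronological life span

The survival computation consumes lag and doubling times from the
outgrowth plates of successive age points:

* Δtₙ = lag(age n) − lag(initial age); may be negative, in which case
  survival above 100% is reported and flagged, never clamped.
* δ = arithmetic mean of the per-age-point doubling times (invalid age
  points excluded; if the initial point is invalid the curve errors —
  there is no reference).
* Sₙ = 100·2^(−Δtₙ/δ), exactly 100 at the initial age point.
* SI = trapezoid area under (Age, S), in %·days.

Age points whose growth fit failed are dropped (and reported), not
interpolated.  When per-replicate lags are available the replicate
spread of S is carried through as a standard deviation per age point.

**The common lag baseline.**  Lag *shifts* are only meaningful against
one shared baseline OD.  Beyond that requirement, where the baseline
sits is a free choice — outgrowth curves of the same strain are nearly
time-shifted copies, so Δt is invariant to it — but the *noise* of an
individual lag is not: extrapolating a fitted exponential to a
baseline a factor F away from the fitted window multiplies rate noise
by ln F, and at a baseline near the starting OD (≈ 0.01) an additive
error ε in the curve shifts the crossing by ε/(μ·OD) ≈ 40ε hours.
The aging pipeline therefore derives the baseline from the data: the
median OD at the time of μ_max, pooled over the sample wells of all
age points (a first extraction pass collects it, a second computes
lags against it).  This anchors the baseline where the rate is
actually measured, making the extrapolation lever arm near zero.

**Aging extraction defaults.**  Lag extraction for aging courses uses
`window_omega = 16` and `smoothing_half_width = 8` (exposed as
`AGING_CONFIG`), heavier than the plain growth defaults.  The
justification is specific to differences: the curve-shape bias that a
long window and strong smoothing introduce is shared by all age points
and cancels in Δt, while the noise damping directly steadies the
shifts.  The same settings would be inappropriate for reporting
absolute μ_max.

## The synthetic-data generator

Wells follow a shifted logistic
`OD(t) = K / (1 + ((K−N0)/N0)·e^{−r(t−t₀)})` for t ≥ t₀ (flat at N0
before), with defaults r = 0.5/h, N0 = 0.01, K = 1.2 and a 48-h run at
a 10-min kinetic cycle.  Observations add a medium background
(0.08 OD), a slow linear blank drift (0.01 OD over the run, an
evaporation proxy), optional detector saturation (the inverse cubic),
and noise `OD·(1+ε₁) + ε₂` with independent zero-mean Gaussians
(σ₁ = 2%, σ₂ = 0.002 OD).  All randomness derives from an explicit
seed.  Aging courses are generated by inverting the outgrowth logic:
viable fraction f at an age point delays that plate's lag offset by
δ_true·log₂(1/f), where δ_true = ln 2 / (r(1−N0/K)) is the analytic
doubling time at the start of growth; three replicate wells and two
blanks per age point emulate a typical course of biological
triplicates.

What the generator does *not* emulate: well-to-well spatial effects,
aggregation/sedimentation artifacts, diauxic shifts or respiratory
growth, biological lag variability between replicates (all replicates
of an age point share one lag offset), and condition-dependent medium
absorbance changes.  Passing recovery tests on these synthetics
therefore demonstrates the estimators' correctness and noise
robustness under the stated noise model, not robustness to every
artifact of real plates.  One consequence of the shared lag offset is
worth noting: at coarse kinetic cycles (≥ 15 min) all replicates of an
age point acquire the *same* quantization bias of the winning window
relative to the lag kink, which replication cannot average away; at
the default 10-min cycle the effect is small.

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` run two standing studies,
sized to complete in minutes on one CPU:

* **Growth recovery** — 96 logistic wells at 15-min sampling with
  r ∈ [0.2, 0.7]/h and lag offsets in [0.5, 3] h, generator defaults
  otherwise.  Noiseless: every μ_max within 5% of r, every lag within
  0.25 h of the analytic lag, every yield within 2% of K.  At default
  noise: ≥95% of wells within 10% on μ_max.
* **CLS recovery** — 20 independent aging courses with viabilities
  (100, 60, 30, 10, 3, 1)% at ages (2, 5, 7, 10, 12, 14) days;
  recovered Sₙ within ±5 percentage points per age point and SI within
  5% of the truth.

Residual CLS error decomposes into a small systematic part (the mean
doubling time δ̂ from heavily-smoothed windowed fits runs ~2–3% above
the generator's analytic value, contributing ~+1 point at mid-course
survival) and a noise part dominated by the initial plate's mean lag
error, which offsets every Δtₙ with the same sign.  With three
replicates and two blanks per plate the worst repetition in a 20-course
study typically reaches ~4 points and ~4% SI; occasionally an unlucky
course can push SI slightly past 5%.  More replicate or blank wells
shrink this tail in proportion.

## Numerical and format choices

* Times are stored in hours; exports carry seconds and are converted
  at parse time, with the plate's first reading as the origin.
* Ties for μ_max break to the earliest window midpoint; all floating
  comparisons in the estimator are deterministic, so repeated runs are
  byte-identical (fixed 6-significant-digit formatting and fixed row
  order in CSVs).
* The analysis state is a schema-versioned JSON document (config,
  calibration, blacklist, per-well results, input digests); reloading
  reproduces results without recomputation, and result equality treats
  NaN fields (undetermined parameters) as equal.
* Degenerate inputs fail loudly with the offending line, well,
  condition or age point named: ragged rows, non-monotone time stamps,
  duplicate well ids, missing blanks, non-monotone calibration data,
  aging courses with fewer than two age points.

## Known limitations

* The piecewise-exponential estimator reports the maximal *local*
  rate; for curves without a clear exponential phase (quasi-linear
  respiratory growth) the result is labelled valid only if the sanity
  checks pass, but its interpretation is weak.
* The absolute-slope plateau criterion for yield depends on two
  configured constants; noisy plateaus near the tolerance boundary can
  flip between plateau and no-plateau.
* Lag times inherit the baseline convention; comparing lags across
  analyses requires the same baseline choice.
* The saturation cubic is instrument- and organism-specific and must
  be re-fitted per laboratory setup; the packaged coefficients appear
  only in tests and examples.
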