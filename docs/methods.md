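# Methods

This note documents the models implemented in `pepsim`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter.

## Activity surfaces (`pepsim.models`)

Pepsin activity is modelled as a polynomial in pH (A) and temperature B
(°C) on the log10 scale; the antilog is activity as a percentage of the
enzyme's activity at the reference optimum, pH 2 / 37 °C. The log
transform reflects the ~200-fold max/min range of measured activities and
means the polynomial can never predict a non-positive activity. Values
above 100 % are meaningful (some conditions beat the nominal optimum) and
are never clipped.

The validated domain is pH 1–7, 4–60 °C — the range the underlying
experiments covered. Evaluation outside the domain is *extrapolation of a
cubic polynomial* and can be wildly wrong; the default policy is to allow
it but warn and flag the prediction (`extrapolated=True`); `forbid` and
`allow` policies are available.

Two published coefficient sets ship with the package, each in two variants:

* **human, 7 terms** {1, A, B, AB, A², B², AB²}. As printed, the
  temperature-linear coefficient is 0.88912, which puts the optimum
  prediction at 10³¹·⁶ % — physically impossible, and almost certainly a
  misplaced decimal point. The `corrected` variant uses 0.088912, which
  restores the optimum prediction to 101.16 % (within ~1 % of the expected
  100). No other coefficient is touched: a single documented amendment is
  defensible, a multi-coefficient re-tuning would be fabrication.
* **porcine, 9 terms** (adds A³, B³). As printed it evaluates to ≈59.5 % at
  its own optimum rather than ≈100 %. No single-coefficient change fixes
  this, so the `corrected` variant is coefficient-identical (an identity
  amendment, retagged) and the documented recommendation is
  `predict_relative`, which renormalises by the surface's own reference
  value and is exactly 100 at the optimum regardless of calibration. The
  authoritative alternative is refitting from data (`pepsim.fitting`).

A model whose own reference-condition prediction is more than one decade
away from 100 % triggers `CoefficientSanityWarning` on prediction — a
model-agnostic guard that fires for the printed human surface.

Models serialise to a small JSON schema (species, variant, transform,
reference, domain, term list, provenance); a round trip reproduces
predictions bit-for-bit because coefficients are stored as native floats.

## Response-surface fitting (`pepsim.fitting`)

Ordinary least squares of log10(activity) on the monomial basis, solved by
QR decomposition. Conventions follow the response-surface software the
published fits came from:

* model F = (SS_model/df_model)/(SS_residual/df_residual), df_model = p − 1,
  against the corrected total SS; p-value from the F(p−1, n−p) distribution
  (a single model test, no multiplicity machinery);
* adjusted R² = 1 − (1 − R²)(n − 1)/(n − p);
* PRESS by the hat-matrix identity Σ(eᵢ/(1 − hᵢᵢ))², predicted
  R² = 1 − PRESS/SS_total. An explicit leave-one-out refit oracle
  (`predicted_r2_bruteforce`) is provided and agrees to ~1e−13 relative;
* outlier flagging by externally studentized residuals (default threshold
  |t| > 3) as the algorithmic proxy for visual residuals-vs-predicted
  inspection; explicit run-id exclusion is supported for reproducing
  manual removals. Note the proxy only works when the basis matches the
  data-generating surface well — lack-of-fit error inflates the residual
  scale and masks moderate outliers;
* factors may be fitted in actual units or linearly coded to [−1, 1]. Both
  bases used here are downward-closed, so the two codings span the same
  column space and F/R²/adjusted/predicted R² are coding-invariant (tested
  to 1e−9). Coded fits are decoded to actual-unit coefficients on export
  via binomial expansion;
* degenerate (constant) responses give R² = 0 and an undefined (NaN) F with
  a warning; singular designs raise an error naming the collinear columns.

**D-optimal selection** maximises det(XᵀX) over a candidate set by Fedorov
exchange from a seeded random full-rank start, with columns rescaled to
unit norm for determinant conditioning (a per-column constant rescaling
does not change the argmax; the reported determinant is of the unscaled
design). Exchange guarantees a local optimum only; the test suite checks
it beats 50 random subsets and matches brute force on a small example.

**Reproduction helper.** The published methods text pairs the 7-term basis
with three removed outlier runs (printed activities 20.62, 7.63, 11.28 %)
and the 9-term basis with one (14.3 %), but labels those fits with species
inconsistently with the printed equations (the 7-term equation is labelled
human, the 9-term porcine). `reproduce_published_statistics` therefore
takes two datasets, locates the printed outlier activities in each, refits
both bases, and reports which assignment reproduces the published
statistics (F within ±0.5, R² within ±0.02) — resolving the swap from data
instead of guessing. The original 37-point tables exist only in the
publication's supplementary spreadsheets and are not redistributed; the
helper is exercised on synthetic data with planted outliers.

## Units (`pepsim.assay`)

One unit produces a ΔA280 of 0.001 per minute at pH 2 / 37 °C (TCA-soluble
haemoglobin digestion products). The published work states only the unit
definition, not the full formula; this package adopts the
per-mL-of-enzyme-solution convention that matches the reported U/mL
framing: `U/mL = (ΔA280/min / 0.001) · dilution / aliquot_mL`. A blank
exceeding the sample clamps ΔA to zero with a warning (blanks can exceed
samples by noise) rather than erroring.

## Digestion profiles (`pepsim.profiles`)

Profiles are piecewise-linear in time; conditions are interpolated but
never extrapolated outside the recorded span. AUC uses the composite
trapezoid rule on the native (possibly irregular) grid — exact for
piecewise-linear series, matching spreadsheet practice, and invariant
under grid refinement. Cross-profile comparison interpolates both series
onto the union grid over the overlapping time range; a zero denominator
AUC reports a NaN ratio rather than raising. Temperature is carried per
timepoint even when constant so thermal transients (cold-meal ingestion)
are expressible.

## Gastric simulator (`pepsim.simulator`)

A single well-mixed compartment. Fluid: constant secretion (default
1 mL/min — the parameter table's value; the accompanying narrative once
says 0.9 mL/min, and the field is configurable) minus volumetric emptying
(2 mL/min; for the 1 kcal/mL meal considered, the 2 kcal/min caloric
emptying rate is equivalent). Pepsin: constant secretion 46.8 mg/h, loss
with emptied fluid at concentration P/V. The meal (50 mL, pepsin-free) is
added instantaneously at t = 0 to the 33 mL basal volume. pH is an
exogenous input curve (no acid-secretion feedback or buffering chemistry);
temperature is fixed at 37 °C unless a temperature curve is supplied.
Total activity = P · 2,000 U/mg · relative_activity(pH, T)/100.

Integration is explicit Euler at dt = 1 min, deliberately mirroring a
row-per-minute spreadsheet computation; halving dt changes the default
scenario's AUC by ~0.4 %, and a warning fires when dt is large relative to
the emptying timescale. Volume and mass are floored at zero, with the
emptying term dropped at zero volume.

Choices made where the source was silent:

* **Older adults**: output_reduction = 0.4 multiplies the pepsin secretion
  rate; `reduce_basal` (default True) applies it to the basal pepsin pool
  too. Because the volume trajectory is pepsin-independent and the pepsin
  balance is linear, the fully reduced run is *exactly* 0.6× the adult
  trajectory (AUC ratio 1/0.6 ≈ 1.67, consistent with the reported near
  doubling of adult vs older-adult cumulative activity). With
  `reduce_basal=False` the ratio lies strictly between 1 and 1/0.6.
* **Default duration 75 min**: the default rates give a net fluid balance
  of −1 mL/min from 83 mL, so the volume reaches zero at 83 min; 75 min
  keeps the whole default trajectory in the physically meaningful regime
  while exhibiting the expected meal shape — total units rising to a
  single interior peak before declining, with pepsin concentration
  increasing monotonically throughout (it approaches the 0.78 mg/mL
  secretion-to-emptying ratio from below).
* The reported absolute peak (~42,000 U) and AUC values are **not**
  reproducible because the driving in vivo pH curve's anchors were never
  published; only ratios and qualitative shape are checked.

## Thermal inactivation (`pepsim.thermal`)

The built-in retention table holds the measured values above. Lookups are
exact at tabulated points; durations between tabulated values at a
tabulated temperature are linearly interpolated; between tabulated
temperatures the *higher* (lower-temperature) neighbouring value is
returned, because under-estimating residual activity risks a false
"inactivated" call. All non-tabulated answers are flagged.

`is_irreversibly_inactivated(T, t)` is true iff T ≥ 75 °C and t ≥ 5 min —
the minimal validated treatment — and is deliberately conservative below
either threshold (e.g. 95 °C for 4 min returns False: plausible but
unvalidated). The rule is monotone in both arguments.

The 65 °C decay accelerates with time (95.35 → 72.37 → 45.21 % at 5/10/15
min is not first-order), so `fit_loglinear_rate` is a descriptive summary
only: with the (0 min, 100 %) anchor it gives k = 0.0531 /min with
R² = 0.887 (without the anchor, k = 0.0746 /min, R² = 0.978). It is never
extrapolated beyond 15 min. The source's methods text once says
"5, 10–20 min" but all results report 5/10/15 min; the table uses 5/10/15.

## Synthetic data (`pepsim.synthetic`)

All generators are pure functions of a `GeneratorSpec` (seeded
`numpy.random.default_rng`; identical spec ⇒ byte-identical output).

* **Activity datasets**: activityᵢ = 10^(L(pHᵢ, Tᵢ) + εᵢ) with
  εᵢ ~ N(0, σ) on the log10 scale (noise where the fit assumes it);
  default σ = 0.05, chosen so recovery tests are meaningful but stable.
  The 37-point "paper-like" design is a seeded D-optimal 26-point
  selection over the pH 1–7 × 4–60 °C grid plus 11 points along a
  semi-dynamic pH 6.5 → 2 trajectory at 37 °C, emulating the structure
  (26 + 11) of the original experiment without claiming to equal its
  undisclosed design.
* **pH curves**: static (constant), semi-dynamic (strictly monotone
  exponential approach hitting the end pH exactly at the end time, descent
  rate jittered ±20 % by seed), and a meal shape (plateau for the first
  15 % of the window, then the same descent).
* **Assay readings** invert the unit formula exactly, plus Gaussian
  absorbance noise on the sample reading.

What passing tests on synthetic data do *not* show: the generators share
the package's own surface models and noise assumptions, so they validate
internal consistency (round trips, estimator calibration, structural
properties), not predictive accuracy on real digesta — real measurement
error need not be log-normal, real designs are not D-optimal, and real
gastric pH curves are rougher than the smooth parametric shapes here.
Confidence-interval coverage of coefficient recovery (n = 37, σ = 0.05,
200 replicates) is asserted per-coefficient at ≥ 90 % (each ~95 %
nominally); joint all-coefficients coverage is necessarily lower (~0.95⁷)
and is reported but not asserted.

## Known limitations

* The surfaces are calibrated on haemoglobin in solution; substrate and
  food-matrix effects (e.g. casein digestion at pH > 5) are out of scope.
* The printed human equation is unusable as printed; the corrected variant
  rests on a single presumed decimal-point error. The porcine surface's
  absolute calibration is off by ~0.23 decades; use relative predictions.
* The simulator has no nutrient hydrolysis, buffering, or feedback; pH is
  exogenous, and the default parameterisation is only meaningful until the
  compartment volume empties (~83 min).
* Thermal guidance interpolates a 4 × 3 grid; nothing is asserted below
  65 °C, above 95 °C, or beyond 15 min.
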