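# Methods

## The model

The package implements the classical three-parameter model of aerobic
endurance performance applied to the running speed at the second lactate
threshold (vLT2), the highest speed still compatible with a lactate steady
state:

```
vLT2 = LT2% · V̇O2peak / (C_R · 60)        [m·s⁻¹]
```

* **V̇O2peak** (mL·kg⁻¹·min⁻¹) — highest 30-s moving average of oxygen
  uptake in an incremental treadmill test to exhaustion.
* **LT2%** — fractional utilization, the fraction of V̇O2peak elicited at
  LT2. Stored internally as a fraction; rendered as a percentage in
  reports.
* **C_R** (mL·kg⁻¹·m⁻¹) — oxygen cost of running, V̇O2 at a submaximal
  anchor speed divided by that speed. The factor 60 converts per-minute
  V̇O2 to the per-second speed basis and lives in exactly one function
  (`calculate_vlt2`).

The model is an algebraic identity when C_R is the athlete's true cost at
vLT2 itself, because LT2%·V̇O2peak is by definition V̇O2 at vLT2. Its
practical accuracy therefore hinges on where C_R is anchored, which is why
three determinations are carried side by side:

* `fix` — the fixed speed 2.8 m·s⁻¹ (second protocol stage), V̇O2 from
  that stage's steady state;
* `lt1` — the speed at the first lactate threshold, V̇O2 linearly
  interpolated between adjacent stage steady states;
* `pct80` — the speed at 80% V̇O2peak obtained from the linear regression
  of steady-state V̇O2 on speed over the submaximal stages, with
  V̇O2 = 0.8·V̇O2peak by construction (consistent with how the speed is
  derived, rather than re-interpolated from stages).

## Test protocol and stage processing

Sessions follow a fixed step protocol: 2.4 m·s⁻¹ start, +0.4 m·s⁻¹ per
5-min stage, 30-s sampling breaks, 1% incline, run to volitional
exhaustion. Spirometric channels are averaged over the last third of each
stage (`stage_steady_state`); samples beyond the stage duration (rest
breaks) are excluded. V̇O2peak uses the 30-s moving average of the 1-s
series when raw gas data exist; for stage-level-only data the maximum
stage value is the documented fallback. Exhaustion is verified as
volitional exhaustion plus at least K of three objective criteria
(peak RER ≥ 1.10, peak HR ≥ 95% of age-predicted maximum, post-test
lactate ≥ 8 mmol·L⁻¹), K = 2 by default, 3 in strict mode; the
age-predicted maximum defaults to 220 − age and is configurable, since no
particular equation is canonical. All criterion thresholds are inclusive.

## Threshold detection

End-stage blood lactate of the completed stages is fitted against speed by
an ordinary least-squares third-order polynomial (at least four distinct
speeds; the final, uncompleted stage is excluded from the fit). Two
points are then derived:

* **LT1** — the smallest speed in the fit domain where the fitted
  derivative equals the slope criterion 1.00 mmol·L⁻¹ per m·s⁻¹ while the
  second derivative is positive (first rise on the ascending limb). The
  quadratic in the derivative is solved in closed form. The criterion is
  absolute, so it is *not* invariant to rescaling the lactate axis or the
  speed unit; a `kmh` mode rescales the criterion for data recorded per
  km·h⁻¹.
* **LT2 (modified maximal deviation / Dmax)** — the speed between LT1 and
  the peak lactate point with maximal perpendicular distance (raw axis
  units, no normalization — consistent with the classical Dmax
  literature) below the chord joining the LT1 point and the peak point.
  The peak point defaults to (highest speed attained, max(final-stage
  lactate, post-test lactate)); a `fitted` policy uses the curve value at
  the top speed instead. Stationary points of the vertical deviation
  (curve slope = chord slope) are solved analytically; a 1e-4 m·s⁻¹ grid
  over interior local maxima is the fallback. Ties resolve to the smaller
  speed. Because the measured peak point generally lies above the fitted
  curve, the deviation is largest at the chord's right endpoint; that
  boundary value is not a curve maximum and is never returned — the Dmax
  point is the interior parallel-tangent maximum.

When the top attained speed comes from the uncompleted final stage, the
chord endpoint lies one increment beyond the fitted domain and the cubic
is evaluated there by extrapolation; V̇O2 at a threshold beyond the last
completed stage is extended with the submaximal regression line.

Athlete-level detection failures (no slope-1.00 crossing, curve never
below the chord) become per-athlete flags, not exceptions, so cohort runs
survive individual bad curves. Fractional utilization above 1.05 is
rejected as a measurement inconsistency.

## Energy cost

Oxygen cost is converted to energy cost with the linear non-protein
caloric-equivalent table: 4.686 kcal·L⁻¹ at RER 0.707 rising linearly to
5.047 at RER 1.00, times 4.184 J·cal⁻¹ (19.61–21.12 J per mL O2). RER is
clamped to the table range by default; an `extrapolate` policy extends
the line, since published energy costs sometimes imply equivalents above
the RER = 1.00 value and the exact convention varies between labs.

## Cohort filter

A session enters the modeled cohort when all of: age < 19 y; exhaustion
verified; LT1 and LT2 validly determined (algorithmic success is the
validity criterion); more than three *completed* stages (a cubic needs
four points); speed at 80% V̇O2peak within [2.4 m·s⁻¹, athlete's top
speed]; and only the earliest visit per athlete (date ties broken by file
order). The filter is idempotent and reports per-criterion failures.

## Statistics

* **Bland–Altman** — bias = mean(modeled − measured), limits of agreement
  bias ± 1.96·SD (n−1). The percent half-width uses the mean *measured*
  (criterion) speed as denominator, rounded to integer percent.
* **ICC** — single-measure absolute agreement from the two-way ANOVA mean
  squares, (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)), the quantity
  SPSS labels "two-way mixed, absolute agreement, single measures"; CI by
  the McGraw–Wong F construction. Interpretation bands: <0.50 poor,
  0.50–0.75 moderate, 0.75–0.90 good, >0.90 excellent.
* **Pearson** bands: <0.30 negligible, 0.30–0.50 low, 0.50–0.70 moderate,
  0.70–0.90 high, >0.90 very high (absolute value; a boundary value falls
  in the lower band).
* **Group comparisons** — independent-samples t-tests, pooled-variance by
  default (variance homogeneity assumed verified), Welch optional.
* **Stepwise regression** — bidirectional with F-probability criteria
  (enter p ≤ 0.05, remove p ≥ 0.10); entry picks the smallest partial-F
  p-value, ties broken by larger F then column order, mirroring common
  statistical-package behavior; partial F uses (1, n − p − 1) df at the
  larger model's residual df. With a numerically exact model the 0/0
  partial F counts as no improvement (p = 1), so noise predictors cannot
  ride in on a zero-residual fit. Standardized betas are
  coefficient · sd(x)/sd(y).
* **Commonality analysis** — all 2^k − 1 subset regressions; the
  component of subset S is C(S) = Σ_{T⊆S} (−1)^{|T|+1} R²(T ∪ (K∖S)).
  Components sum to the full-model R² and, per predictor, to its squared
  zero-order correlation. Percentages are reported signed relative to the
  total R², so suppression appears as negative percentages. Guarded at
  k ≤ 5 (2^k growth); the pipeline uses k = 3. In the pipeline the
  dependent variable is the modeled threshold speed from the pct80 cost
  (the method the agreement analysis favors), with sex and age offered as
  additional stepwise candidates.

## Synthetic cohort generator

No athlete-level data are public, so all cohort-scale behavior is
exercised on a seeded generator emulating the study population: young
squad athletes, 45 male + 55 female by default.

Latent parameters are drawn per sex from normal distributions whose
defaults equal the published cohort descriptives (male/female V̇O2peak
56.4 ± 5.9 / 47.3 ± 4.3 mL·kg⁻¹·min⁻¹; oxygen cost 0.229 ± 0.018 /
0.216 ± 0.016 mL·kg⁻¹·m⁻¹; LT2% 0.870 ± 0.029 / 0.870 ± 0.024; plus age,
height, mass), truncated at physiological floors (truncation, not
rejection). The latent threshold follows the model,
v_LT2 = LT2%·V̇O2peak/(C·60), and v_LT1 = 0.84·v_LT2 (ratio of the
published group means). Ages are truncated below 19 y because the
descriptives characterize the *included* (post-filter) cohort.

Stage V̇O2 is C·60·speed plus Gaussian noise (σ = 1.2 mL·kg⁻¹·min⁻¹);
stages are completed while demand stays within the latent V̇O2peak, and
the first stage beyond it is attempted but unfinished, with V̇O2
plateauing at peak. Blood lactate follows a smoothed-hinge (softplus)
curve la(v) = la0 + (S/κ)·ln(1 + e^{κ(v−vh)}): flat baseline
(la0 = 1.0 ± 0.15 mmol·L⁻¹), exponential rise around the hinge, bounded
maximal slope S (7 ± 0.7 mmol·L⁻¹ per m·s⁻¹), sharpness κ
(6 ± 0.7 per m·s⁻¹ at a 3.4 m·s⁻¹ reference threshold, rescaled by
3.4/v_LT2 per athlete because lactate kinetics track relative intensity).
The hinge is placed so the analytic slope equals exactly 1.0 at the latent
LT1. Two deliberate properties: the family is *not* a cubic — testing the
cubic estimator on its own model family would be circular — and a
saturating slope keeps the chord slope below the curve's maximal slope so
the maximal-deviation point stays interior; with these defaults the
analytic Dmax lands close to the latent v_LT2, as in real curves. Lactate
noise (σ = 0.2 mmol·L⁻¹, an implementer choice — the study reports no
within-athlete lactate error) is truncated to keep the sequence
non-decreasing. RER and HR ramp linearly to above-criterion peaks and the
post-test lactate is the curve's end-test value plus a 1 mmol·L⁻¹
post-exercise bump, at least 8 mmol·L⁻¹.

Each athlete draws from a substream keyed by (seed, index), so cohorts
are byte-reproducible and individual athletes are stable under
cohort-size changes. Draws are retried (up to 60, with a warning) when
the latent profile completes fewer than four stages or the simulated
session would fail the inclusion filter — the generator emulates the
included cohort, mirroring the study's own screening of a much larger
testing pool. Conditioning on admissibility slightly favors noise draws
with flatter early lactate segments; this is the synthetic analog of the
real inclusion step.

**What the generator does not emulate:** breath-by-breath noise
structure and V̇O2 slow components (stage values are drawn i.i.d. around
a strictly linear speed–V̇O2 relationship through the origin);
correlated day-level measurement error; menstrual-cycle or substrate
effects; discipline heterogeneity; pacing or partial-stage termination
dynamics. Passing tests therefore show the estimators are correct and
internally consistent under these idealized conditions, not that field
data would reach the same agreement.

## Numerical choices and degenerate inputs

* Threshold maximization: closed-form stationary points first, 1e-4 grid
  fallback restricted to interior local maxima; tie → smaller speed.
* The cubic's Dmax inherits an approximation bias relative to the
  non-cubic generating family — on noise-free default cohorts the median
  discrepancy against the dense-grid truth stays below 0.05 m·s⁻¹ (the
  test-suite bound), but individual athletes whose lactate rise sits at
  the edge of the completed-stage grid can deviate by several tenths.
  This is a property of fitting a cubic to a saturating-exponential
  curve, not of the maximizer.
* Session CSV floats are written with shortest round-trip repr and parsed
  with correctly-rounded conversion, so read∘write is byte-lossless on
  the canonical dialect. Report tables round half-away-from-zero: speeds
  2 decimals, costs 3, V̇O2peak/LT2% 1 — the precision of the published
  tables.
* Zero-variance inputs raise typed errors (undefined ICC/correlation);
  rank-deficient designs raise collinearity errors naming the columns.
* The whole pipeline is deterministic: identical config + seed give
  byte-identical report bundles, and the manifest records every policy
  knob plus a config hash.

## Problem sizes

Default analyses use cohorts of 100 athletes (45 male, 55 female),
matching the study; property suites use 10 pinned-seed cohorts of 100 for
directional checks, 200 random datasets for the commonality identities,
and 50 for the stepwise-vs-exhaustive comparison. All run in seconds on
one CPU.
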