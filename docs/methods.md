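# Methods

## Problem

UAV campaigns over a rice field trial yield, per line and observation
date, a canopy height (CH, cm) and a chlorophyll index green
(CIg = ρNIR/ρgreen, unitless).  `phenocurve` reduces each line's season of
weekly observations to a handful of interpretable growth-curve parameters,
predicts five manually measured traits — days to heading (DTH), culm
length (CL), aboveground dried weight (ADW), stem-and-leaf weight (SLW),
panicle weight (PW); ADW ≡ SLW + PW — from those parameters with linear
models, and corrects the systematic bias that appears when a model trained
under one cultivation condition (transplanting protocol or year) is
applied under another.

## Growth models

CH follows a modified three-parameter logistic with a quadratic decline
after the day `d1` at which the maximum is reached:

    y(x) = K / (1 + exp(r1 (d0 − x)))            x ≤ d1
    y(x) = K / (1 + exp(r1 (d0 − x))) − a (x−d1)²   x > d1

with `K` the maximum height (cm), `r1` the pre-peak growth rate (1/day),
`d0` the day of maximum growth rate, and `a` the late decline rate
(cm/day²).  The curve is continuous at `d1`.  CIg follows a double
logistic,

    y(x) = ymax [ 1/(1 + exp(r2 (d2 − x))) − 1/(1 + exp(r3 (d3 − x))) ],

rising around `d2` at rate `r2` and falling around `d3` at rate `r3`,
scaled by `ymax`.

### Fitting

Both fits are bounded nonlinear least squares (scipy `least_squares`,
trust-region reflective, tolerances 1e-10, ≤500 evaluations).  Bounds:
K ∈ (0, 2·max y], rates ∈ (1e-4, 1], day parameters ∈ [0, max x + 30],
a ∈ [0, 1].

* **CH**: a profiled multi-start — a grid of candidate `d1` values at the
  observation spacing, fitting (K, r1, d0, a) at each with d0 ≤ d1
  enforced through the box bounds, followed by a joint polish of all five
  parameters with `d1` reparametrised as `d0 + δ`, δ ≥ 0.  The procedure
  is deterministic (no random starts) and refitting from the returned
  optimum reproduces it.
* **CIg**: `ymax` is fixed at the observed series maximum; (r2, r3, d2,
  d3) start from the conventional initial vector (0.05, 0.05, 40, 100),
  with a small deterministic multi-start fallback over shifted day
  anchors.  The same ymax-fixation rule is applied when the double
  logistic is fitted to CH for model comparison.

Goodness of fit is the per-series R² = 1 − SSE/SST; campaign-level fit
quality is the average of per-series R² values.  Degenerate inputs
(constant series, fewer observations than parameters + 1) are flagged
non-convergent or rejected before fitting.

### Identifiability of d1

The gradient directions of `d1` (2a(x−d1)) and `a` (−(x−d1)²) over the
post-peak observations are ~0.97 collinear, so the two parameters are
jointly weakly identified at weekly sampling.  At 1 cm observation noise
and a realistic decline (a ≈ 0.008, i.e. ~25 cm over the last eight
weeks), the Cramér–Rao bound for `d1` is ≈3.4 days; reaching a 1-day
standard error would require a ≥ 0.03, an implausible ≥75 cm decline.
Fitted `d1` values should therefore be read as ±3-day estimates under
field-grade noise; `K`, by contrast, is estimated to well under 1%.
This is an information limit of the design, not of the optimizer: the
returned optimum coincides with a fine profile-likelihood scan over `d1`.

## Raster extraction

Plot CH is the 95th percentile of the plot's DSM pixels (linear
interpolation between order statistics — the percentile convention is a
package choice, documented because conventions differ) minus the bare
ground level, converted to cm.  Plot CIg is the arithmetic mean of
per-pixel NIR/green ratios (ratio first, then mean); zero-green pixels are
masked and logged, never propagated as infinities.  A `minus_one` flag
switches to the CIg = ρNIR/ρgreen − 1 form of the index.  Plot geometry is
a 0-based half-open pixel-rectangle cut from field-level matrices;
georeferencing and photogrammetry are out of scope.

## Trait models

Six specifications: CH, CIg and Hybrid predictor pools, each full or
VIF-selected.  The canonical selected sets {K, d0, d1} (CH) and
{r2, d2, d3, ymax} (CIg; Hybrid = union) are frozen defaults because the
downstream evaluation depends on fixed sets; data-driven backward VIF
selection (drop the largest-VIF predictor until all VIF < 5, ties broken
by the canonical parameter order) is available explicitly.
VIF_j = 1/(1 − R²_j) from regressing predictor j on the rest with
intercept.  Trait models are OLS with intercept; p-values are classical
two-sided t-tests with no multiplicity correction; rows with missing
parameters (non-converged curve fits) are dropped with a logged count.

## Validation schemes

* **Fitness** — R² of the model refit on all lines of one
  protocol × year.
* **Accuracy** — 10-fold cross-validation repeated 100 times with fresh
  random unstratified folds; per repetition the held-out predictions of
  all folds are pooled before computing RMSE and Pearson correlation
  (pooling rather than per-fold averaging is the stabler convention and is
  fixed here; at n ≈ 100 the two differ by well under 1%), then mean and
  sd across repetitions are reported.
* **Type-1 robustness** — train on one transplanting protocol, test on
  the other, same year.
* **Type-2 robustness** — train on one year, test on the same protocol
  the next year.

All schemes are deterministic given the seed.  Correlation is invariant
under any additive bias in the test traits while RMSE inflates as
√(σ² + b²), which is exactly the failure mode the calibration targets.

## Parental calibration

Five steps: fit the prediction model on the training condition; predict
the test-condition lines; predict the test-condition parents; regress
parent observed on parent predicted (observed-on-predicted, so application
is a direct affine map; the inverse-regression alternative is noted as an
option); apply the line to the line predictions.  With the customary four
anchors no outlier handling is applied.  Metrics exclude the parents to
avoid anchor leakage.  Affine calibration with positive slope leaves the
correlation exactly unchanged; with anchors spanning the line range it
removes additive condition bias down to anchor noise, while clustered
anchors can estimate the slope so poorly that calibration worsens RMSE —
both behaviours are asserted in the test suite.

## Synthetic campaigns

The generator emulates a two-protocol (regular/delayed transplanting),
two-year trial of 100 lines plus 4 parental cultivars, observed weekly on
days 7–140 after transplanting.

* **Parameters** are drawn from a truncated multivariate Gaussian
  (resample on constraint violation, ≤1000 attempts, then deterministic
  clipping) with protocol-specific means.  Defaults (regular protocol):
  K = 100 ± 8 cm, r1 = 0.11 ± 0.012/day, d0 = 42 ± 3.5 d, d1 = 76 ± 5.5 d,
  a = 0.008 ± 0.0015 cm/day², ymax = 5.5 ± 0.45, r2 = 0.15 ± 0.018/day,
  r3 = 0.12 ± 0.012/day, d2 = 38 ± 3 d, d3 = 112 ± 5.5 d.  The delayed
  protocol lowers the day parameters and raises the early rates (warmer
  establishment → earlier, faster early growth).  The correlation matrix
  comes from a three-factor construction (phenology timing, canopy scale,
  rate-specific) that is positive definite by construction and yields the
  cluster structure such trials show: timing (d0, d1, d3) tightly
  positive, scale (K, ymax) moderately positive, rates (r1, r2, r3)
  positive among themselves and negative against timing, d2 opposed to r2.
  Under these defaults the full 10-parameter design is genuinely
  multicollinear (population VIF of d0/d1 ≈ 6–7), so backward selection
  has real work to do.
* **Cross-condition structure**: a latent per-line genotype effect common
  to all conditions carries a `repeatability` share (default 0.75) of the
  parameter variance, giving realistic cross-protocol trait correlations
  (≈0.5–0.95 depending on trait noise).
* **Traits** are affine in the parameters plus Gaussian noise (DTH ± 2 d,
  CL ± 2.5 cm, SLW ± 4 g, PW ± 3.5 g), with DTH loading mainly on d1, CL
  on K, SLW on d1/d3, PW positively on ymax and negatively on d3;
  ADW = SLW + PW holds exactly.  Intercepts place the regular-2022 trait
  ranges at DTH ≈ 59–97 d, CL ≈ 61–98 cm, SLW ≈ 31–66 g, PW ≈ 27–54 g.
  Additive protocol/year offsets (configurable; defaults of ±2–5 units)
  inject the cross-condition bias the calibration corrects.
* **Parents** are drawn from the same distribution; with
  `parents_span_range` on, four-parent draws are rejected until they
  jointly span ≥80% of the line range per trait, keeping the
  best-spanning attempt if the target is never met (the achieved span is
  recorded on the table).
* **Series** are the model curves plus iid Gaussian noise (defaults: 1 cm
  CH, 0.1 CIg), floored at 0 for CH.  `include_peak_day` inserts the
  analytic curve-peak day, which makes the observed maximum a faithful
  stand-in for the curve supremum in noiseless oracles.

What the generator does **not** emulate: spatially correlated or
heteroscedastic observation noise, missing flights, lodging, genotype ×
environment interaction beyond additive condition offsets, or non-linear
parameter–trait relationships.  Passing tests therefore demonstrate the
correctness and statistical behaviour of the pipeline under its stated
model, not the field-data effect sizes.

## Problem sizes

The default test-suite and acceptance-script sizes — 100 lines for
recovery and calibration studies, 30–80 lines for structural checks, CV at
100 repetitions where reported, 2–5 repetitions inside simulation loops —
are chosen so each statistical assertion has comfortable Monte-Carlo
margin while the whole suite stays quick to run end-to-end.

## Known limitations

* `d1` (and to a lesser degree `a`) carries a ±3-day uncertainty at
  field-grade noise (see above); downstream trait models are largely
  insensitive because DTH/SLW load on d1 through its large between-line
  variance (σ ≈ 5.5 d).
* Fixing `ymax` at the observed maximum biases the double-logistic rate
  estimates by a few percent when the curve peak sits below the asymptotic
  scale (narrow rise–fall separation, shallow rates).
* The calibration assumes the condition shift acts affinely on the
  predicted-observed relation; trait-specific non-affine shifts are out of
  scope, as is any replicate-plot averaging of parents (one value per
  parent per condition).
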