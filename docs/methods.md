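# Methods

## Response-surface engine

**Design geometry.** `build_ccd` produces a two-block central composite
design for two factors. The packaged sedimentation design places the 2²
factorial points at coded ±2 (block 1, with three centre replicates) and the
axial points at ±1 (block 2, with three more centres) — the inverse of the
textbook circumscribed CCD. Both radii are parameters, so the textbook
layout (cube ±1, axial ±2) is one call away. Run order within blocks is
randomized by an explicit seed (default 0).

**Coding.** Factors map linearly between coded and actual units,
`actual = center + coded·step`; the packaged factors are pH (centre 7, step
1.5) and salinity (centre 20, step 7.5 ppt), so coded −2…+2 spans pH 4–10
and 5–35 ppt.

**Model and fitting.** Each response is fitted by OLS to the full
second-order polynomial in *actual* units — `[1, x₁, x₂, x₁², x₂², x₁x₂]` —
plus sum-to-zero (deviation-coded) block contrasts. With equal block sizes
the intercept is then the blocks-averaged one, and the coefficient vector is
directly comparable to an uncoded regression equation as statistical
packages print it. Predictions use the blocks-averaged surface; points
outside the coded [−2, 2] box trigger a warning, not an error. A
rank-deficient model matrix raises an error naming the collinear terms.

**ANOVA conventions.** Term tests use Type-III (adjusted) sums of squares:
the SSE increase when the term is dropped from the full model, computed on
the **coded** design matrix. This is the convention of the mainstream RSM
packages, and it matters: in actual units the linear columns are not
orthogonal to the quadratic ones, so single-term drops there give different
(much larger) SS and the per-factor rows would no longer decompose the
pooled Linear row. The fitted surface is unchanged either way — the model
subspace is identical under any affine recoding, so SSE, R², and the
model-level F are coding-invariant (a property the test suite asserts).
Pooled rows (Linear, Square, 2-way interaction) drop their whole group
jointly. The Model row aggregates every fitted term including blocks
(df = p − 1, SS = SST − SSE). Pure error is the within-group variation of
replicated factor settings *within each block*; lack of fit is the
remainder of the error SS, tested against pure-error MS. A design with no
replicates reports the lack-of-fit row as not estimable rather than
dropping it. The default significance level for these small response-surface
models is α = 0.1 (90% confidence), with 0.05 used elsewhere in the package.

**Summary diagnostics.** S = √(SSE/df_error); R² and adjusted R² in percent;
predicted R² from PRESS, computed via leverages as
PRESS = Σ(eᵢ/(1−hᵢᵢ))² and verified in tests against literal leave-one-out
refits. Predicted R² is stored signed and floored at zero only for
reporting. A leverage of 1 (a run that uniquely determines a parameter)
raises an explicit error.

**Multi-response optimization.** The joint optimum maximizes a
geometric-mean desirability: efficiency is larger-is-better, time
smaller-is-better, each with a linear desirability anchored at the observed
min/max of that response in the fitted data. Desirabilities are clipped
below at zero but left open above one during the search, so that surface
predictions beyond the best observed response still rank instead of
producing a flat saturated plateau (the reported objective value is capped
at 1). Search is a dense grid (default step 0.05 in actual units) with ties
broken toward lower salinity then lower pH, followed by a Nelder-Mead
polish; the analytic stationary point of each single-response surface and
the per-response grid optima are reported alongside. Weights default to
equal. Note the exact efficiency/time trade-off is a modelling choice: with
equal weights the *C. sorokiniana* joint optimum sits near 17.8 ppt,
while pure efficiency maximization puts it at 17.4 ppt (both at the pH 4
boundary); the package exposes the weights rather than hard-coding a rule.

**Validation statistics.** Simple y~x regression (with the same R² family
incl. PRESS) and Pearson/Spearman correlations back the method-validation
workflows (manual vs automated counts, photographic vs optical-density
efficiency). Correlation machinery delegates to scipy.stats; the test suite
keeps independent closed-form and brute-force-rank oracles.

## Hemocytometer counting

Pipeline: luminance grayscale → Gaussian blur (default σ = 1.5 px) → global
Otsu threshold (fixed threshold optional) with polarity `dark_on_light` for
Lugol-stained cells → hole filling and removal of specks below min_area/4 →
Euclidean distance transform → local-maximum markers separated by at least
half the expected/median object diameter → watershed constrained to the
foreground. Objects outside the area gates (expected diameter ± 60% when
given) or touching any image border are discarded and labels are contiguous
from 1. The marker separation of 0.5× diameter is chosen so that two cells
whose centres are 1.2 radii apart — a moderate, frequently occurring fusion
— still receive two markers, while disjoint cells are never merged; larger
factors leave such pairs as one object. An Otsu split with less than
`min_contrast` (default 0.15 in normalized intensity) between the class
means is treated as no detection, so a cell-free chamber whose faint grid
rulings would otherwise threshold as "objects" counts zero.

The border rule is plain exclusion on all four edges, not the classical
two-edge counting convention; for concentration work either calibrate the
chamber volume accordingly or pass a interior crop. Counts convert to
cells·mL⁻¹ via `count / (chamber_volume_nl × 10⁻⁶) × dilution`.

## Photographic settling curves

The mean green-channel intensity of a fixed column ROI is tracked over the
time-lapse; efficiency at time t is 100·(I₀ − I_t)/I₀. Negative values
(intensity rising above the start frame, usually illumination drift) are
kept and flagged, never clipped. A `chromaticity` mode uses G/(R+G+B)
instead of the raw channel and is invariant to global brightness scaling;
the default remains raw green since the intended capture setup is controlled
indoor lighting. No blank-column correction is applied by default.

Settling time is *defined* here — the endpoint is not standardized in the
settling literature — as the first time the smoothed efficiency curve
(centred moving average, window 3) reaches 95% of its plateau (mean of the
last window), linearly interpolated between frames; both the fraction and
window are parameters and the convention is stated in outputs. On sampled
curves the crossing is resolved to within one frame interval, which is the
tolerance the tests assert for exponential and step-shaped truths.

## Cost model

Cost per m³ is energy·rate + consumables. Since 1 mg/L ≡ 1 g/m³, the volume
needed for 1 kg of dry biomass is 1000/harvested(mg/L) m³, and cost per kg
is the product. Defaults (packaged JSON): centrifugation at 5.8 kWh/m³ and
$0.33/kWh; sedimentation consumables $0.42761/m³ (5 kg NaCl + 10 mL 33% HCl
per m³ at the optimized pH 4 / 5 ppt protocol, taken as a single input
constant because itemized unit prices vary by market); recoveries 96.14% /
88.7% (species-specific sedimentation) and 90% (centrifugation). Currency
is fixed USD; capital and labor costs are out of scope.

## Synthetic generators

All generators are deterministic under a fixed seed and export their ground
truth.

- **Hemocytometer fields**: dark ellipses (default semi-axis 6–10 px,
  ellipticity ≤ 1.3) on a bright background (220) with faint rulings (200)
  and Gaussian pixel noise (σ = 3 by default). Overlap is budgeted by
  rejection sampling on centre distances; at overlap 0 cells are disjoint
  with a safety margin so exact count recovery is a meaningful test.
- **Settling frames**: ROI green level I(t) = I∞ + (I₀ − I∞)e^(−kt)
  (defaults I₀ = 180, I∞ = 20, k = 0.1 h⁻¹, frames every 2 h to 72 h,
  pixel σ = 2) over a static textured background; red/blue in the column are
  static so chromaticity falls as cells settle. Single-exponential decay is
  a deliberate simplification of monotone settling curves — it is not a
  hindered-settling or flocculation-kinetics model, and recovery tests on it
  say nothing about non-monotone or multi-phase real columns.
- **Response tables**: quadratic surface + per-block offsets + N(0, σ)
  noise on any design; the packaged published surfaces serve as default
  truths.
- **Growth series**: piecewise-exponential counts with lognormal
  multiplicative noise (mean-one parameterization).

Passing recovery tests on these generators demonstrates the correctness of
the measurement pipelines under the stated noise models; they do not
capture focus drift, uneven illumination, debris, bubbles, or cell-shape
diversity of real micrographs and columns.

## Numerical choices

- OLS via `numpy.linalg.lstsq`; leverages via thin QR.
- SS additivity (model + error = total) holds to 1e−8 relative and is
  asserted for every fit.
- Grid-search ties broken lexicographically (salinity, then pH) for
  determinism; all stochastic paths take explicit seeds.
- p-values from the F survival function; rendered tables print three
  decimals with `<0.001` flooring.
- Parameter-recovery testing uses 200 replicates at noise σ = 0.5 and
  checks each coefficient against its 3·SE band per replicate; with only 7
  error df a *joint* all-six-coefficients criterion would fail a few percent
  of replicates by construction, so coverage is assessed per coefficient.

## Known limitations

- Only two-factor quadratic designs; no Box-Behnken, mixtures, >2 factors,
  random block effects, or response transformations.
- Blocks are fixed effects; the blocks-averaged intercept is only the
  unweighted average under deviation coding.
- The watershed pipeline assumes roughly convex cells; heavily elongated or
  chained morphologies will over-split.
- Settling analysis assumes a fixed camera and ROI; no column detection or
  sludge-interface tracking.
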