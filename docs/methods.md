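# Methods

## Scope and model

`dxeval` evaluates one index test at a time against a binary reference
standard (1 = diseased, 0 = non-diseased). Two test kinds are supported:

- **qualitative** — the test already yields 0/1 classifications; the 2×2
  confusion matrix is built directly;
- **quantitative** — a numeric marker is first thresholded. The ROC curve
  is evaluated on every candidate threshold, the cutoff closest to the
  top-left corner of ROC space is selected, the marker is dichotomized at
  that cutoff, and all indicators are then computed from the resulting
  confusion matrix. This makes the reported Se/Sp *operating-point*
  estimates at a data-chosen cutoff; see Limitations.

The statistical content — indicator definitions, interval constructions,
missing-value rule — is summarised in the README; this note records the
assumptions and the choices that were genuinely open.

## Confidence intervals

- All intervals are 95%, with the normal quantile fixed at the literal
  constant **z = 1.96** (not `qnorm(0.975)`; the difference is ~3.6e-5 and
  only visible in cross-checks against other software). No user override
  is offered.
- **Wilson intervals** (Se, Sp, accuracy) are clamped to [0, 1]; at 0
  successes the lower bound is exactly 0 and at n successes the upper
  bound exactly 1 — the score interval collapses there algebraically, and
  the clamp protects that identity against floating-point round-off in
  the square root.
- **PPV/NPV propagation**: the Bayes expressions are monotone
  non-decreasing in both Se and Sp, so the min/max over the four
  (Se-bound, Sp-bound) combinations is attained at (lower, lower) and
  (upper, upper); the implementation still evaluates all four and the
  test suite asserts the attainment. This propagation is conservative and
  distribution-free, preferred here over delta-method intervals (poor
  small-sample normality) and bootstrap intervals (resampling noise,
  cost).
- **Likelihood ratios**: Simel log-scale intervals. The point estimate is
  missing only when its own denominator is degenerate (an empty margin,
  Sp = 1 for LR+, Sp = 0 for LR−). The interval is additionally missing
  whenever a cell entering a reciprocal of the log-variance is zero
  (TP or FP for LR+; FN or TN for LR−). So LR− = 0 with a missing
  interval is a representable state (perfect test). No continuity
  correction is applied.
- **Youden index**: variance is the sum of the two binomial variances,
  which assumes Se and Sp are independent — exact here, since they are
  estimated on disjoint margins. Bounds are reported **unclipped**: a
  bound slightly outside [0, 1] faithfully reflects the normal
  approximation, and clipping is left to presentation layers that want
  it.
- **Missing-value rule**: any zero denominator produces the missing
  sentinel (`None` internally, "NA" in rendered output), never an
  exception, an infinity or a NaN. A metric whose inputs are missing is
  fully missing.

## ROC analysis

- **Candidate thresholds** are the midpoints between consecutive distinct
  observed values, flanked by ∓∞ sentinels. With midpoints, strict (>)
  and non-strict (≥) positivity rules classify the observed data
  identically; the implementation uses *strictly greater* (mirrored for
  markers that run low-in-disease).
- **Direction** (whether high or low values indicate disease) is
  auto-detected by comparing group medians, ties resolving to
  higher-is-positive; an explicit override is available in both the API
  and the CLI.
- **AUC** is the trapezoidal area of this curve, which equals the
  Mann–Whitney probability with ties counted ½ — an identity the test
  suite verifies to 1e-12 against a pairwise-counting oracle.
- **DeLong interval**: placement values are computed via midranks
  (`scipy.stats.rankdata`), variance = S₁₀/m + S₀₁/n with unbiased
  (ddof = 1) sample variances, interval clipped to [0, 1]. With fewer
  than two cases or two controls the variance is undefined: the AUC is
  still reported, the bounds are missing.
- **Optimal cutoff**: minimises d(t) = √((1−Se)² + (1−Sp)²) over finite
  thresholds. Tie-break: smallest distance, then highest sensitivity,
  then smallest threshold — deterministic, and preferring case detection.
  Constant markers have no finite threshold and no cutoff.
- **Bootstrap band**: stratified (cases and controls resampled
  separately, so a replicate can never lose a class), default 5000
  iterations, sensitivity interpolated on a specificity grid of step
  0.01 (linear interpolation along the curve's upper envelope), band =
  pointwise 2.5th/97.5th percentiles. A replicate with constant scores
  degenerates to the diagonal curve and is retained. Seeded runs are
  bit-reproducible; unseeded runs use fresh randomness, so the band may
  vary slightly across runs. The band is graphical only — it is not used
  for any reported interval.
- **Qualitative tests** reuse the same machinery on 0/1 scores; the AUC
  then equals (Se + Sp)/2, and cutoff search and band are skipped.

## Input validation

Selected columns are cleaned row-wise (a row is dropped when *either*
selected cell is missing; other columns are irrelevant), then validated.
The four user-facing messages are fixed strings: qualitative test not
0/1; reference not 0/1; quantitative test not numeric; reference lacking
both levels after cleaning. Number-like text ("1.5") is accepted as
numeric, and 0.0/1.0 count as binary while 0.5 does not. Duplicate
header names are rejected outright rather than silently renamed. The
population prevalence must lie strictly inside (0, 1).

## Synthetic data generator

The generator emulates a small single-test evaluation study:
Disease ~ Bernoulli(p_disease); Test1 | Disease ~ χ² with
group-specific degrees of freedom (a positive, right-skewed marker);
Test2 | Disease ~ Bernoulli with the configured sensitivity (diseased)
or false-positive rate 1−specificity (non-diseased).

Defaults: n = 113, p_disease = 0.64 (a case-enriched cohort, distinct
from the analysis prevalence of 0.1 used in the examples — the package
deliberately separates cohort composition from population prevalence),
χ² df = 3.0 (diseased) vs 1.5 (non-diseased), binary_se = 0.9,
binary_sp = 0.7. The df pair was chosen so that the marker's AUC sits
near 0.73 (P(χ²₃ > χ²₁.₅) ≈ 0.729 by simulation), i.e. the moderate-
discrimination regime typical of real markers; df = (3, 1) would give a
noticeably stronger 0.82.

What the generator does **not** emulate: measurement error or assay
imprecision, within-subject correlation between Test1 and Test2 beyond
their common dependence on Disease, covariate structure, spectrum
effects, or verification bias. Passing tests on this cohort therefore
demonstrate the correctness of the computations and the pipeline, not
the field performance of any real assay.

## Problem sizes and tolerances in the test suite

Oracle-equivalence checks (AUC vs pairwise Mann–Whitney, DeLong variance
vs enumerated placements, cutoff vs exhaustive search) run on 500 random
instances with group sizes ≤ 20 at tolerance 1e-12. Interval coverage is
simulated with 2000 binomial draws (Wilson at p = 0.8, n = 40) and 500
seeded pipeline replicates at n = 200 (binary-test recovery). Generator
law-of-large-numbers checks use n = 10⁴–2·10⁵. The bootstrap band uses
50–200 iterations in tests and the 5000-iteration default everywhere
else.

## Known limitations

- Single-test analyses only: no comparative ROC between two markers, no
  partial or smoothed AUC, no multivariable adjustment, no
  time-dependent ROC.
- Se/Sp at the selected cutoff are reported without correction for the
  optimism induced by choosing the cutoff on the same data.
- LR and predictive-value intervals can be wide or missing with extreme
  or zero cell counts; no continuity corrections are applied.
- Predictive values inherit whatever error is in the user-supplied
  prevalence.
- Input format is .xlsx only.
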