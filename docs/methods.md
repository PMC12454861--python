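# Methods

## The estimation problem

A diagnostic AI emits a confidence score in [0, 1] per finding; deployment
requires a cutoff.  Two data sources constrain the choice in complementary
ways.  A pathology-enriched validation cohort with a multi-reader reference
standard estimates *sensitivity as a function of threshold* —
prevalence-independent, hence transferable out of the enriched setting.  A
large unlabelled clinical cohort estimates the *alert rate as a function of
threshold* — the prevalence-dependent quantity users actually experience,
available at scale because it needs no expert reading.  The pipeline
composes the two through the threshold: each achievable sensitivity maps to
the alert rate its threshold would produce in a chosen clinical subgroup.

## Reference standards from Likert ratings

Readers rate each case 0 (no suspicion) to 4 (certain).  Pooling to binary
uses four nested rules: RFS I counts only 4 as positive, RFS II ≥ 3,
RFS III ≥ 2, RFS IV ≥ 1.  The endpoints fix the intermediate rules as the
only monotone completion.  Positive sets nest from I to IV by construction;
the package asserts this on every cohort.  Missing rating cells are hard
validation errors, not imputed — the design assumes complete reading.  The
sensitizing analysis defaults to RFS IV.

## ROC conventions

A case is called positive iff score ≥ threshold; the convention is isolated
in one predicate because the alternative (>) is equally defensible.
Candidate thresholds are the unique observed scores plus a sentinel one ulp
above the maximum (the sensitivity-0 corner); tied scores collapse to one
operating point, with no interpolation — matching the iterative threshold
sampling the linkage stage performs.  AUC is the trapezoidal area, equal to
the normalized Mann–Whitney U with ties counted ½, and exactly invariant
under duplication of one class.  Youden's threshold maximizes
J = sensitivity + specificity − 1, breaking ties (within one ulp) toward
the highest threshold: fewest alerts at equal J.

Inverting a step-function ROC at a target sensitivity returns the *largest*
threshold whose sensitivity reaches the target — minimal sensitization —
together with the realized sensitivity of that operating point, which may
overshoot the target between steps.

## Linkage and the slope criterion

The linkage curve evaluates, per reader and grid sensitivity (default
0–100% in 1% steps), the inverted threshold and its alert rate
(#{score ≥ t}/n) in the subgroup; the mean curve averages alert rates
across readers at fixed sensitivity (not thresholds — averaging thresholds
would mix operating points of different sensitivity).

The target sensitivity is the first grid point whose slope of mean alert %
per sensitivity % exceeds 1.  Two estimator choices matter, both
configurable:

* **Realized denominator.**  Slopes divide the alert change by the change
  in *realized* mean sensitivity.  A fixed requested step sometimes crosses
  two ROC operating points and sometimes one; dividing by the requested
  step aliases this into spurious ×2 slope spikes, while the realized
  denominator keeps the estimate centred on dA/dS.  Grid steps reaching no
  new operating point carry no information and cannot trigger.
* **Windowed secant (default ±5 percentage points).**  Across one
  inter-positive-score gap, the alert change is approximately exponentially
  distributed around its mean, so a one-step slope estimate from an
  enriched cohort with ~10² positives has relative spread near 1 and the
  first-crossing scan would trigger on noise long before the true crossing.
  The centred ±5%-window secant averages over ~10–15 gaps; because the true
  slope increases monotonically through the crossing, the centred secant is
  unbiased there to first order (exact for locally linear slope).  Setting
  the window at or below the grid step recovers the plain forward
  difference, which remains the right choice for noise-free analytic
  curves.

If no slope exceeds 1, the maximum-sensitivity grid point is returned
flagged `criterion_triggered=False`: the criterion defines an upper limit
of justifiable sensitization, and when the limit never binds, the most
sensitive operating point is that limit.  A slope exactly at 1 (identical
score channels degenerate the curve to the identity) does not trigger; the
comparison carries a 10⁻⁹ roundoff guard.

Per-reader optimized thresholds invert each reader's own ROC at the common
mean-curve target (per-reader targets are available but not default); the
aggregate OT is their arithmetic mean (median selectable).  The alert rate
is re-measured at the aggregate OT.

## Diagnostic metrics and reconstruction

Each metric is a binomial proportion with its own numerator/denominator and
a 95% Wald interval p̂ ± 1.959964·√(p̂(1−p̂)/n), clipped to [0, 100]; Wald
(not Wilson) is the default because it is the convention of the reader-study
tables this package audits, and it reproduces their printed brackets
exactly.  Zero-denominator metrics are flagged undefined rather than NaN.
Two-proportion comparisons use the continuity-corrected chi-square with a
Fisher-exact fallback when any expected cell is below 5; the comparison is
unpaired, a deliberate approximation since the paired structure of
same-sample threshold contrasts is not recoverable from summaries.

Reconstruction inverts printed one-decimal summaries: positives
P = round(prev·n/100), tp the integer rendering closest to the printed
sensitivity over P (ties toward the larger count, flagged ambiguous), tn
likewise over n − P.  If no integer lands within 0.05 percentage points
(half a printed decimal) of the stated percent the summary is internally
inconsistent and reconstruction refuses — which it provably does for a
handful of published cells whose printed values are truncations or copy
errors; the test suite pins those as known discordant.  Projected subgroup
counts use the ceiling of prev·size, the only rounding rule consistent with
the published projections.

## Synthetic study generator

The generator emulates the two-cohort design, not images:

* **Scores.**  Per pathology, diseased ~ Beta(2, 3), healthy ~ Beta(1, 14)
  by default: bounded support, right-skewed mass near zero as routine CXR
  score histograms show, AUC ≈ 0.93, and optimized thresholds landing in
  the low-score range where vendor defaults live.
* **Readers.**  Diseased cases carry latent severity s ~ U(0, 1) (healthy:
  0); reader r perceives s + N(0, σ_r) (σ_r = 0.1) and maps it through
  cutpoints (0.15, 0.35, 0.55, 0.75) to Likert 0–4 (count of cutpoints
  strictly below).  The diseased score is the Beta quantile of the same
  severity, coupling reader perception to the AI score as real severity
  does.
* **Cohorts.**  The enriched cohort is composed (exactly round(n·prev)
  diseased per pathology — it is deliberately enriched, not sampled) at
  prevalences 24.9/25.9/10.3/8.4% over 563 cases with six readers; the
  clinical cohort samples Bernoulli disease states at subgroup prevalences
  (outpatient 23.5/23.5/2.5/8.0%, inpatient 46.5/29.0/12.5/5.5%) over
  3,619 + 11,900 cases, with a 200-case ground-truth sample reading per
  subgroup.
* **Determinism.**  One global seed; per-stream seeds derived by SHA-256 of
  (seed, purpose, pathology, subgroup), so adding a pathology never
  perturbs another's draws, and runs are byte-identical across platforms.

In the noise-free regime (σ_r = 0, first cutpoint 0) reader labels equal
ground truth and the linkage has the closed form
A(t) = π·SF₁(t) + (1−π)·SF₀(t) with sensitivity S(t) = SF₁(t); the target
threshold solves dA/dS = π + (1−π)·f₀/f₁ = 1.  These oracles back the
recovery tests: with noise-free readers and large cohorts (10⁴ enriched /
10⁵ clinical — at 563 cases the sensitivity axis itself carries ~3-point
quantile noise that no estimator can remove) the empirical target matches
the oracle to one grid step; at study-design sizes with default noisy
readers the median absolute OT error over 20 replicates stays within 0.05
score units.  Residual bias at paper scale comes from the reference
standard itself: noisy readers admit false-positive reference cases and
miss low-severity ones, tilting the measured sensitivity axis — a property
of the design, not of the estimator.

What the generator does not emulate: inter-pathology co-occurrence, device
artifacts (drains mimicking pneumothorax), reader-specific bias or
experience structure, case-mix drift between cohorts.  Passing recovery
tests therefore show the pipeline's statistical machinery is correct under
the stated model, not that any particular clinical threshold is right.

## Problem sizes and numerical choices

Tests run the full design at its native sizes (563 / 15,786) where the
check concerns that design, and scaled-down cohorts (≤ 3,000 clinical
cases) for plumbing checks; the Monte-Carlo oracle for the analytic linkage
uses 10⁶ draws.  Alert counting uses a presorted score array with binary
search.  Score CSVs round to six decimals — far below any quantity of
interest, exactly reproducible.  Figures are best-effort illustration;
emitted CSV/JSON numbers are the contract and are compared byte-for-byte
across reruns.

## Known limitations

* The slope criterion is a first-crossing rule on an estimated curve; with
  very small reader panels its variance is dominated by the enriched
  cohort's positive count, and the ±5% window trades a little localization
  for false-trigger control.  Alternative estimators (isotonic or convex
  regression of the linkage curve) would be natural extensions.
* The unpaired proportion test understates the power of same-sample
  threshold comparisons.
* Published-table reconstruction assumes half-up rounding to one decimal;
  truncated or mistyped cells are detected, not repaired.
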