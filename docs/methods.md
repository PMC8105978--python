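# Methods

## Scope and model

`sarcoscreen` validates a continuous screening score against a binary
reference standard, the design of a classical diagnostic-test-accuracy (DTA)
study. The concrete instance shipped is the Ishii sarcopenia score versus
the AWGS2019 rule, but every layer (contingency engine, ROC analysis,
generator) is generic over the screen.

**Reference standard.** AWGS2019 diagnoses sarcopenia as low muscle mass
(ASMI < 7.0 kg/m² men, < 5.7 kg/m² women) together with low strength
(grip < 28 kg men, < 18 kg women) or low performance (gait < 1.0 m/s).
Every comparison is strict `<`; a measurement exactly at a cut-off is
normal. The consensus texts write the strength and gait cuts with `<` and
we apply the same operator to ASMI for uniformity — this is a package
convention, exposed via `CriteriaThresholds` so any variant can be
configured. "Severe" sarcopenia (all three components low) is derived but
unused by the pipeline.

**Screen.** The Ishii score is affine in (age, grip, CC) with sex-specific
coefficients; it is evaluated at full floating precision (no rounding before
comparison with a cut-off — whether the original study rounded is unstated,
so the cleaner convention is the default). Screen positivity is
`score >= cutoff` by default; a `gt` convention is provided because the
source material itself is inconsistent ("≥ 105" in one place, "more than 95"
in another), and every report records which convention was used.

## Accuracy metrics

From a 2×2 table: sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV
tp/(tp+fp), NPV tn/(tn+fn), LR+ = sens/(1−spec), LR− = (1−sens)/spec,
J = sens + spec − 1. PPV/NPV are the observed proportions in the study's own
table (prevalence as observed), not Bayes-transported values. Degenerate
ratios are flagged (`math.inf` for LR+ at perfect specificity, `None` where
undefined) rather than silently zeroed, and render as `∞` / `NA`.

Display rounding is half-up on the percent scale — the convention under
which the published female rows are internally consistent — with the mixed
precision of the published table: 2 decimals for sensitivity/specificity and
LRs, integer percent for PPV/NPV. Computation always runs at full precision;
rounding is display-only.

## Count reconstruction

`reconstruct_counts` inverts a printed accuracy row: exhaustive search over
tp ∈ 0..n_pos × tn ∈ 0..n_neg keeping every table whose rounded
sensitivity/specificity equal the printed values. All consistent tables are
returned: one (unique inversion), several (under-determined), or none. The
published male original-cut-off row (64.94%/85.46% on margins 92/370) admits
no integer table at 2-decimal rounding — the search provably returns empty,
which the package surfaces as a finding (a possible analysis-set exclusion
or typo upstream) and never repairs.

## ROC analysis

Candidate thresholds are the distinct observed scores (descending) plus a
leading sentinel, positivity `score >= t`; the curve therefore starts at
(0,0) and ends at (1,1) with nondecreasing coordinates. AUC is the
trapezoidal area, which equals the Mann–Whitney statistic
mean[1(pos>neg) + ½·1(pos=neg)]; both are implemented independently and
their equality is a tested invariant, alongside invariance under strictly
increasing score transforms and the binormal closed form
AUC → Φ((μ₁−μ₀)/√(σ₀²+σ₁²)).

**Confidence intervals.** Default is DeLong's asymptotic interval via
placement values (deterministic; the variance is S₁₀/m + S₀₁/n with sample
variances of the per-subject placements), truncated to [0,1]. A
class-stratified percentile bootstrap (default 2000 resamples, seeded) is
provided as a cross-check; on moderate samples the two agree to ~0.02. The
original study does not name its CI method; DeLong is the standard
deterministic choice.

**Youden-optimal cut-off.** J is evaluated at every candidate threshold;
ties go to the smallest threshold (maximizing sensitivity among tied
candidates) and are flagged. The search runs over observed score values by
default; an integer grid is available (`integer_cutoff_grid` /
`grid=range(...)`) since published "new" cut-offs are often integers, which
suggests a gridded search upstream.

## Synthetic cohort generator

The validation study's participant-level data are unreleased, so the
generator emulates the published structure: cohort size 941 with male
fraction 462/941; per-sex age-band probabilities (<65, 65–69, 70–79, ≥80)
and per-sex mean ± SD for height, ASMI, grip, gait speed and CC taken from
the published descriptive table; age support 60–92 years.

Joint structure is a Gaussian copula: a 6-dimensional correlated standard
normal is drawn per subject; the age coordinate is pushed through the
band-mixture quantile function (uniform within bands), the rest through
their Gaussian marginals. Gaussian marginals are the minimal assumption
given that only means ± SD are published. Physiologically impossible rows
(outside e.g. grip ∈ [5, 70] kg, gait ∈ [0.2, 2.5] m/s) are redrawn, with
clipping only as a last resort; the bounds sit ≥ 3 SD from every mean, so
rejection is rare and marginal distortion negligible (sample means verified
within 3 SE at n = 50 000).

**Correlation matrix.** Inter-measurement correlations are not published
anywhere in the source material; the shipped matrix is a calibrated package
convention: age moderately degrades grip, gait and muscle mass (−0.15 to
−0.35), muscle-mass variables cohere (ASMI–grip 0.50, ASMI–CC 0.55), the
rest mild positive. It was fixed once by requiring (a) positive
definiteness, (b) rank-based parameter recovery within ±0.03 at n = 50 000,
and (c) an emergent Ishii-vs-AWGS2019 AUC inside [0.75, 0.90] per sex — the
envelope of the published per-sex 95% intervals. With it the emergent AUC is
≈ 0.84 in both sexes.

**Emergent status and prevalence calibration.** Sarcopenia status is never
sampled as a label; it is derived by the classifier from the generated
measurements, preserving the screen/reference-standard dependence the ROC
needs. With the published means verbatim, the emergent prevalence is ≈ 24%
rather than the reported 18.38% — expected, since marginal means ± SD under
a Gaussian copula do not pin down the joint exceedance probabilities.
`calibrate_prevalence` therefore bisects a single scalar shift t (in SD
units, applied to the ASMI/grip/gait means of both sexes; SDs, correlations
and the other marginals untouched) until the emergent prevalence on a
50 000-subject calibration cohort hits the target; common random numbers
make the search monotone and deterministic, and a target outside the
reachable range raises with the full search trace. The required shift is
small (≈ +0.1 SD).

**What passing tests do and do not show.** The generator matches published
marginals, band proportions and the calibrated prevalence, and yields a
screen with realistic discrimination. It does not reproduce the actual
cohort: real anthropometric data have skewness, digit preference,
measurement error and age-dependent variance the copula omits, and the
published dataset-dependent numbers (AUC 0.84/0.81, new cut-offs 102/95)
are checked only as plausibility envelopes, never as point targets.

## Numerical and interface choices

- All randomness flows from a single integer seed (`numpy.random.default_rng`);
  same seed ⇒ byte-identical cohorts and reports.
- Cohort CSVs round-trip exactly (`float_precision="round_trip"` on read).
- Sample (n−1) SD throughout; SD undefined (reported absent) for n = 1.
- Validation bounds (age 60–120, height 1.0–2.2 m, gait ≤ 3 m/s,
  CC 15–60 cm, all measurements positive and finite) are sanity limits;
  failing rows are excluded and logged, mirroring a complete-case analysis.
  The default assumes zero exclusions, since none are reported upstream.
- A sex stratum with a single reference class skips its ROC with a logged
  warning instead of failing the study.
- Problem sizes in the test suite and acceptance script: exactness checks
  run on the published margins (n ≤ 941); stochastic checks use n = 20 000
  cohorts (AUC envelope, binormal limit) and n = 50 000 (marginal fidelity,
  correlation recovery, calibration), which keeps Monte-Carlo error an order
  of magnitude below each tolerance.

## Known limitations

- The copula correlation matrix is a convention, not an estimate; downstream
  quantities that depend on the full joint (PPV at a given cut-off, the
  exact Youden-optimal threshold) vary with it.
- DeLong assumes asymptotic normality of the placement-value statistic; for
  very small or extremely imbalanced strata prefer the bootstrap.
- No CIs on sensitivity/specificity/PPV/NPV (none are published for the
  rows being validated); no partial AUC, smoothed ROC, or paired AUC
  comparison tests.
- Single-visit cohorts only; no longitudinal support or unit autodetection.
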