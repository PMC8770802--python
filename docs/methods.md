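# Methods

## Scope and model

The package evaluates a fixed six-item clinical screen (ER²) against a
binary reference diagnosis of major neurocognitive disorder (MND) in a
cross-sectional ED cohort. There is no model fitting in the instrument
itself: the score is a deterministic weighted sum (weights 1,1,1,1,5,5) and
the strata are fixed closed intervals (low 0–3, moderate 4–5, high ≥ 6).
Exhaustive enumeration of the 64 item vectors shows the moderate band is
reachable only as four 1-point items (score 4) or a single 5-point item
(score 5), and the high band exactly as both 5-point items or one 5-point
item plus at least one 1-point item.

## Accuracy metrics

Metrics are exact rationals of the 2×2 cell counts; rounding is half-up and
applied only to display values, so reproduction checks never depend on
float formatting. Design choices:

- **AUROC of a binary screen** is taken as (sensitivity + specificity)/2,
  the trapezoidal area through the screen's single operating point. This
  identity reproduces both published AUROCs (0.71, 0.82) to 2 dp, and
  `roc_over_score` verifies it coincides with the full-score trapezoid
  restricted to the dichotomised predictor.
- **Negative-likelihood-ratio convention.** Both LR− = (1−sens)/spec and its
  reciprocal spec/(1−sens) are computed. The reciprocal (values > 1) is the
  convention behind the published row (10.34, 7.87); the count-exact
  high-risk value is 10.346, one unit of the last printed digit away from
  10.34. Reports label the convention explicitly.
- **Undefined ratios** (zero denominators, e.g. LR+ of a perfect screen) are
  reported as explicit `undefined` flags, never as infinities. No
  continuity correction is applied inside accuracy metrics; the intended
  counts are large.
- **Known inconsistency.** The published high-risk PPV (0.59) cannot be
  produced from the published counts, which give 340/684 = 0.497. The
  pipeline reports 0.50 with an attached discrepancy note; it does not
  attempt to match 0.59.
- **Proportion CIs** (not part of the published table, provided as good
  practice): Wilson score interval by default, Clopper–Pearson (exact beta)
  by flag; bounds clipped to [0, 1].

## Association

The unadjusted odds ratio is computed two ways that must agree: the
cross-product ratio with the Woolf interval
exp(log OR ± z·√(Σ 1/cell)), and a maximum-likelihood logistic regression
with the single binary covariate, fitted as a two-row grouped-binomial GLM
(statsmodels, IRLS tolerance 1e−12). With one binary covariate the model is
saturated, so the MLE equals the cross-product ratio and its Wald CI equals
the Woolf interval; the test suite asserts agreement to well under four
significant digits on randomised tables. Woolf reproduces all four
published CI bounds ([10.9; 31.2], [17.7; 39.3]) at 1 dp, which is why it
is the lead method. A zero cell is reported as separation, not as a silent
huge estimate; a Haldane–Anscombe +0.5 correction is available by flag and
flagged in the result. A generic multi-covariate logistic fit is provided
as exploratory plumbing only; no particular adjusted model is endorsed
because no adjustment set is specified for the published adjusted
estimates, which are therefore out of scope.

Group comparisons use uncorrected Pearson chi-square for categorical
variables (Yates by flag) and the pooled-variance unpaired t-test for
continuous ones (Welch by flag); uncorrected/pooled defaults match the
large-sample conventions of the source analysis era. On 2×2 tables the
chi-square equals the squared pooled two-proportion z, which the suite
checks as an algebraic identity.

## Synthetic cohort generator

The generator emulates the published group-level margins, since no
patient-level data are deposited. Defaults (the study conditions, not
tuning knobs): n = 999; MND prevalence 356/999; per-group item
probabilities — temporal disorientation 323/356 vs 174/643, polypharmacy
288/356 vs 475/643, home support 314/356 vs 398/643, male 1−237/356 vs
1−414/643, walking aid 0.256 vs 0.255 (the published MND+ count, 572 of
356, is internally impossible, so the printed percentages are used); age
truncated-normal at (86.6, 5.3) / (83.9, 5.5) years with the inclusion
floor of 75; visit-reason and triage distributions from the printed
percentages, normalised to sum to one (they print to 100.1% and 100.5% in
the MND+ group); hospital admission 0.482/0.463 as inert metadata.

Items are drawn conditionally independently given MND status, because only
per-group marginals are published. Consequences a user should expect:

- The "age 85+" item is recomputed from the drawn age (records stay
  internally coherent), so its marginal follows from the truncated-normal
  age model rather than being set directly.
- The high-risk stratum is a function of the joint item vector, so its
  simulated per-group rates (~0.93 MND+, ~0.44 MND−) only approximate the
  published 95.2%/53.5% — real items are correlated. The frozen published
  counts (`fixture_table1`), not simulation, are therefore the reproduction
  surface for the accuracy and association tables. An optional
  Gaussian-copula `item_correlation` knob couples the four drawn items for
  sensitivity analyses; it preserves the marginals.
- Because ages are truncated at 75, the empirical age mean/SD differ from
  the location/scale parameters (e.g. 84.53 vs 83.9 for the MND− group);
  recovery tests compare against the truncated-normal theory values.

Passing simulation tests therefore show the pipeline is correct under
conditional independence and the stated margins; they do not certify
performance on real, correlated ED data.

## Numerical and reproducibility choices

All randomness flows through one `numpy` generator seeded from the
configuration; the seed is echoed in the report provenance and in a comment
line of written cohort CSVs, and identical seeds give byte-identical CSVs
and JSON reports. Replicate studies derive child seeds from
`numpy.random.SeedSequence`, kept below 2³¹. Problem sizes used by the
checked examples: 64-vector exhaustive enumeration; 1,000 random tables for
the logistic/cross-product identity; 200 replicate cohorts of n = 999 for
parameter recovery in the test suite (100 in the acceptance script);
n = 100,000 for single-cohort recovery at 2-SE binomial bands.

## Known limitations

- Missing item answers fail hard by default; the optional missing-as-no
  policy is logged on every use. How the instrument handles refusals or
  unassessable patients (e.g. aphasia) is not specified anywhere, so no
  policy beyond these two is offered.
- Single-centre cross-sectional margins drive the generator; no arrival
  processes, admission outcomes, or MND severity/subtype are modelled.
- No multi-reader ROC comparison statistics (e.g. DeLong); only the panel
  above plus CIs.
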