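# er2screen

Diagnostic-accuracy toolkit for the **ER² (Emergency Room Evaluation and
Recommendations)** geriatric screening instrument, evaluated as a screen for
**major neurocognitive disorders (MND)** in older emergency-department (ED)
visitors.

## Who this is for

Clinical epidemiologists and geriatric-ED researchers who want to (a) score
patients with the ER² instrument, (b) compute the full diagnostic-accuracy
panel of a binary screen against a reference diagnosis, (c) estimate
unadjusted odds ratios two ways (closed form and logistic MLE), and (d) test
every stage on synthetic cohorts with realistic structure when patient-level
data are unavailable.

## The instrument and the statistics

ER² asks six closed yes/no questions: age ≥ 85 years, male sex, polypharmacy
(≥ 5 daily medications), use of formal/informal home support (1 point each),
use of a walking aid, and temporal disorientation — inability to name the
current month and/or year (5 points each). The total score *S* ∈ [0, 14]
stratifies risk as low (0–3), moderate (4–5), high (≥ 6).

For a binary screen cross-tabulated against the MND diagnosis
(tp, fp, fn, tn):

- sensitivity = tp/(tp+fn), specificity = tn/(fp+tn), PPV = tp/(tp+fp),
  NPV = tn/(fn+tn), LR+ = sens/(1−spec), LR− = (1−sens)/spec;
- AUROC of a single-threshold test = (sens + spec)/2 (the two-point
  trapezoid), generalised to the full score by `roc_over_score`;
- odds ratio OR = (tp·tn)/(fp·fn) with the Woolf interval
  exp(log OR ± z·√(1/tp + 1/fp + 1/fn + 1/tn)), cross-checked against a
  saturated logistic regression.

All count-derived metrics are carried as exact rational numbers
(`fractions.Fraction`); decimal rounding (half-up) happens only at display.

Two reporting quirks of the source analysis are handled explicitly: the
"negative likelihood ratio" is quoted in its reciprocal convention
spec/(1−sens) (values > 1), and the published high-risk PPV (0.59) is not
derivable from the published counts (340/684 = 0.50) — the report computes
the count-based value and attaches a discrepancy note rather than matching
the printed one.

## Worked example

Score one patient (87-year-old man, ≥5 medications, home support, no walking
aid, cannot name the month):

```
$ er2 score --age 87 --sex male --polypharmacy yes --home-support yes \
            --walking-aid no --temporal-disorientation yes
{"score": 9, "risk_level": "high"}
```

1 (age) + 1 (male) + 1 (polypharmacy) + 1 (home support) + 5 (temporal
disorientation) = 9 points → high-risk stratum.

Reproduce the accuracy analysis from the frozen published cross-tabulations
(356 MND+ / 643 MND− of 999 visitors; 340/344 screened high-risk, 323/174
temporally disoriented per group):

```
$ er2 report --fixture
| Metric | High-risk level | Temporal disorientation |
|---|---|---|
| Sensitivity | 0.96 | 0.91 |
| Specificity | 0.47 | 0.73 |
| Positive predictive value | 0.50 | 0.65 |
| Negative predictive value | 0.95 | 0.93 |
| LR+ (sens/(1-spec)) | 1.79 | 3.35 |
| LR- ((1-sens)/spec) | 0.10 | 0.13 |
| 1/LR- (spec/(1-sens)) | 10.35 | 7.87 |
| AUROC | 0.71 | 0.82 |

| Screen | OR | 95% CI | method |
|---|---|---|---|
| ER² high-risk level | 18.5 | [10.9; 31.2] | woolf |
| Temporal disorientation item | 26.4 | [17.7; 39.3] | woolf |
```

Reading: the high-risk level is the more sensitive screen (0.96 — it misses
only 16 of 356 MND+ patients) while the temporal-disorientation item alone
is the more specific and informative one (LR+ 3.35, AUROC 0.82, OR 26.4).

Simulate a cohort and analyse it end to end:

```
$ er2 simulate --seed 7 --out cohort.csv
$ er2 evaluate --cohort cohort.csv --out report.json --md report.md
```

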