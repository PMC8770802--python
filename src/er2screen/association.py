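"""Odds-ratio estimation and baseline group comparisons.

Two routes to the same unadjusted association between a binary screen and
the MND diagnosis:

* the closed-form cross-product odds ratio with a Woolf confidence
  interval, CI = exp(log OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)); and
* maximum-likelihood logistic regression with the single binary covariate,
  whose exponentiated coefficient equals the cross-product ratio exactly
  (the model is saturated), fitted through statsmodels.

Group comparisons for the baseline-characteristics table use Pearson
chi-square (no continuity correction by default) for categorical variables
and the unpaired t-test (pooled variance by default, Welch by flag) for
continuous ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .diagnostics import ConfusionTable

__all__ = [
    "OddsRatioEstimate",
    "GroupComparison",
    "SeparationError",
    "odds_ratio_2x2",
    "logistic_fit_binary",
    "logistic_fit",
    "compare_groups",
    "table1_summary",
    "TABLE1_VARIABLES",
]


class SeparationError(ValueError):
    """A zero cell makes the logistic MLE diverge (complete separation)."""


@dataclass(frozen=True)
class OddsRatioEstimate:
    """Odds ratio with Wald CI on the log scale and two-sided p-value."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    p_value: float
    method: str  # "woolf_closed_form" | "logistic_mle"
    corrected: bool = False  # Haldane–Anscombe +0.5 applied


@dataclass(frozen=True)
class GroupComparison:
    """One row of a baseline-characteristics comparison."""

    variable: str
    kind: str  # "continuous" | "binary" | "categorical"
    summaries: dict
    test: str  # "chi-square" | "t-test"
    statistic: float
    df: float
    p_value: float
    warnings: tuple[str, ...] = ()


def odds_ratio_2x2(
    table: ConfusionTable,
    alpha: float = 0.05,
    *,
    haldane: bool = False,
) -> OddsRatioEstimate:
    """Cross-product odds ratio with the Woolf confidence interval.

    OR = (tp*tn)/(fp*fn); se(log OR) = sqrt(1/tp + 1/fp + 1/fn + 1/tn);
    CI = exp(log OR ± z_{1-alpha/2} * se). With a zero cell the estimate
    does not exist: either raise, or with ``haldane=True`` add 0.5 to every
    cell (flagged in the result).
    """
    cells = [table.tp, table.fp, table.fn, table.tn]
    corrected = False
    if any(c == 0 for c in cells):
        if not haldane:
            raise SeparationError(
                "zero cell in 2x2 table; pass haldane=True for the +0.5 "
                "corrected estimate"
            )
        cells = [c + 0.5 for c in cells]
        corrected = True
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioEstimate(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        log_or=log_or,
        se_log_or=se,
        p_value=float(p),
        method="woolf_closed_form",
        corrected=corrected,
    )


def logistic_fit_binary(
    cohort_or_table: ConfusionTable | Sequence,
    predictor: str | None = None,
    outcome: str = "mnd_diagnosis",
    alpha: float = 0.05,
) -> OddsRatioEstimate:
    """Logistic MLE of the outcome on one binary predictor.

    Accepts either a prebuilt :class:`ConfusionTable` or a cohort plus a
    named predictor (see :data:`er2screen.diagnostics.PREDICTORS`). With a
    single binary covariate the model is saturated, so the exponentiated
    coefficient must reproduce the cross-product ratio; the Wald CI matches
    the Woolf interval.
    """
    if isinstance(cohort_or_table, ConfusionTable):
        table = cohort_or_table
    else:
        from .diagnostics import build_confusion

        if predictor is None:
            raise ValueError("a predictor name is required with a cohort")
        table = build_confusion(cohort_or_table, predictor)

    if min(table.tp, table.fp, table.fn, table.tn) == 0:
        raise SeparationError(
            "complete separation: a 2x2 cell is zero, the logistic MLE "
            "does not converge to a finite coefficient"
        )

    # grouped-binomial GLM: one row per screen arm. The model is saturated
    # (2 rows, 2 parameters), so statsmodels warns about zero residual df
    # and "perfect prediction"; both are expected here and silenced.
    endog = np.array([[table.tp, table.fp], [table.fn, table.tn]], dtype=float)
    exog = sm.add_constant(np.array([[1.0], [0.0]]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
            tol=1e-12, maxiter=200
        )
    log_or = float(fit.params[1])
    se = float(fit.bse[1])
    z = stats.norm.ppf(1 - alpha / 2)
    return OddsRatioEstimate(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        log_or=log_or,
        se_log_or=se,
        p_value=float(fit.pvalues[1]),
        method="logistic_mle",
    )


def logistic_fit(
    frame: pd.DataFrame, outcome: str, covariates: Sequence[str]
) -> pd.DataFrame:
    """Generic multi-covariate logistic fit (exploratory plumbing).

    Returns exponentiated coefficients with Wald 95% CIs, one row per
    covariate. Provided so users can explore covariate adjustments; no
    particular adjusted model is endorsed.
    """
    exog = sm.add_constant(frame[list(covariates)].astype(float))
    fit = sm.GLM(
        frame[outcome].astype(float), exog, family=sm.families.Binomial()
    ).fit()
    z = stats.norm.ppf(0.975)
    rows = []
    for name in covariates:
        b, se = float(fit.params[name]), float(fit.bse[name])
        rows.append(
            {
                "covariate": name,
                "odds_ratio": math.exp(b),
                "ci_low": math.exp(b - z * se),
                "ci_high": math.exp(b + z * se),
                "p_value": float(fit.pvalues[name]),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


#: Baseline variables summarised by :func:`table1_summary`:
#: (column, kind). ``binary`` columns are summarised per category level.
TABLE1_VARIABLES: tuple[tuple[str, str], ...] = (
    ("age", "continuous"),
    ("female", "binary"),
    ("lives_at_home", "binary"),
    ("home_support", "binary"),
    ("polypharmacy", "binary"),
    ("walking_aid", "binary"),
    ("temporal_disorientation", "binary"),
    ("visit_reason", "categorical"),
    ("triage_level", "categorical"),
    ("er2_score", "continuous"),
    ("er2_risk_level", "categorical"),
    ("admitted", "binary"),
)


def _chi_square(
    grouped: pd.DataFrame, yates: bool
) -> tuple[float, float, float, tuple[str, ...]]:
    notes: list[str] = []
    res = stats.chi2_contingency(grouped.to_numpy(), correction=yates)
    if (res.expected_freq < 1).any():
        notes.append("expected cell count < 1")
    return float(res.statistic), float(res.dof), float(res.pvalue), tuple(notes)


def compare_groups(
    frame: pd.DataFrame,
    variables: Sequence[tuple[str, str]],
    group: str = "mnd_diagnosis",
    *,
    yates: bool = False,
    welch: bool = False,
) -> list[GroupComparison]:
    """Compare each variable between the two diagnosis groups.

    ``frame`` is a patient-level DataFrame (see
    :func:`er2screen.cohort.cohort_to_frame`). Categorical and binary
    variables get a Pearson chi-square on the groups-by-levels table;
    continuous ones get an unpaired two-sided t-test (pooled variance
    unless ``welch``).
    """
    g = frame[group].astype(bool)
    if g.all() or not g.any():
        raise ValueError("both diagnosis groups must be non-empty")

    out: list[GroupComparison] = []
    for name, kind in variables:
        if name not in frame.columns:
            raise KeyError(f"variable {name!r} not in cohort frame")
        col = frame[name]
        if kind == "continuous":
            a = col[g].astype(float).to_numpy()
            b = col[~g].astype(float).to_numpy()
            notes: tuple[str, ...] = ()
            if len(a) < 2 or len(b) < 2:
                stat, p, df = math.nan, math.nan, math.nan
                notes = ("t-test undefined: a group has fewer than 2 subjects",)
            else:
                res = stats.ttest_ind(a, b, equal_var=not welch)
                stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
            summaries = {
                "present": {"mean": float(np.mean(a)), "sd": float(np.std(a, ddof=1)) if len(a) > 1 else math.nan, "n": len(a)},
                "absent": {"mean": float(np.mean(b)), "sd": float(np.std(b, ddof=1)) if len(b) > 1 else math.nan, "n": len(b)},
            }
            out.append(
                GroupComparison(name, kind, summaries, "t-test", stat, df, p, notes)
            )
        else:
            tab = pd.crosstab(g, col)
            stat, df, p, notes = _chi_square(tab, yates)
            summaries = {}
            for label, row in (("present", True), ("absent", False)):
                counts = tab.loc[row] if row in tab.index else tab.iloc[0] * 0
                total = int(counts.sum())
                summaries[label] = {
                    str(level): {
                        "count": int(cnt),
                        "percent": 100.0 * cnt / total if total else math.nan,
                    }
                    for level, cnt in counts.items()
                }
            out.append(
                GroupComparison(
                    name, kind, summaries, "chi-square", stat, df, p, notes
                )
            )
    return out


def table1_summary(
    frame: pd.DataFrame,
    variables: Sequence[tuple[str, str]] = TABLE1_VARIABLES,
    *,
    yates: bool = False,
    welch: bool = False,
) -> tuple[list[GroupComparison], str]:
    """Baseline-characteristics table by diagnosis group, plus markdown.

    Returns the structured comparisons and a rendered markdown table with
    counts (percentages), means ± SD, and p-values.
    """
    variables = [v for v in variables if v[0] in frame.columns]
    comparisons = compare_groups(frame, variables, yates=yates, welch=welch)

    lines = [
        "| Variable | MND present | MND absent | P-value |",
        "|---|---|---|---|",
    ]
    for c in comparisons:
        if c.kind == "continuous":
            p_ = c.summaries["present"]
            a_ = c.summaries["absent"]
            lines.append(
                f"| {c.variable}, mean ± SD | {p_['mean']:.1f} ± {p_['sd']:.1f} "
                f"| {a_['mean']:.1f} ± {a_['sd']:.1f} | {_fmt_p(c.p_value)} |"
            )
        elif c.kind == "binary":
            p_ = c.summaries["present"].get("True", {"count": 0, "percent": 0.0})
            a_ = c.summaries["absent"].get("True", {"count": 0, "percent": 0.0})
            lines.append(
                f"| {c.variable}, n (%) | {p_['count']} ({p_['percent']:.1f}) "
                f"| {a_['count']} ({a_['percent']:.1f}) | {_fmt_p(c.p_value)} |"
            )
        else:
            lines.append(f"| **{c.variable}**, n (%) |  |  | {_fmt_p(c.p_value)} |")
            for level in c.summaries["present"]:
                p_ = c.summaries["present"][level]
                a_ = c.summaries["absent"].get(level, {"count": 0, "percent": 0.0})
                lines.append(
                    f"| &nbsp;&nbsp;{level} | {p_['count']} ({p_['percent']:.1f}) "
                    f"| {a_['count']} ({a_['percent']:.1f}) |  |"
                )
    return comparisons, "\n".join(lines)


def _fmt_p(p: float) -> str:
    if math.isnan(p):
        return "undefined"
    return "<0.001" if p < 0.001 else f"{p:.3f}"
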