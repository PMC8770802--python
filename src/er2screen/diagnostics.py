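"""Screen-vs-diagnosis 2x2 tables and the diagnostic performance panel.

Everything downstream of the cohort reduces to a 2x2 cross-tabulation of a
binary screen (ER² high-risk level, the temporal-disorientation item, or a
custom score threshold) against the binary reference diagnosis of major
neurocognitive disorder (MND). Metrics are carried as exact rational
numbers (:class:`fractions.Fraction`); rounding happens only at
presentation.

The area under the ROC curve of a single-threshold binary screen equals
(sensitivity + specificity) / 2 — the trapezoid through its one operating
point. :func:`roc_over_score` generalises this to the full 0–14 score.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .instrument import ER2Items, classify_risk, is_high_risk, score_er2

__all__ = [
    "ConfusionTable",
    "DiagnosticPerformance",
    "PREDICTORS",
    "build_confusion",
    "diagnostic_performance",
    "binary_auroc",
    "roc_over_score",
    "proportion_ci",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of a binary screen against the binary reference diagnosis.

    tp: screen+, MND+   fp: screen+, MND-
    fn: screen-, MND+   tn: screen-, MND-
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"cell {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"cell {name} must be non-negative, got {v}")

    @property
    def n_positive(self) -> int:
        """Number of diseased (MND+) subjects."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped_screen(self) -> "ConfusionTable":
        """The table with screen labels inverted (tp<->fn, fp<->tn)."""
        return ConfusionTable(tp=self.fn, fp=self.tn, fn=self.tp, tn=self.fp)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """The seven-metric accuracy panel of a binary screen, with 95% CIs.

    ``inv_lr_neg`` is specificity / (1 - sensitivity) — the reciprocal of
    the conventional negative likelihood ratio. Some reports print this
    reciprocal (values > 1) under the heading "likelihood ratio of negative
    test"; both conventions are carried so either can be quoted explicitly.

    Metrics whose defining denominator is zero are ``None`` and listed in
    ``undefined``.
    """

    sensitivity: Fraction | None
    specificity: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None
    lr_pos: Fraction | None
    lr_neg: Fraction | None
    inv_lr_neg: Fraction | None
    auroc: Fraction | None
    prevalence: Fraction
    ci: dict[str, tuple[float, float]]
    ci_method: str
    undefined: tuple[str, ...]
    table: ConfusionTable


def _er2_result(record):
    items: ER2Items = record.er2_items
    return score_er2(items)


#: Named binary predictors usable with :func:`build_confusion`.
PREDICTORS: dict[str, Callable] = {
    "er2_high_risk": lambda r: is_high_risk(_er2_result(r)),
    "temporal_disorientation": lambda r: bool(
        r.er2_items.temporal_disorientation
    ),
}


def build_confusion(
    cohort: Sequence,
    screen: str | Callable[[object], bool],
    *,
    score_threshold: int | None = None,
) -> ConfusionTable:
    """Cross-tabulate a binary screen against the MND diagnosis flag.

    ``screen`` is ``"er2_high_risk"``, ``"temporal_disorientation"``,
    ``"score_threshold"`` (with ``score_threshold=t``, screen+ iff
    score >= t), or any callable mapping a record to a bool.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if callable(screen):
        predictor = screen
    elif screen == "score_threshold":
        if score_threshold is None:
            raise ValueError("score_threshold predictor needs a threshold")
        t = score_threshold
        predictor = lambda r: _er2_result(r).score >= t  # noqa: E731
    else:
        try:
            predictor = PREDICTORS[screen]
        except KeyError:
            raise ValueError(
                f"unknown predictor {screen!r}; choose from "
                f"{sorted(PREDICTORS)} or 'score_threshold'"
            ) from None

    bad = [i for i, r in enumerate(cohort) if r.mnd_diagnosis is None]
    if bad:
        raise ValueError(f"missing MND diagnosis flag in record(s) {bad}")

    tp = fp = fn = tn = 0
    for r in cohort:
        pos = bool(predictor(r))
        if r.mnd_diagnosis:
            tp, fn = (tp + 1, fn) if pos else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pos else (fp, tn + 1)
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def diagnostic_performance(
    table: ConfusionTable, *, ci_method: str = "wilson"
) -> DiagnosticPerformance:
    """Compute the full performance panel from a 2x2 table.

    All metrics are exact fractions of the integer cell counts. Ratios with
    a zero denominator (e.g. LR+ of a perfectly specific screen) are
    reported as undefined rather than silently as infinities.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> Fraction | None:
        if den == 0:
            undefined.append(name)
            return None
        return Fraction(num, den)

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, fp + tn, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, fn + tn, "npv")

    def fratio(num: Fraction | None, den: Fraction | None, name: str):
        if num is None or den is None or den == 0:
            undefined.append(name)
            return None
        return num / den

    lr_pos = fratio(sens, 1 - spec if spec is not None else None, "lr_pos")
    lr_neg = fratio(1 - sens if sens is not None else None, spec, "lr_neg")
    inv_lr_neg = fratio(spec, 1 - sens if sens is not None else None, "inv_lr_neg")
    auroc = (
        (sens + spec) / 2 if sens is not None and spec is not None else None
    )
    if auroc is None:
        undefined.append("auroc")

    ci: dict[str, tuple[float, float]] = {}
    for name, successes, n in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, fp + tn),
        ("ppv", tp, tp + fp),
        ("npv", tn, fn + tn),
    ):
        if n > 0:
            ci[name] = proportion_ci(successes, n, method=ci_method)

    return DiagnosticPerformance(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        inv_lr_neg=inv_lr_neg,
        auroc=auroc,
        prevalence=Fraction(table.n_positive, table.total),
        ci=ci,
        ci_method=ci_method,
        undefined=tuple(undefined),
        table=table,
    )


def binary_auroc(table: ConfusionTable) -> Fraction:
    """AUROC of a single-threshold binary screen: (sens + spec) / 2."""
    if table.n_positive == 0 or table.n_negative == 0:
        raise ValueError("AUROC undefined: a diagnosis margin is empty")
    sens = Fraction(table.tp, table.n_positive)
    spec = Fraction(table.tn, table.n_negative)
    return (sens + spec) / 2


def roc_over_score(
    cohort: Sequence,
) -> tuple[list[tuple[int, Fraction, Fraction]], float]:
    """ROC over the full 0–14 score: screen+ iff score >= threshold.

    Returns one (threshold, sensitivity, specificity) operating point per
    threshold t in 0..15 and the trapezoidal AUROC over those points.
    Sensitivity is non-increasing in t; t=15 gives the (0, 1) corner.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    scores = np.array([_er2_result(r).score for r in cohort])
    disease = np.array([bool(r.mnd_diagnosis) for r in cohort])
    n_pos = int(disease.sum())
    n_neg = int((~disease).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: a diagnosis margin is empty")

    points = []
    for t in range(16):
        pos = scores >= t
        sens = Fraction(int((pos & disease).sum()), n_pos)
        spec = Fraction(int((~pos & ~disease).sum()), n_neg)
        points.append((t, sens, spec))

    # trapezoid in (FPR, TPR) space, points ordered by decreasing FPR
    fpr = [float(1 - p[2]) for p in points]
    tpr = [float(p[1]) for p in points]
    auc = 0.0
    for i in range(len(points) - 1):
        auc += (fpr[i] - fpr[i + 1]) * (tpr[i] + tpr[i + 1]) / 2
    return points, auc


def proportion_ci(
    successes: int, n: int, *, method: str = "wilson", alpha: float = 0.05
) -> tuple[float, float]:
    """95% (by default) CI for a binomial proportion, clipped to [0, 1].

    ``method`` is ``"wilson"`` (score interval) or ``"clopper-pearson"``
    (exact beta).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(successes, n, alpha=alpha, method=sm_method)
    return (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))
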