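"""Synthetic ED-visitor cohorts with the structure of the study population.

The reference cohort is 999 older adults (age >= 75, unplanned ED visit,
on a stretcher) of whom 356 carried a physician-documented diagnosis of
major neurocognitive disorder (MND). No patient-level data are deposited,
so this module generates cohorts from the published group-level margins:
MND prevalence, per-group prevalences of each ER² item, per-group age
moments, and per-group categorical distributions of visit reason and
triage level.

Given diagnosis status, items are drawn conditionally independently at the
group marginals by default; an optional Gaussian-copula correlation knob
couples the four directly drawn binary items for sensitivity analyses.
Age is truncated-normal with a floor at the inclusion age of 75, and the
"age 85 and over" item is recomputed from the drawn age so each record is
internally coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import ConfusionTable, proportion_ci
from .instrument import ER2Items, score_er2

__all__ = [
    "CohortModel",
    "PatientRecord",
    "CohortEstimate",
    "ParameterEstimate",
    "Table1Fixtures",
    "generate_cohort",
    "recover_parameters",
    "fixture_table1",
    "cohort_to_frame",
]

VISIT_REASONS = (
    "organ_failure",
    "mobility_disorders",
    "neuropsychiatric_disorders",
    "social_issue",
)
TRIAGE_LEVELS = (1, 2, 3, 4, 5)

#: Items drawn directly as Bernoulli variables (age_85_plus comes from age,
#: male from the sex draw).
DRAWN_ITEMS = ("polypharmacy", "home_support", "walking_aid", "temporal_disorientation")

INCLUSION_AGE = 75.0


def _normalised(p: Sequence[float]) -> tuple[float, ...]:
    arr = np.asarray(p, dtype=float)
    return tuple(arr / arr.sum())


@dataclass(frozen=True)
class CohortModel:
    """Generative parameters of a synthetic cohort.

    Probabilities are given per diagnosis group as (p | MND+, p | MND-).
    Defaults reproduce the published cohort margins: n=999, prevalence
    356/999, temporal disorientation 323/356 vs 174/643, ages
    86.6 ± 5.3 vs 83.9 ± 5.5 years (truncated at 75). The published
    walking-aid count for the MND+ group is internally impossible
    (572 of 356); the printed percentages 25.6/25.5 are used instead.
    """

    n_total: int = 999
    prevalence: float = 356 / 999
    item_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "male": (1 - 237 / 356, 1 - 414 / 643),
            "polypharmacy": (288 / 356, 475 / 643),
            "home_support": (314 / 356, 398 / 643),
            "walking_aid": (0.256, 0.255),
            "temporal_disorientation": (323 / 356, 174 / 643),
        }
    )
    lives_at_home: tuple[float, float] = (133 / 356, 432 / 643)
    age_mean: tuple[float, float] = (86.6, 83.9)
    age_sd: tuple[float, float] = (5.3, 5.5)
    visit_reason_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "present": _normalised((0.440, 0.174, 0.297, 0.090)),
            "absent": _normalised((0.698, 0.190, 0.067, 0.045)),
        }
    )
    triage_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "present": _normalised((0.042, 0.227, 0.527, 0.202, 0.007)),
            "absent": _normalised((0.009, 0.311, 0.526, 0.149, 0.005)),
        }
    )
    admitted: tuple[float, float] = (0.482, 0.463)
    item_correlation: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        probs = [self.prevalence, *self.lives_at_home, *self.admitted]
        for name, pair in self.item_probs.items():
            if name not in ("male", *DRAWN_ITEMS):
                raise ValueError(f"unknown item {name!r}")
            probs.extend(pair)
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for dist, n in ((self.visit_reason_probs, 4), (self.triage_probs, 5)):
            for group in ("present", "absent"):
                vec = np.asarray(dist[group], dtype=float)
                if len(vec) != n or (vec < 0).any() or abs(vec.sum() - 1) > 1e-9:
                    raise ValueError(f"invalid categorical distribution for {group}")
        if not -0.99 <= self.item_correlation <= 0.99:
            raise ValueError("item_correlation outside (-0.99, 0.99)")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")


@dataclass(frozen=True)
class PatientRecord:
    """One ED visitor: demographics, visit metadata, ER² items, diagnosis."""

    id: int
    age: float
    sex: str  # "male" | "female"
    lives_at_home: bool
    visit_reason: str
    triage_level: int
    er2_items: ER2Items
    mnd_diagnosis: bool
    admitted: bool

    def __post_init__(self) -> None:
        if self.age < INCLUSION_AGE:
            raise ValueError(f"age {self.age} below inclusion criterion of 75")
        if self.er2_items.age_85_plus is not None and self.er2_items.age_85_plus != (
            self.age >= 85
        ):
            raise ValueError("age_85_plus item inconsistent with age")


def _draw_items(
    rng: np.random.Generator, n: int, probs: Sequence[float], rho: float
) -> np.ndarray:
    """n x k binary draws, independent (rho=0) or Gaussian-copula coupled."""
    k = len(probs)
    if rho == 0.0:
        return rng.random((n, k)) < np.asarray(probs)
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    latent = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    thresholds = stats.norm.ppf(probs)
    return latent < thresholds


def generate_cohort(
    model: CohortModel, seed: int | None = None
) -> list[PatientRecord]:
    """Draw a synthetic cohort from the model; deterministic given the seed.

    MND status is Bernoulli(prevalence); conditional on status, items come
    from the per-group probabilities, age from a truncated normal at the
    group moments (floor 75), and visit reason / triage level from the
    group categoricals. ``seed`` overrides ``model.seed``; one must be set.
    """
    model.validate()
    if seed is None:
        seed = model.seed
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    rng = np.random.default_rng(seed)
    n = model.n_total

    mnd = rng.random(n) < model.prevalence

    age = np.empty(n)
    male = np.empty(n, dtype=bool)
    items = np.empty((n, len(DRAWN_ITEMS)), dtype=bool)
    home = np.empty(n, dtype=bool)
    reason = np.empty(n, dtype=object)
    triage = np.empty(n, dtype=int)
    admitted = np.empty(n, dtype=bool)

    for gi, (group, mask) in enumerate((("present", mnd), ("absent", ~mnd))):
        m = int(mask.sum())
        if m == 0:
            continue
        mu, sd = model.age_mean[gi], model.age_sd[gi]
        a = (INCLUSION_AGE - mu) / sd
        age[mask] = stats.truncnorm.rvs(
            a, np.inf, loc=mu, scale=sd, size=m, random_state=rng
        )
        male[mask] = rng.random(m) < model.item_probs["male"][gi]
        items[mask] = _draw_items(
            rng,
            m,
            [model.item_probs[it][gi] for it in DRAWN_ITEMS],
            model.item_correlation,
        )
        home[mask] = rng.random(m) < model.lives_at_home[gi]
        reason[mask] = rng.choice(
            VISIT_REASONS, size=m, p=model.visit_reason_probs[group]
        )
        triage[mask] = rng.choice(
            TRIAGE_LEVELS, size=m, p=model.triage_probs[group]
        )
        admitted[mask] = rng.random(m) < model.admitted[gi]

    records = []
    by_item = dict(zip(DRAWN_ITEMS, items.T))
    for i in range(n):
        age_i = round(float(age[i]), 1)
        er2 = ER2Items(
            age_85_plus=age_i >= 85,
            male=bool(male[i]),
            polypharmacy=bool(by_item["polypharmacy"][i]),
            home_support=bool(by_item["home_support"][i]),
            walking_aid=bool(by_item["walking_aid"][i]),
            temporal_disorientation=bool(by_item["temporal_disorientation"][i]),
        )
        records.append(
            PatientRecord(
                id=i + 1,
                age=age_i,
                sex="male" if male[i] else "female",
                lives_at_home=bool(home[i]),
                visit_reason=str(reason[i]),
                triage_level=int(triage[i]),
                er2_items=er2,
                mnd_diagnosis=bool(mnd[i]),
                admitted=bool(admitted[i]),
            )
        )
    return records


@dataclass(frozen=True)
class ParameterEstimate:
    """Point estimate with a 95% CI; ``value`` is None when undefined."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    n: int = 0


@dataclass(frozen=True)
class CohortEstimate:
    """Empirical counterpart of :class:`CohortModel` with 95% CIs."""

    prevalence: ParameterEstimate
    item_probs: dict[str, tuple[ParameterEstimate, ParameterEstimate]]
    age_mean: tuple[ParameterEstimate, ParameterEstimate]
    age_sd: tuple[float | None, float | None]
    n_total: int


def _prop_estimate(successes: int, n: int) -> ParameterEstimate:
    if n == 0:
        return ParameterEstimate(None)
    lo, hi = proportion_ci(successes, n, method="wilson")
    return ParameterEstimate(successes / n, lo, hi, n)


def recover_parameters(cohort: Sequence[PatientRecord]) -> CohortEstimate:
    """Estimate generator parameters from a cohort.

    Proportions get Wilson 95% CIs; age means get normal-theory CIs. An
    empty diagnosis group yields undefined (None) per-group estimates.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    mnd = np.array([r.mnd_diagnosis for r in cohort], dtype=bool)
    prevalence = _prop_estimate(int(mnd.sum()), n)

    item_probs: dict[str, tuple[ParameterEstimate, ParameterEstimate]] = {}
    for name in ("male", *DRAWN_ITEMS):
        per_group = []
        for mask in (mnd, ~mnd):
            m = int(mask.sum())
            hits = sum(
                1
                for r, keep in zip(cohort, mask)
                if keep and getattr(r.er2_items, name)
            )
            per_group.append(_prop_estimate(hits, m))
        item_probs[name] = tuple(per_group)

    age = np.array([r.age for r in cohort])
    means, sds = [], []
    for mask in (mnd, ~mnd):
        m = int(mask.sum())
        if m < 2:
            means.append(ParameterEstimate(None, n=m))
            sds.append(None)
            continue
        mu = float(age[mask].mean())
        sd = float(age[mask].std(ddof=1))
        half = 1.959963984540054 * sd / np.sqrt(m)
        means.append(ParameterEstimate(mu, mu - half, mu + half, m))
        sds.append(sd)

    return CohortEstimate(
        prevalence=prevalence,
        item_probs=item_probs,
        age_mean=tuple(means),
        age_sd=tuple(sds),
        n_total=n,
    )


@dataclass(frozen=True)
class Table1Fixtures:
    """The published cross-tabulations, frozen.

    ``high_risk``: ER² high-risk level vs MND — 340 of 356 MND+ and 344 of
    643 MND- screened high. ``temporal``: the temporal-disorientation item
    vs MND — 323 of 356 and 174 of 643 positive.
    """

    high_risk: ConfusionTable = ConfusionTable(tp=340, fp=344, fn=16, tn=299)
    temporal: ConfusionTable = ConfusionTable(tp=323, fp=174, fn=33, tn=469)
    n_mnd: int = 356
    n_no_mnd: int = 643


def fixture_table1() -> Table1Fixtures:
    """Return the frozen published counts behind the accuracy tables."""
    return Table1Fixtures()


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Patient-level DataFrame with scored ER² columns for group analyses."""
    rows = []
    for r in cohort:
        res = score_er2(r.er2_items)
        rows.append(
            {
                "id": r.id,
                "age": r.age,
                "female": r.sex == "female",
                "lives_at_home": r.lives_at_home,
                "home_support": r.er2_items.home_support,
                "polypharmacy": r.er2_items.polypharmacy,
                "walking_aid": r.er2_items.walking_aid,
                "temporal_disorientation": r.er2_items.temporal_disorientation,
                "visit_reason": r.visit_reason,
                "triage_level": r.triage_level,
                "er2_score": res.score,
                "er2_risk_level": res.risk_level.value,
                "admitted": r.admitted,
                "mnd_diagnosis": r.mnd_diagnosis,
            }
        )
    return pd.DataFrame(rows)
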