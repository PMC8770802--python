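"""The ER² screening instrument: items, weights, score, and risk strata.

ER² (Emergency Room Evaluation and Recommendations) is a six-item bedside
screen for older emergency-department visitors. Each item is a closed
yes/no question:

====================  ======  =========================================
item                  points  definition
====================  ======  =========================================
age 85 and over          1    chronological age >= 85 years
male                     1    male sex
polypharmacy             1    >= 5 medications taken daily
home support             1    formal (health/social services) and/or
                               informal (family/friend) home support
use of a walking aid     5    any type of walking aid
temporal                 5    unable to name the current month and/or
disorientation                 year
====================  ======  =========================================

The total score ranges from 0 (lowest risk) to 14 (highest risk) and is
stratified into three risk levels: low (0–3), moderate (4–5) and
high (>= 6).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, fields

__all__ = [
    "ITEM_NAMES",
    "ITEM_WEIGHTS",
    "MAX_SCORE",
    "RiskLevel",
    "ER2Items",
    "ER2Result",
    "IncompleteAssessmentError",
    "score_er2",
    "classify_risk",
    "is_high_risk",
]

logger = logging.getLogger(__name__)

#: Item point weights; walking aid and temporal disorientation carry 5
#: points each, the remaining four items 1 point each.
ITEM_WEIGHTS: dict[str, int] = {
    "age_85_plus": 1,
    "male": 1,
    "polypharmacy": 1,
    "home_support": 1,
    "walking_aid": 5,
    "temporal_disorientation": 5,
}

ITEM_NAMES: tuple[str, ...] = tuple(ITEM_WEIGHTS)

MAX_SCORE: int = sum(ITEM_WEIGHTS.values())  # 14

POLYPHARMACY_THRESHOLD: int = 5
AGE_ITEM_THRESHOLD: int = 85


class RiskLevel(str, enum.Enum):
    """Risk stratum for undesirable hospital-related events."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class IncompleteAssessmentError(ValueError):
    """Raised when items are missing and no missing-item policy was given."""

    def __init__(self, missing: tuple[str, ...]):
        self.missing = missing
        super().__init__(
            "incomplete assessment: missing item(s) " + ", ".join(missing)
        )


@dataclass(frozen=True)
class ER2Items:
    """Answers to the six ER² questions; ``None`` marks a missing answer."""

    age_85_plus: bool | None
    male: bool | None
    polypharmacy: bool | None
    home_support: bool | None
    walking_aid: bool | None
    temporal_disorientation: bool | None

    @classmethod
    def from_raw(
        cls,
        *,
        age: float,
        male: bool,
        home_support: bool,
        walking_aid: bool,
        temporal_disorientation: bool,
        daily_medications: int | None = None,
        polypharmacy: bool | None = None,
    ) -> "ER2Items":
        """Build items from raw measurements.

        ``age`` (years) is dichotomised at 85; ``daily_medications`` at the
        polypharmacy threshold of 5, unless a ``polypharmacy`` flag is given
        directly.
        """
        if polypharmacy is None and daily_medications is not None:
            polypharmacy = daily_medications >= POLYPHARMACY_THRESHOLD
        return cls(
            age_85_plus=age >= AGE_ITEM_THRESHOLD,
            male=male,
            polypharmacy=polypharmacy,
            home_support=home_support,
            walking_aid=walking_aid,
            temporal_disorientation=temporal_disorientation,
        )

    def missing_items(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self) if getattr(self, f.name) is None)

    def as_dict(self) -> dict[str, bool | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ER2Result:
    """Computed ER² score with its risk stratum and the items it used."""

    score: int
    risk_level: RiskLevel
    items_used: ER2Items = field(repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.score <= MAX_SCORE:
            raise ValueError(f"score {self.score} outside [0, {MAX_SCORE}]")


def classify_risk(score: int) -> RiskLevel:
    """Map a total score to its risk stratum.

    Low for scores 0–3, moderate for 4–5, high for >= 6.
    """
    if not 0 <= score <= MAX_SCORE:
        raise ValueError(f"score {score} outside [0, {MAX_SCORE}]")
    if score <= 3:
        return RiskLevel.LOW
    if score <= 5:
        return RiskLevel.MODERATE
    return RiskLevel.HIGH


def score_er2(items: ER2Items, *, missing_as_no: bool = False) -> ER2Result:
    """Score the six items and stratify the result.

    By default every item must be answered; an unanswered item raises
    :class:`IncompleteAssessmentError` naming it. With ``missing_as_no=True``
    missing answers count as "no" — every such use is logged, because it
    biases the score downward and should be a conscious decision.
    """
    missing = items.missing_items()
    if missing:
        if not missing_as_no:
            raise IncompleteAssessmentError(missing)
        logger.warning(
            "missing-as-no policy applied to item(s): %s", ", ".join(missing)
        )
    score = sum(
        w for name, w in ITEM_WEIGHTS.items() if getattr(items, name) is True
    )
    return ER2Result(score=score, risk_level=classify_risk(score), items_used=items)


def is_high_risk(result: ER2Result) -> bool:
    """True iff the result falls in the high stratum (score >= 6)."""
    return result.risk_level is RiskLevel.HIGH
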