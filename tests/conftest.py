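"""Shared fixtures: item vectors and cohorts realizing given 2x2 counts."""

from __future__ import annotations

import pytest
from hypothesis import settings

from er2screen import ConfusionTable, ER2Items, PatientRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

ITEM_DEFAULTS = dict(
    age_85_plus=False,
    male=False,
    polypharmacy=False,
    home_support=False,
    walking_aid=False,
    temporal_disorientation=False,
)


def make_items(**overrides) -> ER2Items:
    """Six-item vector, defaulting every answer to 'no'."""
    return ER2Items(**{**ITEM_DEFAULTS, **overrides})


def make_record(
    id: int, items: ER2Items, mnd: bool | None, *, age: float = 80.0
) -> PatientRecord:
    return PatientRecord(
        id=id,
        age=age,
        sex="male" if items.male else "female",
        lives_at_home=True,
        visit_reason="organ_failure",
        triage_level=3,
        er2_items=items,
        mnd_diagnosis=mnd,
        admitted=False,
    )


def cohort_from_table(
    table: ConfusionTable, positive_items: ER2Items, negative_items: ER2Items
) -> list[PatientRecord]:
    """Patient-level cohort whose screen/diagnosis cross-tab equals ``table``.

    ``positive_items`` must make the screen under test positive,
    ``negative_items`` negative.
    """
    cohort = []
    i = 0
    for count, items, mnd in (
        (table.tp, positive_items, True),
        (table.fp, positive_items, False),
        (table.fn, negative_items, True),
        (table.tn, negative_items, False),
    ):
        for _ in range(count):
            i += 1
            cohort.append(make_record(i, items, mnd))
    return cohort


@pytest.fixture
def high_risk_counts() -> ConfusionTable:
    """Published high-risk-level cross-tab: 340/344/16/299."""
    return ConfusionTable(tp=340, fp=344, fn=16, tn=299)


@pytest.fixture
def temporal_counts() -> ConfusionTable:
    """Published temporal-disorientation cross-tab: 323/174/33/469."""
    return ConfusionTable(tp=323, fp=174, fn=33, tn=469)
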