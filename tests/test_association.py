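"""Odds ratios (closed form and logistic MLE) and group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from er2screen import (
    ConfusionTable,
    SeparationError,
    compare_groups,
    cohort_to_frame,
    logistic_fit,
    logistic_fit_binary,
    odds_ratio_2x2,
    table1_summary,
)
from er2screen import CohortModel, generate_cohort
from er2screen._format import round_half_up

from conftest import cohort_from_table, make_items

TEMP_POS = make_items(temporal_disorientation=True)
TEMP_NEG = make_items()
HIGH_POS = make_items(walking_aid=True, male=True)

tables = st.builds(
    ConfusionTable,
    tp=st.integers(1, 400),
    fp=st.integers(1, 400),
    fn=st.integers(1, 400),
    tn=st.integers(1, 400),
)


class TestWoolfOddsRatio:
    def test_high_risk_level_published_interval(self, high_risk_counts):
        est = odds_ratio_2x2(high_risk_counts)
        assert round_half_up(est.odds_ratio, 1) == 18.5
        assert round_half_up(est.ci_low, 1) == 10.9
        assert round_half_up(est.ci_high, 1) == 31.2
        assert est.p_value < 0.001
        assert est.odds_ratio == pytest.approx((340 * 299) / (344 * 16))

    def test_temporal_item_published_interval(self, temporal_counts):
        est = odds_ratio_2x2(temporal_counts)
        assert round_half_up(est.odds_ratio, 1) == 26.4
        assert round_half_up(est.ci_low, 1) == 17.7
        assert round_half_up(est.ci_high, 1) == 39.3
        assert est.p_value < 0.001

    def test_null_association_gives_unit_or(self):
        est = odds_ratio_2x2(ConfusionTable(tp=6, fp=3, fn=4, tn=2))
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_zero_cell_raises_unless_haldane(self):
        table = ConfusionTable(tp=5, fp=0, fn=3, tn=7)
        with pytest.raises(SeparationError):
            odds_ratio_2x2(table)
        est = odds_ratio_2x2(table, haldane=True)
        assert est.corrected
        assert est.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    @given(tables, st.integers(2, 5))
    def test_or_invariant_under_row_and_column_scaling(self, table, k):
        base = odds_ratio_2x2(table).odds_ratio
        row = ConfusionTable(table.tp * k, table.fp * k, table.fn, table.tn)
        col = ConfusionTable(table.tp * k, table.fp, table.fn * k, table.tn)
        assert odds_ratio_2x2(row).odds_ratio == pytest.approx(base, rel=1e-12)
        assert odds_ratio_2x2(col).odds_ratio == pytest.approx(base, rel=1e-12)

    def test_exp_log_or_consistency(self, temporal_counts):
        est = odds_ratio_2x2(temporal_counts)
        assert math.exp(est.log_or) == pytest.approx(est.odds_ratio, rel=1e-12)
        assert est.ci_low <= est.odds_ratio <= est.ci_high


class TestLogisticRoute:
    def test_matches_cross_product_on_published_tables(
        self, high_risk_counts, temporal_counts
    ):
        for table in (high_risk_counts, temporal_counts):
            closed = odds_ratio_2x2(table)
            mle = logistic_fit_binary(table)
            assert mle.odds_ratio == pytest.approx(closed.odds_ratio, rel=1e-4)
            assert mle.ci_low == pytest.approx(closed.ci_low, rel=1e-3)
            assert mle.ci_high == pytest.approx(closed.ci_high, rel=1e-3)
        assert round_half_up(logistic_fit_binary(temporal_counts).odds_ratio, 1) == 26.4

    def test_accepts_cohort_and_predictor_name(self, temporal_counts):
        cohort = cohort_from_table(temporal_counts, TEMP_POS, TEMP_NEG)
        est = logistic_fit_binary(cohort, "temporal_disorientation")
        assert est.odds_ratio == pytest.approx(
            odds_ratio_2x2(temporal_counts).odds_ratio, rel=1e-4
        )

    def test_separation_is_diagnosed(self):
        with pytest.raises(SeparationError, match="separation"):
            logistic_fit_binary(ConfusionTable(tp=10, fp=0, fn=2, tn=8))

    @given(tables)
    @settings(max_examples=40)
    def test_saturated_model_identity(self, table):
        """Single-binary-covariate MLE equals the cross-product ratio."""
        closed = odds_ratio_2x2(table)
        mle = logistic_fit_binary(table)
        assert mle.log_or == pytest.approx(closed.log_or, abs=1e-6)
        assert mle.se_log_or == pytest.approx(closed.se_log_or, rel=1e-6)

    def test_independent_predictor_gives_or_near_one(self):
        model = CohortModel(
            n_total=20_000,
            item_probs={
                "male": (0.35, 0.35),
                "polypharmacy": (0.75, 0.75),
                "home_support": (0.70, 0.70),
                "walking_aid": (0.25, 0.25),
                "temporal_disorientation": (0.40, 0.40),
            },
            age_mean=(84.0, 84.0),
            age_sd=(5.5, 5.5),
        )
        cohort = generate_cohort(model, seed=5)
        est = logistic_fit_binary(cohort, "temporal_disorientation")
        assert est.ci_low < 1.0 < est.ci_high

    def test_multi_covariate_plumbing_reduces_to_single_predictor(
        self, temporal_counts
    ):
        cohort = cohort_from_table(temporal_counts, TEMP_POS, TEMP_NEG)
        frame = cohort_to_frame(cohort)
        fit = logistic_fit(frame, "mnd_diagnosis", ["temporal_disorientation"])
        assert fit.loc["temporal_disorientation", "odds_ratio"] == pytest.approx(
            odds_ratio_2x2(temporal_counts).odds_ratio, rel=1e-4
        )


def _two_group_frame(counts: ConfusionTable) -> pd.DataFrame:
    rows = []
    for n, flag, mnd in (
        (counts.tp, True, True),
        (counts.fp, True, False),
        (counts.fn, False, True),
        (counts.tn, False, False),
    ):
        rows += [{"x": flag, "mnd_diagnosis": mnd}] * n
    return pd.DataFrame(rows)


class TestGroupComparisons:
    def test_temporal_two_by_two_is_highly_significant(self, temporal_counts):
        frame = _two_group_frame(temporal_counts)
        (comp,) = compare_groups(frame, [("x", "binary")])
        assert comp.test == "chi-square"
        assert comp.p_value < 0.001

    def test_identical_proportions_give_zero_statistic(self):
        frame = pd.DataFrame(
            {"x": [True, False] * 20, "mnd_diagnosis": [True] * 20 + [False] * 20}
        )
        (comp,) = compare_groups(frame, [("x", "binary")])
        assert comp.statistic == pytest.approx(0.0)
        assert comp.p_value == pytest.approx(1.0)

    @given(tables)
    @settings(max_examples=40)
    def test_chi_square_equals_squared_two_proportion_z(self, table):
        """Uncorrected Pearson chi-square on 2x2 == squared pooled z."""
        frame = _two_group_frame(table)
        (comp,) = compare_groups(frame, [("x", "binary")])
        n1, n2 = table.n_positive, table.n_negative
        p1, p2 = table.tp / n1, table.fp / n2
        p = (table.tp + table.fp) / (n1 + n2)
        if p in (0.0, 1.0):
            return
        z = (p1 - p2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert comp.statistic == pytest.approx(z**2, rel=1e-10)

    def test_age_difference_detected_in_nearly_all_replicates(self):
        """Monte-Carlo power check at the two groups' age moments."""
        rng = np.random.default_rng(20)
        hits = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(86.6, 5.3, 356)
            b = rng.normal(83.9, 5.5, 643)
            frame = pd.DataFrame(
                {
                    "age": np.concatenate([a, b]),
                    "mnd_diagnosis": [True] * 356 + [False] * 643,
                }
            )
            (comp,) = compare_groups(frame, [("age", "continuous")])
            hits += comp.p_value < 0.001
        assert hits >= 99

    def test_empty_group_rejected(self):
        frame = pd.DataFrame({"x": [True, False], "mnd_diagnosis": [True, True]})
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups(frame, [("x", "binary")])

    def test_unknown_variable_rejected(self):
        frame = _two_group_frame(ConfusionTable(2, 2, 2, 2))
        with pytest.raises(KeyError, match="nope"):
            compare_groups(frame, [("nope", "binary")])


class TestTable1Summary:
    def test_synthetic_cohort_summary_matches_generating_margins(self):
        cohort = generate_cohort(CohortModel(), seed=3)
        frame = cohort_to_frame(cohort)
        comparisons, markdown = table1_summary(frame)
        by_name = {c.variable: c for c in comparisons}
        # items drawn at the published per-group rates are recovered closely
        temp = by_name["temporal_disorientation"].summaries
        assert temp["present"]["True"]["percent"] == pytest.approx(90.5, abs=5)
        assert temp["absent"]["True"]["percent"] == pytest.approx(27.1, abs=5)
        # the high-risk stratum emerges from the item draws; conditional
        # independence makes it approximate the published 95.2/53.5 only
        risk = by_name["er2_risk_level"].summaries
        assert 85 <= risk["present"]["high"]["percent"] <= 99
        assert 35 <= risk["absent"]["high"]["percent"] <= 60
        assert by_name["age"].p_value < 0.001
        assert "| Variable | MND present | MND absent |" in markdown

    def test_single_patient_per_group_flags_t_test_undefined(self):
        frame = pd.DataFrame(
            {
                "age": [80.0, 90.0],
                "x": [True, False],
                "mnd_diagnosis": [True, False],
            }
        )
        comparisons = compare_groups(
            frame, [("age", "continuous"), ("x", "binary")]
        )
        age = comparisons[0]
        assert math.isnan(age.p_value)
        assert any("undefined" in w for w in age.warnings)
        x = comparisons[1]
        assert all(
            entry["percent"] in (0.0, 100.0)
            for group in x.summaries.values()
            for entry in group.values()
        )

    def test_empty_variable_list_gives_empty_table(self, temporal_counts):
        frame = _two_group_frame(temporal_counts)
        comparisons, markdown = table1_summary(frame, variables=())
        assert comparisons == []
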