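"""The 3-group allocation rule, scenario evaluation and group summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

import sciatica_triage as st
from sciatica_triage.allocation import (
    SCENARIOS,
    AllocationError,
    ScenarioRule,
    allocate,
    allocate_cohort,
    evaluate_rule,
    group_summary,
    metrics_from_confusion,
)
from sciatica_triage.association import TwoByTwoTable
from sciatica_triage.predictors import ClinicalCharacteristics

RISK_ORDER = {"low": 0, "medium": 1, "high": 2}


def _chars(count: int) -> ClinicalCharacteristics:
    flags = [i < count for i in range(4)]
    return ClinicalCharacteristics(*flags)


class TestAllocate:
    @pytest.mark.parametrize(
        "risk, count, group",
        [
            ("low", 0, 1), ("low", 4, 1),           # low risk always group 1
            ("medium", 4, 3), ("high", 3, 3), ("high", 4, 3),
            ("high", 2, 2), ("medium", 3, 2), ("medium", 0, 2),
        ],
    )
    def test_published_rule_examples(self, risk, count, group):
        assert allocate(risk, count) == group
        assert allocate(risk, _chars(count)) == group

    def test_rule_is_total_over_all_fifteen_cells(self):
        for risk in ("low", "medium", "high"):
            for count in range(5):
                g = allocate(risk, count)
                assert g in (1, 2, 3)
                # partition: exactly the published cells map to each group
                if risk == "low":
                    assert g == 1
                elif (risk == "high" and count >= 3) or (risk == "medium" and count == 4):
                    assert g == 3
                else:
                    assert g == 2

    def test_monotone_in_count_and_risk(self):
        for risk in ("low", "medium", "high"):
            groups = [allocate(risk, c) for c in range(5)]
            # adding a characteristic never lowers the group
            assert all(b >= a for a, b in zip(groups, groups[1:]))
        for count in range(5):
            by_risk = [allocate(r, count) for r in ("low", "medium", "high")]
            assert all(b >= a for a, b in zip(by_risk, by_risk[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="risk"):
            allocate("severe", 2)
        with pytest.raises(ValueError, match="count"):
            allocate("high", 5)

    def test_indeterminate_flags_allowed_when_group_forced(self):
        # low risk: characteristics irrelevant
        assert allocate("low", ClinicalCharacteristics(None, None, None, None)) == 1
        # high risk with three definite positives: group 3 whatever the fourth
        assert allocate("high", ClinicalCharacteristics(True, True, True, None)) == 3
        # medium risk with any definite negative can never reach count 4
        assert allocate("medium", ClinicalCharacteristics(False, None, None, None)) == 2

    def test_indeterminate_flags_refused_when_group_ambiguous(self):
        with pytest.raises(AllocationError, match="indeterminate"):
            allocate("high", ClinicalCharacteristics(True, True, None, None))
        with pytest.raises(AllocationError, match="indeterminate"):
            allocate("medium", ClinicalCharacteristics(True, True, True, None))


class TestAllocateCohort:
    def test_matches_scalar_rule(self, eligible_cohort):
        out = allocate_cohort(eligible_cohort)
        ok = out.dropna(subset=["startback_risk", "char_count"])
        for _, row in ok.sample(80, random_state=0).iterrows():
            assert row["group"] == allocate(str(row["startback_risk"]), int(row["char_count"]))

    def test_group_sizes_partition_allocated_sample(self, eligible_cohort):
        out = allocate_cohort(eligible_cohort)
        sizes = out["group"].value_counts()
        assert sizes.sum() + out["group"].isna().sum() == len(out)

    def test_all_low_risk_cohort_lands_in_group_one(self, eligible_cohort):
        df = eligible_cohort.copy()
        df["startback_risk"] = "low"
        out = allocate_cohort(df)
        assert (out["group"] == 1).all()


class TestScenarioRules:
    def test_rule_requires_exactly_one_predicate_form(self):
        with pytest.raises(ValueError):
            ScenarioRule("bad")
        with pytest.raises(ValueError):
            ScenarioRule("bad", min_count=3, per_class_min={"high": 3})

    def test_predicate_total_over_all_cells(self):
        for rule in SCENARIOS:
            for risk, count in itertools.product(("low", "medium", "high"), range(5)):
                assert rule.fast_track(risk, count) in (True, False)

    def test_scenario3_predicate_matches_published_wording(self):
        s3 = SCENARIOS[2]
        assert s3.fast_track("high", 3) and s3.fast_track("high", 4)
        assert not s3.fast_track("high", 2)
        assert s3.fast_track("medium", 4) and not s3.fast_track("medium", 3)
        assert not s3.fast_track("low", 4)  # excluded, stays in denominators

    def test_fast_track_everyone_rule(self, eligible_cohort):
        everyone = ScenarioRule("all", min_count=0)
        m = evaluate_rule(everyone, allocate_cohort(eligible_cohort))
        assert m.sensitivity == pytest.approx(100.0)
        assert m.specificity == pytest.approx(0.0)
        assert m.fraction_fast_tracked == pytest.approx(100.0)

    def test_scenario3_fast_track_equals_group3(self, eligible_cohort):
        """The adopted fast-track rule and the allocation algorithm agree:
        fast-tracked if and only if allocated to group 3."""
        out = allocate_cohort(eligible_cohort).dropna(
            subset=["startback_risk", "char_count", "referred"]
        )
        fast = np.array(
            [SCENARIOS[2].fast_track(str(r), int(c))
             for r, c in zip(out["startback_risk"], out["char_count"])]
        )
        assert (fast == (out["group"] == 3).to_numpy()).all()


class TestClassificationMetrics:
    def test_reconstructed_scenario1_table(self):
        """Confusion table reconstructed from the published scenario-1
        marginals (186/429 fast-tracked, 57 referred, sensitivity 68%)."""
        m = metrics_from_confusion(TwoByTwoTable(39, 147, 18, 225))
        assert round(m.sensitivity) == 68
        assert round(m.specificity) == 60
        assert round(m.ppv) == 21
        assert round(m.npv) == 93
        assert round(m.fraction_fast_tracked) == 43

    def test_reconstructed_scenario3_table(self):
        m = metrics_from_confusion(TwoByTwoTable(29, 100, 28, 272))
        assert round(m.sensitivity) == 51
        assert round(m.specificity) == 73
        assert round(m.ppv) == 22
        assert round(m.npv) == 91
        assert round(m.fraction_fast_tracked) == 30

    def test_exact_intervals_match_published_scenario3_row(self):
        m = metrics_from_confusion(TwoByTwoTable(29, 100, 28, 272))
        assert tuple(round(v) for v in m.sensitivity_ci) == (37, 64)
        assert tuple(round(v) for v in m.specificity_ci) == (68, 78)
        assert tuple(round(v) for v in m.ppv_ci) == (16, 31)
        assert tuple(round(v) for v in m.npv_ci) == (87, 94)

    @given(
        tp=hst.integers(0, 80), fp=hst.integers(0, 300),
        fn=hst.integers(0, 80), tn=hst.integers(0, 300),
    )
    def test_metric_identities(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = metrics_from_confusion(TwoByTwoTable(tp, fp, fn, tn))
        if tp + fn > 0:
            assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
        else:
            assert m.sensitivity is None
        if tp + fp > 0:
            assert m.ppv == pytest.approx(100 * tp / (tp + fp))
        else:
            assert m.ppv is None  # undefined on a zero predicted-positive margin
        if fn + tn > 0:
            assert m.npv * (fn + tn) / 100 == pytest.approx(tn)
        assert m.fraction_fast_tracked == pytest.approx(100 * (tp + fp) / m.n)

    def test_zero_observed_referrals_flagged(self, eligible_cohort):
        df = allocate_cohort(eligible_cohort).copy()
        df["referred"] = False
        m = evaluate_rule(SCENARIOS[2], df)
        assert m.sensitivity is None and m.sensitivity_ci is None


class TestGroupSummary:
    def test_partition_and_ordering(self, eligible_cohort):
        out = allocate_cohort(eligible_cohort)
        summary = group_summary(out)
        ns = summary[(summary["variable"] == "n")].set_index("group")["value"]
        assert ns.sum() == out["group"].notna().sum()
        leg = summary[
            (summary["variable"] == "leg_pain_current") & (summary["statistic"] == "mean")
        ].set_index("group")["value"]
        # severity gradient: fast-track group reports worse leg pain
        assert leg[3] > leg[1]

    def test_empty_groups_emitted_with_zero_n(self, eligible_cohort):
        df = eligible_cohort.copy()
        df["startback_risk"] = "low"
        summary = group_summary(allocate_cohort(df))
        ns = summary[summary["variable"] == "n"].set_index("group")["value"]
        assert ns[2] == 0 and ns[3] == 0 and ns[1] > 0
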