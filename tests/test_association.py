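"""Odds ratios, collinearity screening and block-wise model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

import sciatica_triage as st
from sciatica_triage.association import (
    SeparationError,
    TwoByTwoTable,
    blockwise_selection,
    collinearity_screen,
    encode_terms,
    fit_logistic,
    odds_ratio_2x2,
)
from sciatica_triage.predictors import DEFAULT_BLOCKS


class TestOddsRatio2x2:
    @pytest.mark.parametrize(
        "cells, expected_or",
        [
            # published contingency rows: impact, myotomal weakness,
            # loss of sensation, tingling/numbness, cough/sneeze
            ((43, 14, 200, 172), 2.64),
            ((20, 37, 82, 290), 1.91),
            ((11, 40, 20, 190), 2.61),
            ((40, 17, 241, 131), 1.28),
            ((20, 37, 97, 275), 1.53),
        ],
    )
    def test_published_table_rows(self, cells, expected_or):
        res = odds_ratio_2x2(TwoByTwoTable(*cells))
        assert round(res.odds_ratio, 2) == expected_or

    def test_impact_confidence_interval(self):
        res = odds_ratio_2x2(TwoByTwoTable(43, 14, 200, 172))
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.40, 4.99)

    @pytest.mark.parametrize("k", [1, 7, 100])
    def test_symmetric_table_gives_unity(self, k):
        res = odds_ratio_2x2(TwoByTwoTable(k, k, k, k))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            odds_ratio_2x2(TwoByTwoTable(0, 0, 5, 7))
        with pytest.raises(ValueError, match="margin"):
            odds_ratio_2x2(TwoByTwoTable(0, 5, 0, 7))

    def test_zero_cell_continuity_correction_flagged(self):
        res = odds_ratio_2x2(TwoByTwoTable(0, 10, 5, 7))
        assert res.continuity_corrected
        assert res.odds_ratio == pytest.approx((0.5 * 7.5) / (10.5 * 5.5))

    def test_negative_or_fractional_cells_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            TwoByTwoTable(1.5, 2, 3, 4)

    @given(
        a=hst.integers(1, 200), b=hst.integers(1, 200),
        c=hst.integers(1, 200), d=hst.integers(1, 200),
    )
    def test_transposing_exposure_inverts_or(self, a, b, c, d):
        direct = odds_ratio_2x2(TwoByTwoTable(a, b, c, d)).odds_ratio
        flipped = odds_ratio_2x2(TwoByTwoTable(b, a, d, c)).odds_ratio
        assert direct == pytest.approx(1 / flipped, rel=1e-12)

    @pytest.mark.parametrize("cells", [(43, 14, 200, 172), (11, 40, 20, 190), (9, 3, 4, 8)])
    def test_matches_univariable_logistic_oracle(self, cells):
        """exp(logistic coefficient) on the expanded 0/1 data equals the
        closed-form OR to 1e-6 relative error."""
        a, b, c, d = cells
        x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        fit = fit_logistic(y, x[:, None], ["exposed"])
        res = odds_ratio_2x2(TwoByTwoTable(a, b, c, d))
        assert np.exp(fit.params[1]) == pytest.approx(res.odds_ratio, rel=1e-6)


class TestCollinearityScreen:
    def test_duplicate_variable_dropped(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=200)})
        df["x_copy"] = df["x"]
        retained, dropped = collinearity_screen(df, ["x", "x_copy"])
        assert retained == ["x"]
        assert dropped[0][0] == "x_copy" and "|r|=1.000" in dropped[0][1]

    def test_constant_variable_dropped_with_reason(self):
        df = pd.DataFrame({"x": np.arange(50.0), "c": np.ones(50)})
        retained, dropped = collinearity_screen(df, ["x", "c"])
        assert retained == ["x"]
        assert ("c", "zero variance") in dropped

    def test_independent_variables_all_retained_vif_near_one(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.normal(size=(10_000, 3)), columns=["u", "v", "w"])
        retained, dropped = collinearity_screen(df, ["u", "v", "w"])
        assert retained == ["u", "v", "w"] and dropped == []
        # brute-force VIF oracle: 1 / (1 - R^2) from OLS of each on the rest
        for col in ["u", "v", "w"]:
            others = [c for c in ["u", "v", "w"] if c != col]
            X = np.column_stack([np.ones(len(df)), df[others].to_numpy()])
            beta, *_ = np.linalg.lstsq(X, df[col].to_numpy(), rcond=None)
            resid = df[col].to_numpy() - X @ beta
            r2 = 1 - resid.var() / df[col].to_numpy().var()
            assert 1 / (1 - r2) < 5

    def test_forced_survivor_wins_block2_screen(self, eligible_cohort):
        """The latent-severity block collapses to the clinically chosen
        representative (current leg pain)."""
        block2 = next(b for b in DEFAULT_BLOCKS if b.block_id == 2)
        retained, dropped = collinearity_screen(
            eligible_cohort, list(block2.variables), forced=["leg_pain_current"]
        )
        assert retained == ["leg_pain_current"]
        assert len(dropped) == len(block2.variables) - 1

    def test_vif_drop_on_near_linear_combination(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=5000)
        v = rng.normal(size=5000)
        # w is a near-linear combination of u and v (VIF ~ 12) while every
        # pairwise correlation stays below the 0.7 threshold (~0.68)
        w = (u + v) / np.sqrt(2) + rng.normal(scale=0.3, size=5000)
        df = pd.DataFrame({"u": u, "v": v, "w": w})
        retained, dropped = collinearity_screen(df, ["u", "v", "w"])
        assert any("VIF" in reason for _, reason in dropped)


class TestBlockwiseSelection:
    def test_deterministic_given_data(self, eligible_cohort):
        t1 = blockwise_selection(eligible_cohort)
        t2 = blockwise_selection(eligible_cohort)
        assert t1.to_dict() == t2.to_dict()

    def test_single_variable_block_passes_univariable_result(self, eligible_cohort):
        trace = blockwise_selection(eligible_cohort)
        # block 1 has exactly one variable: its stage-2 survival is decided
        # by the univariable p-value alone
        if trace.univariable_p["c_impact"] < 0.05:
            assert trace.block_survivors[1] == ["c_impact"]
        else:
            assert trace.block_survivors[1] == []

    def test_every_variable_has_exactly_one_disposition(self, eligible_cohort):
        trace = blockwise_selection(eligible_cohort)
        all_vars = [v for b in DEFAULT_BLOCKS for v in b.variables]
        assert sorted(trace.disposition) == sorted(all_vars)

    def test_final_model_terms_all_significant(self, eligible_cohort):
        trace = blockwise_selection(eligible_cohort)
        assert trace.final_model is not None
        terms = trace.final_model.iloc[1:]
        # every retained single-df term significant; factors checked by LR
        for var in trace.final_variables:
            rows = terms[terms.index.str.startswith(var)]
            assert len(rows) > 0

    def test_only_truly_predictive_factor_retained(self):
        """With a generating model where only the impact characteristic
        carries signal, selection keeps impact and controls false
        retention of the other factors near the nominal level."""
        null_model = st.ReferralModel(
            intercept=-2.2, impact=np.log(3.5), leg_pain=0.0, sensory=0.0,
            below_knee=0.0, medium_risk=0.0, high_risk=0.0,
        )
        n_reps = 15
        impact_kept = 0
        false_kept = 0
        false_opportunities = 0
        for r in range(n_reps):
            cfg = st.GeneratorConfig(seed=40_000 + r, referral_model=null_model)
            cohort = st.prepare_cohort(st.generate_eligible_cohort(429, cfg))
            trace = blockwise_selection(cohort)
            impact_kept += "c_impact" in trace.final_variables
            others = [v for v in trace.final_variables if v != "c_impact"]
            false_kept += len(others)
            false_opportunities += len([v for b in DEFAULT_BLOCKS for v in b.variables]) - 1
        assert impact_kept >= int(0.8 * n_reps)
        assert false_kept / false_opportunities <= 0.05

    def test_separation_flagged_not_fatal(self):
        rng = np.random.default_rng(0)
        n = 120
        sep = np.concatenate([np.zeros(60), np.ones(60)])
        df = pd.DataFrame(
            {
                "referred": sep.astype(int),
                "perfect": sep.astype(int),
                "noise": rng.normal(size=n),
            }
        )
        from sciatica_triage.predictors import BlockSpec

        blocks = (BlockSpec(1, "test", ("perfect", "noise")),)
        trace = blockwise_selection(df, blocks, forced_survivors={})
        assert any(v == "perfect" for v, _ in trace.separation_flagged)
        assert "perfect" not in trace.final_variables


def test_fit_logistic_single_class_raises():
    with pytest.raises(SeparationError):
        fit_logistic(np.ones(20), np.random.default_rng(0).normal(size=(20, 1)))


def test_encode_terms_categorical_dummies(eligible_cohort):
    X, names, spans = encode_terms(eligible_cohort, ["pinprick_sensation"])
    assert names == ["pinprick_sensation[reduced]", "pinprick_sensation[loss]"]
    assert X.shape[1] == 2
    assert spans["pinprick_sensation"] == [0, 1]
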