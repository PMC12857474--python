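"""Frailty proxy, CAN proxy, IAH-Q/HNHR indicators, stratum, feature rows."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from plirisk import (
    CanProxyModel,
    DEFAULT_FRAILTY_MAP,
    FrailtyMap,
    build_feature_rows,
    compute_can_proxy,
    compute_jfi_proxy,
    race_centered_age,
)
from plirisk.covariates import (
    CHRONIC_CONDITIONS,
    assign_stratum,
    jfi_scores,
    monthly_hnhr,
    monthly_iahq,
)

INDEX = date(2017, 10, 1)


class TestJFIProxy:
    def test_no_diagnoses_scores_zero(self):
        assert compute_jfi_proxy([]) == 0

    def test_three_groups_score_three(self):
        assert compute_jfi_proxy(["dementia", "stroke", "malnutrition"]) == 3

    def test_within_group_duplicates_add_once(self):
        assert compute_jfi_proxy(["multiple_sclerosis", "spinal_cord_injury"]) == 1

    def test_all_groups_saturate_at_max_score(self):
        all_conds = [c for g in DEFAULT_FRAILTY_MAP.groups.values() for c in g]
        assert compute_jfi_proxy(all_conds) == DEFAULT_FRAILTY_MAP.max_score == 13

    def test_unknown_condition_ignored(self):
        assert compute_jfi_proxy(["dementia", "not_a_code"]) == 1

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="reuses"):
            FrailtyMap(groups={"a": ("dementia",), "b": ("dementia", "stroke")})

    def test_vectorized_scores_agree_with_scalar(self):
        dx = pd.DataFrame({
            "person_id": ["A", "A", "A", "B"],
            "condition": ["dementia", "stroke", "dementia", "diabetes"],
            "month": [-3, -5, -14, -1],
            "source": ["VA"] * 4,
        })
        s = jfi_scores(dx, ["A", "B", "C"])
        # A's month -14 dementia event is outside the 12-month look-back but
        # the month -3 event still counts the group once
        assert s.tolist() == [2, 1, 0]


class TestCanProxy:
    def test_intercept_only_scores_constant(self):
        model = CanProxyModel.intercept_only(0.1)
        feats = pd.DataFrame({f: np.zeros(5) for f in CanProxyModel.FEATURES})
        out = compute_can_proxy(feats, model, missing_fraction=0.0)
        assert np.allclose(out["can"], 0.1)
        assert (out["can_missing"] == 0).all()

    def test_missing_flagged_and_imputed_with_median(self):
        model = CanProxyModel()
        model.params_ = pd.Series({"const": -2.0, "jfi": 0.5})
        feats = pd.DataFrame({f: np.zeros(1000) for f in CanProxyModel.FEATURES})
        feats["jfi"] = np.arange(1000) % 10
        rng = np.random.default_rng(0)
        out = compute_can_proxy(feats, model, missing_fraction=0.3, rng=rng)
        miss = out["can_missing"] == 1
        assert miss.any()
        med = np.median(out.loc[~miss, "can"])
        assert np.allclose(out.loc[miss, "can"], med)

    def test_missing_fraction_binomial(self):
        """Missing count at n=100,000 with 4.5% missingness is within
        binomial sampling error of 4,500."""
        model = CanProxyModel.intercept_only(0.1)
        feats = pd.DataFrame({f: np.zeros(100_000) for f in CanProxyModel.FEATURES})
        out = compute_can_proxy(feats, model, missing_fraction=0.045,
                                rng=np.random.default_rng(12))
        n_missing = int(out["can_missing"].sum())
        sd = np.sqrt(100_000 * 0.045 * 0.955)  # ~65.6
        assert abs(n_missing - 4500) < 4 * sd


class TestRaceCenteredAge:
    def test_simple_residual(self):
        out = race_centered_age([70.4], ["g"], {"g": 60.4})
        assert out.iloc[0] == pytest.approx(10.0)

    def test_degenerate_group_centers_to_zero(self):
        out = race_centered_age([55.0] * 4, ["g"] * 4)
        assert np.allclose(out, 0.0)

    def test_two_groups_with_cohort_means(self):
        age = [62, 58, 58, 52, 58, 58]
        race = ["a", "a", "a", "b", "b", "b"]
        out = race_centered_age(age, race)  # means: a=59.333.., b=56
        # explicit given means, matching the worked example
        out2 = race_centered_age([58, 58], ["a", "b"], {"a": 60.0, "b": 55.0})
        assert out2.tolist() == [-2.0, 3.0]
        for g in ("a", "b"):
            sel = [r == g for r in race]
            assert abs(out[sel].mean()) < 1e-9

    def test_group_means_average_to_zero_within_groups(self):
        rng = np.random.default_rng(3)
        age = rng.normal(60, 15, size=500)
        race = rng.choice(["a", "b", "c"], size=500)
        out = race_centered_age(age, race)
        for g in ("a", "b", "c"):
            assert abs(out[race == g].mean()) < 1e-9

    def test_unknown_group_error_names_group(self):
        with pytest.raises(KeyError, match="martian"):
            race_centered_age([60.0], ["martian"], {"g": 60.0})


class TestMonthlyIndicators:
    @pytest.mark.parametrize(
        "hosp,snf,nchronic,jfi,expected",
        [
            (True, True, 3, 6, True),
            (True, True, 3, 5, False),   # frailty threshold
            (False, True, 3, 9, False),  # conjunction: no hospitalization
            (True, False, 3, 9, False),  # no post-acute care
            (True, True, 1, 9, False),   # too few chronic conditions
        ],
    )
    def test_iahq_truth_table(self, hosp, snf, nchronic, jfi, expected):
        assert monthly_iahq(hosp, snf, nchronic, jfi) is expected

    @pytest.mark.parametrize(
        "hosp,jfi_va,hospice,hbpc,esrd,expected",
        [
            (True, 5, False, False, False, True),
            (True, 5, False, False, True, False),   # ESRD exclusion
            (False, 9, False, False, False, False), # no hospitalization
            (True, 4, False, False, False, False),  # frailty threshold
            (True, 7, True, False, False, False),   # hospice/palliative
            (True, 7, False, True, False, False),   # HBPC/CLC enrollment
        ],
    )
    def test_hnhr_truth_table(self, hosp, jfi_va, hospice, hbpc, esrd, expected):
        assert monthly_hnhr(hosp, jfi_va, hospice, hbpc, esrd) is expected

    def test_stratum_any_month(self):
        none = [False] * 12
        one = [False] * 12
        one[2] = True
        assert assign_stratum(one, none) == "ER"
        assert assign_stratum(none, none) == "CR"
        last = [False] * 12
        last[11] = True
        assert assign_stratum(none, last) == "ER"

    def test_stratum_monotone_in_qualifying_months(self):
        months = [False] * 12
        assert assign_stratum(months, months) == "CR"
        for i in range(12):
            months2 = list(months)
            months2[i] = True
            assert assign_stratum(months2, months) == "ER"


def _mini_cohort_tables():
    """Three handcrafted persons: one clearly ER, two CR."""
    persons = pd.DataFrame({
        "person_id": ["E1", "C1", "C2"],
        "facility_id": ["F001"] * 3,
        "race": ["white", "white", "black"],
        "age": [78.0, 60.0, 55.0],
        "male": 1, "married": 0, "rural": 0, "priority_group_1": 0,
        "homeless": 0, "esrd": 0, "palliative": 0, "hbpc": 0, "clc": 0,
        "prior_cost": [30000.0, 5000.0, 4000.0],
    })
    dx_rows = []
    # E1: six frailty groups, recorded monthly through the baseline year
    for cond in ("dementia", "stroke", "heart_failure", "diabetes",
                 "pressure_ulcer", "malnutrition"):
        for m in range(-12, 0):
            dx_rows.append(("E1", cond, m, "VA"))
    dx_rows.append(("C1", "diabetes", -4, "VA"))
    dx = pd.DataFrame(dx_rows, columns=["person_id", "condition", "month", "source"])
    stays = pd.DataFrame([
        # E1: hospitalization and a post-acute SNF stay in the baseline year
        ("E1", "hospital", date(2017, 2, 1), date(2017, 2, 7), "VA", False),
        ("E1", "NH", date(2017, 2, 8), date(2017, 3, 9), "Medicare", False),
        ("C1", "hospital", date(2017, 5, 1), date(2017, 5, 3), "VA", False),
    ], columns=["person_id", "setting", "start", "end", "payer", "face_to_face"])
    return persons, dx, stays


class TestBuildFeatureRows:
    def test_mini_cohort_features(self):
        persons, dx, stays = _mini_cohort_tables()
        feats = build_feature_rows(persons, dx, stays, INDEX, mode="complete")
        assert feats.loc["E1", "stratum"] == "ER"
        assert feats.loc["C1", "stratum"] == "CR"  # hospitalized but JFI 1
        assert feats.loc["C2", "stratum"] == "CR"
        assert feats.loc["E1", "jfi"] == 6
        assert feats.loc["C1", "jfi"] == 1
        assert feats.loc["E1", "prior_hospitalization"] == 1
        assert feats.loc["E1", "prior_snf"] == 1
        assert feats.loc["C2", "prior_hospitalization"] == 0
        assert feats.loc["E1", "dementia"] == 1 and feats.loc["C2", "dementia"] == 0
        # cost standardized to $10,000 units
        assert feats.loc["E1", "prior_cost"] == pytest.approx(3.0)

    def test_lag_zero_production_equals_complete(self):
        """With no claims lag and all information in the baseline year, the
        production covariates reduce exactly to the complete-data ones."""
        persons, dx, stays = _mini_cohort_tables()
        a = build_feature_rows(persons, dx, stays, INDEX, mode="complete",
                               can_missing_fraction=0.0)
        b = build_feature_rows(persons, dx, stays, INDEX, mode="production",
                               lag_months=0, can_missing_fraction=0.0)
        pd.testing.assert_frame_equal(a, b)

    def test_production_jfi_is_max_of_monthly_scores(self):
        """Conditions recorded only early in the look-back still count in the
        production frailty score through the monthly maximum."""
        persons, dx, stays = _mini_cohort_tables()
        # C2: two group events at months -12 and -11 only; at month -1 the
        # 12-month window has dropped the first, so the monthly sequence
        # decreases and the production score takes its maximum (2).
        extra = pd.DataFrame({
            "person_id": ["C2", "C2"],
            "condition": ["dementia", "stroke"],
            "month": [-12, -11],
            "source": ["VA", "VA"],
        })
        dx2 = pd.concat([dx, extra], ignore_index=True)
        complete = build_feature_rows(persons, dx2, stays, INDEX, mode="complete")
        production = build_feature_rows(persons, dx2, stays, INDEX,
                                        mode="production", lag_months=9)
        assert complete.loc["C2", "jfi"] == 2   # both events inside months -12..-1
        assert production.loc["C2", "jfi"] == 2
        # shift one event to month -13: outside the complete look-back but
        # the production monthly max still sees it
        dx3 = dx2.copy()
        dx3.loc[dx3["month"] == -12, "month"] = -13
        complete3 = build_feature_rows(persons, dx3, stays, INDEX, mode="complete")
        production3 = build_feature_rows(persons, dx3, stays, INDEX,
                                         mode="production", lag_months=9)
        assert complete3.loc["C2", "jfi"] == 1
        assert production3.loc["C2", "jfi"] == 2

    def test_prior_lti_window_is_months_13_to_24(self):
        """A qualifying spell ending three months before the index date does
        not set the prior-LTI flag (ascertained in months 13-24 only); one
        confined to months 13-24 does."""
        persons, dx, stays = _mini_cohort_tables()
        recent = pd.DataFrame([
            ("C2", "NH", date(2017, 3, 1), date(2017, 6, 30), "Medicare", False),
        ], columns=stays.columns)  # 122 days, ends ~3 months pre-index
        old = pd.DataFrame([
            ("C1", "NH", date(2016, 1, 1), date(2016, 5, 15), "Medicare", False),
        ], columns=stays.columns)  # 136 days in months 13-24
        stays2 = pd.concat([stays, recent, old], ignore_index=True)
        for mode, lag in (("complete", 0), ("production", 9)):
            feats = build_feature_rows(persons, dx, stays2, INDEX, mode=mode,
                                       lag_months=lag)
            assert feats.loc["C2", "prior_lti"] == 0, mode
            assert feats.loc["C1", "prior_lti"] == 1, mode

    def test_lag_suppresses_recent_nonva_records(self):
        """A Medicare-recorded condition seen only in the lag window is
        invisible to the production covariates."""
        persons, dx, stays = _mini_cohort_tables()
        extra = pd.DataFrame({
            "person_id": ["C2"], "condition": ["parkinsons"],
            "month": [-2], "source": ["medicare"],
        })
        dx2 = pd.concat([dx, extra], ignore_index=True)
        complete = build_feature_rows(persons, dx2, stays, INDEX, mode="complete")
        production = build_feature_rows(persons, dx2, stays, INDEX,
                                        mode="production", lag_months=9)
        assert complete.loc["C2", "parkinsons"] == 1
        assert production.loc["C2", "parkinsons"] == 0


class TestCohortLevelProperties:
    def test_er_share_near_nine_percent(self, pipeline_result):
        er = (pipeline_result["features"]["stratum"] == "ER").mean()
        assert abs(er - 0.093) < 0.02

    def test_race_centered_age_zero_mean_by_group(self, pipeline_result):
        feats = pipeline_result["features"]
        for g, grp in feats.groupby("race"):
            assert abs(grp["race_centered_age"].mean()) < 1e-9

    def test_er_stratum_prevalence_contrast(self, pipeline_result):
        feats = pipeline_result["features"]
        er = feats["stratum"] == "ER"
        assert feats.loc[er, "jfi"].mean() > feats.loc[~er, "jfi"].mean() + 2
        assert feats.loc[er, "dementia"].mean() > 2 * feats.loc[~er, "dementia"].mean()
        assert feats.loc[er, "prior_hospitalization"].mean() > 0.8
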