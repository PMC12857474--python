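"""Stratified GLM fitting, prediction, marginal effects, retention."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from plirisk import (
    PerfectSeparationError,
    StratifiedRiskModel,
    average_marginal_effect,
    variable_retention,
)


def frame(stratum="CR", **cols):
    df = pd.DataFrame(cols)
    df["stratum"] = stratum
    return df


class TestFitBasics:
    def test_two_by_two_table_recovers_log_odds_ratio(self):
        """Saturated single-binary-covariate logit equals the table log OR."""
        x = np.r_[np.zeros(100), np.ones(100)]
        y = np.r_[np.ones(10), np.zeros(90), np.ones(30), np.zeros(70)]
        m = StratifiedRiskModel().fit(frame(x=x), y).models_["CR"]
        log_or = np.log((30 / 70) / (10 / 90))
        assert m.coefficients["x"] == pytest.approx(log_or, abs=1e-6)
        assert m.intercept == pytest.approx(np.log(10 / 90), abs=1e-6)

    def test_null_model_intercept_is_logodds_prevalence(self):
        rng = np.random.default_rng(0)
        y = (rng.random(5000) < 0.07).astype(int)
        x = rng.normal(size=5000)  # pure noise
        m = StratifiedRiskModel().fit(frame(x=x), y).models_["CR"]
        prev = y.mean()
        assert m.intercept == pytest.approx(np.log(prev / (1 - prev)), abs=0.15)
        assert abs(m.coefficients["x"]) < 3 * m.bse["x"]

    def test_mean_prediction_equals_prevalence(self):
        """Logit-with-intercept score equations force calibration in the mean."""
        rng = np.random.default_rng(1)
        X = frame(x=rng.normal(size=4000), z=(rng.random(4000) < 0.3).astype(float))
        y = (rng.random(4000) < expit(-2 + 0.8 * X["x"])).astype(int)
        mdl = StratifiedRiskModel().fit(X, y)
        assert mdl.predict_risk(X).mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_parameter_recovery_single_fit(self):
        rng = np.random.default_rng(7)
        n = 50_000
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.3).astype(float)
        beta = {"x1": 0.5, "x2": 0.8}
        eta = -4.0 + beta["x1"] * x1 + beta["x2"] * x2
        y = (rng.random(n) < expit(eta)).astype(int)
        m = StratifiedRiskModel().fit(frame(x1=x1, x2=x2), y).models_["CR"]
        for name, b in beta.items():
            assert m.coefficients[name] == pytest.approx(b, abs=3.5 * m.bse[name])
        assert m.intercept == pytest.approx(-4.0, abs=3.5 * m.bse["const"])

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X = frame(x=rng.normal(size=500), c=np.ones(500))
        y = (rng.random(500) < 0.3).astype(int)
        with pytest.warns(UserWarning, match="constant covariate 'c'"):
            mdl = StratifiedRiskModel().fit(X, y)
        assert "c" not in mdl.models_["CR"].coefficients.index

    def test_perfect_separation_names_covariate(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        y = x.copy()
        with pytest.raises(PerfectSeparationError, match="'x'"):
            StratifiedRiskModel().fit(frame(x=x), y)

    def test_needs_both_outcome_classes(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            StratifiedRiskModel().fit(frame(x=np.arange(10.0)), np.zeros(10))

    def test_pseudo_r2_properties(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=3000)
        y = (rng.random(3000) < expit(-2 + x)).astype(int)
        m = StratifiedRiskModel().fit(frame(x=x), y).models_["CR"]
        assert 0.0 < m.pseudo_r2 < 1.0
        noise = rng.normal(size=3000)  # intercept-only after dropping nothing
        m0 = StratifiedRiskModel(features=[]).fit(frame(x=noise), y).models_["CR"]
        assert m0.pseudo_r2 == pytest.approx(0.0, abs=1e-8)


class TestPredict:
    def test_inverse_logit_intercept(self):
        X = frame(x=np.zeros(3))
        y = np.array([0, 1, 0])
        mdl = StratifiedRiskModel(features=[]).fit(X, y)
        mdl.models_["CR"].intercept = -4.6
        p = mdl.predict_risk(X)
        assert np.allclose(p, expit(-4.6))
        assert p.iloc[0] == pytest.approx(0.0099, abs=2e-4)
        mdl.models_["CR"].intercept = 0.0
        assert np.allclose(mdl.predict_risk(X), 0.5)

    def test_probit_and_logit_rank_agree(self):
        rng = np.random.default_rng(5)
        n = 8000
        X = frame(x1=rng.normal(size=n), x2=(rng.random(n) < 0.4).astype(float))
        y = (rng.random(n) < expit(-3 + 0.9 * X["x1"] + 0.7 * X["x2"])).astype(int)
        p_logit = StratifiedRiskModel(link="logit").fit(X, y).predict_risk(X)
        p_probit = StratifiedRiskModel(link="probit").fit(X, y).predict_risk(X)
        rho = spearmanr(p_logit, p_probit).statistic
        assert rho > 0.99

    def test_probit_recovers_null_slopes(self):
        rng = np.random.default_rng(8)
        n = 20_000
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.05).astype(int)
        m = StratifiedRiskModel(link="probit").fit(frame(x=x), y).models_["CR"]
        assert abs(m.coefficients["x"]) < 3.5 * m.bse["x"]

    def test_missing_covariate_error_names_it(self):
        X = frame(x=np.arange(20.0))
        y = (np.arange(20) % 3 == 0).astype(int)
        mdl = StratifiedRiskModel().fit(X, y)
        with pytest.raises(ValueError, match="x"):
            mdl.predict_risk(frame(z=np.arange(20.0)))

    def test_unseen_facility_maps_to_zero_effect(self):
        rng = np.random.default_rng(6)
        n = 3000
        X = frame(x=rng.normal(size=n))
        X["facility_id"] = rng.choice(["F1", "F2", "F3"], size=n)
        y = (rng.random(n) < 0.2).astype(int)
        mdl = StratifiedRiskModel(with_facility_effects=True).fit(X, y)
        Xnew = X.head(10).copy()
        Xnew["facility_id"] = "F999"
        p_new = mdl.predict_risk(Xnew)
        m = mdl.models_["CR"]
        eta = m.intercept + m.coefficients["x"] * Xnew["x"].to_numpy()
        assert np.allclose(p_new, expit(eta))

    def test_fit_deterministic_under_row_shuffle(self):
        rng = np.random.default_rng(9)
        n = 2000
        X = frame(x=rng.normal(size=n))
        X.index = pd.Index([f"P{i:05d}" for i in range(n)], name="person_id")
        y = pd.Series((rng.random(n) < 0.2).astype(int), index=X.index)
        perm = rng.permutation(n)
        m1 = StratifiedRiskModel().fit(X, y.to_numpy()).models_["CR"]
        m2 = StratifiedRiskModel().fit(X.iloc[perm], y.iloc[perm].to_numpy()).models_["CR"]
        assert m1.coefficients["x"] == m2.coefficients["x"]
        assert m1.intercept == m2.intercept


class TestAME:
    @staticmethod
    def _fitted(link="logit"):
        rng = np.random.default_rng(4)
        n = 4000
        X = frame(x=rng.normal(size=n), b=(rng.random(n) < 0.4).astype(float))
        y = (rng.random(n) < expit(-2.5 + 0.6 * X["x"] + 0.9 * X["b"])).astype(int)
        mdl = StratifiedRiskModel(link=link).fit(X, y)
        return mdl.models_["CR"], X

    def test_zero_coefficient_gives_zero_ame(self):
        m, X = self._fitted()
        m.coefficients["b"] = 0.0
        out = average_marginal_effect(m, X, "b")
        assert out["ame"] == 0.0

    def test_continuous_ame_at_half(self):
        """Single row at p=0.5 with beta 0.1: AME = p(1-p)*beta = 0.025."""
        m, _ = self._fitted()
        m.coefficients[:] = 0.0
        m.coefficients["x"] = 0.1
        m.intercept = 0.0
        row = frame(x=np.array([0.0]), b=np.array([0.0]))
        out = average_marginal_effect(m, row, "x", kind="continuous")
        assert out["ame"] == pytest.approx(0.025, abs=1e-12)

    def test_binary_ame_matches_hand_counterfactuals(self):
        m, _ = self._fitted()
        rows = frame(x=np.array([0.0, 1.0, -1.0]), b=np.array([0.0, 1.0, 0.0]))
        out = average_marginal_effect(m, rows, "b")
        beta = m.coefficients
        eta = m.intercept + beta["x"] * rows["x"].to_numpy()
        hand = np.mean(expit(eta + beta["b"]) - expit(eta))
        assert out["ame"] == pytest.approx(hand, abs=1e-12)

    def test_ame_matches_statsmodels_margeff(self):
        """Independent route: statsmodels' own AME machinery."""
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        n = 3000
        x = rng.normal(size=n)
        b = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < expit(-2 + 0.5 * x + 0.8 * b)).astype(int)
        X = frame(x=x, b=b)
        m = StratifiedRiskModel().fit(X, y).models_["CR"]
        ours_x = average_marginal_effect(m, X, "x")
        ours_b = average_marginal_effect(m, X, "b")

        design = sm.add_constant(pd.DataFrame({"x": x, "b": b}))
        res = sm.Logit(y, design).fit(disp=0)
        me = res.get_margeff(at="overall", method="dydx", dummy=True)
        sm_vals = dict(zip(["x", "b"], me.margeff))
        sm_se = dict(zip(["x", "b"], me.margeff_se))
        assert ours_x["ame"] == pytest.approx(sm_vals["x"], rel=1e-6)
        assert ours_b["ame"] == pytest.approx(sm_vals["b"], rel=1e-6)
        assert ours_x["se"] == pytest.approx(sm_se["x"], rel=1e-4)
        assert ours_b["se"] == pytest.approx(sm_se["b"], rel=1e-4)

    def test_absent_covariate_errors(self):
        m, X = self._fitted()
        with pytest.raises(ValueError, match="nope"):
            average_marginal_effect(m, X, "nope")


class TestRetention:
    @staticmethod
    def _two_strata(seed=0, beta_er=1.2, beta_cr=0.0, n=4000):
        rng = np.random.default_rng(seed)
        stratum = np.where(rng.random(n) < 0.5, "ER", "CR")
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        beta = np.where(stratum == "ER", beta_er, beta_cr)
        y = (rng.random(n) < expit(-1.5 + beta * x)).astype(int)
        X = pd.DataFrame({"x": x, "z": z, "stratum": stratum})
        return X, y

    def test_significant_in_one_stratum_retained_in_both(self):
        X, y = self._two_strata()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mdl = StratifiedRiskModel(retention_alpha=0.05).fit(X, y)
        assert "x" in mdl.retained_
        for s in ("ER", "CR"):
            assert "x" in mdl.models_[s].coefficients.index

    def test_nothing_significant_refits_intercept_only(self):
        X, y = self._two_strata(beta_er=0.0)
        # z and x are both pure noise at n small enough to stay insignificant
        X, y = X.head(300), y[:300]
        with pytest.warns(UserWarning, match="no covariate significant"):
            mdl = StratifiedRiskModel(retention_alpha=1e-8).fit(X, y)
        for s in ("ER", "CR"):
            assert len(mdl.models_[s].coefficients) == 0

    def test_type_one_error_rate_near_alpha(self):
        """Null covariates are retained at about the nominal 5% rate."""
        hits = 0
        reps = 120
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            n = 1500
            x = rng.normal(size=n)
            y = (rng.random(n) < 0.2).astype(int)
            m = StratifiedRiskModel().fit(frame(x=x), y).models_["CR"]
            hits += m.wald_pvalues()["x"] < 0.05
        rate = hits / reps
        # binomial 99.7% band around 0.05 with 120 draws
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / reps) <= rate \
            <= 0.05 + 4 * np.sqrt(0.05 * 0.95 / reps)

    def test_variable_retention_unions_across_strata(self):
        X, y = self._two_strata()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = StratifiedRiskModel().fit(X, y)
        retained = variable_retention(full.models_, alpha=0.05)
        assert "x" in retained
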