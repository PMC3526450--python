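"""Annual cost panels and two-part models: conventions, diagnostics, recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import make_separation
from race_e.costs import (
    TwoPartCostModel,
    build_annual_panel,
    discounted_lifetime_cost,
    fit_two_part,
    modified_park_test,
    nearest_variance_power,
    ramsey_reset,
    select_link,
    year_index,
)
from race_e.schemas import COST_CATEGORIES

DAYS = 365.25


def toy_endpoint(pid="p1", endpoint="2004-01-01", death=None, censor="2008-06-30"):
    return pd.DataFrame([{
        "patient_id": pid,
        "endpoint_type": "no_event",
        "endpoint_date": pd.Timestamp(endpoint),
        "death_date": pd.Timestamp(death) if death else pd.NaT,
        "censor_date": pd.Timestamp(censor),
        "x": 1.0,
    }])


def toy_costs(sid, total):
    row = {"separation_id": sid}
    per = total / len(COST_CATEGORIES)
    for c in COST_CATEGORIES:
        row[f"cost_{c}"] = per
    return row


def constant_two_part(p, m, link="log"):
    """Two-part model with constant incidence p and magnitude m."""
    eta = {"log": np.log(m), "identity": m, "sqrt": np.sqrt(m)}[link]
    return TwoPartCostModel(
        logit_coefs=pd.Series({"const": np.log(p / (1 - p))}),
        glm_family="gamma", glm_link=link,
        glm_coefs=pd.Series({"const": eta}),
        covariates_logit=[], covariates_glm=[],
    )


class TestAnnualPanel:
    def test_year_index_convention(self):
        # day 0 (the event admission itself) belongs to year 1; a whole year
        # boundary belongs to the earlier year per the half-open (a-1, a]
        assert list(year_index(np.array([0, 1, 365, 365.25, 366, 900]))) == \
            [1, 1, 1, 1, 2, 3]

    def test_partial_final_year_dropped(self):
        ep = toy_endpoint(death=pd.Timestamp("2004-01-01") + pd.Timedelta(days=int(2.6 * DAYS)))
        admit = pd.Timestamp("2004-01-01") + pd.Timedelta(days=int(1.5 * DAYS))
        sep = pd.DataFrame([
            make_separation("p1", admit, icd="I69", drg="B82Z", sid="s1"),
        ])
        costs = pd.DataFrame([toy_costs("s1", 1000.0)])
        panel = build_annual_panel(ep, sep, costs, set(), "no_event", ["x"])
        assert list(panel["year_index"]) == [1, 2]
        assert panel.loc[panel.year_index == 1, "cost"].iloc[0] == 0.0
        assert panel.loc[panel.year_index == 2, "cost"].iloc[0] == pytest.approx(1000.0)
        assert list(panel["first_year_flag"]) == [True, False]
        assert list(panel["any_cost"]) == [False, True]

    def test_no_relevant_admissions_gives_zero_rows(self):
        ep = toy_endpoint(death=pd.Timestamp("2004-01-01") + pd.Timedelta(days=int(3.2 * DAYS)))
        sep = pd.DataFrame([
            make_separation("p1", "2004-06-01", icd="R07", drg="F74Z", sid="s1"),
        ])
        costs = pd.DataFrame([toy_costs("s1", 500.0)])
        panel = build_annual_panel(ep, sep, costs, set(), "no_event", ["x"])
        assert len(panel) == 3
        assert (panel["cost"] == 0).all()
        assert not panel["any_cost"].any()

    def test_cardiac_drg_admissions_count_as_relevant(self):
        ep = toy_endpoint(death=pd.Timestamp("2004-01-01") + pd.Timedelta(days=int(1.5 * DAYS)))
        sep = pd.DataFrame([
            make_separation("p1", "2004-03-01", icd="I21", drg="F60A", sid="s1"),
        ])
        costs = pd.DataFrame([toy_costs("s1", 700.0)])
        panel = build_annual_panel(ep, sep, costs, {"F60A"}, "no_event", ["x"])
        assert panel.loc[panel.year_index == 1, "cost"].iloc[0] == pytest.approx(700.0)


class TestModifiedPark:
    def test_gamma_data_recovers_power_two(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=5000)
        mu = np.exp(7 + 0.5 * x)
        y = rng.gamma(1.5, mu / 1.5)
        fit = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Gamma(link=sm.families.links.Log())).fit()
        fam, slope, se = modified_park_test(y, np.asarray(fit.fittedvalues),
                                            return_slope=True)
        assert fam == "gamma"
        assert slope == pytest.approx(2.0, abs=0.4)

    def test_constant_variance_data_recovers_gaussian(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=5000)
        y = 100 + 5 * x + rng.normal(0, 3, 5000)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        fam = modified_park_test(y, np.asarray(fit.fittedvalues))
        assert fam == "gaussian"

    @pytest.mark.parametrize("slope, power", [
        (1.5, 1), (2.5, 2), (0.49, 0), (2.0, 2), (3.7, 3), (-0.4, 0),
    ])
    def test_tie_breaks_toward_lower_power(self, slope, power):
        assert nearest_variance_power(slope) == power

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="30"):
            modified_park_test(np.ones(10), np.linspace(1, 2, 10))

    def test_degenerate_fitted_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            modified_park_test(np.arange(1.0, 41.0), np.full(40, 2.0))


class TestLinkSelection:
    def test_log_link_data_selects_log(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=3000)
        y = rng.gamma(2.0, np.exp(2 + 0.8 * x) / 2.0)
        assert select_link(y, sm.add_constant(x), "gamma") == "log"

    def test_single_candidate_returned_unconditionally(self):
        assert select_link(np.ones(5), np.ones((5, 1)), "gamma",
                           candidate_links=("sqrt",)) == "sqrt"

    def test_pregibon_type_one_error_near_alpha(self):
        """On a correctly specified model the Pregibon test rejects ~5% of the time."""
        from race_e.costs import _pregibon_test

        rng = np.random.default_rng(33)
        fam = sm.families.Gamma(link=sm.families.links.Log())
        rejections = 0
        reps = 150
        for _ in range(reps):
            x = rng.normal(size=400)
            y = rng.gamma(2.0, np.exp(1 + 0.5 * x) / 2.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = _pregibon_test(y, sm.add_constant(x), fam)
            rejections += int(p < 0.05)
        assert 0.005 < rejections / reps < 0.12


class TestTwoPart:
    def simulate_panel(self, rng, n=5000, p=0.3, slope=0.5):
        x = rng.normal(size=n)
        any_c = rng.random(n) < p
        amt = rng.gamma(1.5, np.exp(1 + slope * x) / 1.5)
        return pd.DataFrame({
            "patient_id": np.arange(n), "year_index": 1, "first_year_flag": True,
            "cost": np.where(any_c, amt, 0.0), "any_cost": any_c, "x": x,
        })

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(34)
        panel = self.simulate_panel(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_two_part(panel, ["x"], select=False)
        assert m.glm_family == "gamma"
        assert m.glm_link == "log"
        se_logit = m.diagnostics["logit_bse"]["const"]
        se_glm = m.diagnostics["glm_bse"]["x"]
        assert abs(m.logit_coefs["const"] - np.log(0.3 / 0.7)) < 3 * se_logit
        assert abs(m.glm_coefs["x"] - 0.5) < 3 * se_glm

    def test_all_zero_panel_degenerates_with_warning(self):
        panel = pd.DataFrame({"patient_id": [1, 2], "year_index": [1, 1],
                              "first_year_flag": [True, True],
                              "cost": [0.0, 0.0], "any_cost": [False, False],
                              "x": [0.1, 0.2]})
        with pytest.warns(RuntimeWarning):
            m = fit_two_part(panel, ["x"])
        assert m.degenerate_zero
        assert (m.predict_annual_cost(panel) == 0).all()

    def test_two_part_prediction_is_product_of_parts(self):
        rng = np.random.default_rng(35)
        panel = self.simulate_panel(rng, n=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_two_part(panel, ["x"], select=False)
        X = panel.iloc[:5]
        np.testing.assert_allclose(
            m.predict_annual_cost(X), m.predict_any(X) * m.predict_positive(X))

    def test_calibration_of_mean_annual_cost(self):
        rng = np.random.default_rng(36)
        panel = self.simulate_panel(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_two_part(panel, ["x"], select=False)
        pred = m.predict_annual_cost(panel).mean()
        emp = panel["cost"].mean()
        assert pred == pytest.approx(emp, rel=0.05)

    def test_reset_type_one_error_near_alpha(self):
        rng = np.random.default_rng(37)
        rejections = 0
        reps = 150
        for _ in range(reps):
            x = rng.normal(size=500)
            p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
            y = (rng.random(500) < p).astype(float)
            pv = ramsey_reset(y, sm.add_constant(x))
            rejections += int(pv < 0.05)
        assert 0.005 < rejections / reps < 0.12


class TestLifetimeCost:
    def test_geometric_closed_form(self):
        s, c, T = 0.9, 250.0, 30
        model = constant_two_part(0.5, c / 0.5)  # E[C] = c
        S = s ** np.arange(1, T + 1)
        X = pd.DataFrame(index=[0])
        out = discounted_lifetime_cost(model, model, S[None, :], X, discount_rate=0.0)
        expected = c * s * (1 - s**T) / (1 - s)
        assert out[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_cost_gives_zero(self):
        model = constant_two_part(0.5, 1.0)
        model.glm_coefs = pd.Series({"const": -np.inf})
        S = np.full((1, 10), 0.9)
        out = discounted_lifetime_cost(model, model, S, pd.DataFrame(index=[0]), 0.05)
        assert out[0] == 0.0

    def test_annuity_factor_under_discounting(self):
        c, T, r = 100.0, 30, 0.05
        model = constant_two_part(0.5, c / 0.5)
        S = np.ones((1, T))
        X = pd.DataFrame(index=[0])
        v0 = discounted_lifetime_cost(model, model, S, X, 0.0)[0]
        v5 = discounted_lifetime_cost(model, model, S, X, r)[0]
        annuity = (1 - (1 + r) ** -T) / r
        assert v0 == pytest.approx(c * T, rel=1e-9)
        assert v5 == pytest.approx(c * annuity, rel=1e-9)
        assert v5 / v0 == pytest.approx(annuity / T, rel=1e-9)

    def test_monotone_in_annual_cost(self):
        S = np.full((1, 20), 0.8)
        X = pd.DataFrame(index=[0])
        lo = constant_two_part(0.3, 100.0)
        hi = constant_two_part(0.3, 150.0)
        assert discounted_lifetime_cost(hi, hi, S, X, 0.05)[0] > \
            discounted_lifetime_cost(lo, lo, S, X, 0.05)[0]
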