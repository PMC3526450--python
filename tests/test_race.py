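"""Risk adjustment arithmetic, dominance/ICER logic, and observed-lifetime oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_separation
from race_e.costs import TwoPartCostModel
from race_e.race import (
    cost_effectiveness,
    design_from_names,
    fit_expected_models,
    hospital_summary,
    observed_lifetime_table,
    risk_adjust,
)
from race_e.schemas import COST_CATEGORIES
from race_e.survival import FlexSurvModel
from race_e.spline import SplineBasis

DAYS = 365.25


def patients_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "hospital", "observed_cost",
                                       "observed_ly", "expected_cost", "expected_ly"])


class TestRiskAdjustArithmetic:
    def test_worked_example_500_dollars(self):
        """A at +$300 vs expected and B at -$200 differ by exactly $500 adjusted."""
        pts = patients_frame([
            ("a1", "A", 10300.0, 5.0, 10000.0, 5.0),
            ("b1", "B", 9800.0, 5.0, 10000.0, 5.0),
        ])
        adj = risk_adjust(pts)
        means = hospital_summary(adj)
        assert means.loc["A", "adj_cost"] == 300.0
        assert means.loc["B", "adj_cost"] == -200.0
        assert means.loc["A", "adj_cost"] - means.loc["B", "adj_cost"] == 500.0

    def test_observed_equals_expected_gives_zero_adjustment(self):
        pts = patients_frame([("p", "A", 123.0, 4.5, 123.0, 4.5)])
        adj = risk_adjust(pts)
        assert adj["adj_cost"].iloc[0] == 0.0
        assert adj["adj_ly"].iloc[0] == 0.0

    def test_missing_expected_columns_rejected(self):
        pts = patients_frame([("p", "A", 1.0, 1.0, 1.0, 1.0)]).drop(columns=["expected_ly"])
        with pytest.raises(ValueError):
            risk_adjust(pts)


# observed / expected hospital means as printed in the published comparison
PRINTED = pd.DataFrame(
    {
        "observed_cost": [16504.0, 16073.0, 12471.0, 15157.0],
        "observed_ly": [6.202, 7.903, 8.139, 7.463],
        "expected_cost": [16056.0, 15244.0, 16855.0, 14626.0],
        "expected_ly": [6.442, 8.084, 8.088, 7.098],
    },
    index=pd.Index(["B", "C", "D", "A"], name="hospital"),
)


class TestPublishedTableArithmetic:
    def adjusted(self):
        pts = PRINTED.reset_index()
        pts["patient_id"] = pts["hospital"]
        return hospital_summary(risk_adjust(pts))

    def test_adjusted_cost_cells(self):
        means = self.adjusted()
        assert means.loc["D", "adj_cost"] == pytest.approx(-4384.0)
        assert means.loc["C", "adj_cost"] == pytest.approx(829.0)

    def test_adjusted_survival_cells_to_two_decimals(self):
        means = self.adjusted()
        assert round(means.loc["B", "adj_ly"], 2) == pytest.approx(-0.24)
        assert round(means.loc["D", "adj_ly"], 2) == pytest.approx(0.05)

    def test_unadjusted_dominance_lowest_cost_highest_survival(self):
        ce = cost_effectiveness(PRINTED, use_adjusted=False)
        assert ce.dominant == ["D"]
        for h in ("A", "B", "C"):
            assert "D" in ce.dominated_by[h]
        assert ce.dominated_by["D"] == []

    def test_adjusted_icer_between_survivors_matches_hand_computation(self):
        means = self.adjusted()
        ce = cost_effectiveness(means, use_adjusted=True)
        pair = [i for i in ce.icers if i["from"] == "D" and i["to"] == "A"]
        assert pair, "D and A should be successive non-dominated hospitals"
        # differences of the printed observed/expected means
        hand = ((15157.0 - 14626.0) - (12471.0 - 16855.0)) / \
            ((7.463 - 7.098) - (8.139 - 8.088))
        assert pair[0]["icer"] == pytest.approx(hand, rel=1e-9)


class TestDominanceLogic:
    def test_strict_dominance(self):
        s = pd.DataFrame({"observed_cost": [10.0, 20.0], "observed_ly": [2.0, 1.0]},
                         index=pd.Index(["A", "B"], name="hospital"))
        ce = cost_effectiveness(s, use_adjusted=False)
        assert ce.dominated_by["B"] == ["A"]
        assert ce.dominant == ["A"]

    def test_identical_hospitals_neither_dominated_icer_undefined(self):
        s = pd.DataFrame({"observed_cost": [10.0, 10.0], "observed_ly": [2.0, 2.0]},
                         index=pd.Index(["A", "B"], name="hospital"))
        ce = cost_effectiveness(s, use_adjusted=False)
        assert ce.dominated_by == {"A": [], "B": []}
        assert ce.icers[0]["icer"] is None

    def test_dominance_invariant_to_common_cost_shift(self):
        rng = np.random.default_rng(40)
        s = pd.DataFrame({"observed_cost": rng.normal(100, 30, 5),
                          "observed_ly": rng.normal(5, 1, 5)},
                         index=pd.Index(list("ABCDE"), name="hospital"))
        ce1 = cost_effectiveness(s, use_adjusted=False)
        s2 = s.assign(observed_cost=s["observed_cost"] + 12345.0)
        ce2 = cost_effectiveness(s2, use_adjusted=False)
        assert ce1.dominated_by == ce2.dominated_by
        assert ce1.ordering == ce2.ordering

    def test_single_hospital_rejected(self):
        s = pd.DataFrame({"observed_cost": [1.0], "observed_ly": [1.0]},
                         index=pd.Index(["A"], name="hospital"))
        with pytest.raises(ValueError):
            cost_effectiveness(s, use_adjusted=False)


def exponential_model(h):
    return FlexSurvModel(basis=SplineBasis((), (np.log(0.01), np.log(100.0))),
                         gamma=np.array([np.log(h), 1.0]), beta=np.empty(0),
                         covariates=[], loglik=0.0, aic=0.0, n=0, n_events=0)


def constant_cost_model(p, m):
    return TwoPartCostModel(
        logit_coefs=pd.Series({"const": np.log(p / (1 - p))}),
        glm_family="gamma", glm_link="log",
        glm_coefs=pd.Series({"const": np.log(m)}),
        covariates_logit=[], covariates_glm=[],
    )


class TestObservedLifetime:
    def build(self, endpoint_type, endpoint_days, death=None, admissions=()):
        index_admit = pd.Timestamp("2004-01-01")
        endpoint_date = index_admit + pd.Timedelta(days=endpoint_days)
        ep = pd.DataFrame([{
            "patient_id": "p1", "hospital": "A",
            "endpoint_type": endpoint_type,
            "index_date": index_admit,
            "index_sep": index_admit + pd.Timedelta(days=10),
            "endpoint_date": endpoint_date,
            "death_date": pd.Timestamp(death) if death else pd.NaT,
            "censor_date": pd.Timestamp("2008-06-30"),
            "age_at_endpoint": 72.0,
        }])
        sep_rows, cost_rows = [], []
        for i, (day, amount) in enumerate(admissions):
            sid = f"s{i}"
            sep_rows.append(make_separation(
                "p1", index_admit + pd.Timedelta(days=day), icd="I63", drg="B70B", sid=sid))
            row = {"separation_id": sid}
            for c in COST_CATEGORIES:
                row[f"cost_{c}"] = amount / len(COST_CATEGORIES)
            cost_rows.append(row)
        return ep, pd.DataFrame(sep_rows), pd.DataFrame(cost_rows)

    def test_death_endpoint_uses_observed_values_only(self):
        r = 0.05
        u = 1.2
        ep, sep, costs = self.build("death", int(round(u * DAYS)),
                                    death=pd.Timestamp("2004-01-01") + pd.Timedelta(days=int(round(u * DAYS))),
                                    admissions=[(0, 8000.0)])
        out = observed_lifetime_table(ep, sep, costs, set(), {}, {}, discount_rate=r)
        u_days = int(round(u * DAYS)) / DAYS
        expected_ly = 1 / 1.05 + (u_days - 1.0) * 1.05 ** -2
        assert out["observed_ly"].iloc[0] == pytest.approx(expected_ly, rel=1e-9)
        assert out["observed_cost"].iloc[0] == pytest.approx(8000.0 / 1.05, rel=1e-9)

    def test_discounting_matches_day_level_brute_force(self):
        """Independent day-by-day accumulation reproduces the vectorised totals."""
        r = 0.05
        death_days = 1000
        admissions = [(0, 5000.0), (250, 1200.0), (800, 900.0)]
        ep, sep, costs = self.build("death", death_days,
                                    death=pd.Timestamp("2004-01-01") + pd.Timedelta(days=death_days),
                                    admissions=admissions)
        out = observed_lifetime_table(ep, sep, costs, set(), {}, {}, discount_rate=r)
        # oracle: walk every day, assign it to the annual cycle (a-1, a]
        ly = 0.0
        for day in range(1, death_days + 1):
            a = int(np.ceil(day / DAYS))
            ly += (1.0 / DAYS) * (1 + r) ** -a
        cost = 0.0
        for day, amount in admissions:
            a = max(int(np.ceil(day / DAYS)), 1)
            cost += amount * (1 + r) ** -a
        assert out["observed_ly"].iloc[0] == pytest.approx(ly, rel=1e-3)
        assert out["observed_cost"].iloc[0] == pytest.approx(cost, rel=1e-3)

    def test_no_event_patient_combines_observed_and_extrapolated(self):
        r, h, p, m = 0.05, 0.2, 0.4, 1000.0
        ep, sep, costs = self.build("no_event", 10, admissions=[(0, 5000.0)])
        surv = {"no_event": exponential_model(h)}
        cm = constant_cost_model(p, m / p)
        cost_models = {("no_event", "first"): cm, ("no_event", "later"): cm}
        out = observed_lifetime_table(ep, sep, costs, set(), surv, cost_models,
                                      discount_rate=r)
        u = 10 / DAYS
        comp = (1 + r) ** -u
        T = 100 - 72
        a = np.arange(1, T + 1)
        S = np.exp(-h * a)
        disc = (1 + r) ** -a.astype(float)
        tail_ly = (S * disc).sum()
        tail_cost = (S * disc).sum() * m
        expected_ly = u * (1 + r) ** -1 + comp * tail_ly
        expected_cost = 5000.0 * (1 + r) ** -1 + comp * tail_cost
        assert out["observed_ly"].iloc[0] == pytest.approx(expected_ly, rel=1e-9)
        assert out["observed_cost"].iloc[0] == pytest.approx(expected_cost, rel=1e-9)

    def test_missing_model_for_endpoint_type_raises(self):
        ep, sep, costs = self.build("no_event", 10, admissions=[(0, 100.0)])
        with pytest.raises(KeyError, match="no_event"):
            observed_lifetime_table(ep, sep, costs, set(), {}, {})


class TestExpectedModels:
    def lifetimes(self, rng, n=600):
        age = rng.normal(0.4, 1.0, n)
        cost = rng.gamma(2.0, np.exp(9 + 0.3 * age) / 2.0)
        ly = np.maximum(rng.normal(8 - 1.5 * age, 2.0), 0.3)
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "hospital": rng.choice(["A", "B"], n),
            "observed_cost": cost, "observed_ly": ly, "age_index_c": age,
        })

    def test_hospital_covariate_rejected(self):
        rng = np.random.default_rng(41)
        with pytest.raises(ValueError, match="[Hh]ospital"):
            fit_expected_models(self.lifetimes(rng), ["age_index_c", "hospital_b"])

    def test_grand_mean_of_adjusted_values_near_zero(self):
        rng = np.random.default_rng(42)
        lt = self.lifetimes(rng)
        models = fit_expected_models(lt, ["age_index_c"], select=False, n_knots=1)
        adj = risk_adjust(lt, models)
        assert abs(adj["adj_cost"].mean()) < 0.02 * lt["observed_cost"].mean()
        assert abs(adj["adj_ly"].mean()) < 0.15

    def test_identical_covariates_give_constant_expected_values(self):
        rng = np.random.default_rng(43)
        lt = self.lifetimes(rng)
        lt["age_index_c"] = 0.0
        models = fit_expected_models(lt, ["age_index_c"], select=False, n_knots=1)
        adj = risk_adjust(lt, models)
        assert adj["expected_cost"].nunique() == 1
        assert adj["expected_ly"].nunique() == 1
        assert abs(adj["adj_cost"].mean()) < 0.02 * lt["observed_cost"].mean()


class TestPipelineCalibration:
    def test_grand_mean_adjusted_near_zero_on_simulated_cohort(self, base_analysis):
        pts = base_analysis.patients
        assert abs(pts["adj_cost"].mean()) < 0.02 * pts["observed_cost"].mean()
        assert abs(pts["adj_ly"].mean()) < 0.15

    def test_hospital_means_equal_member_patient_means(self, base_analysis):
        pts = base_analysis.patients
        manual = pts.groupby("hospital")["adj_cost"].mean()
        pd.testing.assert_series_equal(manual, base_analysis.summary["adj_cost"],
                                       check_names=False)

    def test_observed_ly_positive_for_all_patients(self, base_analysis):
        assert (base_analysis.patients["observed_ly"] > 0).all()

    def test_thirteen_extrapolation_models(self, base_analysis):
        assert base_analysis.n_models == 13
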