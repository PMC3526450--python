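"""Observed and expected lifetime values, risk adjustment, and cost-effectiveness.

Each patient's "observed" lifetime cost and survival combine what was actually
observed between the index stroke and the intermediate endpoint with
model-extrapolated values beyond it (patients whose endpoint is death use
observed values only).  "Expected" values come from regressions on the pooled
cohort using covariates fixed at the index event — deliberately blind to the
intermediate endpoints and to hospital identity — so that the per-patient
difference ``observed - expected`` is a casemix-adjusted performance signal.
Hospital means of these differences feed dominance classification and
incremental cost-effectiveness ratios.

Discounting uses an annual end-of-year convention throughout: year ``a``
after a reference date carries the factor ``(1+r)^-a``, and extrapolated
tails are brought back to the index date with the factor ``(1+r)^-u`` for an
endpoint ``u`` years after the index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .costs import (
    TwoPartCostModel,
    _glm_family,
    discounted_lifetime_cost,
    modified_park_test,
    relevant_admissions,
    select_link,
    year_index,
    _backwards_stepwise_glm,
)
from .schemas import total_cost
from .survival import FlexSurvModel, fit_flexsurv
from .spline import SplineBasis

__all__ = [
    "add_model_columns",
    "design_from_names",
    "observed_lifetime_table",
    "GlmModel",
    "ExpectedModels",
    "fit_expected_models",
    "risk_adjust",
    "hospital_summary",
    "CeResult",
    "cost_effectiveness",
]

DAYS_PER_YEAR = 365.25

DEFAULT_COVARIATES = [
    "age_c", "sex_male", "sev_B70A", "sev_B70B", "ses",
    "copd", "anaemia", "diabetes", "lrti_influenza", "uti",
    "urinary_symptoms", "minor_vascular",
]


def add_model_columns(endpoints: pd.DataFrame) -> pd.DataFrame:
    """Derive the numeric modelling columns used across all regressions.

    ``age_c`` centres age (at endpoint) at 70 and scales to decades;
    ``age_index_c`` does the same for age at the index event; severity
    dummies code the B70A/B70B DRG tiers against a B70C baseline.
    """
    out = endpoints.copy()
    out["sex_male"] = (out["sex"].astype(str) == "M").astype(float)
    out["sev_B70A"] = (out["drg"].astype(str) == "B70A").astype(float)
    out["sev_B70B"] = (out["drg"].astype(str) == "B70B").astype(float)
    out["age_c"] = (out["age_at_endpoint"].astype(float) - 70.0) / 10.0
    out["age_index_c"] = (out["age"].astype(float) - 70.0) / 10.0
    return out


def design_from_names(df: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    """Build a design frame; a name like ``a:b`` is the product of columns a and b."""
    cols = {}
    for nm in names:
        if ":" in nm:
            a, b = nm.split(":", 1)
            cols[nm] = df[a].astype(float) * df[b].astype(float)
        else:
            cols[nm] = df[nm].astype(float)
    return pd.DataFrame(cols, index=df.index)


def _discounted_duration(u: np.ndarray, r: float) -> np.ndarray:
    """Discounted life-years lived over the first ``u`` years (end-of-year factors)."""
    u = np.asarray(u, dtype=float)
    if r == 0:
        return u.copy()
    fl = np.floor(u)
    frac = u - fl
    v = 1.0 / (1.0 + r)
    whole = v * (1.0 - v**fl) / (1.0 - v)
    return whole + frac * v ** (fl + 1.0)


def observed_lifetime_table(
    endpoints: pd.DataFrame,
    separations: pd.DataFrame,
    costs: pd.DataFrame,
    cardiac_drg_set: set[str],
    surv_models: dict[str, FlexSurvModel],
    cost_models: dict[tuple[str, str], TwoPartCostModel],
    discount_rate: float = 0.05,
    age_cap: float = 100.0,
    icd_prefixes: tuple[str, ...] = ("I6",),
) -> pd.DataFrame:
    """Per-patient observed(+extrapolated) lifetime cost and life-years.

    ``endpoints`` must carry the modelling columns (see
    :func:`add_model_columns`).  ``surv_models`` maps the three non-death
    endpoint types to fitted survival models; ``cost_models`` maps
    ``(endpoint_type, "first"|"later")`` to two-part cost models.  Patients
    with the death endpoint contribute observed values only.
    """
    from .schemas import validate_costs, validate_separations

    separations = validate_separations(separations)
    costs = validate_costs(costs)
    ep = endpoints.reset_index(drop=True)
    missing = {t for t in ep["endpoint_type"].unique() if t != "death"} - set(surv_models)
    if missing:
        raise KeyError(f"no survival model for endpoint type(s): {sorted(missing)}")

    rel = relevant_admissions(separations, cardiac_drg_set, icd_prefixes)
    totals = total_cost(costs)
    rel = rel.assign(total=rel["separation_id"].map(totals).fillna(0.0))
    merged = rel.merge(
        ep[["patient_id", "index_date", "endpoint_date", "endpoint_type"]],
        on="patient_id", how="inner",
    )
    is_death = merged["endpoint_type"] == "death"
    keep = (merged["admit_date"] >= merged["index_date"]) & (
        (merged["admit_date"] == merged["index_date"])
        | np.where(is_death,
                   merged["admit_date"] <= merged["endpoint_date"],
                   merged["admit_date"] < merged["endpoint_date"])
    )
    obs = merged[keep].copy()
    a = year_index((obs["admit_date"] - obs["index_date"]).dt.days)
    obs["disc_cost"] = obs["total"] * (1.0 + discount_rate) ** (-a)
    obs_cost = obs.groupby("patient_id")["disc_cost"].sum()

    u = (ep["endpoint_date"] - ep["index_date"]).dt.days.to_numpy() / DAYS_PER_YEAR
    obs_ly = _discounted_duration(u, discount_rate)
    comp = (1.0 + discount_rate) ** (-u)

    tail_ly = np.zeros(len(ep))
    tail_cost = np.zeros(len(ep))
    for etype, model in surv_models.items():
        mask = (ep["endpoint_type"] == etype).to_numpy()
        if not mask.any():
            continue
        sub = ep[mask]
        T = (age_cap - np.floor(sub["age_at_endpoint"].to_numpy(dtype=float))).astype(int)
        T = np.maximum(T, 1)
        Tmax = int(T.max())
        t_grid = np.arange(1, Tmax + 1, dtype=float)
        Xs = design_from_names(sub, model.covariates).to_numpy() if model.covariates else \
            np.empty((len(sub), 0))
        S = model.survival_matrix(t_grid, Xs)
        S = np.minimum.accumulate(S, axis=1)  # numeric guard: enforce monotone
        S[t_grid[None, :] > T[:, None]] = 0.0
        disc = (1.0 + discount_rate) ** (-t_grid)
        tail_ly[mask] = (S * disc[None, :]).sum(axis=1)
        first_m = cost_models[(etype, "first")]
        later_m = cost_models[(etype, "later")]
        tail_cost[mask] = discounted_lifetime_cost(first_m, later_m, S, sub, discount_rate)

    out = ep[["patient_id", "hospital", "endpoint_type"]].copy()
    within_cost = ep["patient_id"].map(obs_cost).fillna(0.0).to_numpy()
    out["observed_cost"] = within_cost + comp * tail_cost
    out["observed_ly"] = obs_ly + comp * tail_ly
    # split retained for diagnostics: hospital effects only act on the
    # within-period part (extrapolation models pool hospitals by design)
    out["observed_cost_within"] = within_cost
    out["observed_ly_within"] = obs_ly
    out["within_period_years"] = u
    if not (out["observed_ly"] > 0).all():
        raise ValueError("observed life-years must be positive for every cohort patient")
    return out


@dataclass
class GlmModel:
    """A fitted GLM (family, link, named coefficients) with prediction."""

    coefs: pd.Series
    family: str
    link: str
    covariates: list[str]
    diagnostics: dict = field(default_factory=dict)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = design_from_names(df, self.covariates)
        Xd = sm.add_constant(X, has_constant="add")
        eta = Xd.to_numpy(dtype=float) @ self.coefs.to_numpy()
        if self.link == "log":
            return np.exp(eta)
        if self.link == "identity":
            return eta
        if self.link == "sqrt":
            return np.maximum(eta, 0.0) ** 2
        raise ValueError(f"unknown link {self.link}")


@dataclass
class ExpectedModels:
    """Expected-cost GLM and expected-survival spline model (index covariates)."""

    cost_model: GlmModel
    survival_model: FlexSurvModel
    survival_covariates: list[str]
    ly_upper: float  # quadrature horizon for the mean of the survival model

    def predict(self, df: pd.DataFrame, n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
        exp_cost = self.cost_model.predict(df)
        X = design_from_names(df, self.survival_covariates).to_numpy() if \
            self.survival_covariates else np.empty((len(df), 0))
        grid = np.linspace(1e-6, self.ly_upper, n_grid)
        S = self.survival_model.survival_matrix(grid, X)
        exp_ly = np.trapezoid(S, grid, axis=1)
        return exp_cost, exp_ly


def fit_expected_models(
    lifetimes: pd.DataFrame,
    index_covariates: list[str],
    alpha: float = 0.05,
    select: bool = True,
    n_knots: int = 2,
    frozen: ExpectedModels | None = None,
) -> ExpectedModels:
    """Fit the expected-cost GLM and expected-survival model on pooled lifetimes.

    ``lifetimes`` must contain ``observed_cost``/``observed_ly`` plus the
    index covariate columns.  Hospital identity is rejected as a covariate:
    including it would absorb exactly the contrasts the adjustment is meant
    to reveal.  ``frozen`` refits a previously selected specification on new
    (e.g. bootstrap-resampled) rows.
    """
    banned = {c for c in index_covariates if "hospital" in c.lower()}
    if banned:
        raise ValueError(
            f"hospital identity must not enter the expected models: {sorted(banned)}"
        )
    y_cost = lifetimes["observed_cost"].to_numpy(dtype=float)
    y_ly = lifetimes["observed_ly"].to_numpy(dtype=float)

    if frozen is not None:
        cm = frozen.cost_model
        X = design_from_names(lifetimes, cm.covariates)
        Xd = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(np.maximum(y_cost, 1e-6), Xd,
                         family=_glm_family(cm.family, cm.link)).fit(
                start_params=cm.coefs.to_numpy())
        cost_model = GlmModel(pd.Series(fit.params.to_numpy(), index=Xd.columns),
                              cm.family, cm.link, cm.covariates)
        sm_frozen = frozen.survival_model
        Xs = design_from_names(lifetimes, frozen.survival_covariates)
        surv = fit_flexsurv(
            np.maximum(y_ly, 1e-4), np.ones(len(lifetimes)), Xs,
            basis=sm_frozen.basis, start=sm_frozen.params, compute_cov=False,
        )
        return ExpectedModels(cost_model, surv, frozen.survival_covariates, frozen.ly_upper)

    X = design_from_names(lifetimes, index_covariates)
    if select:
        cols, _ = _backwards_stepwise_glm(
            np.maximum(y_cost, 1e-6), X, _glm_family("gamma", "log"), alpha)
    else:
        cols = list(index_covariates)
    Xd = sm.add_constant(X[cols], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prov = sm.GLM(np.maximum(y_cost, 1e-6), Xd, family=_glm_family("gamma", "log")).fit()
    if select:
        family, slope, se = modified_park_test(y_cost, np.asarray(prov.fittedvalues),
                                               return_slope=True)
        link = select_link(np.maximum(y_cost, 1e-6), Xd.to_numpy(dtype=float), family,
                           alpha=alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(np.maximum(y_cost, 1e-6), Xd,
                         family=_glm_family(family, link)).fit()
        diagnostics = {"park_slope": slope, "park_se": se}
    else:
        family, link, fit, diagnostics = "gamma", "log", prov, {}
    cost_model = GlmModel(pd.Series(fit.params.to_numpy(), index=Xd.columns),
                          family, link, cols, diagnostics)

    Xs = design_from_names(lifetimes, cols if select else index_covariates)
    surv = fit_flexsurv(np.maximum(y_ly, 1e-4), np.ones(len(lifetimes)), Xs,
                        n_knots=n_knots)
    ly_upper = float(np.max(y_ly) * 1.5 + 1.0)
    return ExpectedModels(cost_model, surv, list(Xs.columns), ly_upper)


def risk_adjust(lifetimes: pd.DataFrame, expected: ExpectedModels | None = None) -> pd.DataFrame:
    """Attach expected predictions and the observed-minus-expected columns.

    With ``expected=None`` the frame must already carry ``expected_cost`` /
    ``expected_ly`` columns (e.g. externally supplied expected means); only
    the subtraction is performed.
    """
    out = lifetimes.copy()
    if expected is not None:
        exp_cost, exp_ly = expected.predict(out)
        out["expected_cost"] = exp_cost
        out["expected_ly"] = exp_ly
    elif not {"expected_cost", "expected_ly"} <= set(out.columns):
        raise ValueError("expected_cost/expected_ly columns required when no model is given")
    out["adj_cost"] = out["observed_cost"] - out["expected_cost"]
    out["adj_ly"] = out["observed_ly"] - out["expected_ly"]
    return out


def hospital_summary(patients: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic hospital means of observed / expected / adjusted values."""
    cols = [c for c in ["observed_cost", "observed_ly", "expected_cost",
                        "expected_ly", "adj_cost", "adj_ly"] if c in patients.columns]
    g = patients.groupby("hospital")[cols].mean()
    g["n"] = patients.groupby("hospital").size()
    return g


@dataclass
class CeResult:
    """Dominance labels and ICERs between hospitals, in cost order."""

    ordering: list[str]                # hospitals sorted by mean cost (ascending)
    dominated_by: dict[str, list[str]]
    dominant: list[str]                # hospitals dominating every other
    icers: list[dict]                  # successive non-dominated pairs
    means: pd.DataFrame

    @property
    def non_dominated(self) -> list[str]:
        return [h for h in self.ordering if not self.dominated_by[h]]

    def to_dict(self) -> dict:
        return {
            "ordering": self.ordering,
            "dominated_by": self.dominated_by,
            "dominant": self.dominant,
            "icers": self.icers,
            "means": self.means.to_dict(orient="index"),
        }


def cost_effectiveness(summary: pd.DataFrame, use_adjusted: bool = True) -> CeResult:
    """Strict-dominance classification and ICERs between successive survivors.

    A hospital is dominated when some other hospital has strictly lower mean
    cost and strictly higher mean survival.  ICERs are computed between
    successive non-dominated hospitals in ascending-cost order; a zero
    survival difference leaves the ICER undefined (``None``).
    """
    cost_col = "adj_cost" if use_adjusted else "observed_cost"
    ly_col = "adj_ly" if use_adjusted else "observed_ly"
    if len(summary) < 2:
        raise ValueError("need at least two hospitals to compare")
    means = summary[[cost_col, ly_col]].rename(
        columns={cost_col: "mean_cost", ly_col: "mean_survival"})
    order = means.sort_values(["mean_cost", "mean_survival"]).index.tolist()
    dominated_by = {
        h: sorted(
            k for k in means.index
            if k != h
            and means.at[k, "mean_cost"] < means.at[h, "mean_cost"]
            and means.at[k, "mean_survival"] > means.at[h, "mean_survival"]
        )
        for h in means.index
    }
    dominant = [
        h for h in means.index
        if all(
            means.at[h, "mean_cost"] < means.at[k, "mean_cost"]
            and means.at[h, "mean_survival"] > means.at[k, "mean_survival"]
            for k in means.index if k != h
        )
    ]
    nd = [h for h in order if not dominated_by[h]]
    icers = []
    for lo, hi in zip(nd, nd[1:]):
        dc = float(means.at[hi, "mean_cost"] - means.at[lo, "mean_cost"])
        dly = float(means.at[hi, "mean_survival"] - means.at[lo, "mean_survival"])
        icers.append({
            "from": lo, "to": hi,
            "delta_cost": dc, "delta_ly": dly,
            "icer": dc / dly if dly != 0 else None,
        })
    return CeResult(order, dominated_by, dominant, icers, means)
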