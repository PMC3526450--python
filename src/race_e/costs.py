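"""Annual cost panels and two-part cost models.

Annual stroke/cardiac-related hospital costs are modelled in two parts: a
logistic regression for the probability of incurring any cost in a year, and
a GLM for the positive amount.  The GLM's variance family is chosen by the
modified Park test (regress squared raw-scale residuals on log fitted values;
the slope's nearest power in {0,1,2,3} picks gaussian / poisson / gamma /
inverse gaussian) and its link by scoring candidate power links with the
Pearson-correlation, Pregibon link, and modified Hosmer–Lemeshow tests.  The
logistic part is checked with a Ramsey RESET test.

Separate first-year and subsequent-year models are fitted for the non-fatal
stroke and cardiac endpoints and a single model for the no-event cohort —
ten fitted regressions in all.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .schemas import total_cost

__all__ = [
    "AnnualPanelError",
    "TwoPartCostModel",
    "build_annual_panel",
    "modified_park_test",
    "select_link",
    "fit_two_part",
    "discounted_lifetime_cost",
    "relevant_admissions",
]

DAYS_PER_YEAR = 365.25

FAMILY_BY_POWER = {0: "gaussian", 1: "poisson", 2: "gamma", 3: "inverse_gaussian"}
DEFAULT_RELEVANT_ICD_PREFIXES = ("I6",)


class AnnualPanelError(ValueError):
    """Inconsistent inputs while building the annual cost panel."""


def _glm_family(name: str, link):
    links = {"log": sm.families.links.Log(),
             "identity": sm.families.links.Identity(),
             "sqrt": sm.families.links.Power(0.5)}
    lk = links[link] if isinstance(link, str) else link
    fams = {
        "gaussian": sm.families.Gaussian,
        "poisson": sm.families.Poisson,
        "gamma": sm.families.Gamma,
        "inverse_gaussian": sm.families.InverseGaussian,
    }
    return fams[name](link=lk)


def relevant_admissions(
    separations: pd.DataFrame,
    cardiac_drg_set: set[str],
    icd_prefixes: tuple[str, ...] = DEFAULT_RELEVANT_ICD_PREFIXES,
) -> pd.DataFrame:
    """Stroke- or cardiac-related admissions (the ones whose costs count)."""
    icd = separations["icd_principal"].astype(str)
    drg = separations["drg"].astype(str)
    mask = icd.str.startswith(tuple(icd_prefixes)) | drg.isin(set(map(str, cardiac_drg_set)))
    return separations[mask]


def year_index(elapsed_days: np.ndarray) -> np.ndarray:
    """Map days-since-endpoint to the annual cycle (a-1, a]; day 0 -> year 1."""
    years = np.asarray(elapsed_days, dtype=float) / DAYS_PER_YEAR
    return np.maximum(np.ceil(years), 1.0).astype(int)


def build_annual_panel(
    endpoints: pd.DataFrame,
    separations: pd.DataFrame,
    costs: pd.DataFrame,
    cardiac_drg_set: set[str],
    endpoint_type: str,
    covariates: list[str],
    icd_prefixes: tuple[str, ...] = DEFAULT_RELEVANT_ICD_PREFIXES,
) -> pd.DataFrame:
    """One row per patient per full year of life after the intermediate endpoint.

    The year's cost is the 16-category total over related admissions whose
    admit date falls in that year (half-open (a-1, a] from the endpoint
    date); partial final years are dropped.
    """
    sub = endpoints[endpoints["endpoint_type"] == endpoint_type]
    if endpoint_type == "death":
        raise ValueError("no cost panel is built for the death endpoint")
    from .schemas import validate_costs, validate_separations

    separations = validate_separations(separations)
    costs = validate_costs(costs)
    rel = relevant_admissions(separations, cardiac_drg_set, icd_prefixes)
    totals = total_cost(costs)
    rel = rel.assign(total=rel["separation_id"].map(totals).fillna(0.0))

    merged = rel.merge(
        sub[["patient_id", "endpoint_date", "death_date", "censor_date"]],
        on="patient_id",
        how="inner",
    )
    alive_end = merged["death_date"].fillna(merged["censor_date"])
    alive_end = alive_end.where(alive_end <= merged["censor_date"], merged["censor_date"])
    if ((merged["admit_date"] - alive_end).dt.days > 0).any():
        raise AnnualPanelError("related admission after the patient's alive interval")
    post = merged[merged["admit_date"] >= merged["endpoint_date"]].copy()
    post["year_index"] = year_index((post["admit_date"] - post["endpoint_date"]).dt.days)
    year_cost = post.groupby(["patient_id", "year_index"])["total"].sum()

    rows = []
    for _, p in sub.iterrows():
        end = p["death_date"] if pd.notna(p["death_date"]) else p["censor_date"]
        end = min(end, p["censor_date"])
        full_years = int(np.floor((end - p["endpoint_date"]).days / DAYS_PER_YEAR))
        for a in range(1, full_years + 1):
            c = float(year_cost.get((p["patient_id"], a), 0.0))
            row = {
                "patient_id": p["patient_id"],
                "year_index": a,
                "first_year_flag": a == 1,
                "cost": c,
                "any_cost": c > 0,
            }
            for cv in covariates:
                row[cv] = p[cv]
            rows.append(row)
    cols = ["patient_id", "year_index", "first_year_flag", "cost", "any_cost"] + list(covariates)
    return pd.DataFrame(rows, columns=cols)


def nearest_variance_power(slope: float) -> int:
    """Round the Park slope to the nearest power in {0,1,2,3}; ties go down."""
    powers = np.array(sorted(FAMILY_BY_POWER))
    dist = np.abs(powers - slope)
    return int(powers[np.argmin(dist + 1e-12 * powers)])


def modified_park_test(y, mu, return_slope: bool = False):
    """Choose the GLM variance family from positive-cost data.

    Regresses squared raw-scale residuals on log fitted values with a
    log-link quasi-GLM and maps the slope to the nearest variance power in
    {0, 1, 2, 3} (ties broken toward the lower power): gaussian, poisson,
    gamma, inverse gaussian.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.size < 30:
        raise ValueError("modified Park test needs at least 30 positive-cost rows")
    if np.any(mu <= 0) or np.allclose(mu, mu[0]):
        raise ValueError("degenerate fitted values in the Park regression")
    r2 = (y - mu) ** 2
    Xp = sm.add_constant(np.log(mu))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # log-link quasi-GLM; the gamma family matches the heavy right tail of
        # squared residuals and is much more efficient than a Poisson-type fit
        if np.all(r2 > 0):
            park = sm.GLM(r2, Xp, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
        else:
            park = sm.GLM(r2, Xp, family=sm.families.Poisson()).fit()
    slope = float(park.params[1])
    se = float(park.bse[1])
    family = FAMILY_BY_POWER[nearest_variance_power(slope)]
    if return_slope:
        return family, slope, se
    return family


def _pearson_corr_test(resid, fitted) -> float:
    if np.allclose(resid, resid[0]) or np.allclose(fitted, fitted[0]):
        return 1.0
    return float(stats.pearsonr(resid, fitted).pvalue)


def _pregibon_test(y, X, family) -> float:
    """p-value of the squared linear predictor added to the fit."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = sm.GLM(y, X, family=family).fit()
        eta = base.predict(X, which="linear")
        Xa = np.column_stack([X, eta**2])
        aug = sm.GLM(y, Xa, family=family).fit()
    return float(aug.pvalues[-1])


def _modified_hosmer_lemeshow(resid, fitted, n_groups: int = 10) -> float:
    """F-test that decile-of-fitted group mean residuals are jointly zero."""
    order = np.argsort(fitted, kind="stable")
    groups = np.array_split(order, n_groups)
    groups = [g for g in groups if g.size]
    D = np.zeros((resid.size, len(groups)))
    for j, g in enumerate(groups):
        D[g, j] = 1.0
    ols = sm.OLS(resid, D).fit()
    ftest = ols.f_test(np.eye(len(groups)))
    return float(ftest.pvalue)


def select_link(
    y,
    X,
    family_name: str,
    candidate_links: tuple[str, ...] = ("log", "identity", "sqrt"),
    alpha: float = 0.05,
    return_scores: bool = False,
):
    """Score candidate power links; return the one passing the most tests.

    Each candidate link is scored by the Pearson-correlation, Pregibon and
    modified Hosmer–Lemeshow tests (a pass is p > ``alpha``); ties go to the
    log link.  If every link fails every test, log is returned with a
    warning.
    """
    if len(candidate_links) == 1:
        return (candidate_links[0], {}) if return_scores else candidate_links[0]
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    scores: dict[str, int] = {}
    detail: dict[str, dict] = {}
    for link in candidate_links:
        try:
            fam = _glm_family(family_name, link)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=fam).fit()
            mu = np.asarray(fit.fittedvalues)
            resid = y - mu
            ps = {
                "pearson": _pearson_corr_test(resid, mu),
                "pregibon": _pregibon_test(y, X, fam),
                "hosmer_lemeshow": _modified_hosmer_lemeshow(resid, mu),
            }
        except Exception:  # non-convergent candidate: zero passes
            ps = {"pearson": 0.0, "pregibon": 0.0, "hosmer_lemeshow": 0.0}
        detail[link] = ps
        scores[link] = sum(p > alpha for p in ps.values())
    best_score = max(scores.values())
    if best_score == 0:
        warnings.warn("all candidate links fail all specification tests; using log",
                      RuntimeWarning, stacklevel=2)
        chosen = "log"
    elif "log" in scores and scores["log"] == best_score:
        chosen = "log"
    else:
        chosen = max(candidate_links, key=lambda k: scores[k])
    return (chosen, detail) if return_scores else chosen


def ramsey_reset(y, X, family=None, powers=(2, 3)) -> float:
    """RESET: add powers of the linear predictor, Wald-test their joint nullity."""
    fam = family or sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = sm.GLM(y, X, family=fam).fit()
        eta = np.asarray(base.predict(X, which="linear"))
        extra = np.column_stack([eta**p for p in powers])
        aug = sm.GLM(y, np.column_stack([X, extra]), family=fam).fit()
    k = extra.shape[1]
    R = np.zeros((k, aug.params.size))
    for i in range(k):
        R[i, -k + i] = 1.0
    return float(aug.wald_test(R, scalar=True).pvalue)


def _backwards_stepwise_glm(y, X: pd.DataFrame, family, alpha: float):
    """Drop the worst Wald p-value until all covariates pass; returns (cols, trace)."""
    cols = list(X.columns)
    trace = []
    while cols:
        Xd = sm.add_constant(X[cols], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, Xd, family=family).fit()
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] <= alpha:
            break
        trace.append(("drop", worst, float(pvals[worst])))
        cols.remove(worst)
    return cols, trace


@dataclass
class TwoPartCostModel:
    """Logistic any-cost model paired with a GLM for the positive amount."""

    logit_coefs: pd.Series | None
    glm_family: str
    glm_link: str
    glm_coefs: pd.Series | None
    covariates_logit: list[str] = field(default_factory=list)
    covariates_glm: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    degenerate_zero: bool = False
    selection_trace: list = field(default_factory=list)

    def predict_any(self, X: pd.DataFrame) -> np.ndarray:
        if self.degenerate_zero:
            return np.zeros(len(X))
        Xd = sm.add_constant(X[self.covariates_logit], has_constant="add")
        eta = Xd.to_numpy(dtype=float) @ self.logit_coefs.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_positive(self, X: pd.DataFrame) -> np.ndarray:
        if self.degenerate_zero:
            return np.zeros(len(X))
        Xd = sm.add_constant(X[self.covariates_glm], has_constant="add")
        eta = Xd.to_numpy(dtype=float) @ self.glm_coefs.to_numpy()
        if self.glm_link == "log":
            return np.exp(eta)
        if self.glm_link == "identity":
            return np.maximum(eta, 0.0)
        if self.glm_link == "sqrt":
            return np.maximum(eta, 0.0) ** 2
        raise ValueError(f"unknown link {self.glm_link}")

    def predict_annual_cost(self, X: pd.DataFrame) -> np.ndarray:
        """Expected annual cost: E[C] = p * m (standard two-part identity)."""
        if self.degenerate_zero:
            return np.zeros(len(X))
        return self.predict_any(X) * self.predict_positive(X)

    def to_dict(self) -> dict:
        return {
            "logit_coefs": None if self.logit_coefs is None else self.logit_coefs.to_dict(),
            "glm_family": self.glm_family,
            "glm_link": self.glm_link,
            "glm_coefs": None if self.glm_coefs is None else self.glm_coefs.to_dict(),
            "covariates_logit": self.covariates_logit,
            "covariates_glm": self.covariates_glm,
            "diagnostics": self.diagnostics,
            "degenerate_zero": self.degenerate_zero,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def fit_two_part(
    panel: pd.DataFrame,
    covariates: list[str],
    alpha: float = 0.05,
    select: bool = True,
    family: str | None = None,
    link: str | None = None,
    candidate_links: tuple[str, ...] = ("log", "identity", "sqrt"),
) -> TwoPartCostModel:
    """Fit the two-part model on an annual cost panel.

    ``select=False`` freezes the covariate set, family and link (as the
    bootstrap does); otherwise backwards stepwise selection is applied to both
    parts, the family comes from the modified Park test and the link from the
    specification-test scoreboard.
    """
    if panel.empty or not panel["any_cost"].any():
        warnings.warn("panel has no positive costs; returning degenerate zero-cost model",
                      RuntimeWarning, stacklevel=2)
        return TwoPartCostModel(None, family or "gamma", link or "log", None,
                                degenerate_zero=True)
    y_any = panel["any_cost"].astype(float).to_numpy()
    X = panel[covariates].astype(float)
    trace: list = []

    # ---- part 1: logistic ----
    fam_bin = sm.families.Binomial()
    if len(panel) < max(30, len(covariates) + 10):
        # too few patient-years to support covariate effects on incidence
        warnings.warn("sparse panel; fitting intercept-only incidence model",
                      RuntimeWarning, stacklevel=2)
        cols_logit = []
    elif select:
        cols_logit, tr = _backwards_stepwise_glm(y_any, X, fam_bin, alpha)
        trace += [("logit",) + t for t in tr]
    else:
        cols_logit = list(covariates)
    if 0 < y_any.mean() < 1:
        Xd = sm.add_constant(X[cols_logit], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logit_fit = sm.GLM(y_any, Xd, family=fam_bin).fit()
        if np.abs(logit_fit.params).max() > 30:
            if select:
                raise ValueError(
                    "separation detected in the logistic part; reduce the covariate set"
                )
            # frozen specification: degrade to the intercept-only incidence model
            warnings.warn("separation in the logistic part; using intercept-only "
                          "incidence model", RuntimeWarning, stacklevel=2)
            cols_logit = []
            Xd = sm.add_constant(X[cols_logit], has_constant="add")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                logit_fit = sm.GLM(y_any, Xd, family=fam_bin).fit()
        logit_coefs = pd.Series(logit_fit.params.to_numpy(), index=Xd.columns)
        logit_bse = pd.Series(logit_fit.bse.to_numpy(), index=Xd.columns)
        reset_p = ramsey_reset(y_any, Xd.to_numpy(dtype=float)) if len(panel) > 50 else np.nan
    else:  # every year incurred a cost: probability part is constant 1
        logit_coefs = pd.Series({"const": 50.0})
        logit_bse = pd.Series({"const": np.nan})
        cols_logit = []
        reset_p = np.nan

    # ---- part 2: GLM on positive rows ----
    pos = panel[panel["any_cost"]]
    y_pos = pos["cost"].to_numpy(dtype=float)
    Xp = pos[covariates].astype(float)
    if len(pos) < max(30, len(covariates) + 5):
        # too few positive years to support stable covariate effects (30 is
        # also the floor the Park diagnostic needs)
        warnings.warn("sparse positive-cost panel; fitting intercept-only magnitude model",
                      RuntimeWarning, stacklevel=2)
        covariates = []
        Xp = pos[covariates].astype(float)
        select = False
    if len(pos) < 5:
        # a handful of positive years: moment-match the mean, skip IRLS
        family = family or "gamma"
        link = link or "log"
        mean_pos = float(np.mean(y_pos))
        const = {"log": np.log(mean_pos), "identity": mean_pos,
                 "sqrt": np.sqrt(mean_pos)}[link]
        return TwoPartCostModel(
            logit_coefs=logit_coefs, glm_family=family, glm_link=link,
            glm_coefs=pd.Series({"const": const}),
            covariates_logit=cols_logit, covariates_glm=[],
            diagnostics={"reset_p": reset_p, "n": int(len(panel)),
                         "n_positive": int(len(pos)), "moment_matched": True},
            selection_trace=trace,
        )
    if select:
        cols_glm, tr = _backwards_stepwise_glm(
            y_pos, Xp, _glm_family("gamma", "log"), alpha
        )
        trace += [("glm",) + t for t in tr]
    else:
        cols_glm = list(covariates)
    Xpd = sm.add_constant(Xp[cols_glm], has_constant="add")

    park_slope = park_se = np.nan
    if (family is None or link is None) and len(y_pos) < 30:
        # too few positive years to diagnose; fall back to the canonical
        # cost-model family and link
        warnings.warn("fewer than 30 positive-cost rows; defaulting to gamma/log",
                      RuntimeWarning, stacklevel=2)
        family = family or "gamma"
        link = link or "log"
    if family is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prov = sm.GLM(y_pos, Xpd, family=_glm_family("gamma", "log")).fit()
        family, park_slope, park_se = modified_park_test(
            y_pos, np.asarray(prov.fittedvalues), return_slope=True
        )
    link_detail = {}
    if link is None:
        link, link_detail = select_link(
            y_pos, Xpd.to_numpy(dtype=float), family,
            candidate_links=candidate_links, alpha=alpha, return_scores=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            glm_fit = sm.GLM(y_pos, Xpd, family=_glm_family(family, link)).fit()
        except (ValueError, np.linalg.LinAlgError):
            # ill-conditioned covariate fit: retreat to the intercept-only model
            warnings.warn("magnitude GLM failed with covariates; refitting intercept-only",
                          RuntimeWarning, stacklevel=2)
            cols_glm = []
            Xpd = sm.add_constant(Xp[cols_glm], has_constant="add")
            glm_fit = sm.GLM(y_pos, Xpd, family=_glm_family(family, link)).fit()
    glm_coefs = pd.Series(glm_fit.params.to_numpy(), index=Xpd.columns)

    return TwoPartCostModel(
        logit_coefs=logit_coefs,
        glm_family=family,
        glm_link=link,
        glm_coefs=glm_coefs,
        covariates_logit=cols_logit,
        covariates_glm=cols_glm,
        diagnostics={
            "park_slope": park_slope,
            "park_se": park_se,
            "reset_p": reset_p,
            "link_tests": link_detail,
            "n": int(len(panel)),
            "n_positive": int(len(pos)),
            "logit_bse": logit_bse.to_dict(),
            "glm_bse": dict(zip(Xpd.columns, glm_fit.bse)),
        },
        selection_trace=trace,
    )


def discounted_lifetime_cost(
    first_year_model: TwoPartCostModel,
    later_year_model: TwoPartCostModel,
    annual_survival: np.ndarray,
    X: pd.DataFrame,
    discount_rate: float = 0.05,
) -> np.ndarray:
    """Discounted lifetime cost per patient: sum_a S_a * C_a * (1+r)^-a.

    ``annual_survival`` is an (n_patients, n_years) array of cumulative
    survival to each year end (entries beyond a patient's horizon should be
    0); ``C_a`` uses the first-year model for a=1 and the later-year model
    for a>=2, evaluated at the patient's covariates.
    """
    S = np.atleast_2d(np.asarray(annual_survival, dtype=float))
    n_years = S.shape[1]
    a = np.arange(1, n_years + 1, dtype=float)
    disc = (1.0 + discount_rate) ** (-a)
    c1 = first_year_model.predict_annual_cost(X)
    cl = later_year_model.predict_annual_cost(X)
    out = S[:, 0] * disc[0] * c1
    if n_years > 1:
        out = out + (S[:, 1:] * disc[1:]).sum(axis=1) * cl
    return out
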