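"""End-to-end RAC-E analysis: cohort -> extrapolation models -> risk adjustment.

`run_race_analysis` performs the full base-case analysis and returns a
:class:`RaceAnalysis` bundle holding every intermediate product (endpoint
datasets, the 3 survival and 10 cost regressions, per-patient lifetimes,
expected models, hospital summary and cost-effectiveness result) so the
probabilistic sensitivity analysis can resample and refit the same
specifications.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from .costs import TwoPartCostModel, build_annual_panel, fit_two_part
from .race import (
    CeResult,
    DEFAULT_COVARIATES,
    ExpectedModels,
    add_model_columns,
    cost_effectiveness,
    design_from_names,
    fit_expected_models,
    hospital_summary,
    observed_lifetime_table,
    risk_adjust,
)
from .schemas import validate_costs, validate_deaths, validate_separations
from .survival import FlexSurvModel, fit_flexsurv, select_survival_model

log = logging.getLogger("race_e")

__all__ = ["PipelineConfig", "RaceAnalysis", "run_race_analysis", "run_pipeline"]

NONFATAL_TYPES = ["no_event", "recurrent_stroke", "cardiac_event"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable analysis constants (defaults follow the published design)."""

    cohort_start: str = "2005-07-01"
    cohort_end: str = "2006-06-30"
    extrapolation_start: str = "2002-07-01"
    followup_end: str = "2008-06-30"
    lookback_days: int = 365
    early_death_exclusion_days: int = 5
    nonfatal_window_days: int = 28
    endpoint_window_days: int = 730
    cardiac_mortality_threshold: float = 0.40
    discount_rate: float = 0.05
    age_cap: float = 100.0
    stepwise_alpha: float = 0.05
    knot_min: int = 1
    knot_max: int = 5
    psa_iterations: int = 2000
    seed: int = 1
    threshold_min: float = 0.0
    threshold_max: float = 100_000.0
    threshold_step: float = 1_000.0
    covariates: tuple = tuple(DEFAULT_COVARIATES)
    relevant_icd_prefixes: tuple = ("I6",)
    #: run the full selection machinery (stepwise / Park / link / knot scan);
    #: False freezes a lean specification (fast, used by simulation studies)
    select_models: bool = True
    fixed_knots: int = 1

    def cohort_config(self) -> coh.CohortConfig:
        return coh.CohortConfig(
            cohort_start=self.cohort_start,
            cohort_end=self.cohort_end,
            extrapolation_start=self.extrapolation_start,
            followup_end=self.followup_end,
            lookback_days=self.lookback_days,
            early_death_exclusion_days=self.early_death_exclusion_days,
            nonfatal_window_days=self.nonfatal_window_days,
            endpoint_window_days=self.endpoint_window_days,
            cardiac_mortality_threshold=self.cardiac_mortality_threshold,
        )

    def thresholds(self) -> np.ndarray:
        return np.arange(self.threshold_min,
                         self.threshold_max + self.threshold_step / 2,
                         self.threshold_step)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("covariates", "relevant_icd_prefixes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        d["relevant_icd_prefixes"] = list(d["relevant_icd_prefixes"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        d["relevant_icd_prefixes"] = list(d["relevant_icd_prefixes"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RaceAnalysis:
    """Everything the base-case analysis produced (inputs to the PSA)."""

    config: PipelineConfig
    endpoints_extrap: pd.DataFrame
    endpoints_cohort: pd.DataFrame
    cardiac_drg_set: set
    surv_data: dict                      # endpoint type -> survival dataset
    surv_models: dict                    # endpoint type -> FlexSurvModel
    panels: dict                         # (endpoint type, "first"|"later") -> panel
    cost_models: dict                    # (endpoint type, "first"|"later") -> TwoPartCostModel
    lifetimes: pd.DataFrame
    expected: ExpectedModels
    patients: pd.DataFrame               # lifetimes + expected + adjusted
    summary: pd.DataFrame
    ce_adjusted: CeResult
    ce_unadjusted: CeResult
    separations: pd.DataFrame
    costs: pd.DataFrame

    @property
    def n_models(self) -> int:
        """3 survival + 10 cost regressions (5 two-part pairs)."""
        n_cost = sum(2 for k, m in self.cost_models.items()
                     if k[1] == "first" or k[0] != "no_event")
        return len(self.surv_models) + n_cost


def _fit_survival(cfg: PipelineConfig, data: pd.DataFrame, covariates: list[str]):
    n_events = int(data["event"].sum())
    if n_events < 3 or len(data) < 15:
        # too sparse for a spline fit: smoothed constant-hazard model
        log.warning("sparse survival dataset (n=%d, events=%d); using exponential fallback",
                    len(data), n_events)
        t = data["time"].to_numpy(dtype=float)
        if t.size:
            rate = (n_events + 0.5) / t.sum()
            lo, hi = float(np.log(t.min())), float(np.log(t.max()))
        else:  # endpoint type absent from the data entirely
            rate, lo, hi = 0.2, np.log(0.1), np.log(10.0)
        if hi <= lo:
            lo, hi = lo - 0.5, lo + 0.5
        from .spline import SplineBasis

        return FlexSurvModel(
            basis=SplineBasis((), (lo, hi)),
            gamma=np.array([np.log(rate), 1.0]),
            beta=np.empty(0), covariates=[],
            loglik=float("nan"), aic=float("nan"),
            n=len(data), n_events=n_events,
        )
    X = design_from_names(data, covariates)
    if cfg.select_models:
        return select_survival_model(
            data["time"], data["event"], X,
            alpha=cfg.stepwise_alpha,
            knot_range=range(cfg.knot_min, cfg.knot_max + 1),
        )
    return fit_flexsurv(data["time"], data["event"], X, n_knots=cfg.fixed_knots)


def _fit_cost_pair(cfg: PipelineConfig, etype: str, panel: pd.DataFrame,
                   covariates: list[str]):
    """First-year / later-year two-part models (a single shared model for no-event)."""
    sel = cfg.select_models
    kw = dict(alpha=cfg.stepwise_alpha, select=sel)
    if not sel:  # lean frozen specification: canonical cost-model family/link
        kw.update(family="gamma", link="log")
    if etype == "no_event":
        m = fit_two_part(panel, covariates, **kw)
        return {(etype, "first"): m, (etype, "later"): m}
    first = panel[panel["first_year_flag"]]
    later = panel[~panel["first_year_flag"]]
    m1 = fit_two_part(first, covariates, **kw)
    m2 = fit_two_part(later, covariates, **kw) if len(later) else m1
    return {(etype, "first"): m1, (etype, "later"): m2}


def compute_lifetimes(ep_cohort, separations, costs, cardiac, surv_models,
                      cost_models, cfg: PipelineConfig) -> pd.DataFrame:
    """Observed lifetime values for the main cohort, with index covariates attached."""
    lifetimes = observed_lifetime_table(
        ep_cohort, separations, costs, cardiac, surv_models, cost_models,
        discount_rate=cfg.discount_rate, age_cap=cfg.age_cap,
        icd_prefixes=cfg.relevant_icd_prefixes,
    )
    keep = set(cfg.covariates) | {"age_index_c", "age_c", "sex_male",
                                  "sev_B70A", "sev_B70B", "ses"}
    return lifetimes.join(
        ep_cohort.set_index("patient_id")[[c for c in keep if c in ep_cohort.columns]],
        on="patient_id",
    )


def run_race_analysis(separations, costs, deaths, config: PipelineConfig | None = None,
                      ) -> RaceAnalysis:
    """Run the full base-case RAC-E analysis on linked tables."""
    cfg = config or PipelineConfig()
    separations = validate_separations(separations)
    costs = validate_costs(costs)
    deaths = validate_deaths(deaths)
    cc = cfg.cohort_config()

    index_extrap = coh.select_index_strokes(separations, deaths, cc)
    log.info("extrapolation index cohort: %d patients", len(index_extrap))
    cardiac = coh.derive_cardiac_drg_set(separations, deaths, index_extrap, cc)
    log.info("cardiac DRG set: %s", sorted(cardiac))
    ep_extrap = add_model_columns(
        coh.classify_endpoints(index_extrap, separations, deaths, cardiac, cc))
    log.info("extrapolation endpoints: %s",
             ep_extrap["endpoint_type"].value_counts().to_dict())

    index_cohort = coh.select_index_strokes(
        separations, deaths, cc, window=(cfg.cohort_start, cfg.cohort_end))
    ep_cohort = add_model_columns(
        coh.classify_endpoints(index_cohort, separations, deaths, cardiac, cc))
    log.info("main cohort: %d patients", len(ep_cohort))

    covs = list(cfg.covariates)
    surv_data, surv_models = {}, {}
    for etype in NONFATAL_TYPES:
        data = coh.endpoint_survival_data(ep_extrap, etype)
        surv_data[etype] = data
        surv_models[etype] = _fit_survival(cfg, data, covs)
        log.info("survival model %s: n=%d events=%d aic=%.1f", etype,
                 len(data), int(data["event"].sum()), surv_models[etype].aic)

    panels, cost_models = {}, {}
    for etype in NONFATAL_TYPES:
        panel = build_annual_panel(ep_extrap, separations, costs, cardiac, etype,
                                   covs, cfg.relevant_icd_prefixes)
        pair = _fit_cost_pair(cfg, etype, panel, covs)
        cost_models.update(pair)
        if etype == "no_event":
            panels[(etype, "all")] = panel
        else:
            panels[(etype, "first")] = panel[panel["first_year_flag"]]
            panels[(etype, "later")] = panel[~panel["first_year_flag"]]

    lifetimes = compute_lifetimes(ep_cohort, separations, costs, cardiac,
                                  surv_models, cost_models, cfg)
    # expected models use covariates fixed at the index event
    index_covs = ["age_index_c" if c == "age_c" else c for c in covs]
    expected = fit_expected_models(
        lifetimes, index_covs, alpha=cfg.stepwise_alpha,
        select=cfg.select_models, n_knots=cfg.fixed_knots,
    )
    patients = risk_adjust(lifetimes, expected)
    summary = hospital_summary(patients)
    ce_adj = cost_effectiveness(summary, use_adjusted=True)
    ce_unadj = cost_effectiveness(summary, use_adjusted=False)
    return RaceAnalysis(
        config=cfg,
        endpoints_extrap=ep_extrap,
        endpoints_cohort=ep_cohort,
        cardiac_drg_set=cardiac,
        surv_data=surv_data,
        surv_models=surv_models,
        panels=panels,
        cost_models=cost_models,
        lifetimes=lifetimes,
        expected=expected,
        patients=patients,
        summary=summary,
        ce_adjusted=ce_adj,
        ce_unadjusted=ce_unadj,
        separations=separations,
        costs=costs,
    )


def run_pipeline(separations, costs, deaths, config: PipelineConfig,
                 outdir, run_psa_stage: bool = False) -> Path:
    """Execute the pipeline and write every artifact (plus a manifest) to ``outdir``."""
    from . import __version__
    from .psa import ceac, run_psa

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = run_race_analysis(separations, costs, deaths, config)

    analysis.endpoints_cohort.to_csv(out / "endpoints.csv", index=False)
    analysis.patients.to_csv(out / "patient_lifetimes.csv", index=False)
    analysis.summary.to_csv(out / "hospital_summary.csv")
    with open(out / "ce_result.json", "w") as fh:
        json.dump({"adjusted": analysis.ce_adjusted.to_dict(),
                   "unadjusted": analysis.ce_unadjusted.to_dict()}, fh, indent=2)
    models = {
        "survival": {k: m.to_dict() for k, m in analysis.surv_models.items()},
        "cost": {f"{k[0]}_{k[1]}": m.to_dict() for k, m in analysis.cost_models.items()},
        "cardiac_drg_set": sorted(analysis.cardiac_drg_set),
    }
    with open(out / "models.json", "w") as fh:
        json.dump(models, fh, indent=2, default=float)

    if run_psa_stage:
        iters = run_psa(analysis, n_iterations=config.psa_iterations, seed=config.seed)
        iters.to_csv(out / "psa_iterations.csv", index=False)
        cc = ceac(iters, config.thresholds())
        cc.table().to_csv(out / "ceac.csv", index=False)

    config.to_yaml(out / "config.yaml")
    manifest = {
        "config_digest": config.digest(),
        "package_version": __version__,
        "seed": config.seed,
        "n_cohort": int(len(analysis.endpoints_cohort)),
        "n_extrapolation": int(len(analysis.endpoints_extrap)),
        "endpoint_counts": analysis.endpoints_cohort["endpoint_type"]
        .value_counts().to_dict(),
        "n_models": analysis.n_models,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
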