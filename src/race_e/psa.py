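"""Multi-stage bootstrap PSA and cost-effectiveness acceptability curves.

Sampling uncertainty is propagated by resampling, with replacement at the
patient level, (1) each of the three endpoint survival datasets and the five
annual cost panels, refitting the 13 extrapolation regressions with their
base-case specifications frozen (covariate sets, knot locations, families and
links), (2) recomputing every cohort patient's observed lifetime values, and
(3) resampling the pooled lifetime dataset and refitting the expected-value
models before recomputing adjusted hospital means.  Replicate ``r`` draws all
of its randomness from the substream ``(master seed, r)``, so results do not
depend on execution order and a run can be resumed at any iteration index.

CEACs report, at each willingness-to-pay threshold, the fraction of
replicates in which each hospital attains the maximum net monetary benefit
(ties split equally).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .costs import TwoPartCostModel, _glm_family
from .pipeline import NONFATAL_TYPES, RaceAnalysis, compute_lifetimes
from .race import fit_expected_models, hospital_summary, risk_adjust
from .survival import fit_flexsurv
from .race import design_from_names

log = logging.getLogger("race_e")

__all__ = ["PsaError", "psa_iteration", "run_psa", "ceac", "Ceac"]


class PsaError(RuntimeError):
    """More than the tolerated share of bootstrap replicates failed."""


def _resample_patients(df: pd.DataFrame, rng: np.random.Generator,
                       id_col: str = "patient_id") -> pd.DataFrame:
    """Patient-level bootstrap: all of a patient's rows move together."""
    ids = df[id_col].unique()
    draw = rng.choice(ids, size=ids.size, replace=True)
    groups = {pid: g for pid, g in df.groupby(id_col, sort=False)}
    out = pd.concat([groups[pid] for pid in draw], ignore_index=True)
    return out


def _refit_two_part(model: TwoPartCostModel, panel: pd.DataFrame) -> TwoPartCostModel:
    """Re-estimate both parts on a resampled panel with the frozen specification."""
    if model.degenerate_zero or not panel["any_cost"].any():
        return model
    y_any = panel["any_cost"].astype(float).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if 0 < y_any.mean() < 1 and model.covariates_logit is not None:
            Xd = sm.add_constant(panel[model.covariates_logit].astype(float),
                                 has_constant="add")
            fit = sm.GLM(y_any, Xd, family=sm.families.Binomial()).fit(
                start_params=model.logit_coefs.reindex(Xd.columns).to_numpy())
            logit_coefs = pd.Series(fit.params.to_numpy(), index=Xd.columns)
            cols_logit = model.covariates_logit
        else:
            logit_coefs = pd.Series({"const": 50.0})
            cols_logit = []
        pos = panel[panel["any_cost"]]
        if len(pos) < 5:  # moment-match tiny resampled panels, as the base fit does
            mean_pos = float(pos["cost"].mean())
            const = {"log": np.log(mean_pos), "identity": mean_pos,
                     "sqrt": np.sqrt(mean_pos)}[model.glm_link]
            return TwoPartCostModel(
                logit_coefs=logit_coefs, glm_family=model.glm_family,
                glm_link=model.glm_link, glm_coefs=pd.Series({"const": const}),
                covariates_logit=cols_logit, covariates_glm=[],
            )
        # same sparse-panel guard as the base fit: covariate effects need a
        # reasonable number of positive rows to stay stable
        cols_glm = model.covariates_glm if len(pos) >= 30 else []
        Xpd = sm.add_constant(pos[cols_glm].astype(float), has_constant="add")
        gfit = sm.GLM(pos["cost"].to_numpy(dtype=float), Xpd,
                      family=_glm_family(model.glm_family, model.glm_link)).fit(
            start_params=model.glm_coefs.reindex(Xpd.columns).dropna().to_numpy()
            if set(Xpd.columns) <= set(model.glm_coefs.index) else None)
    return TwoPartCostModel(
        logit_coefs=logit_coefs,
        glm_family=model.glm_family,
        glm_link=model.glm_link,
        glm_coefs=pd.Series(gfit.params.to_numpy(), index=Xpd.columns),
        covariates_logit=cols_logit,
        covariates_glm=cols_glm,
    )


def psa_iteration(analysis: RaceAnalysis, seed: int, index: int,
                  identity: bool = False) -> pd.DataFrame:
    """One bootstrap replicate: per-hospital adjusted means for substream (seed, index).

    ``identity=True`` disables resampling and refitting (same data implies
    the same maximum-likelihood fits) and must reproduce the base case
    exactly; it exists to validate the plumbing.
    """
    cfg = analysis.config
    rng = np.random.default_rng([seed, index])

    if identity:
        surv_models = analysis.surv_models
        cost_models = analysis.cost_models
    else:
        surv_models = {}
        for etype in NONFATAL_TYPES:
            base = analysis.surv_models[etype]
            data = _resample_patients(analysis.surv_data[etype], rng)
            X = design_from_names(data, base.covariates) if base.covariates else None
            surv_models[etype] = fit_flexsurv(
                data["time"], data["event"], X, covariates=base.covariates,
                basis=base.basis, start=base.params, compute_cov=False,
            )
        cost_models = {}
        for etype in NONFATAL_TYPES:
            if etype == "no_event":
                panel = _resample_patients(analysis.panels[(etype, "all")], rng)
                m = _refit_two_part(analysis.cost_models[(etype, "first")], panel)
                cost_models[(etype, "first")] = cost_models[(etype, "later")] = m
            else:
                for part in ("first", "later"):
                    panel = analysis.panels[(etype, part)]
                    if len(panel):
                        panel = _resample_patients(panel, rng)
                    cost_models[(etype, part)] = _refit_two_part(
                        analysis.cost_models[(etype, part)], panel)

    lifetimes = compute_lifetimes(
        analysis.endpoints_cohort, analysis.separations, analysis.costs,
        analysis.cardiac_drg_set, surv_models, cost_models, cfg,
    )
    if not identity:
        lifetimes = _resample_patients(lifetimes, rng)
        expected = fit_expected_models(lifetimes, [], frozen=analysis.expected)
    else:
        expected = analysis.expected
    patients = risk_adjust(lifetimes, expected)
    out = hospital_summary(patients)[["adj_cost", "adj_ly"]].reset_index()
    out.insert(0, "iteration", index)
    return out


def run_psa(analysis: RaceAnalysis, n_iterations: int = 2000, seed: int = 1,
            max_failure_rate: float = 0.10, start_index: int = 0,
            progress_every: int = 200) -> pd.DataFrame:
    """Run the multi-stage bootstrap; returns iteration x hospital adjusted means.

    Failed replicates are excluded (and counted in the ``n_failed`` attribute
    of the returned frame); more than ``max_failure_rate`` failures aborts —
    that level of refit fragility means the base-case models are unstable.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    hospitals_base = set(analysis.summary.index)
    frames, failed = [], []
    for r in range(start_index, start_index + n_iterations):
        try:
            it = psa_iteration(analysis, seed, r)
            if set(it["hospital"]) != hospitals_base:
                raise RuntimeError("replicate lost a hospital entirely")
            if not np.isfinite(it[["adj_cost", "adj_ly"]].to_numpy()).all():
                raise RuntimeError("non-finite replicate values")
            frames.append(it)
        except Exception as exc:  # refit failure: record and move on
            failed.append((r, str(exc)))
        if progress_every and (r + 1 - start_index) % progress_every == 0:
            log.info("PSA: %d/%d replicates done (%d failed)",
                     r + 1 - start_index, n_iterations, len(failed))
    if len(failed) > max_failure_rate * n_iterations:
        raise PsaError(
            f"{len(failed)}/{n_iterations} bootstrap replicates failed; "
            f"first failure: {failed[0]}"
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_failed"] = len(failed)
    out.attrs["failures"] = failed
    return out


@dataclass
class Ceac:
    """Probability each hospital is cost-effective across WTP thresholds."""

    thresholds: np.ndarray
    hospitals: list[str]
    probabilities: np.ndarray  # (n_thresholds, n_hospitals), rows sum to 1

    def table(self) -> pd.DataFrame:
        rows = []
        for i, lam in enumerate(self.thresholds):
            for j, h in enumerate(self.hospitals):
                rows.append({"threshold": lam, "hospital": h,
                             "probability": self.probabilities[i, j]})
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j, h in enumerate(self.hospitals):
            ax.plot(self.thresholds, self.probabilities[:, j], label=h)
        ax.set_xlabel("value of a life year")
        ax.set_ylabel("probability most cost-effective")
        ax.set_ylim(0, 1)
        ax.legend(title="hospital")
        return ax


def ceac(iterations: pd.DataFrame, thresholds) -> Ceac:
    """Net-monetary-benefit tournament across bootstrap replicates.

    At threshold lambda, replicate ``r`` is won by the hospital(s) maximising
    ``NMB = lambda * adj_ly - adj_cost``; ties share the win equally.
    """
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if (thresholds < 0).any():
        raise ValueError("thresholds must be >= 0")
    if iterations.empty:
        raise ValueError("need at least one PSA iteration")
    cost = iterations.pivot(index="iteration", columns="hospital", values="adj_cost")
    ly = iterations.pivot(index="iteration", columns="hospital", values="adj_ly")
    hospitals = list(cost.columns)
    C = cost.to_numpy()
    L = ly.to_numpy()
    probs = np.empty((thresholds.size, len(hospitals)))
    for i, lam in enumerate(thresholds):
        nmb = lam * L - C
        best = nmb.max(axis=1, keepdims=True)
        win = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        weights = win / win.sum(axis=1, keepdims=True)
        probs[i] = weights.mean(axis=0)
    return Ceac(thresholds=thresholds, hospitals=hospitals, probabilities=probs)
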