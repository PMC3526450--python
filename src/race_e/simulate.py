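"""Synthetic linked hospital-separation / cost / mortality data.

The generator emulates the statistical structure the RAC-E analysis assumes:
index stroke admissions (ICD-10 I60–I64, AR-DRG B70A/B/C severity tiers) at a
handful of hospitals, competing intermediate events (recurrent stroke, major
cardiac event, death) driven by exponential clocks, right-censored long-term
survival with covariate and hospital effects, and annual stroke/cardiac
related hospital costs with a point mass at zero and a gamma-distributed
positive part with a log-link mean (so the modified Park test has a known
correct answer of 2).

Every run is reproducible: one pseudo-random stream per output table, all
derived from the master seed, and ground truth (the realized endpoint of each
patient plus the true model parameters) is returned alongside the tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemas import (
    COMORBIDITY_FLAGS,
    COST_CATEGORIES,
    COST_COLUMNS,
    DEATH_COLUMNS,
    SEPARATION_COLUMNS,
)

__all__ = [
    "ConfigurationError",
    "HospitalSpec",
    "CovariateSpec",
    "EndpointHazards",
    "CostSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_linked_data",
    "inject_known_effects",
    "write_tables",
]

DAYS_PER_YEAR = 365.25

STROKE_ICD_CODES = ["I60", "I61", "I62", "I63", "I64"]
SEVERITY_TIERS = ["B70A", "B70B", "B70C"]


class ConfigurationError(ValueError):
    """An invalid simulation-configuration field (named in the message)."""


@dataclass(frozen=True)
class HospitalSpec:
    """One hospital: admission share plus injected ground-truth effects.

    ``cost_multiplier`` scales every cost incurred at the hospital;
    ``log_hazard_offset`` shifts the patient's log death hazard (before and
    after any intermediate event); ``age_shift`` moves the hospital's age mix
    to create confounded casemix.
    """

    label: str
    share: float = 1.0
    cost_multiplier: float = 1.0
    log_hazard_offset: float = 0.0
    age_shift: float = 0.0


@dataclass(frozen=True)
class CovariateSpec:
    age_mean: float = 74.0
    age_sd: float = 12.0
    age_min: float = 30.0
    age_max: float = 99.0
    male_prob: float = 0.5
    comorbidity_prevs: dict = field(
        default_factory=lambda: {
            "copd": 0.09,
            "anaemia": 0.11,
            "diabetes": 0.24,
            "lrti_influenza": 0.10,
            "uti": 0.19,
            "urinary_symptoms": 0.13,
            "minor_vascular": 0.77,
        }
    )
    ses_mean: float = 0.0
    ses_sd: float = 1.0


@dataclass(frozen=True)
class EndpointHazards:
    """Yearly exponential rates for the competing intermediate-event clocks."""

    recurrent_stroke: float = 0.05
    cardiac_event: float = 0.05
    death: float = 0.12
    #: per-year-of-age log hazard ratio on every death clock
    age_log_hr: float = 0.06
    #: death hazard after a non-fatal recurrent stroke / cardiac event
    post_stroke_death: float = 0.25
    post_cardiac_death: float = 0.70


@dataclass(frozen=True)
class CostSpec:
    """Annual related-care cost process and admission cost levels."""

    p_any: float = 0.35
    gamma_shape: float = 1.5
    annual_mean: float = 3000.0
    #: per-year-of-age log effect on the positive-cost mean (log link)
    age_log_coef: float = 0.015
    index_mean: dict = field(
        default_factory=lambda: {"B70A": 14000.0, "B70B": 9000.0, "B70C": 5500.0}
    )
    index_shape: float = 3.0
    event_mean: dict = field(default_factory=lambda: {"stroke": 8000.0, "cardiac": 7000.0})
    noise_mean: float = 800.0


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 2000
    hospitals: tuple = (
        HospitalSpec("A", 0.25),
        HospitalSpec("B", 0.25),
        HospitalSpec("C", 0.25),
        HospitalSpec("D", 0.25),
    )
    covariate_spec: CovariateSpec = CovariateSpec()
    severity_probs: dict = field(
        default_factory=lambda: {"B70A": 0.34, "B70B": 0.38, "B70C": 0.28}
    )
    endpoint_hazards: EndpointHazards = EndpointHazards()
    cost_spec: CostSpec = CostSpec()
    index_start: str = "2002-07-01"
    index_end: str = "2006-06-30"
    followup_end: str = "2008-06-30"
    registry_end: str = "2008-12-31"
    seed: int = 0
    #: intermediate endpoints are assessed within this window after the index
    #: separation; later events/deaths belong to the no-event follow-up
    endpoint_window_days: int = 730
    transfer_prob: float = 0.05
    #: per-alive-year rate of low-mortality circulatory "noise" readmissions
    noise_readmission_rate: float = 0.10
    cardiac_drg_codes: tuple = ("F60A", "F41B", "F62A")
    noise_drg: str = "F74Z"
    los_mean: dict = field(default_factory=lambda: {"B70A": 18.0, "B70B": 12.0, "B70C": 7.0})
    inhospital_death_prob: dict = field(
        default_factory=lambda: {"B70A": 0.14, "B70B": 0.06, "B70C": 0.02}
    )

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if not self.hospitals:
            raise ConfigurationError("hospitals must be non-empty")
        shares = np.array([h.share for h in self.hospitals], dtype=float)
        if (shares < 0).any() or shares.sum() <= 0:
            raise ConfigurationError("hospitals: shares must be non-negative and sum > 0")
        for h in self.hospitals:
            if h.cost_multiplier <= 0:
                raise ConfigurationError(f"hospitals[{h.label}].cost_multiplier must be > 0")
        sp = self.severity_probs
        if set(sp) != set(SEVERITY_TIERS):
            raise ConfigurationError("severity_probs must cover exactly B70A/B70B/B70C")
        vals = np.array(list(sp.values()), dtype=float)
        if (vals < 0).any() or (vals > 1).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigurationError("severity_probs must lie in [0,1] and sum to 1")
        hz = self.endpoint_hazards
        for name in ("recurrent_stroke", "cardiac_event", "death",
                     "post_stroke_death", "post_cardiac_death"):
            if getattr(hz, name) < 0:
                raise ConfigurationError(f"endpoint_hazards.{name} must be >= 0")
        cs = self.cost_spec
        if not 0.0 <= cs.p_any <= 1.0:
            raise ConfigurationError("cost_spec.p_any must lie in [0,1]")
        if cs.gamma_shape <= 0 or cs.annual_mean <= 0:
            raise ConfigurationError("cost_spec gamma shape/mean must be > 0")
        cov = self.covariate_spec
        if not 0.0 <= cov.male_prob <= 1.0:
            raise ConfigurationError("covariate_spec.male_prob must lie in [0,1]")
        for k, v in cov.comorbidity_prevs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"covariate_spec.comorbidity_prevs[{k}] must lie in [0,1]")
        if not 0.0 <= self.transfer_prob <= 1.0:
            raise ConfigurationError("transfer_prob must lie in [0,1]")
        if pd.Timestamp(self.index_end) < pd.Timestamp(self.index_start):
            raise ConfigurationError("index_end must not precede index_start")
        if pd.Timestamp(self.followup_end) < pd.Timestamp(self.index_end):
            raise ConfigurationError("followup_end must not precede index_end")

    @property
    def hospital_labels(self) -> list[str]:
        return [h.label for h in self.hospitals]


@dataclass
class GroundTruth:
    """Realized per-patient endpoints plus the generating parameters."""

    patients: pd.DataFrame
    params: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "params": self.params,
                    "patients": self.patients.assign(
                        **{
                            c: self.patients[c].astype(str)
                            for c in self.patients.columns
                            if pd.api.types.is_datetime64_any_dtype(self.patients[c])
                        }
                    ).to_dict(orient="list"),
                },
                fh,
                indent=2,
                default=str,
            )


def inject_known_effects(config: SimulationConfig, hospital_effects: dict) -> SimulationConfig:
    """Return a config whose hospitals carry the requested ground-truth effects.

    ``hospital_effects`` maps hospital label to a dict with any of
    ``cost_multiplier``, ``log_hazard_offset``, ``age_shift``.
    """
    labels = config.hospital_labels
    unknown = set(hospital_effects) - set(labels)
    if unknown:
        raise ConfigurationError(f"unknown hospital label(s): {sorted(unknown)}")
    new_hosps = []
    for h in config.hospitals:
        eff = hospital_effects.get(h.label, {})
        bad = set(eff) - {"cost_multiplier", "log_hazard_offset", "age_shift"}
        if bad:
            raise ConfigurationError(f"unknown effect field(s) for {h.label}: {sorted(bad)}")
        new_hosps.append(dataclasses.replace(h, **eff))
    return dataclasses.replace(config, hospitals=tuple(new_hosps))


def _empty_tables(config):
    sep = pd.DataFrame(columns=SEPARATION_COLUMNS)
    costs = pd.DataFrame(columns=COST_COLUMNS)
    deaths = pd.DataFrame(columns=DEATH_COLUMNS)
    gt = GroundTruth(
        patients=pd.DataFrame(
            columns=["patient_id", "hospital", "age", "endpoint_type", "endpoint_date",
                     "event_date", "death_date"]
        ),
        params=_true_params(config),
    )
    return sep, costs, deaths, gt


def _true_params(config: SimulationConfig) -> dict:
    return {
        "seed": config.seed,
        "endpoint_hazards": dataclasses.asdict(config.endpoint_hazards),
        "cost_spec": {
            "p_any": config.cost_spec.p_any,
            "gamma_shape": config.cost_spec.gamma_shape,
            "annual_mean": config.cost_spec.annual_mean,
            "age_log_coef": config.cost_spec.age_log_coef,
        },
        "hospital_effects": {
            h.label: {
                "cost_multiplier": h.cost_multiplier,
                "log_hazard_offset": h.log_hazard_offset,
                "age_shift": h.age_shift,
            }
            for h in config.hospitals
        },
    }


def _split_categories(total: float, rng: np.random.Generator) -> list[float]:
    w = rng.dirichlet(np.ones(len(COST_CATEGORIES)) * 0.6)
    return list(np.round(total * w, 2))


def generate_linked_data(config: SimulationConfig):
    """Generate (separations, costs, deaths, GroundTruth) for ``config``.

    Tables satisfy the documented CSV schemas; identical config (including
    seed) yields byte-identical tables.
    """
    config.validate()
    if config.n_patients == 0:
        return _empty_tables(config)

    n = config.n_patients
    rng_pat = np.random.default_rng([config.seed, 0])
    rng_event = np.random.default_rng([config.seed, 1])
    rng_cost = np.random.default_rng([config.seed, 2])
    rng_admin = np.random.default_rng([config.seed, 3])

    cov = config.covariate_spec
    hz = config.endpoint_hazards
    cs = config.cost_spec

    shares = np.array([h.share for h in config.hospitals], dtype=float)
    shares = shares / shares.sum()
    hosp_idx = rng_pat.choice(len(config.hospitals), size=n, p=shares)
    hosp_specs = [config.hospitals[i] for i in hosp_idx]
    age_shift = np.array([h.age_shift for h in hosp_specs])
    log_hr_hosp = np.array([h.log_hazard_offset for h in hosp_specs])
    cost_mult = np.array([h.cost_multiplier for h in hosp_specs])

    age = np.clip(rng_pat.normal(cov.age_mean + age_shift, cov.age_sd), cov.age_min, cov.age_max)
    sex = np.where(rng_pat.random(n) < cov.male_prob, "M", "F")
    flags = {
        f: (rng_pat.random(n) < cov.comorbidity_prevs.get(f, 0.0)).astype(int)
        for f in COMORBIDITY_FLAGS
    }
    ses = rng_pat.normal(cov.ses_mean, cov.ses_sd, n)

    idx_start = pd.Timestamp(config.index_start)
    idx_days = (pd.Timestamp(config.index_end) - idx_start).days
    admit_off = rng_pat.integers(0, idx_days + 1, n)
    tiers = rng_pat.choice(SEVERITY_TIERS, size=n, p=[config.severity_probs[t] for t in SEVERITY_TIERS])
    icd = rng_pat.choice(STROKE_ICD_CODES, size=n)
    los_mean = np.array([config.los_mean[t] for t in tiers])
    los = np.maximum(1, np.round(rng_pat.gamma(2.0, los_mean / 2.0))).astype(int)

    followup_end = pd.Timestamp(config.followup_end)
    registry_end = pd.Timestamp(config.registry_end)

    # death-clock log hazard multipliers (age + hospital), shared by all phases
    log_mult = hz.age_log_hr * (age - cov.age_mean) + log_hr_hosp
    death_rate = hz.death * np.exp(log_mult)

    # in-hospital deaths (exercise the early-death exclusion)
    p_inhosp = np.array([config.inhospital_death_prob[t] for t in tiers])
    inhosp = rng_event.random(n) < p_inhosp
    inhosp_day = np.minimum(np.floor(rng_event.random(n) * los).astype(int), los - 1)

    # competing clocks (years from index separation)
    with np.errstate(divide="ignore"):
        t_stroke = rng_event.exponential(1.0, n) / max(hz.recurrent_stroke, 1e-300)
        t_card = rng_event.exponential(1.0, n) / max(hz.cardiac_event, 1e-300)
        t_death = rng_event.exponential(1.0, n) / np.maximum(death_rate, 1e-300)
    t_post_stroke = rng_event.exponential(1.0, n) / np.maximum(
        hz.post_stroke_death * np.exp(log_mult), 1e-300
    )
    t_post_card = rng_event.exponential(1.0, n) / np.maximum(
        hz.post_cardiac_death * np.exp(log_mult), 1e-300
    )

    sep_rows: list[dict] = []
    cost_rows: list[dict] = []
    death_rows: list[dict] = []
    gt_rows: list[dict] = []
    sep_seq = 0

    def add_sep(pid, i, admit, sepd, icd_code, drg, transfer=False):
        nonlocal sep_seq
        sep_seq += 1
        sid = f"S{sep_seq:07d}"
        row = {
            "separation_id": sid,
            "patient_id": pid,
            "hospital": hosp_specs[i].label,
            "admit_date": admit.date().isoformat(),
            "sep_date": sepd.date().isoformat(),
            "icd_principal": icd_code,
            "drg": drg,
            "age": round(float(age[i]), 1),
            "sex": sex[i],
            "ses": round(float(ses[i]), 3),
            "transfer_flag": int(transfer),
        }
        for f in COMORBIDITY_FLAGS:
            row[f] = int(flags[f][i])
        sep_rows.append(row)
        return sid

    def add_cost(sid, total):
        parts = _split_categories(max(total, 0.0), rng_cost)
        row = {"separation_id": sid}
        for c, v in zip(COST_CATEGORIES, parts):
            row[f"cost_{c}"] = v
        cost_rows.append(row)

    def annual_cost_mean(i):
        return cs.annual_mean * np.exp(cs.age_log_coef * (age[i] - cov.age_mean)) * cost_mult[i]

    for i in range(n):
        pid = f"P{i:06d}"
        admit = idx_start + pd.Timedelta(days=int(admit_off[i]))
        sepd = admit + pd.Timedelta(days=int(los[i]))
        death_date = None
        endpoint_type = "no_event"
        endpoint_date = None
        event_date = None
        event_kind = None

        if inhosp[i]:
            death_date = admit + pd.Timedelta(days=int(inhosp_day[i]) + 1)
            sepd = death_date
            endpoint_type = "death"
            endpoint_date = death_date
        else:
            tmin = min(t_death[i], t_stroke[i], t_card[i])
            # fixed tie priority: death > stroke > cardiac
            if t_death[i] == tmin:
                kind = "death"
            elif t_stroke[i] == tmin:
                kind = "stroke"
            else:
                kind = "cardiac"
            days = max(int(round(min(tmin, 200.0) * DAYS_PER_YEAR)), 1)
            when = sepd + pd.Timedelta(days=days)
            # endpoints are assessed within this window; later events/deaths
            # belong to the no-event follow-up
            window_end = min(sepd + pd.Timedelta(days=config.endpoint_window_days), followup_end)
            if kind == "death":
                if when <= window_end:
                    endpoint_type, endpoint_date, death_date = "death", when, when
                elif when <= registry_end:
                    death_date = when  # recorded but outside the endpoint window
            elif when <= followup_end:
                # the admission exists in the data even when it falls outside
                # the endpoint window (it then only contributes costs)
                event_kind = kind
                event_date = when
                t_post = t_post_stroke[i] if kind == "stroke" else t_post_card[i]
                post_days = max(int(round(min(t_post, 200.0) * DAYS_PER_YEAR)), 1)
                dd = when + pd.Timedelta(days=post_days)
                if dd <= registry_end:
                    death_date = dd
                if when <= window_end:
                    fatal = (
                        death_date is not None
                        and (death_date - when).days <= 28
                        and death_date <= followup_end
                    )
                    if fatal:
                        endpoint_type, endpoint_date = "death", death_date
                    else:
                        endpoint_type = "recurrent_stroke" if kind == "stroke" else "cardiac_event"
                        endpoint_date = when
            else:
                # first clock fires after follow-up end: censored, but a death
                # clock may still land inside the registry window
                dd_days = max(int(round(min(t_death[i], 200.0) * DAYS_PER_YEAR)), 1)
                dd = sepd + pd.Timedelta(days=dd_days)
                if dd <= registry_end:
                    death_date = dd

        if endpoint_type == "no_event":
            endpoint_date = sepd

        # ---- index admission (possibly split across a transfer) ----
        base_cost = rng_cost.gamma(cs.index_shape, cs.index_mean[tiers[i]] / cs.index_shape)
        base_cost *= cost_mult[i]
        if (not inhosp[i]) and config.transfer_prob > 0 and rng_admin.random() < config.transfer_prob \
                and (sepd - admit).days >= 2 and len(config.hospitals) > 1:
            cut = admit + pd.Timedelta(days=int((sepd - admit).days // 2))
            sid1 = add_sep(pid, i, admit, cut, icd[i], tiers[i])
            # receiving hospital differs; effects stay attributed to the index hospital
            j = int(rng_admin.integers(0, len(config.hospitals)))
            recv = config.hospitals[j].label
            sep_seq_before = sep_seq
            sid2 = add_sep(pid, i, cut, sepd, icd[i], tiers[i], transfer=True)
            sep_rows[-1]["hospital"] = recv
            frac = 0.5
            add_cost(sid1, base_cost * frac)
            add_cost(sid2, base_cost * (1 - frac))
        else:
            sid = add_sep(pid, i, admit, sepd, icd[i], tiers[i])
            add_cost(sid, base_cost)

        alive_end = min(death_date, followup_end) if death_date is not None else followup_end

        # ---- event admission ----
        if event_kind is not None:
            ev_los = max(1, int(round(rng_admin.gamma(2.0, 5.0))))
            ev_sep = event_date + pd.Timedelta(days=ev_los)
            if death_date is not None:
                ev_sep = min(ev_sep, death_date)
            if event_kind == "stroke":
                sid = add_sep(pid, i, event_date, ev_sep, "I63", "B70B")
            else:
                drg = str(rng_admin.choice(list(config.cardiac_drg_codes)))
                sid = add_sep(pid, i, event_date, ev_sep, "I21", drg)
            add_cost(sid, rng_cost.gamma(cs.index_shape, cs.event_mean[event_kind] / cs.index_shape)
                     * cost_mult[i])

        # ---- annual related-care cost admissions after the endpoint ----
        if endpoint_type != "death":
            start = endpoint_date
            alive_years = (alive_end - start).days / DAYS_PER_YEAR
            a = 1
            while a - 1 < alive_years:
                frac = min(alive_years - (a - 1), 1.0)
                if rng_cost.random() < cs.p_any * frac:
                    day = (a - 1 + rng_cost.random() * frac) * DAYS_PER_YEAR
                    ad = start + pd.Timedelta(days=int(np.floor(day)) + 1)
                    if ad <= alive_end:
                        ad_sep = min(ad + pd.Timedelta(days=int(rng_admin.integers(1, 6))), alive_end)
                        total = rng_cost.gamma(cs.gamma_shape, annual_cost_mean(i) / cs.gamma_shape)
                        sid = add_sep(pid, i, ad, ad_sep, "I69", "B82Z")
                        add_cost(sid, total)
                a += 1

        # ---- low-mortality circulatory noise readmissions ----
        if config.noise_readmission_rate > 0 and endpoint_type != "death":
            span = (alive_end - sepd).days / DAYS_PER_YEAR
            if span > 0:
                k = rng_admin.poisson(config.noise_readmission_rate * span)
                for _ in range(int(k)):
                    off = int(rng_admin.integers(1, max(int(span * DAYS_PER_YEAR), 2)))
                    ad = sepd + pd.Timedelta(days=off)
                    if ad >= alive_end:
                        continue
                    ad_sep = min(ad + pd.Timedelta(days=2), alive_end)
                    sid = add_sep(pid, i, ad, ad_sep, "R07", config.noise_drg)
                    add_cost(sid, rng_cost.gamma(1.2, cs.noise_mean / 1.2))

        if death_date is not None and death_date <= registry_end:
            death_rows.append({"patient_id": pid, "death_date": death_date.date().isoformat()})

        gt_rows.append(
            {
                "patient_id": pid,
                "hospital": hosp_specs[i].label,
                "age": round(float(age[i]), 1),
                "endpoint_type": endpoint_type,
                "endpoint_date": endpoint_date.date().isoformat(),
                "event_date": event_date.date().isoformat() if event_date is not None else "",
                "death_date": death_date.date().isoformat() if death_date is not None else "",
            }
        )

    separations = pd.DataFrame(sep_rows, columns=SEPARATION_COLUMNS)
    costs = pd.DataFrame(cost_rows, columns=COST_COLUMNS)
    deaths = pd.DataFrame(death_rows, columns=DEATH_COLUMNS)
    gt = GroundTruth(patients=pd.DataFrame(gt_rows), params=_true_params(config))
    return separations, costs, deaths, gt


def write_tables(outdir, separations, costs, deaths, ground_truth: GroundTruth) -> None:
    """Write the four outputs (CSV + JSON) into ``outdir``."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    separations.to_csv(out / "separations.csv", index=False)
    costs.to_csv(out / "costs.csv", index=False)
    deaths.to_csv(out / "deaths.csv", index=False)
    ground_truth.to_json(out / "ground_truth.json")
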