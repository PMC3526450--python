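"""Study-cohort construction and intermediate-endpoint classification.

Index stroke admissions are selected on ICD-10 principal diagnosis I60–I64
with a B70 AR-DRG (craniotomy B02, extracranial vascular B04 and
tracheostomy/ventilation A06 DRGs excluded), dropping patients who die within
a few days of admission and patients with a documented stroke in a lookback
window before the index.  Each remaining patient is then assigned to exactly
one of four mutually exclusive intermediate endpoints — non-fatal recurrent
stroke, non-fatal major cardiac event, death (without, or within 28 days of,
a non-fatal event), or no subsequent event — based on the first qualifying
admission after the index separation.

The major-cardiac-event admission set is derived from the data: circulatory
(MDC 5) DRG codes whose empirical 1-year mortality among the stroke cohort's
readmissions meets a threshold (40% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemas import COMORBIDITY_FLAGS, SchemaError, validate_deaths, validate_separations

__all__ = [
    "CohortConfig",
    "DataIntegrityError",
    "merge_transfer_episodes",
    "select_index_strokes",
    "derive_cardiac_drg_set",
    "classify_endpoints",
    "endpoint_survival_data",
]

DAYS_PER_YEAR = 365.25

STROKE_ICD_PREFIXES = ("I60", "I61", "I62", "I63", "I64")
EXCLUDED_DRG_PREFIXES = ("B02", "B04", "A06")

ENDPOINT_TYPES = ["no_event", "recurrent_stroke", "cardiac_event", "death"]


class DataIntegrityError(ValueError):
    """Input rows that are mutually inconsistent (e.g. admission after death)."""


@dataclass(frozen=True)
class CohortConfig:
    """Windows and rules for cohort construction (defaults follow the study design)."""

    cohort_start: str = "2005-07-01"
    cohort_end: str = "2006-06-30"
    extrapolation_start: str = "2002-07-01"
    followup_end: str = "2008-06-30"
    lookback_days: int = 365
    early_death_exclusion_days: int = 5
    nonfatal_window_days: int = 28
    #: events/deaths within this window after the index separation define the
    #: intermediate endpoint ("death within 2 years"); later deaths are events
    #: in the no-event extrapolation dataset
    endpoint_window_days: int = 730
    cardiac_mortality_threshold: float = 0.40
    circulatory_drg_prefix: str = "F"
    #: same-day stroke and cardiac admissions: which event wins
    same_day_priority: str = "recurrent_stroke"
    #: a separation continuing the previous one within this many days, with
    #: transfer_flag set, is merged into the same episode
    transfer_gap_days: int = 1

    def validate(self) -> None:
        if self.lookback_days <= 0:
            raise ValueError("lookback_days must be > 0")
        if self.early_death_exclusion_days <= 0:
            raise ValueError("early_death_exclusion_days must be > 0")
        if self.nonfatal_window_days <= 0:
            raise ValueError("nonfatal_window_days must be > 0")
        if not 0.0 <= self.cardiac_mortality_threshold <= 1.0:
            # 0 is the degenerate "every observed DRG qualifies" threshold
            raise ValueError("cardiac_mortality_threshold must lie in [0, 1]")


def _is_stroke_icd(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.startswith(STROKE_ICD_PREFIXES)


def merge_transfer_episodes(separations: pd.DataFrame, gap_days: int = 1) -> pd.DataFrame:
    """Collapse transfer chains into single episodes.

    A separation whose ``admit_date`` is within ``gap_days`` of the previous
    separation's ``sep_date`` for the same patient, with ``transfer_flag``
    set, continues the same episode.  The merged episode keeps the first
    row's codes and hospital (care is attributed to the admitting hospital)
    and extends ``sep_date``; member separation ids are retained so costs can
    be aggregated.
    """
    if separations.empty:
        out = separations.copy()
        out["member_separations"] = [[] for _ in range(len(out))]
        return out
    df = separations.sort_values(["patient_id", "admit_date", "sep_date"]).reset_index(drop=True)
    prev_pid = df["patient_id"].shift()
    prev_sep = df["sep_date"].shift()
    cont = (
        (df["patient_id"] == prev_pid)
        & (df["transfer_flag"].astype(bool))
        & (df["admit_date"] <= prev_sep + pd.Timedelta(days=gap_days))
    )
    episode = (~cont).cumsum()
    first = df.groupby(episode, sort=True).first()
    last_sep = df.groupby(episode, sort=True)["sep_date"].max()
    members = df.groupby(episode, sort=True)["separation_id"].agg(list)
    out = first.copy()
    out["sep_date"] = last_sep
    out["member_separations"] = members
    return out.reset_index(drop=True)


def select_index_strokes(
    separations: pd.DataFrame, deaths: pd.DataFrame, config: CohortConfig,
    window: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """One row per eligible patient: the first index stroke episode in the window.

    ``window`` defaults to the extrapolation window (extrapolation_start to
    cohort_end); pass ``(cohort_start, cohort_end)`` to restrict to the main
    study year.
    """
    config.validate()
    separations = validate_separations(separations)
    deaths = validate_deaths(deaths)
    start, end = window or (config.extrapolation_start, config.cohort_end)
    start, end = pd.Timestamp(start), pd.Timestamp(end)

    episodes = merge_transfer_episodes(separations, config.transfer_gap_days)
    if episodes.empty:
        return episodes.iloc[0:0]

    stroke_any = episodes[_is_stroke_icd(episodes["icd_principal"])]
    eligible = stroke_any[
        stroke_any["drg"].astype(str).str.startswith("B70")
        & ~stroke_any["drg"].astype(str).str.startswith(EXCLUDED_DRG_PREFIXES)
    ]
    in_window = eligible[(eligible["admit_date"] >= start) & (eligible["admit_date"] <= end)]
    idx = in_window.sort_values(["patient_id", "admit_date"]).groupby("patient_id").first()
    idx = idx.reset_index()

    death_map = deaths.set_index("patient_id")["death_date"]
    dd = idx["patient_id"].map(death_map)
    early = (dd - idx["admit_date"]).dt.days <= config.early_death_exclusion_days
    idx = idx[~early.fillna(False)]

    # lookback: any documented stroke separation strictly before the index
    prior = stroke_any.merge(
        idx[["patient_id", "admit_date"]].rename(columns={"admit_date": "index_admit"}),
        on="patient_id",
    )
    bad = prior[
        (prior["admit_date"] < prior["index_admit"])
        & (prior["admit_date"] >= prior["index_admit"] - pd.Timedelta(days=config.lookback_days))
    ]["patient_id"].unique()
    idx = idx[~idx["patient_id"].isin(bad)].reset_index(drop=True)

    idx = idx.rename(columns={"admit_date": "index_admit", "sep_date": "index_sep"})
    cols = (
        ["patient_id", "hospital", "index_admit", "index_sep", "icd_principal", "drg",
         "age", "sex", "ses", "member_separations"] + COMORBIDITY_FLAGS
    )
    return idx[cols]


def derive_cardiac_drg_set(
    separations: pd.DataFrame,
    deaths: pd.DataFrame,
    index_events: pd.DataFrame,
    config: CohortConfig,
) -> set[str]:
    """Circulatory DRGs whose 1-year mortality after readmission meets the threshold.

    Considers readmissions of the index cohort (admit after the index
    separation) whose DRG starts with the configured circulatory prefix and is
    not a stroke DRG; mortality is measured within 365.25 days of the
    readmission date.  Deterministic given its inputs.
    """
    config.validate()
    separations = validate_separations(separations)
    deaths = validate_deaths(deaths)
    if separations.empty or index_events.empty:
        warnings.warn("no qualifying readmissions; cardiac DRG set is empty",
                      RuntimeWarning, stacklevel=2)
        return set()
    readm = separations.merge(
        index_events[["patient_id", "index_sep"]], on="patient_id", how="inner"
    )
    readm = readm[readm["admit_date"] > readm["index_sep"]]
    readm = readm[
        readm["drg"].astype(str).str.startswith(config.circulatory_drg_prefix)
        & ~readm["drg"].astype(str).str.startswith("B70")
    ]
    if readm.empty:
        warnings.warn("no qualifying readmissions; cardiac DRG set is empty",
                      RuntimeWarning, stacklevel=2)
        return set()
    death_map = deaths.set_index("patient_id")["death_date"]
    dd = readm["patient_id"].map(death_map)
    died_1y = ((dd - readm["admit_date"]).dt.days <= DAYS_PER_YEAR).fillna(False)
    rate = died_1y.groupby(readm["drg"]).mean()
    return set(rate[rate >= config.cardiac_mortality_threshold].index.astype(str))


def classify_endpoints(
    index_events: pd.DataFrame,
    separations: pd.DataFrame,
    deaths: pd.DataFrame,
    cardiac_drg_set: set[str],
    config: CohortConfig,
) -> pd.DataFrame:
    """Assign each index patient to exactly one intermediate endpoint.

    The first qualifying admission after the index separation wins: a
    stroke-principal-diagnosis admission (recurrent stroke) or an admission
    with a DRG in ``cardiac_drg_set`` (major cardiac event).  An event is
    non-fatal only if the patient survives more than the non-fatal window
    (28 days by default) from the event admission date; otherwise — or if
    death occurs with no prior event by follow-up end — the endpoint is
    death.  Patients with neither are censored (``no_event``) with endpoint
    date equal to the index separation date.
    """
    config.validate()
    if index_events.empty:
        raise ValueError("index_events is empty")
    separations = validate_separations(separations)
    deaths = validate_deaths(deaths)
    followup_end = pd.Timestamp(config.followup_end)
    nonfatal = pd.Timedelta(days=config.nonfatal_window_days)

    episodes = merge_transfer_episodes(separations, config.transfer_gap_days)
    death_map = deaths.set_index("patient_id")["death_date"]

    cand = episodes.merge(
        index_events[["patient_id", "index_admit", "index_sep"]], on="patient_id", how="inner"
    )
    dd_cand = cand["patient_id"].map(death_map)
    if ((cand["admit_date"] - dd_cand).dt.days > 0).fillna(False).any():
        raise DataIntegrityError("admission recorded after the patient's death date")

    window_end = cand["index_sep"] + pd.Timedelta(days=config.endpoint_window_days)
    cand = cand[
        (cand["admit_date"] > cand["index_sep"])
        & (cand["admit_date"] <= followup_end)
        & (cand["admit_date"] <= window_end)
    ]
    is_stroke = _is_stroke_icd(cand["icd_principal"])
    is_cardiac = cand["drg"].astype(str).isin(set(map(str, cardiac_drg_set)))
    cand = cand[is_stroke | is_cardiac].copy()
    cand["event_kind"] = np.where(
        _is_stroke_icd(cand["icd_principal"]), "recurrent_stroke", "cardiac_event"
    )
    # first event; same-day ties resolved by configured priority
    pri = {config.same_day_priority: 0}
    cand["_pri"] = cand["event_kind"].map(pri).fillna(1)
    first = (
        cand.sort_values(["patient_id", "admit_date", "_pri"])
        .groupby("patient_id")
        .first()
    )

    rows = []
    for _, p in index_events.iterrows():
        pid = p["patient_id"]
        death_date = death_map.get(pid, pd.NaT)
        ev = first.loc[pid] if pid in first.index else None
        endpoint, endpoint_date, event_date = "no_event", p["index_sep"], pd.NaT
        if ev is not None:
            event_date = ev["admit_date"]
            fatal = (
                pd.notna(death_date)
                and death_date <= event_date + nonfatal
                and death_date <= followup_end
            )
            if fatal:
                endpoint, endpoint_date = "death", death_date
            else:
                endpoint, endpoint_date = ev["event_kind"], event_date
        elif pd.notna(death_date) and death_date <= min(
            followup_end, p["index_sep"] + pd.Timedelta(days=config.endpoint_window_days)
        ):
            endpoint, endpoint_date = "death", death_date
        if endpoint_date < p["index_admit"]:
            raise DataIntegrityError(f"endpoint before index admission for {pid}")
        age_at = p["age"] + (endpoint_date - p["index_admit"]).days / DAYS_PER_YEAR
        row = {
            "patient_id": pid,
            "hospital": p["hospital"],
            "endpoint_type": endpoint,
            "index_date": p["index_admit"],
            "index_sep": p["index_sep"],
            "endpoint_date": endpoint_date,
            "event_date": event_date,
            "age_at_endpoint": age_at,
            "age": p["age"],
            "sex": p["sex"],
            "ses": p["ses"],
            "drg": p["drg"],
            "death_date": death_date if pd.notna(death_date) else pd.NaT,
            "censor_date": followup_end,
        }
        for f in COMORBIDITY_FLAGS:
            row[f] = p[f]
        rows.append(row)
    out = pd.DataFrame(rows)
    for c in ("index_date", "index_sep", "endpoint_date", "event_date",
              "death_date", "censor_date"):
        out[c] = pd.to_datetime(out[c])
    assert set(out["endpoint_type"]).issubset(ENDPOINT_TYPES)
    return out


def endpoint_survival_data(endpoints: pd.DataFrame, endpoint_type: str) -> pd.DataFrame:
    """Time/event pairs (years from endpoint) for one non-death endpoint cohort.

    Time runs from the endpoint date to death or the censor date; rows whose
    follow-up would be non-positive are dropped with a warning.
    """
    if endpoint_type == "death":
        raise ValueError("the death endpoint has no extrapolation dataset")
    sub = endpoints[endpoints["endpoint_type"] == endpoint_type].copy()
    end = sub["death_date"].fillna(sub["censor_date"])
    end = end.where(end <= sub["censor_date"], sub["censor_date"])
    sub["time"] = (end - sub["endpoint_date"]).dt.days / DAYS_PER_YEAR
    sub["event"] = (
        sub["death_date"].notna() & (sub["death_date"] <= sub["censor_date"])
    ).astype(int)
    n_bad = int((sub["time"] <= 0).sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} rows with non-positive follow-up",
                      RuntimeWarning, stacklevel=2)
        sub = sub[sub["time"] > 0]
    return sub.reset_index(drop=True)
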