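"""Shared fixtures: simulated linked data and a fitted base-case analysis."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from race_e.cohort import CohortConfig, classify_endpoints, derive_cardiac_drg_set, \
    select_index_strokes
from race_e.pipeline import PipelineConfig, run_race_analysis
from race_e.schemas import COMORBIDITY_FLAGS, validate_deaths, validate_separations
from race_e.simulate import SimulationConfig, generate_linked_data

FAST_COVARIATES = ("age_c", "sex_male", "sev_B70A", "sev_B70B", "ses")


def fast_pipeline_config(**overrides) -> PipelineConfig:
    """Single-window, frozen-specification pipeline config for simulation tests."""
    kw = dict(
        cohort_start="2002-07-01",
        cohort_end="2006-06-30",
        select_models=False,
        fixed_knots=1,
        covariates=FAST_COVARIATES,
    )
    kw.update(overrides)
    return PipelineConfig(**kw)


@pytest.fixture(scope="session")
def sim_tables():
    """A 1,200-patient linked dataset with the default four hospitals."""
    cfg = SimulationConfig(n_patients=1200, seed=11)
    return cfg, generate_linked_data(cfg)


@pytest.fixture(scope="session")
def cohort_objs(sim_tables):
    _, (sep, costs, deaths, gt) = sim_tables
    cc = CohortConfig(cohort_start="2002-07-01")
    sepv = validate_separations(sep)
    deathsv = validate_deaths(deaths)
    idx = select_index_strokes(sepv, deathsv, cc)
    cardiac = derive_cardiac_drg_set(sepv, deathsv, idx, cc)
    ep = classify_endpoints(idx, sepv, deathsv, cardiac, cc)
    return {"config": cc, "index": idx, "cardiac": cardiac, "endpoints": ep,
            "separations": sepv, "deaths": deathsv, "costs": costs, "gt": gt}


@pytest.fixture(scope="session")
def base_analysis(sim_tables):
    """Full fast-mode RAC-E analysis of the session dataset."""
    _, (sep, costs, deaths, _) = sim_tables
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_race_analysis(sep, costs, deaths, fast_pipeline_config())


def make_separation(pid, admit, sep=None, icd="I63", drg="B70B", hospital="A",
                    transfer=0, age=75.0, sex="M", ses=0.0, sid=None):
    """One schema-complete separation row for toy-table tests."""
    admit = pd.Timestamp(admit)
    sep = pd.Timestamp(sep) if sep is not None else admit + pd.Timedelta(days=7)
    row = {
        "separation_id": sid or f"{pid}-{admit.date()}",
        "patient_id": pid,
        "hospital": hospital,
        "admit_date": admit,
        "sep_date": sep,
        "icd_principal": icd,
        "drg": drg,
        "age": age,
        "sex": sex,
        "ses": ses,
        "transfer_flag": transfer,
    }
    for f in COMORBIDITY_FLAGS:
        row[f] = 0
    return row


def make_deaths(pairs):
    return pd.DataFrame(
        [{"patient_id": p, "death_date": pd.Timestamp(d)} for p, d in pairs],
        columns=["patient_id", "death_date"],
    )
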