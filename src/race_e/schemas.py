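"""Column contracts for the linked CSV inputs and helpers to validate them.

Three tables arrive pre-linked on ``patient_id``:

* ``separations`` — one row per completed hospital admission episode.
* ``costs`` — separation-level costs in 16 categories, keyed by
  ``separation_id``.
* ``deaths`` — all-cause death dates.

Dates are ISO-8601 strings on disk and ``datetime64[ns]`` in memory.
"""

from __future__ import annotations

import pandas as pd

COMORBIDITY_FLAGS = [
    "copd",
    "anaemia",
    "diabetes",
    "lrti_influenza",
    "uti",
    "urinary_symptoms",
    "minor_vascular",
]

#: the 16 separation-level cost categories (direct/indirect ward, surgery,
#: allied health, diagnostics, pharmacy, prostheses and related overheads)
COST_CATEGORIES = [
    "medical_ward",
    "nursing_ward",
    "allied_health",
    "imaging",
    "pathology",
    "pharmacy",
    "icu",
    "operating_room",
    "emergency_dept",
    "prostheses",
    "supplies",
    "hotel_services",
    "depreciation",
    "overheads",
    "specialist_services",
    "other",
]

SEPARATION_COLUMNS = (
    ["separation_id", "patient_id", "hospital", "admit_date", "sep_date",
     "icd_principal", "drg", "age", "sex", "ses", "transfer_flag"]
    + COMORBIDITY_FLAGS
)
COST_COLUMNS = ["separation_id"] + [f"cost_{c}" for c in COST_CATEGORIES]
DEATH_COLUMNS = ["patient_id", "death_date"]

DATE_COLUMNS = {"admit_date", "sep_date", "death_date"}


class SchemaError(ValueError):
    """An input table is missing a required column or fails a basic check."""


def _require(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing required column(s): {missing}")


def _coerce_dates(df: pd.DataFrame) -> pd.DataFrame:
    for c in df.columns:
        if c in DATE_COLUMNS and not pd.api.types.is_datetime64_any_dtype(df[c]):
            df = df.assign(**{c: pd.to_datetime(df[c])})
    return df


def validate_separations(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, SEPARATION_COLUMNS, "separations")
    df = _coerce_dates(df)
    if len(df):
        if (df["sep_date"] < df["admit_date"]).any():
            raise SchemaError("separations: sep_date earlier than admit_date")
        if df["icd_principal"].astype(str).str.len().eq(0).any():
            raise SchemaError("separations: empty icd_principal")
    return df


def validate_costs(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, COST_COLUMNS, "costs")
    if len(df):
        vals = df[[f"cost_{c}" for c in COST_CATEGORIES]]
        if (vals.to_numpy() < 0).any():
            raise SchemaError("costs: negative cost amount")
    return df


def validate_deaths(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, DEATH_COLUMNS, "deaths")
    return _coerce_dates(df)


def total_cost(costs: pd.DataFrame) -> pd.Series:
    """Sum of the 16 categories per separation, indexed by separation_id."""
    cols = [f"cost_{c}" for c in COST_CATEGORIES]
    return costs.set_index("separation_id")[cols].sum(axis=1)
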