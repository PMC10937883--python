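"""Deterministic missing-data rules for covariates.

Area Deprivation Index (ADI): a missing value at any interval is replaced by
the patient's mean over their non-missing intervals; a patient missing ADI at
every interval is excluded from the cohort. Race/ethnicity: missing values are
pooled with the small groups into an "Unknown/Other" level. Rurality: missing
values become a per-interval "unknown" level. No stochastic imputation is used.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["impute_adi", "categorize_unknowns", "UNKNOWN_OTHER", "POOLED_RACE_GROUPS"]

UNKNOWN_OTHER = "Unknown/Other"
#: Small race/ethnicity groups pooled with missing into Unknown/Other.
POOLED_RACE_GROUPS = (
    "American Indian or Alaska Native",
    "Native Hawaiian or Other Pacific Islander",
    "Asian",
)


def impute_adi(panel: pd.DataFrame, adi_col: str = "adi") -> tuple[pd.DataFrame, list]:
    """Fill missing ADI with each patient's all-interval mean.

    Returns the imputed panel and the list of patient ids with no observed ADI
    at any interval (to be excluded). One pass over all intervals is applied
    (current/baseline/lagged uses all draw from the same imputed series).
    Idempotent on fully-observed input.
    """
    panel = panel.copy()
    means = panel.groupby("patient_id")[adi_col].transform("mean")
    panel[adi_col] = panel[adi_col].fillna(means)
    all_missing = panel.groupby("patient_id")[adi_col].apply(lambda s: s.isna().all())
    excluded = list(all_missing[all_missing].index)
    panel = panel[~panel["patient_id"].isin(excluded)]
    return panel, excluded


def categorize_unknowns(
    panel: pd.DataFrame | None = None,
    patients: pd.DataFrame | None = None,
    rurality_col: str = "rurality",
    race_col: str = "race_ethnicity",
) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Give missing categorical covariates explicit levels.

    Patient-level race/ethnicity: missing and the small pooled groups all map
    to "Unknown/Other". Interval-level rurality: missing maps to "unknown" for
    that interval only. Either argument may be omitted.
    """
    if patients is not None:
        patients = patients.copy()
        race = patients[race_col].astype("object")
        race = race.where(~race.isin(POOLED_RACE_GROUPS), UNKNOWN_OTHER)
        race = race.where(~race.isna() & (race != ""), UNKNOWN_OTHER)
        patients[race_col] = race
    if panel is not None:
        panel = panel.copy()
        rur = panel[rurality_col].astype("object")
        rur = rur.where(~rur.isna() & (rur != ""), "unknown")
        panel[rurality_col] = rur
    return panel, patients


def assert_no_missing(df: pd.DataFrame, cols: list[str]) -> None:
    """Sweep guard run before model fitting: no unhandled missing covariates."""
    bad = [c for c in cols if df[c].isna().any()]
    if bad:
        raise ValueError(f"missing values remain in model covariates: {bad}")
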