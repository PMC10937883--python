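"""Readers for the delimited external-interface tables.

All dates are ISO-8601; an empty string means missing. ``labs.csv`` encodes
an uninterpretable result as an empty ``value``.
"""

from __future__ import annotations

import pathlib

import pandas as pd

from .outcomes import Roster

__all__ = ["read_patients", "read_fills", "read_labs", "read_portal_events", "read_zip_panel", "read_tables"]


def _dates(series: pd.Series) -> pd.Series:
    out = pd.to_datetime(series, format="ISO8601", errors="coerce").dt.date
    return out.where(~pd.isna(out), None)


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False, na_values=[""])
    for col in ("registration_date", "ipa_date", "death_date", "diagnosis_date"):
        df[col] = _dates(df[col])
    return df


def read_fills(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["fill_date"] = _dates(df["fill_date"])
    df["days_supply"] = df["days_supply"].astype(int)
    return df


def read_labs(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["test_date"] = _dates(df["test_date"])
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def read_portal_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["event_date"] = _dates(df["event_date"])
    return df


def read_zip_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False, na_values=[""])
    df["adi"] = pd.to_numeric(df["adi"], errors="coerce")
    return df


def read_tables(directory) -> dict:
    """Read the full table set written by ``SyntheticCohort.write_csv``."""
    d = pathlib.Path(directory)
    tables = {
        "patients": read_patients(d / "patients.csv"),
        "fills": read_fills(d / "fills.csv"),
        "labs": read_labs(d / "labs.csv"),
        "portal_events": read_portal_events(d / "portal_events.csv"),
        "zip_panel": read_zip_panel(d / "zip_panel.csv"),
    }
    cov = d / "covariate_panel.csv"
    if cov.exists():
        tables["covariate_panel"] = pd.read_csv(cov, dtype={"patient_id": str})
    roster = d / "roster.yaml"
    if roster.exists():
        tables["roster"] = Roster.from_yaml(roster)
    return tables
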