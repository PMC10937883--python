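"""Cohort entry, eligibility screening, and person-period panel assembly.

Two overlapping cohorts are built from the portal registry: the *refill
access* cohort (entry anchored at portal registration, which unlocks the
prescription-refill tool) and the *full access* cohort (entry anchored at
in-person authentication, IPA, which unlocks the remaining tools). A patient
who registers first and authenticates later belongs to the refill cohort from
registration and to both cohorts from IPA onward.

Eligibility is screened sequentially, in the CONSORT order, and every step's
exclusion count is recorded in a ledger so that `retained + excluded == input`
for any input. Person-period rows enter the analysis only when three temporal
conditions hold: baseline measurements exist in the 6 months before entry, a
full prior interval exists to supply the lagged exposure, and the outcome
interval t+1 is fully observed (no death or study end inside it).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import Interval, interval_index_of
from .outcomes import (
    DEFAULT_SUPPRESSION_THRESHOLD,
    Roster,
    pdc_baseline,
)

__all__ = [
    "CohortSpec",
    "cohort_entry_date",
    "apply_eligibility",
    "assemble_person_periods",
    "mark_unsuppressed_subgroup",
    "write_exclusion_ledger",
]

#: Length of the pre-entry baseline window in days (~6 months).
BASELINE_WINDOW_DAYS = 183

BASELINE_COLS = [
    "sex",
    "race_ethnicity",
    "age_at_entry",
    "years_since_diagnosis",
    "nonva_care",
    "site",
    "entry_interval",
    "baseline_pdc",
]


@dataclass(frozen=True)
class CohortSpec:
    """Which cohort to build and which outcome family it serves.

    The entry window is inclusive at both ends (a patient anchored exactly on
    either boundary date enters).
    """

    cohort_type: str  # refill_access | full_access
    entry_window_start: dt.date
    entry_window_end: dt.date
    outcome_set: str = "adherence"  # adherence | viral_load
    unsuppressed_subgroup: bool = False
    suppression_threshold: float = DEFAULT_SUPPRESSION_THRESHOLD

    def __post_init__(self):
        if self.cohort_type not in ("refill_access", "full_access"):
            raise ValueError(f"unknown cohort_type {self.cohort_type!r}")
        if self.outcome_set not in ("adherence", "viral_load"):
            raise ValueError(f"unknown outcome_set {self.outcome_set!r}")


def cohort_entry_date(patient: pd.Series, spec: CohortSpec) -> dt.date | None:
    """Entry date for one patient row, or None if they never enter this cohort.

    Refill access anchors at the registration date; full access anchors at the
    IPA date (absent IPA means no full-access entry).
    """
    anchor = patient["registration_date"] if spec.cohort_type == "refill_access" else patient.get("ipa_date")
    if anchor is None or pd.isna(anchor):
        return None
    if spec.entry_window_start <= anchor <= spec.entry_window_end:
        return anchor
    return None


def _has_value(x) -> bool:
    return not (x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x) or x == "")


def apply_eligibility(
    patients: pd.DataFrame,
    spec: CohortSpec,
    intervals: list[Interval],
    fills: pd.DataFrame,
    labs: pd.DataFrame,
    zip_panel: pd.DataFrame,
    roster: Roster,
) -> tuple[pd.DataFrame, dict]:
    """Screen patients sequentially; return the eligible table and the ledger.

    Steps, in CONSORT order: entered the cohort within the window; computable
    baseline adherence (>=1 ART fill before entry — the requirement is a
    *measurable* baseline PDC, not a high one); non-missing baseline site;
    >=1 ZIP-level record during the cohort; and, for viral-load outcome sets,
    a numeric baseline viral-load test in the 6 months before entry.

    The returned table adds ``entry_date``, derived baseline covariates and,
    when labs allow, ``baseline_vl_value``/``baseline_suppressed``.
    """
    n_input = len(patients)
    ledger: dict = {"input_patients": n_input, "steps": [], "cohort_type": spec.cohort_type}
    entry_step = "registered" if spec.cohort_type == "refill_access" else "ipa"

    df = patients.copy()
    anchor_col = "registration_date" if spec.cohort_type == "refill_access" else "ipa_date"
    anchor = pd.to_datetime(df[anchor_col])
    in_window = (
        anchor.notna()
        & (anchor >= pd.Timestamp(spec.entry_window_start))
        & (anchor <= pd.Timestamp(spec.entry_window_end))
    )
    df["entry_date"] = df[anchor_col].where(in_window, None)
    df = df[in_window.to_numpy()]
    ledger["steps"].append(
        {"name": entry_step, "retained": len(df), "excluded": n_input - len(df)}
    )

    # baseline adherence computable: any ART-class fill strictly before entry
    art_fills = fills[fills["drug_class"].isin(roster.art_classes)]
    first_fill = art_fills.groupby("patient_id")["fill_date"].min()
    before = len(df)
    has_hist = np.array(
        [
            (pid in first_fill.index) and (first_fill[pid] < e)
            for pid, e in zip(df["patient_id"], df["entry_date"])
        ],
        dtype=bool,
    )
    df = df[has_hist] if len(df) else df
    ledger["steps"].append(
        {"name": "required_baseline_pdc", "retained": len(df), "excluded": before - len(df)}
    )

    before = len(df)
    has_site = np.array([_has_value(s) for s in df["site"]], dtype=bool)
    df = df[has_site] if len(df) else df
    ledger["steps"].append(
        {"name": "required_baseline_visn", "retained": len(df), "excluded": before - len(df)}
    )

    before = len(df)
    zp = zip_panel[zip_panel["patient_id"].isin(df["patient_id"])]
    any_record = np.array(
        [_has_value(r) or _has_value(a) for r, a in zip(zp["rurality"], zp["adi"])], dtype=bool
    )
    with_zip = set(zp[any_record]["patient_id"]) if len(zp) else set()
    df = df[df["patient_id"].isin(with_zip)]
    ledger["steps"].append({"name": "zip_code", "retained": len(df), "excluded": before - len(df)})

    # baseline covariate derivations
    df = df.copy()
    if len(df):
        base = pdc_baseline(
            fills, df[["patient_id", "entry_date"]], roster, window_days=BASELINE_WINDOW_DAYS
        )
        df["baseline_pdc"] = base.loc[df["patient_id"]].to_numpy()
    else:
        df["baseline_pdc"] = np.nan
    df["age_at_entry"] = [e.year - by for e, by in zip(df["entry_date"], df["birth_year"])]
    df["years_since_diagnosis"] = [
        (e - d).days / 365.25 if _has_value(d) else np.nan
        for e, d in zip(df["entry_date"], df["diagnosis_date"])
    ]
    df["entry_interval"] = [
        intervals[i].label if (i := interval_index_of(e, intervals)) is not None else "pre_study"
        for e in df["entry_date"]
    ]

    baseline = _baseline_vl(df, labs, spec.suppression_threshold)
    df = df.merge(baseline, on="patient_id", how="left")
    if spec.outcome_set == "viral_load":
        before = len(df)
        df = df[~df["baseline_vl_value"].isna()]
        ledger["steps"].append(
            {"name": "baseline_viral_load", "retained": len(df), "excluded": before - len(df)}
        )

    ledger["retained_patients"] = len(df)
    assert ledger["retained_patients"] + sum(s["excluded"] for s in ledger["steps"]) == n_input
    return df.reset_index(drop=True), ledger


def _baseline_vl(df: pd.DataFrame, labs: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Most recent numeric viral-load value in the 6 months before entry."""
    out = df[["patient_id"]].copy()
    numeric = labs[~labs["value"].isna()]
    m = numeric.merge(df[["patient_id", "entry_date"]], on="patient_id")
    if len(m):
        td = pd.to_datetime(m["test_date"])
        ed = pd.to_datetime(m["entry_date"])
        lo = ed - pd.Timedelta(days=BASELINE_WINDOW_DAYS)
        m = m[(td >= lo) & (td < ed)]
        m = m.sort_values(["patient_id", "test_date"], kind="stable")
        last = m.groupby("patient_id").tail(1).set_index("patient_id")["value"]
    else:
        last = pd.Series(dtype=float)
    out["baseline_vl_value"] = out["patient_id"].map(last).astype(float)
    out["baseline_suppressed"] = (out["baseline_vl_value"] <= threshold).astype(float).where(
        ~out["baseline_vl_value"].isna()
    )
    return out


def first_full_interval(entry: dt.date, intervals: list[Interval]) -> int | None:
    """Index of the first interval fully inside follow-up (entry on a boundary
    counts that interval as full)."""
    for iv in intervals:
        if iv.start >= entry:
            return iv.index
    return None


def last_full_interval(death: dt.date | None, intervals: list[Interval]) -> int:
    """Index of the last fully observed interval (person-time stops at death)."""
    last = -1
    for iv in intervals:
        if death is not None and not pd.isna(death) and death < iv.end:
            break
        last = iv.index
    return last


def assemble_person_periods(
    eligible: pd.DataFrame,
    intervals: list[Interval],
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> pd.DataFrame:
    """Emit model-eligible person-period rows.

    Component tables are keyed by (patient_id, interval_index); duplicates are
    rejected. A row at interval t is emitted only when t-1 is a full follow-up
    interval (so the lagged exposure exists) and t+1 is fully observed (so the
    next-interval outcome exists) — i.e. t runs from ``first_full + 1`` through
    ``last_full - 1``.
    """
    key = ["patient_id", "interval_index"]
    for name, tab in (("exposures", exposures), ("covariates", covariates), ("outcomes", outcomes)):
        if tab.duplicated(key).any():
            raise ValueError(f"duplicate (patient_id, interval_index) keys in {name} table")

    iv_starts = np.array([np.datetime64(iv.start) for iv in intervals])
    iv_ends = np.array([np.datetime64(iv.end) for iv in intervals])
    entry = pd.to_datetime(eligible["entry_date"]).to_numpy(dtype="M8[D]")
    ff = np.searchsorted(iv_starts, entry, side="left")
    if "death_date" in eligible.columns:
        death = pd.to_datetime(eligible["death_date"]).to_numpy(dtype="M8[D]")
        lf = np.where(
            np.isnat(death),
            len(intervals) - 1,
            np.searchsorted(iv_ends, death, side="right") - 1,
        )
    else:
        lf = np.full(len(eligible), len(intervals) - 1)
    pid_arr = eligible["patient_id"].to_numpy()
    rows = [
        (pid, t)
        for pid, a, b in zip(pid_arr, ff, lf)
        for t in range(int(a) + 1, int(b))
    ]
    if not rows:
        return pd.DataFrame(columns=key)
    pp = pd.DataFrame(rows, columns=key)
    base_cols = [c for c in BASELINE_COLS if c in eligible.columns]
    pp = pp.merge(eligible[["patient_id", "entry_date"] + base_cols], on="patient_id")
    pp = pp.merge(exposures, on=key, how="left")
    pp = pp.merge(covariates, on=key, how="left")
    pp = pp.merge(outcomes, on=key, how="left")
    return pp


def mark_unsuppressed_subgroup(
    panel: pd.DataFrame,
    eligible: pd.DataFrame,
    threshold: float = DEFAULT_SUPPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Restrict a viral-load panel to patients unsuppressed at baseline.

    A baseline value exactly at the threshold counts as suppressed (status is
    ``value <= threshold``), so such patients are *not* in the subgroup.
    """
    unsup = eligible[eligible["baseline_suppressed"] == 0.0]["patient_id"]
    return panel[panel["patient_id"].isin(set(unsup))].reset_index(drop=True)


def write_exclusion_ledger(ledger: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=2, default=str)
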