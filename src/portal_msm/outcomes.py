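"""Outcome derivation from raw pharmacy-fill and viral-load tables.

Three outcomes are derived per patient x interval:

* **PDC adherence** — proportion of days covered, where a day counts as covered
  only if supply from at least two distinct antiretroviral (ART) drug classes is
  simultaneously on hand. Same-class refills during active supply are
  *stockpiled*: the new supply begins when the current supply runs out (the
  Pharmacy Quality Alliance convention). Supplies of different classes are
  independent.
* **Viral-load test receipt** — 1 if any test in the interval returned an
  interpretable numeric value.
* **Viral-load suppression** — the most recent numeric test in the interval,
  dichotomised at a copies/mL threshold (value <= threshold counts as
  suppressed); test-free intervals inherit the last observed status
  (last-observation-carried-forward); intervals before the first test are missing.

Outcome timing: models relate tool use in interval *t* to outcomes in interval
*t+1*; :func:`shift_outcomes_next` performs that re-keying.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .intervals import Interval

__all__ = [
    "Roster",
    "AdherenceResult",
    "class_coverage_days",
    "compute_pdc",
    "pdc_for_window",
    "pdc_panel",
    "vl_test_receipt",
    "vl_suppression_series",
    "receipt_panel",
    "suppression_panel",
    "shift_outcomes_next",
    "DEFAULT_SUPPRESSION_THRESHOLD",
]

#: Default viral-suppression cutoff in copies/mL; a value at the threshold
#: counts as suppressed. Configurable everywhere it is used.
DEFAULT_SUPPRESSION_THRESHOLD = 200.0


@dataclass(frozen=True)
class Roster:
    """Drug -> class mapping plus the set of classes that count as ART."""

    drug_class: dict[str, str]
    art_classes: frozenset[str] = field(default_factory=frozenset)

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(self.drug_class.values()) | self.art_classes

    @classmethod
    def from_yaml(cls, path) -> "Roster":
        """Load a roster file: ``classes: {code: {art: bool}}``, ``drugs: {name: code}``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        art = frozenset(c for c, meta in raw.get("classes", {}).items() if meta.get("art"))
        return cls(drug_class=dict(raw.get("drugs", {})), art_classes=art)

    def validate_classes(self, codes) -> None:
        unknown = set(codes) - set(self.classes)
        if unknown:
            raise ValueError(
                f"unknown drug class code(s) {sorted(unknown)}; "
                f"roster defines {sorted(self.classes)}"
            )


@dataclass(frozen=True)
class AdherenceResult:
    patient_id: object
    interval_index: int
    pdc: float
    covered_days: int
    interval_days: int


def _stockpiled_spans(fills: pd.DataFrame) -> list[tuple[dt.date, dt.date]]:
    """Coverage spans [start, end) for one patient's fills of ONE class.

    A refill during active supply starts when the current supply ends.
    """
    spans: list[tuple[dt.date, dt.date]] = []
    cur_end: dt.date | None = None
    order = np.argsort(fills["fill_date"].to_numpy(), kind="stable")
    for i in order:
        row = fills.iloc[int(i)]
        start = row["fill_date"]
        if cur_end is not None and cur_end > start:
            start = cur_end
        end = start + dt.timedelta(days=int(row["days_supply"]))
        spans.append((start, end))
        cur_end = end
    return spans


def class_coverage_days(
    fills: pd.DataFrame, interval: Interval, drug_class: str, roster: Roster
) -> set[dt.date]:
    """Days of `interval` covered by supply of `drug_class`, with stockpiling.

    `fills` holds one patient's fills (columns ``drug_class``, ``fill_date``,
    ``days_supply``); fills of other classes are ignored. Days contributed by a
    fill straddling the interval boundary are clipped to the interval.
    """
    roster.validate_classes([drug_class])
    if len(fills):
        roster.validate_classes(fills["drug_class"].unique())
    sub = fills[fills["drug_class"] == drug_class]
    covered: set[dt.date] = set()
    for start, end in _stockpiled_spans(sub):
        lo = max(start, interval.start)
        hi = min(end, interval.end)
        d = lo
        while d < hi:
            covered.add(d)
            d += dt.timedelta(days=1)
    return covered


def compute_pdc(fills: pd.DataFrame, interval: Interval, roster: Roster) -> AdherenceResult:
    """PDC for one patient over one interval.

    A day is covered only when >= 2 distinct ART classes are simultaneously on
    hand; single-class coverage contributes nothing. An eligible patient with no
    ART coverage in the interval gets pdc 0.0, not missing.
    """
    if len(roster.art_classes) < 2:
        raise ValueError("roster must define at least 2 ART classes for PDC")
    n_days = interval.n_days
    if n_days <= 0:
        raise ValueError("empty interval")
    if len(fills):
        roster.validate_classes(fills["drug_class"].unique())
    counts: dict[dt.date, int] = {}
    for cls in roster.art_classes:
        for day in class_coverage_days(fills, interval, cls, roster):
            counts[day] = counts.get(day, 0) + 1
    covered = sum(1 for v in counts.values() if v >= 2)
    pid = fills["patient_id"].iloc[0] if len(fills) else None
    return AdherenceResult(
        patient_id=pid,
        interval_index=interval.index,
        pdc=covered / n_days,
        covered_days=covered,
        interval_days=n_days,
    )


def pdc_for_window(
    fills: pd.DataFrame, start: dt.date, end: dt.date, roster: Roster
) -> AdherenceResult:
    """PDC over an arbitrary [start, end) window (e.g. the 6-month baseline)."""
    return compute_pdc(fills, Interval(index=-1, start=start, end=end, label="window"), roster)


def pdc_baseline(
    fills: pd.DataFrame,
    entries: pd.DataFrame,
    roster: Roster,
    window_days: int = 183,
) -> pd.Series:
    """Vectorised PDC over each patient's pre-entry baseline window.

    `entries` has columns ``patient_id`` and ``entry_date``; the window is
    ``[entry - window_days, entry)``. Returns a Series indexed by patient_id.
    """
    if not len(entries):
        return pd.Series(dtype=float)
    patient_ids = entries["patient_id"].to_numpy()
    entry = entries["entry_date"].to_list()
    origin = min(entry) - dt.timedelta(days=window_days)
    n_days = (max(entry) - origin).days
    ge2 = _ge2_matrix(fills, origin, n_days, roster, patient_ids)
    out = np.empty(len(entries))
    for i, e in enumerate(entry):
        b = (e - origin).days
        out[i] = ge2[i, b - window_days : b].sum() / window_days
    return pd.Series(out, index=patient_ids)


def _ge2_matrix(fills: pd.DataFrame, origin: dt.date, n_days: int, roster: Roster, patient_ids) -> np.ndarray:
    """(n_patients, n_days+1) boolean matrix: >= 2 ART classes on hand that day.

    Shared engine of :func:`pdc_panel` and :func:`pdc_baseline`: stockpiling is
    a sequential scan within (patient, class); coverage is accumulated per
    class with difference arrays on the day grid starting at `origin`.
    """
    n_pat = len(patient_ids)
    pid_pos = pd.Series(np.arange(n_pat), index=patient_ids)
    art = fills[fills["drug_class"].isin(roster.art_classes)]
    art = art[art["patient_id"].isin(pid_pos.index)]
    art = art.sort_values(["patient_id", "drug_class", "fill_date"], kind="stable")
    fill_day = np.array([(d - origin).days for d in art["fill_date"]], dtype=np.int64)
    supply = art["days_supply"].to_numpy(dtype=np.int64)
    pids = art["patient_id"].to_numpy()
    clss = art["drug_class"].to_numpy()
    starts = np.empty(len(art), dtype=np.int64)
    ends = np.empty(len(art), dtype=np.int64)
    prev_key = None
    cur_end = 0
    for i in range(len(art)):
        key = (pids[i], clss[i])
        s = fill_day[i]
        if key == prev_key and cur_end > s:
            s = cur_end
        e = s + supply[i]
        starts[i], ends[i] = s, e
        prev_key, cur_end = key, e

    class_count = np.zeros((n_pat, n_days + 1), dtype=np.int16)
    rows_all = pid_pos.loc[pids].to_numpy() if len(art) else np.empty(0, dtype=np.int64)
    for cls in sorted(roster.art_classes):
        sel = clss == cls
        if not sel.any():
            continue
        lo = np.clip(starts[sel], 0, n_days)
        hi = np.clip(ends[sel], 0, n_days)
        diff = np.zeros((n_pat, n_days + 1), dtype=np.int32)
        np.add.at(diff, (rows_all[sel], lo), 1)
        np.add.at(diff, (rows_all[sel], hi), -1)
        class_count += np.cumsum(diff, axis=1) > 0
    return class_count >= 2


def pdc_panel(
    fills: pd.DataFrame,
    intervals: list[Interval],
    roster: Roster,
    patient_ids=None,
) -> pd.DataFrame:
    """Vectorised PDC for every patient x interval on a shared day grid.

    Returns a DataFrame with columns ``patient_id, interval_index, pdc,
    covered_days, interval_days`` covering the full grid (zero rows included).
    Equivalent to calling :func:`compute_pdc` per cell, but runs in a few
    array passes so it scales to simulation studies.
    """
    if len(fills):
        roster.validate_classes(fills["drug_class"].unique())
    if patient_ids is None:
        patient_ids = np.array(sorted(fills["patient_id"].unique()))
    else:
        patient_ids = np.asarray(patient_ids)
    origin = intervals[0].start
    n_days = (intervals[-1].end - origin).days
    ge2 = _ge2_matrix(fills, origin, n_days, roster, patient_ids)

    frames = []
    for iv in intervals:
        a = (iv.start - origin).days
        b = (iv.end - origin).days
        covered = ge2[:, a:b].sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids,
                    "interval_index": iv.index,
                    "pdc": covered / iv.n_days,
                    "covered_days": covered,
                    "interval_days": iv.n_days,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# viral load


def vl_test_receipt(labs: pd.DataFrame, interval: Interval) -> int:
    """1 iff >= 1 lab in the interval has an interpretable numeric value."""
    if not len(labs):
        return 0
    in_iv = [(interval.contains(d) and not pd.isna(v)) for d, v in zip(labs["test_date"], labs["value"])]
    return int(any(in_iv))


def vl_suppression_series(
    labs: pd.DataFrame,
    intervals: list[Interval],
    threshold: float = DEFAULT_SUPPRESSION_THRESHOLD,
) -> list[float]:
    """Per-interval suppression status (1/0/NaN) for one patient's lab history.

    The most recent numeric test inside each interval decides the status
    (value <= threshold -> suppressed). Test-free intervals carry the last
    observed status forward; intervals before the first test are NaN. Two
    numeric tests on the same most-recent date are resolved by taking the last
    record in input order, with a warning (no clinical tie-break is assumed).
    """
    numeric = labs[~labs["value"].isna()] if len(labs) else labs
    out: list[float] = []
    last: float = np.nan
    for iv in intervals:
        if len(numeric):
            in_iv = numeric[[iv.contains(d) for d in numeric["test_date"]]]
        else:
            in_iv = numeric
        if len(in_iv):
            latest = max(in_iv["test_date"])
            at_latest = in_iv[in_iv["test_date"] == latest]
            if len(at_latest) > 1:
                warnings.warn(
                    f"{len(at_latest)} viral-load tests on {latest}; "
                    "using the last record in input order",
                    stacklevel=2,
                )
            last = float(at_latest["value"].iloc[-1] <= threshold)
        out.append(last)
    return out


def receipt_panel(labs: pd.DataFrame, intervals: list[Interval], patient_ids) -> pd.DataFrame:
    """Vectorised test receipt for every patient x interval."""
    patient_ids = np.asarray(patient_ids)
    idx = pd.MultiIndex.from_product(
        [patient_ids, [iv.index for iv in intervals]], names=["patient_id", "interval_index"]
    )
    numeric = labs[~labs["value"].isna()]
    iv_idx = _assign_intervals(numeric["test_date"], intervals)
    ok = iv_idx >= 0
    got = (
        pd.DataFrame({"patient_id": numeric["patient_id"].to_numpy()[ok], "interval_index": iv_idx[ok]})
        .groupby(["patient_id", "interval_index"])
        .size()
    )
    out = pd.Series(0, index=idx, name="vl_receipt")
    hit = got.index.intersection(idx)
    out.loc[hit] = 1
    return out.reset_index()


def suppression_panel(
    labs: pd.DataFrame,
    intervals: list[Interval],
    patient_ids,
    threshold: float = DEFAULT_SUPPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Vectorised LOCF suppression status for every patient x interval."""
    patient_ids = np.asarray(patient_ids)
    numeric = labs[~labs["value"].isna()].copy()
    iv_idx = _assign_intervals(numeric["test_date"], intervals)
    numeric["interval_index"] = iv_idx
    numeric = numeric[iv_idx >= 0]
    # most recent test per (patient, interval); stable sort keeps input order on ties
    numeric = numeric.sort_values(["patient_id", "interval_index", "test_date"], kind="stable")
    last = numeric.groupby(["patient_id", "interval_index"], sort=True).tail(1)
    ties = numeric.groupby(["patient_id", "interval_index", "test_date"]).size()
    n_dup = int((ties[ties > 1]).shape[0])
    if n_dup:
        tied_last = last.set_index(["patient_id", "interval_index", "test_date"]).index
        if any(t in tied_last for t in ties[ties > 1].index):
            warnings.warn(
                f"{n_dup} patient-interval(s) with >1 viral-load test on the most "
                "recent date; using the last record in input order",
                stacklevel=2,
            )
    status = (last["value"] <= threshold).astype(float)
    wide = pd.DataFrame(
        status.to_numpy(),
        index=pd.MultiIndex.from_frame(last[["patient_id", "interval_index"]]),
        columns=["vl_suppressed"],
    )["vl_suppressed"].unstack("interval_index")
    wide = wide.reindex(index=patient_ids, columns=[iv.index for iv in intervals])
    wide = wide.ffill(axis=1)  # LOCF; leading intervals stay NaN
    long = wide.stack(future_stack=True).rename("vl_suppressed").reset_index()
    long.columns = ["patient_id", "interval_index", "vl_suppressed"]
    return long


def _assign_intervals(dates, intervals: list[Interval]) -> np.ndarray:
    """Interval index per date; -1 outside the study window."""
    bounds = np.array(
        [np.datetime64(intervals[0].start)] + [np.datetime64(iv.end) for iv in intervals]
    )
    d = np.array([np.datetime64(x) for x in dates]) if len(dates) else np.empty(0, "M8[D]")
    pos = np.searchsorted(bounds, d, side="right") - 1
    pos[(pos < 0) | (pos >= len(intervals))] = -1
    return pos


def shift_outcomes_next(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Attach interval t+1 outcomes to the exposure row at interval t.

    `outcomes` is keyed by (patient_id, interval_index) with any of the columns
    ``pdc``, ``vl_receipt``, ``vl_suppressed``. The shift only reaches across
    calendar-adjacent intervals: a row with no t+1 row gets missing outcomes.
    """
    key = ["patient_id", "interval_index"]
    nxt = outcomes.copy()
    nxt["interval_index"] = nxt["interval_index"] - 1
    renames = {
        "pdc": "outcome_pdc_next",
        "vl_receipt": "outcome_vl_receipt_next",
        "vl_suppressed": "outcome_vl_suppressed",
    }
    keep = [c for c in renames if c in nxt.columns]
    nxt = nxt[key + keep].rename(columns={c: renames[c] for c in keep})
    return outcomes.merge(nxt, on=key, how="left")
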