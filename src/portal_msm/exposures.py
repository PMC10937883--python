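"""Per-interval binary portal-tool exposures and their 6-month lags.

Five tools are tracked: prescription refill of any medication, prescription
refill of an antiretroviral, secure messaging, view appointments and view labs.
An exposure is 1 if the tool was used at least once in the interval, regardless
of how often. Refill tools are available to every portal registrant; the other
three require in-person authentication (IPA), so pre-IPA intervals carry
structural zeros for them rather than missing values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .intervals import Interval
from .outcomes import _assign_intervals

__all__ = [
    "TOOLS",
    "REFILL_TOOLS",
    "AUTHENTICATED_TOOLS",
    "tool_use_indicator",
    "exposure_panel",
    "zero_fill_unavailable_tools",
    "lag_exposures",
]

TOOLS = ("rx_refill_any", "rx_refill_art", "secure_messaging", "view_appointments", "view_labs")
#: Available with a basic (Advanced) account, from registration.
REFILL_TOOLS = ("rx_refill_any", "rx_refill_art")
#: Require in-person authentication (Premium account).
AUTHENTICATED_TOOLS = ("secure_messaging", "view_appointments", "view_labs")


def tool_use_indicator(events: pd.DataFrame, tool: str, interval: Interval) -> int:
    """1 iff one patient's `events` include >= 1 use of `tool` in `interval`."""
    if tool not in TOOLS:
        raise ValueError(f"unknown tool {tool!r}; expected one of {TOOLS}")
    sub = events[events["tool"] == tool]
    return int(any(interval.contains(d) for d in sub["event_date"]))


def exposure_panel(events: pd.DataFrame, intervals: list[Interval], patient_ids) -> pd.DataFrame:
    """Five 0/1 exposure columns for every patient x interval (full grid)."""
    patient_ids = np.asarray(patient_ids)
    idx = pd.MultiIndex.from_product(
        [patient_ids, [iv.index for iv in intervals]], names=["patient_id", "interval_index"]
    )
    out = pd.DataFrame(0, index=idx, columns=list(TOOLS), dtype=np.int8)
    iv_idx = _assign_intervals(events["event_date"], intervals)
    ok = iv_idx >= 0
    ev = pd.DataFrame(
        {
            "patient_id": events["patient_id"].to_numpy()[ok],
            "interval_index": iv_idx[ok],
            "tool": events["tool"].to_numpy()[ok],
        }
    )
    bad = set(ev["tool"]) - set(TOOLS)
    if bad:
        raise ValueError(f"unknown tool(s) in events: {sorted(bad)}")
    for tool, grp in ev.groupby("tool"):
        hit = pd.MultiIndex.from_frame(grp[["patient_id", "interval_index"]].drop_duplicates())
        out.loc[out.index.intersection(hit), tool] = 1
    return out.reset_index()


def zero_fill_unavailable_tools(panel: pd.DataFrame, patients: pd.DataFrame, intervals: list[Interval]) -> pd.DataFrame:
    """Force authenticated-tool exposures to 0 in pre-IPA intervals.

    A patient without an IPA date has no access to secure messaging, view
    appointments or view labs, so those indicators are structural zeros (never
    missing) for all intervals ending on or before the IPA date. A recorded
    event there is impossible and overwritten with a warning. Idempotent.
    """
    panel = panel.copy()
    ipa = patients.set_index("patient_id")["ipa_date"]
    ends = pd.Series({iv.index: iv.end for iv in intervals})
    # an interval is pre-IPA when it closes on or before the IPA date (or the
    # patient never authenticated); the interval containing the IPA date is
    # partial-access and left as recorded
    ipa_d = panel["patient_id"].map(ipa)
    iv_end = panel["interval_index"].map(ends)
    pre_ipa = ipa_d.isna() | (pd.to_datetime(iv_end) <= pd.to_datetime(ipa_d))
    n_clobbered = int(panel.loc[pre_ipa, list(AUTHENTICATED_TOOLS)].to_numpy().sum())
    if n_clobbered:
        warnings.warn(
            f"{n_clobbered} authenticated-tool use flag(s) recorded before IPA; forced to 0",
            stacklevel=2,
        )
    panel.loc[pre_ipa, list(AUTHENTICATED_TOOLS)] = 0
    return panel


def lag_exposures(panel: pd.DataFrame) -> pd.DataFrame:
    """Add ``<tool>_lag6`` columns: exposure at the calendar-adjacent prior interval.

    A gap in observation (no row at t-1) leaves the lag missing rather than
    reaching further back; rows with missing lags are not model-eligible.
    """
    prev = panel.copy()
    prev["interval_index"] = prev["interval_index"] + 1
    cols = [t for t in TOOLS if t in panel.columns]
    prev = prev[["patient_id", "interval_index"] + cols].rename(
        columns={t: f"{t}_lag6" for t in cols}
    )
    return panel.merge(prev, on=["patient_id", "interval_index"], how="left")
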