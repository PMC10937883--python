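"""Fiscal-half-year intervals.

The VA fiscal year runs October 1 through September 30; analyses use its two
6-month halves as the person-period unit. ``FY13H1`` is [2012-10-01, 2013-04-01)
and ``FY13H2`` is [2013-04-01, 2013-10-01). All intervals are half-open
``[start, end)``: an event on April 1 belongs to the second half.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

__all__ = ["Interval", "build_intervals", "interval_index_of", "interval_label"]

_ANCHOR_MONTHS = (10, 4)  # Oct 1 and Apr 1 are the only legal interval boundaries


@dataclass(frozen=True)
class Interval:
    """One fiscal half-year: half-open [start, end), 0-based index."""

    index: int
    start: dt.date
    end: dt.date
    label: str

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days

    def contains(self, day: dt.date) -> bool:
        return self.start <= day < self.end


def _next_boundary(day: dt.date) -> dt.date:
    if day.month == 10:
        return dt.date(day.year + 1, 4, 1)
    return dt.date(day.year, 10, 1)


def interval_label(start: dt.date) -> str:
    """Fiscal label of the half starting at `start` (e.g. FY13H1 for 2012-10-01)."""
    if start.month == 10:
        return f"FY{(start.year + 1) % 100:02d}H1"
    return f"FY{start.year % 100:02d}H2"


def build_intervals(study_start: dt.date, study_end: dt.date) -> list[Interval]:
    """Tile [study_start, study_end) with contiguous fiscal half-year intervals.

    Parameters
    ----------
    study_start
        Must fall on October 1 or April 1 (the fiscal-half anchors).
    study_end
        Exclusive end of the study window; must lie beyond ``study_start``.
        The final interval is the half containing ``study_end - 1 day``, so a
        study_end on an anchor day yields whole halves exactly tiling the window.
    """
    if not (study_start.day == 1 and study_start.month in _ANCHOR_MONTHS):
        raise ValueError(
            f"study_start {study_start} must fall on October 1 or April 1 "
            "(the two fiscal half-year anchor days)"
        )
    if study_end <= study_start:
        raise ValueError("study_end must be after study_start")
    out: list[Interval] = []
    start = study_start
    while start < study_end:
        end = _next_boundary(start)
        out.append(Interval(index=len(out), start=start, end=end, label=interval_label(start)))
        start = end
    return out


def interval_index_of(day: dt.date, intervals: list[Interval]) -> int | None:
    """Index of the interval containing `day`, or None outside the window."""
    if not intervals or day < intervals[0].start or day >= intervals[-1].end:
        return None
    for iv in intervals:
        if iv.contains(day):
            return iv.index
    return None  # pragma: no cover
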