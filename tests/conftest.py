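"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use different mechanisms from the library: pill-stock
day-by-day simulation for PDC coverage (the library merges supply spans), and
a naive forward scan for LOCF suppression (the library reshapes and ffills).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from portal_msm import Roster, build_intervals
from portal_msm.simulate import default_roster


@pytest.fixture
def roster() -> Roster:
    return default_roster()


@pytest.fixture
def intervals4():
    """Four fiscal halves: FY13H1 .. FY14H2."""
    return build_intervals(dt.date(2012, 10, 1), dt.date(2014, 10, 1))


@pytest.fixture
def intervals6():
    return build_intervals(dt.date(2012, 10, 1), dt.date(2015, 10, 1))


# ---------------------------------------------------------------------------
# brute-force PDC oracle: per-class pill-stock simulation, literal day loop


def _class_stock_covered(grp: pd.DataFrame, horizon_end: dt.date) -> set[dt.date]:
    by_day: dict[dt.date, int] = {}
    for _, r in grp.iterrows():
        by_day[r["fill_date"]] = by_day.get(r["fill_date"], 0) + int(r["days_supply"])
    if not by_day:
        return set()
    covered: set[dt.date] = set()
    stock = 0
    d = min(by_day)
    while d < horizon_end:
        stock += by_day.get(d, 0)
        if stock > 0:
            covered.add(d)
            stock -= 1
        d += dt.timedelta(days=1)
    return covered


def brute_force_pdc(fills: pd.DataFrame, interval, roster: Roster) -> tuple[int, float]:
    """Covered-day count and PDC by literal day-by-day simulation."""
    art = fills[fills["drug_class"].isin(roster.art_classes)] if len(fills) else fills
    per_class = {}
    if len(art):
        for cls, grp in art.groupby("drug_class"):
            per_class[cls] = _class_stock_covered(grp, interval.end)
    days = 0
    d = interval.start
    while d < interval.end:
        if sum(d in cov for cov in per_class.values()) >= 2:
            days += 1
        d += dt.timedelta(days=1)
    return days, days / interval.n_days


def brute_force_class_days(fills: pd.DataFrame, interval, drug_class: str) -> set[dt.date]:
    grp = fills[fills["drug_class"] == drug_class]
    covered = _class_stock_covered(grp, interval.end)
    return {d for d in covered if interval.start <= d < interval.end}


def random_fills(rng: np.random.Generator, interval, roster: Roster, max_fills: int = 8) -> pd.DataFrame:
    """Random fill set around an interval: random classes, dates, supplies,
    overlaps, including pre-interval history and boundary-straddling fills."""
    n = int(rng.integers(0, max_fills + 1))
    classes = sorted(roster.classes)
    lo = interval.start - dt.timedelta(days=60)
    span = (interval.end - lo).days + 10
    rows = [
        {
            "patient_id": "PX",
            "drug_name": "synthetic",
            "drug_class": classes[int(rng.integers(len(classes)))],
            "fill_date": lo + dt.timedelta(days=int(rng.integers(span))),
            "days_supply": int(rng.integers(1, 61)),
        }
        for _ in range(n)
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "drug_name", "drug_class", "fill_date", "days_supply"]
    )


# ---------------------------------------------------------------------------
# naive LOCF suppression oracle


def brute_force_locf(labs: pd.DataFrame, intervals, threshold: float) -> list[float]:
    numeric = labs[~labs["value"].isna()] if len(labs) else labs
    out: list[float] = []
    last = np.nan
    for iv in intervals:
        best_date, best_val = None, None
        for _, r in numeric.iterrows():  # input order; later rows win ties
            if iv.contains(r["test_date"]) and (best_date is None or r["test_date"] >= best_date):
                best_date, best_val = r["test_date"], r["value"]
        if best_date is not None:
            last = float(best_val <= threshold)
        out.append(last)
    return out


def random_labs(rng: np.random.Generator, intervals, max_tests: int = 10) -> pd.DataFrame:
    """Random lab history: numeric and uninterpretable values, same-day ties."""
    n = int(rng.integers(0, max_tests + 1))
    lo = intervals[0].start - dt.timedelta(days=30)
    span = (intervals[-1].end - lo).days + 20
    rows = []
    for _ in range(n):
        d = lo + dt.timedelta(days=int(rng.integers(span)))
        val = np.nan if rng.random() < 0.15 else float(rng.choice([40.0, 150.0, 900.0, 20000.0]))
        rows.append({"patient_id": "PX", "test_date": d, "value": val})
        if rng.random() < 0.1:  # same-day tie
            rows.append({"patient_id": "PX", "test_date": d, "value": float(rng.choice([40.0, 900.0]))})
    return pd.DataFrame(rows, columns=["patient_id", "test_date", "value"])
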