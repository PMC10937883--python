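"""End-to-end orchestration: raw tables -> panels -> weights -> fitted grid.

The default analysis grid mirrors the reporting structure of the study design:
each of the five tools is analysed for all three outcomes in the cohort where
the tool is actually accessible (refill tools in the refill-access cohort, the
authenticated tools in the full-access cohort), plus an exploratory
suppression analysis restricted to patients unsuppressed at baseline — 15
primary cells and 5 subgroup cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    CohortSpec,
    apply_eligibility,
    assemble_person_periods,
    mark_unsuppressed_subgroup,
)
from .exposures import (
    REFILL_TOOLS,
    TOOLS,
    exposure_panel,
    lag_exposures,
    zero_fill_unavailable_tools,
)
from .intervals import Interval
from .iptw import WeightModelSpec, compute_weights
from .missingness import categorize_unknowns, impute_adi
from .msm import fit_weighted_gee, summarize_tool_time
from .outcomes import (
    pdc_panel,
    receipt_panel,
    shift_outcomes_next,
    suppression_panel,
)
from .simulate import SyntheticCohort

log = logging.getLogger("portal_msm")

__all__ = [
    "AnalysisConfig",
    "build_panel",
    "default_weight_spec",
    "run_analysis_grid",
    "RESULT_COLUMNS",
]

BASELINE_TERMS = (
    "baseline_pdc",
    "age_at_entry",
    "C(sex)",
    "C(race_ethnicity)",
    "years_since_diagnosis",
    "C(nonva_care)",
)
TIME_VARYING_TERMS = (
    "outpatient_visits",
    "hiv_outpatient_visits",
    "inpatient_stays",
    "comorbidity_index",
    "housed",
    "C(rurality)",
    "adi",
    "depression",
    "bipolar",
    "psychoses",
    "ptsd",
    "sud",
    "aud",
)
DEFAULT_OUTCOME_TERMS = BASELINE_TERMS + ("C(entry_interval)",)

RESULT_COLUMNS = [
    "cohort",
    "tool",
    "outcome",
    "estimate",
    "scale",
    "robust_se",
    "ci_low",
    "ci_high",
    "n_patients",
    "n_person_periods",
]


@dataclass
class AnalysisConfig:
    """Analysis-side settings (the generator has its own config)."""

    suppression_threshold: float = 200.0
    oracle_weights: bool = False  # use the latent engagement column, if emitted
    outcome_terms: tuple[str, ...] = DEFAULT_OUTCOME_TERMS
    lower_pct: float = 1.0
    upper_pct: float = 99.0
    include_subgroup: bool = True
    lagged_exposure_in_outcome: bool = False  # default: lag lives in the weight models


_TERM_COL = re.compile(r"^C\((\w+)")


def _prune_terms(
    panel: pd.DataFrame, terms: tuple[str, ...], tool: str | None = None
) -> tuple[str, ...]:
    """Drop terms that cannot be estimated in this panel.

    A term goes if its column is absent or constant; a categorical term
    additionally goes if any level has no exposed or no unexposed rows (a
    positivity guard — such levels separate a pooled logit exactly).
    """
    out = []
    for t in terms:
        m = _TERM_COL.match(t)
        col = m.group(1) if m else t
        if col not in panel.columns or panel[col].nunique(dropna=False) < 2:
            continue
        if m and tool is not None:
            ct = pd.crosstab(panel[col], panel[tool])
            if ct.shape[1] < 2 or (ct == 0).any().any():
                continue
        out.append(t)
    return tuple(out)


def default_weight_spec(tool: str, panel: pd.DataFrame, oracle: bool = False) -> WeightModelSpec:
    """Documented default: baseline covariates + lagged exposure in the
    numerator; all time-varying covariates added in the denominator (or the
    latent engagement column in oracle mode)."""
    num = _prune_terms(panel, BASELINE_TERMS, tool) + (f"{tool}_lag6",)
    extra = ("engagement",) if oracle else TIME_VARYING_TERMS
    den = num + _prune_terms(panel, extra, tool)
    iv_term = _prune_terms(panel, ("C(interval_index)",), tool)
    return WeightModelSpec(
        tool=tool,
        numerator_terms=num,
        denominator_terms=den,
        interval_term=iv_term[0] if iv_term else "",
    )


def build_panel(
    data: SyntheticCohort | dict,
    spec: CohortSpec,
    intervals: list[Interval] | None = None,
    roster=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Construct the model-eligible person-period panel for one cohort spec.

    Returns ``(panel, eligible_patients, exclusion_ledger)``. `data` is either
    a :class:`SyntheticCohort` or a dict of raw tables (then `intervals` and
    `roster` are required).
    """
    t0 = time.perf_counter()
    if isinstance(data, SyntheticCohort):
        tables = data.tables()
        intervals = data.intervals
        roster = data.truth.config.roster
    else:
        tables = data
    patients = tables["patients"]
    fills = tables["fills"]
    labs = tables["labs"]
    events = tables["portal_events"]
    zip_panel = tables["zip_panel"]
    cov_panel = tables["covariate_panel"]

    _, patients = categorize_unknowns(patients=patients)
    eligible, ledger = apply_eligibility(patients, spec, intervals, fills, labs, zip_panel, roster)
    pids = eligible["patient_id"].to_numpy()

    # ZIP covariates: label -> index, ADI mean-imputation, rurality unknowns
    label_to_idx = {iv.label: iv.index for iv in intervals}
    zp = zip_panel[zip_panel["patient_id"].isin(pids)].copy()
    zp["interval_index"] = zp["interval_label"].map(label_to_idx)
    zp["adi"] = pd.to_numeric(zp["adi"], errors="coerce")
    zp, adi_excluded = impute_adi(zp)
    if adi_excluded:
        eligible = eligible[~eligible["patient_id"].isin(adi_excluded)]
        pids = eligible["patient_id"].to_numpy()
        ledger["steps"].append(
            {"name": "adi_all_missing", "retained": len(eligible), "excluded": len(adi_excluded)}
        )
        ledger["retained_patients"] = len(eligible)
    zp, _ = categorize_unknowns(panel=zp)
    cov = cov_panel[cov_panel["patient_id"].isin(pids)].merge(
        zp[["patient_id", "interval_index", "rurality", "adi"]],
        on=["patient_id", "interval_index"],
        how="left",
    )
    cov = cov.drop(columns=[c for c in ("interval_label",) if c in cov.columns])

    expo = exposure_panel(events, intervals, pids)
    expo = zero_fill_unavailable_tools(expo, patients, intervals)
    expo = lag_exposures(expo)

    if spec.outcome_set == "adherence":
        out = pdc_panel(fills, intervals, roster, patient_ids=pids)[
            ["patient_id", "interval_index", "pdc"]
        ]
    else:
        rec = receipt_panel(labs, intervals, pids)
        sup = suppression_panel(labs, intervals, pids, threshold=spec.suppression_threshold)
        out = rec.merge(sup, on=["patient_id", "interval_index"])
    out = shift_outcomes_next(out)

    panel = assemble_person_periods(eligible, intervals, expo, cov, out)
    log.info(
        "panel %s/%s: %d patients, %d person-periods (%.2fs)",
        spec.cohort_type,
        spec.outcome_set,
        len(eligible),
        len(panel),
        time.perf_counter() - t0,
    )
    return panel, eligible, ledger


def _empty_cell(cohort: str, tool: str, outcome: str, n_pat: int = 0, n_pp: int = 0) -> dict:
    return {
        "cohort": cohort,
        "tool": tool,
        "outcome": outcome,
        "estimate": np.nan,
        "scale": "",
        "robust_se": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "n_patients": n_pat,
        "n_person_periods": n_pp,
    }


def run_analysis_grid(
    data: SyntheticCohort | dict,
    config: AnalysisConfig | None = None,
    intervals: list[Interval] | None = None,
    roster=None,
    entry_window: tuple | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit the full tool x outcome grid; returns (results table, provenance).

    Results carry one row per cell in the fixed grid order. Cells that cannot
    be fit (no eligible rows, or an exposure that never varies, as happens in
    small subgroups) are recorded as empty cells rather than crashing.
    """
    t0 = time.perf_counter()
    config = config or AnalysisConfig()
    if isinstance(data, SyntheticCohort):
        intervals = data.intervals
        if entry_window is None:
            entry_window = (intervals[0].start, intervals[-1].end)

    def spec_for(cohort_type: str, outcome_set: str) -> CohortSpec:
        return CohortSpec(
            cohort_type=cohort_type,
            entry_window_start=entry_window[0],
            entry_window_end=entry_window[1],
            outcome_set=outcome_set,
            suppression_threshold=config.suppression_threshold,
        )

    panels: dict = {}
    ledgers: dict = {}
    for cohort_type in ("refill_access", "full_access"):
        for outcome_set in ("adherence", "viral_load"):
            panel, eligible, ledger = build_panel(
                data, spec_for(cohort_type, outcome_set), intervals, roster
            )
            panels[(cohort_type, outcome_set)] = (panel, eligible)
            ledgers[f"{cohort_type}/{outcome_set}"] = ledger

    outcome_cells = [
        ("adherence", "outcome_pdc_next", "adherence"),
        ("vl_suppression", "outcome_vl_suppressed", "viral_load"),
        ("vl_receipt", "outcome_vl_receipt_next", "viral_load"),
    ]
    rows: list[dict] = []
    weight_meta: dict = {}

    def fit_cell(panel: pd.DataFrame, cohort_label: str, tool: str, outcome_name: str, col: str):
        if not len(panel) or panel[tool].nunique() < 2:
            rows.append(
                _empty_cell(cohort_label, tool, outcome_name, panel["patient_id"].nunique() if len(panel) else 0, len(panel))
            )
            return
        try:
            wspec = default_weight_spec(tool, panel, oracle=config.oracle_weights)
            weights, meta = compute_weights(panel, wspec, config.lower_pct, config.upper_pct)
            weight_meta[f"{cohort_label}/{tool}/{outcome_name}"] = meta
            terms = _prune_terms(panel, config.outcome_terms, tool)
            if config.lagged_exposure_in_outcome:
                terms = terms + (f"{tool}_lag6",)
            site_col = "site" if _prune_terms(panel, ("C(site)",), tool) else None
            res = fit_weighted_gee(
                panel,
                weights,
                outcome=col,
                tool=tool,
                covariate_terms=terms,
                cohort=cohort_label,
                site_col=site_col,
            )
        except ValueError as ex:
            # degenerate cell (e.g. separation in a tiny subgroup): record, don't crash
            log.warning("cell %s/%s/%s not fit: %s", cohort_label, tool, outcome_name, ex)
            rows.append(
                _empty_cell(cohort_label, tool, outcome_name, panel["patient_id"].nunique(), len(panel))
            )
            return
        d = res.to_dict()
        d["outcome"] = outcome_name
        rows.append({k: d[k] for k in RESULT_COLUMNS})

    for outcome_name, col, outcome_set in outcome_cells:
        for tool in TOOLS:
            cohort_type = "refill_access" if tool in REFILL_TOOLS else "full_access"
            panel, _ = panels[(cohort_type, outcome_set)]
            fit_cell(panel, cohort_type, tool, outcome_name, col)

    if config.include_subgroup:
        for tool in TOOLS:
            cohort_type = "refill_access" if tool in REFILL_TOOLS else "full_access"
            panel, eligible = panels[(cohort_type, "viral_load")]
            sub = mark_unsuppressed_subgroup(panel, eligible, config.suppression_threshold)
            fit_cell(sub, f"{cohort_type}_unsuppressed", tool, "vl_suppression", "outcome_vl_suppressed")

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    provenance = {
        "config": {
            "suppression_threshold": config.suppression_threshold,
            "oracle_weights": config.oracle_weights,
            "outcome_terms": list(config.outcome_terms),
            "truncation_pcts": [config.lower_pct, config.upper_pct],
            "lagged_exposure_in_outcome": config.lagged_exposure_in_outcome,
        },
        "exclusion_ledgers": ledgers,
        "weight_metadata": weight_meta,
        "config_hash": hashlib.sha256(
            json.dumps(
                {"threshold": config.suppression_threshold, "terms": list(config.outcome_terms)},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    if isinstance(data, SyntheticCohort):
        provenance["generator_config"] = data.truth.config.to_dict()
    log.info("analysis grid: %d cells in %.1fs", len(results), provenance["runtime_s"])
    return results, provenance


def summarize_grid_tool_time(data: SyntheticCohort, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Patient-time/outcome summary for each cohort (descriptive companion
    table to the fitted grid)."""
    config = config or AnalysisConfig()
    intervals = data.intervals
    entry_window = (intervals[0].start, intervals[-1].end)
    frames = []
    for cohort_type in ("refill_access", "full_access"):
        tools = REFILL_TOOLS if cohort_type == "refill_access" else tuple(
            t for t in TOOLS if t not in REFILL_TOOLS
        )
        for outcome_set, cols in (
            ("adherence", {"pdc_next": "outcome_pdc_next"}),
            (
                "viral_load",
                {"vl_suppression": "outcome_vl_suppressed", "vl_receipt": "outcome_vl_receipt_next"},
            ),
        ):
            spec = CohortSpec(
                cohort_type=cohort_type,
                entry_window_start=entry_window[0],
                entry_window_end=entry_window[1],
                outcome_set=outcome_set,
                suppression_threshold=config.suppression_threshold,
            )
            panel, _, _ = build_panel(data, spec)
            frames.append(summarize_tool_time(panel, tools, cols, cohort=cohort_type))
    return pd.concat(frames, ignore_index=True)
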