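"""Weighted GEE marginal structural outcome models.

The outcome models are population-averaged regressions on the pooled
person-period panel, estimated by generalized estimating equations with the
normalized stabilized weights as case weights: identity link with Gaussian
variance for the PDC outcome (effects are additive, in PDC points), logit link
with binomial variance for the binary outcomes (effects reported as odds
ratios). Clusters are patients, the working correlation is AR(1) in interval
order, standard errors are robust (sandwich), and baseline site enters as
fixed-effect indicators with the most frequent site as reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .intervals import Interval
from .missingness import assert_no_missing

__all__ = ["MSMResult", "fit_weighted_gee", "summarize_tool_time", "trend_proportions"]

#: Two-sided confidence level; no multiple-comparison correction is applied
#: (the analysis is exploratory, and intervals are reported for interpretation).
Z_95 = 1.959963984540054

GEE_MAXITER = 50
GEE_CTOL = 1e-6


@dataclass(frozen=True)
class MSMResult:
    """One fitted exposure -> outcome contrast on its reporting scale."""

    tool: str
    outcome: str
    cohort: str
    estimate: float
    scale: str  # "coefficient" (additive) or "odds_ratio"
    robust_se: float  # on the estimation (link) scale
    ci_low: float
    ci_high: float
    n_patients: int
    n_person_periods: int

    def to_dict(self) -> dict:
        return asdict(self)


def fit_weighted_gee(
    panel: pd.DataFrame,
    weights: pd.DataFrame | np.ndarray | None,
    outcome: str,
    tool: str,
    covariate_terms: tuple[str, ...] = (),
    cohort: str = "",
    site_col: str | None = "site",
    cov_struct: sm.cov_struct.CovStruct | None = None,
) -> MSMResult:
    """Fit one weighted-GEE outcome model and report it on the paper scale.

    `weights` may be a weight table (keyed by patient_id/interval_index with a
    ``norm_w`` column), a raw array aligned with `panel`, or None for an
    unweighted fit. Rows with a missing outcome are dropped; missing covariates
    are a hard error (they must be handled upstream).
    """
    df = panel.copy()
    if isinstance(weights, pd.DataFrame):
        df = df.merge(
            weights[["patient_id", "interval_index", "norm_w"]],
            on=["patient_id", "interval_index"],
            how="left",
        )
        df["_w"] = df["norm_w"]
    elif weights is None:
        df["_w"] = 1.0
    else:
        df["_w"] = np.asarray(weights, dtype=float)

    df = df[~df[outcome].isna()].copy()
    if not len(df):
        raise ValueError(f"no rows with observed outcome {outcome!r}")
    if df["_w"].isna().any():
        raise ValueError("weights missing for some person-period rows")

    binary = set(pd.unique(df[outcome])) <= {0, 1, 0.0, 1.0}
    family = sm.families.Binomial() if binary else sm.families.Gaussian()

    terms = [tool] + list(covariate_terms)
    if site_col is not None and site_col in df.columns:
        ref = df[site_col].mode().iloc[0]
        terms.append(f"C({site_col}, Treatment(reference={ref!r}))")
    assert_no_missing(df, [tool])
    formula = f"{outcome} ~ " + " + ".join(terms)

    df = df.sort_values(["patient_id", "interval_index"], kind="stable")
    if cov_struct is None:
        cov_struct = sm.cov_struct.Autoregressive(grid=True)
    with warnings.catch_warnings():
        # AR(1) dependence parameter is estimated without case weights in
        # statsmodels; mean params and sandwich SEs do use them.
        warnings.simplefilter("ignore")
        model = smf.gee(
            formula,
            groups="patient_id",
            time=df["interval_index"].to_numpy(),
            data=df,
            family=family,
            cov_struct=cov_struct,
            weights=df["_w"].to_numpy(),
        )
        res = model.fit(maxiter=GEE_MAXITER, ctol=GEE_CTOL)
    if not getattr(res, "converged", True):
        raise RuntimeError(
            f"GEE failed to converge in {GEE_MAXITER} iterations "
            f"(param change history: {getattr(res, 'fit_history', None)})"
        )

    beta = float(res.params[tool])
    se = float(res.bse[tool])  # robust (sandwich) by default
    lo, hi = beta - Z_95 * se, beta + Z_95 * se
    if binary:
        estimate, ci_low, ci_high, scale = np.exp(beta), np.exp(lo), np.exp(hi), "odds_ratio"
    else:
        estimate, ci_low, ci_high, scale = beta, lo, hi, "coefficient"
    return MSMResult(
        tool=tool,
        outcome=outcome,
        cohort=cohort,
        estimate=float(estimate),
        scale=scale,
        robust_se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_patients=int(df["patient_id"].nunique()),
        n_person_periods=int(len(df)),
    )


def summarize_tool_time(
    panel: pd.DataFrame,
    tools: tuple[str, ...],
    outcome_cols: dict[str, str],
    cohort: str = "",
) -> pd.DataFrame:
    """Patient-time and outcome summary by tool use (one row per tool x outcome).

    Percent patient-time using a tool is the mean of the 0/1 indicator over
    person-periods; outcome means are stratified by use vs non-use periods.
    """
    rows = []
    for tool in tools:
        use = panel[tool] == 1
        for outcome_name, col in outcome_cols.items():
            obs = panel[~panel[col].isna()]
            use_obs = obs[tool] == 1
            rows.append(
                {
                    "cohort": cohort,
                    "tool": tool,
                    "outcome": outcome_name,
                    "patients_represented": panel["patient_id"].nunique(),
                    "pct_patient_time_using": 100.0 * use.mean() if len(panel) else np.nan,
                    "patient_time_using": int(use.sum()),
                    "total_patient_time": int(len(panel)),
                    "mean_outcome_tool_use": obs.loc[use_obs, col].mean(),
                    "mean_outcome_no_tool_use": obs.loc[~use_obs, col].mean(),
                }
            )
    return pd.DataFrame(rows)


def trend_proportions(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    intervals: list[Interval],
    tools: tuple[str, ...] | None = None,
    window_days: int = 365,
) -> pd.DataFrame:
    """Per-interval proportion of registrants actively using each tool.

    For each interval, the numerator counts distinct patients with events of
    the tool on at least two separate days within the trailing year ending at
    the interval's close; the denominator counts patients registered by then
    and still alive. An empty denominator yields a missing proportion.
    """
    if tools is None:
        tools = tuple(sorted(events["tool"].unique()))
    ev = events.copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    reg = pd.to_datetime(patients["registration_date"])
    death = pd.to_datetime(patients["death_date"]) if "death_date" in patients else None
    rows = []
    for iv in intervals:
        end = pd.Timestamp(iv.end)
        start = end - pd.Timedelta(days=window_days)
        alive = reg.notna() & (reg <= end)
        if death is not None:
            alive &= death.isna() | (death >= end)
        denom = int(alive.sum())
        win = ev[(ev["event_date"] >= start) & (ev["event_date"] < end)]
        for tool in tools:
            sub = win[win["tool"] == tool]
            days = sub.groupby("patient_id")["event_date"].nunique()
            numer = int((days >= 2).sum())
            rows.append(
                {
                    "interval_label": iv.label,
                    "interval_index": iv.index,
                    "tool": tool,
                    "n_active_users": numer,
                    "n_registered_alive": denom,
                    "proportion": numer / denom if denom else np.nan,
                }
            )
    return pd.DataFrame(rows)
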