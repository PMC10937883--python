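"""Stabilized inverse-probability-of-treatment weights.

For each tool the probability of the observed exposure is modelled twice on the
pooled person-period panel: a *numerator* model using baseline history only
(baseline and time-fixed covariates plus the lagged exposure) and a
*denominator* model adding the time-varying covariates. The stabilized weight
at interval t is the cumulative product, over the patient's model-eligible
intervals up to t, of

    [p_num if exposed else 1 - p_num] / [p_den if exposed else 1 - p_den].

Raw weights are then truncated at the 1st/99th percentiles of the pooled raw
distribution (linear interpolation between order statistics) and divided by
their mean so the normalized weights average exactly 1.

Optional censoring weights reuse the same machinery with "remains uncensored"
as the modelled event; they are off by default and, when enabled, multiply the
treatment weights before truncation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "WeightModelSpec",
    "FittedWeightModels",
    "fit_treatment_models",
    "stabilized_weights",
    "truncate_and_normalize",
    "compute_weights",
    "weights_frame",
]

#: Predicted probabilities are clipped here before ratio formation.
PROB_CLIP = 1e-6
#: |coefficient| beyond this on the logit scale is treated as separation.
SEPARATION_COEF = 15.0


@dataclass(frozen=True)
class WeightModelSpec:
    """Terms of the two pooled exposure-probability models.

    ``numerator_terms`` must be a subset of ``denominator_terms`` (stabilized
    weights require the numerator history to be coarser). ``interval_term`` is
    added to both models; the default pools intervals with a categorical term.
    """

    tool: str
    numerator_terms: tuple[str, ...]
    denominator_terms: tuple[str, ...]
    interval_term: str = "C(interval_index)"

    def __post_init__(self):
        if not set(self.numerator_terms) <= set(self.denominator_terms):
            raise ValueError("numerator_terms must be a subset of denominator_terms")

    def _formula(self, terms) -> str:
        rhs = " + ".join(list(terms) + ([self.interval_term] if self.interval_term else []))
        return f"{self.tool} ~ {rhs or '1'}"

    @property
    def numerator_formula(self) -> str:
        return self._formula(self.numerator_terms)

    @property
    def denominator_formula(self) -> str:
        return self._formula(self.denominator_terms)


@dataclass
class FittedWeightModels:
    spec: WeightModelSpec
    numerator: object
    denominator: object
    p_num: np.ndarray
    p_den: np.ndarray
    index: pd.MultiIndex  # (patient_id, interval_index) rows the fits cover


def _fit_logit(formula: str, panel: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation checked explicitly below
        res = smf.glm(formula, data=panel, family=sm.families.Binomial()).fit()
    worst = res.params.drop(labels=["Intercept"], errors="ignore").abs()
    if len(worst) and worst.max() > SEPARATION_COEF:
        raise ValueError(
            f"perfect separation suspected in exposure model term {worst.idxmax()!r} "
            f"(|coef| = {worst.max():.1f} on the logit scale)"
        )
    return res


def fit_treatment_models(panel: pd.DataFrame, spec: WeightModelSpec) -> FittedWeightModels:
    """Fit the pooled numerator and denominator exposure-probability models.

    Fails if the exposure is constant (no model identifies a probability) or a
    coefficient diverges (perfect separation). Predictions are clipped to
    (0, 1) strictly.
    """
    a = panel[spec.tool].to_numpy()
    if len(np.unique(a[~pd.isna(a)])) < 2:
        raise ValueError(
            f"exposure {spec.tool!r} is constant in the panel; "
            "treatment models are unidentifiable (complete separation)"
        )
    num = _fit_logit(spec.numerator_formula, panel)
    den = _fit_logit(spec.denominator_formula, panel)
    p_num = np.clip(np.asarray(num.fittedvalues), PROB_CLIP, 1 - PROB_CLIP)
    p_den = np.clip(np.asarray(den.fittedvalues), PROB_CLIP, 1 - PROB_CLIP)
    assert np.all((p_num > 0) & (p_num < 1)) and np.all((p_den > 0) & (p_den < 1))
    idx = pd.MultiIndex.from_frame(panel[["patient_id", "interval_index"]])
    return FittedWeightModels(spec=spec, numerator=num, denominator=den, p_num=p_num, p_den=p_den, index=idx)


def stabilized_weights(panel: pd.DataFrame, models: FittedWeightModels) -> pd.DataFrame:
    """Raw stabilized weights: per-row contribution, cumulated within patient.

    The cumulative product runs from each patient's first model-eligible
    interval through t, in interval order.
    """
    a = panel[models.spec.tool].to_numpy().astype(bool)
    num = np.where(a, models.p_num, 1 - models.p_num)
    den = np.where(a, models.p_den, 1 - models.p_den)
    out = panel[["patient_id", "interval_index"]].copy()
    out["contribution"] = num / den
    out = out.sort_values(["patient_id", "interval_index"], kind="stable")
    out["raw_w"] = out.groupby("patient_id")["contribution"].cumprod()
    assert (out["raw_w"] > 0).all()
    return out.reset_index(drop=True)


def truncate_and_normalize(
    weights: pd.DataFrame,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    col: str = "raw_w",
) -> tuple[pd.DataFrame, dict]:
    """Truncate raw weights at pooled percentiles, then normalize to mean 1.

    Percentiles use linear interpolation between order statistics (numpy's
    default); the convention is recorded in the returned metadata because the
    truncation bounds depend on it.
    """
    w = weights[col].to_numpy(dtype=float)
    if len(w) < 100:
        warnings.warn(
            f"only {len(w)} weights; {lower_pct}/{upper_pct} percentiles are "
            "interpolated from few order statistics",
            stacklevel=2,
        )
    lo, hi = np.percentile(w, [lower_pct, upper_pct], method="linear")
    out = weights.copy()
    out["trunc_w"] = np.clip(w, lo, hi)
    out["norm_w"] = out["trunc_w"] / out["trunc_w"].mean()
    meta = {
        "lower_pct": lower_pct,
        "upper_pct": upper_pct,
        "lower_bound": float(lo),
        "upper_bound": float(hi),
        "percentile_convention": "linear interpolation between order statistics",
        "prob_clip": PROB_CLIP,
        "n_weights": int(len(w)),
    }
    return out, meta


def compute_weights(
    panel: pd.DataFrame,
    spec: WeightModelSpec,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    censoring_spec: WeightModelSpec | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit, stabilize, optionally combine censoring weights, truncate, normalize.

    Returns the weight table (``raw_w``, ``trunc_w``, ``norm_w`` keyed by
    patient and interval) and metadata describing the models and conventions.
    """
    models = fit_treatment_models(panel, spec)
    w = stabilized_weights(panel, models)
    if censoring_spec is not None:
        cmod = fit_treatment_models(panel, censoring_spec)
        cw = stabilized_weights(panel, cmod)
        w = w.merge(
            cw[["patient_id", "interval_index", "raw_w"]].rename(columns={"raw_w": "raw_censor_w"}),
            on=["patient_id", "interval_index"],
        )
        w["raw_w"] = w["raw_w"] * w["raw_censor_w"]
    w, meta = truncate_and_normalize(w, lower_pct, upper_pct)
    meta.update(
        {
            "tool": spec.tool,
            "numerator_formula": spec.numerator_formula,
            "denominator_formula": spec.denominator_formula,
            "censoring": censoring_spec is not None,
        }
    )
    return w, meta


def weights_frame(weights: pd.DataFrame, tool: str, intervals) -> pd.DataFrame:
    """Shape a weight table for serialization: interval labels and the tool
    name alongside the raw/truncated/normalized columns."""
    labels = {iv.index: iv.label for iv in intervals}
    out = weights.copy()
    out["interval_label"] = out["interval_index"].map(labels)
    out["tool"] = tool
    return out[["patient_id", "interval_label", "tool", "raw_w", "trunc_w", "norm_w"]]
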