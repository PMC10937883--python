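"""Synthetic longitudinal EHR generator with known causal ground truth.

The generator emits the raw tables the pipeline consumes (patient registry,
pharmacy fills, viral-load labs, portal events, ZIP-level panel, utilization
panel) from a single structural model:

* A latent per-patient *engagement* process evolves as a bounded AR(1)
  (stationary standard normal, clipped at +/-3). Engagement drives both the
  propensity to use portal tools and all three outcomes — it is the
  time-varying confounder the weight models must remove. The pipeline sees it
  only through observable proxies (outpatient visits, housing) unless
  ``oracle_mode`` surfaces the latent value directly for exact-recovery tests.
* Tool use in interval t is Bernoulli with log-odds
  ``logit(base_rate) + confounding_strength * e_t + lag_coef * A_{t-1}``.
  The ART-refill indicator is drawn first and any-refill is its superset, so
  the subset invariant holds by construction.
* Outcomes in interval s are driven by engagement and tool use in interval
  s-1: next-interval PDC is ``pdc_base + slope * e + effect * A`` (clipped to
  [0, 1], clamp count recorded), realised by laying down two ART-class supply
  windows covering exactly the target number of days; viral-load test receipt
  and suppression are Bernoulli on planted log-odds scales, with suppression
  only *observed* when a test occurs (the pipeline's LOCF applies).

Only ``effect_tool`` carries non-null planted effects; the other four tools
are realistic correlated exposures with exactly null effects, which keeps each
per-tool estimand well defined. :func:`true_marginal_effect` computes the
marginal estimands (additive PDC difference; marginal odds ratios of the
*measured*, LOCF outcome) by Monte-Carlo g-computation under forced use
versus forced non-use.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exposures import TOOLS
from .intervals import Interval, build_intervals
from .outcomes import Roster

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "SyntheticCohort",
    "default_roster",
    "generate_cohort",
    "true_marginal_effect",
]


def default_roster() -> Roster:
    """Small fixture roster: three ART classes plus a non-ART drug."""
    return Roster(
        drug_class={
            "lamivudine": "NRTI",
            "tenofovir": "NRTI",
            "dolutegravir": "INSTI",
            "efavirenz": "NNRTI",
            "atorvastatin": "STATIN",
        },
        art_classes=frozenset({"NRTI", "INSTI", "NNRTI"}),
    )


@dataclass
class GeneratorConfig:
    """Knobs of the data-generating process. Defaults are the stated world.

    ``confounding_strength`` is the log-odds effect of engagement on exposure
    propensity; setting it to 0 severs the exposure side of confounding
    entirely. Outcome loadings on engagement are fixed slopes. Planted effects
    apply to ``effect_tool`` only.
    """

    n_patients: int = 1000
    n_intervals: int = 6
    seed: int = 0
    study_start: dt.date = dt.date(2012, 10, 1)

    effect_tool: str = "rx_refill_art"
    true_pdc_effect: float = 0.02
    true_logodds_effects: dict = field(
        default_factory=lambda: {"vl_receipt": 0.2, "vl_suppressed": 0.4}
    )

    confounding_strength: float = 1.0
    exposure_base_rate: float = 0.25
    exposure_lag_coef: float = 0.7
    engagement_ar: float = 0.7
    exposure_feedback: float = 0.0  # effect of prior effect_tool use on engagement

    pdc_base: float = 0.72
    pdc_engagement_slope: float = 0.08
    pdc_noise_sd: float = 0.10
    receipt_base_logit: float = 1.4
    receipt_engagement_slope: float = 0.6
    suppression_base_logit: float = 2.0
    suppression_engagement_slope: float = 0.8

    ipa_probability: float = 0.7
    death_hazard: float = 0.005
    boundary_entry_frac: float = 0.5
    baseline_fill_rate: float = 1.0
    baseline_lab_rate: float = 1.0
    uninterpretable_lab_rate: float = 0.03

    adi_missing_rate: float = 0.05
    race_missing_rate: float = 0.03
    rurality_missing_rate: float = 0.03
    site_missing_rate: float = 0.0

    suppression_threshold: float = 200.0
    oracle_mode: bool = False
    roster: Roster = field(default_factory=default_roster)

    def __post_init__(self):
        if self.n_intervals < 3:
            raise ValueError("n_intervals must be >= 3 (lag + next-interval outcome)")
        for name in (
            "exposure_base_rate",
            "ipa_probability",
            "death_hazard",
            "boundary_entry_frac",
            "baseline_fill_rate",
            "baseline_lab_rate",
            "uninterpretable_lab_rate",
            "adi_missing_rate",
            "race_missing_rate",
            "rurality_missing_rate",
            "site_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.effect_tool not in TOOLS:
            raise ValueError(f"effect_tool must be one of {TOOLS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["study_start"] = str(self.study_start)
        d["roster"] = {"drugs": self.roster.drug_class, "art": sorted(self.roster.art_classes)}
        return d


@dataclass
class TruthRecord:
    """Ground truth and bookkeeping for everything the pipeline recomputes."""

    config: GeneratorConfig
    engagement: np.ndarray  # (n_patients, n_intervals)
    exposures: dict  # tool -> (n_patients, n_intervals) int8
    pdc_target: np.ndarray  # (n_patients, n_intervals) realized (post-clip, quantized)
    receipt: np.ndarray
    suppressed_locf: np.ndarray  # measured LOCF status per interval
    alive_through: np.ndarray  # index of last fully observed interval per patient
    bookkeeping: dict


@dataclass
class SyntheticCohort:
    patients: pd.DataFrame
    fills: pd.DataFrame
    labs: pd.DataFrame
    portal_events: pd.DataFrame
    zip_panel: pd.DataFrame
    covariate_panel: pd.DataFrame
    truth: TruthRecord
    intervals: list

    def tables(self) -> dict:
        return {
            "patients": self.patients,
            "fills": self.fills,
            "labs": self.labs,
            "portal_events": self.portal_events,
            "zip_panel": self.zip_panel,
            "covariate_panel": self.covariate_panel,
        }

    def write_csv(self, outdir) -> None:
        import pathlib

        p = pathlib.Path(outdir)
        p.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables().items():
            tab.to_csv(p / f"{name}.csv", index=False)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def _dates(day64: np.ndarray) -> np.ndarray:
    """datetime64[D] array -> array of datetime.date objects."""
    return day64.astype("M8[D]").astype(object)


RACE_LEVELS = (
    "Black or African American",
    "White",
    "Hispanic or Latino",
    "Asian",
    "American Indian or Alaska Native",
    "Native Hawaiian or Other Pacific Islander",
)
RACE_PROBS = (0.46, 0.40, 0.08, 0.03, 0.015, 0.015)
SITES = tuple(f"V{i:02d}" for i in range(1, 9))


def _engagement_paths(cfg: GeneratorConfig, rng, n: int, a_effect: np.ndarray | None = None):
    """Bounded AR(1) engagement; optional feedback from prior effect-tool use."""
    T = cfg.n_intervals
    e = np.empty((n, T))
    e[:, 0] = rng.standard_normal(n)
    rho = cfg.engagement_ar
    for t in range(1, T):
        innov = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        e[:, t] = rho * e[:, t - 1] + innov
        if a_effect is not None and cfg.exposure_feedback:
            e[:, t] += cfg.exposure_feedback * a_effect[:, t - 1]
    return np.clip(e, -3.0, 3.0)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Simulate the raw tables; deterministic for a fixed config + seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    P, T = cfg.n_patients, cfg.n_intervals
    intervals = _study_intervals(cfg)
    iv_start = np.array([np.datetime64(iv.start) for iv in intervals])
    iv_days = np.array([iv.n_days for iv in intervals])
    pids = np.array([f"P{i:05d}" for i in range(P)])

    # --- registry ------------------------------------------------------------
    boundary = rng.random(P) < cfg.boundary_entry_frac
    reg_offset = np.where(boundary, 0, rng.integers(1, 150, P))
    reg = iv_start[0] + reg_offset.astype("m8[D]")
    has_ipa = rng.random(P) < cfg.ipa_probability
    # half of authenticators do it at the registration visit, the rest within
    # two months; authenticated tools are unusable before the IPA date
    same_day = rng.random(P) < 0.5
    ipa = reg + np.where(same_day, 0, rng.integers(1, 61, P)).astype("m8[D]")

    sex = np.where(rng.random(P) < 0.96, "Male", "Female")
    race = rng.choice(RACE_LEVELS, size=P, p=RACE_PROBS)
    race = np.where(rng.random(P) < cfg.race_missing_rate, "", race)
    age = np.clip(np.round(rng.normal(54, 11, P)), 20, 90).astype(int)
    birth_year = np.array([d.astype("M8[Y]").astype(int) + 1970 for d in reg]) - age
    years_dx = np.clip(rng.normal(9, 5, P), 0.2, 30)
    diag = reg - (years_dx * 365.25).astype(int).astype("m8[D]")
    site = rng.choice(SITES, size=P)
    site = np.where(rng.random(P) < cfg.site_missing_rate, "", site)
    nonva = (rng.random(P) < 0.3).astype(int)

    # death: geometric hazard from interval 1 on; death day uniform in-interval
    death_iv = np.full(P, -1)
    death_day = np.full(P, np.datetime64("NaT"), dtype="M8[D]")
    for t in range(1, T):
        dies = (death_iv < 0) & (rng.random(P) < cfg.death_hazard)
        death_iv[dies] = t
        death_day[dies] = iv_start[t] + rng.integers(0, iv_days[t], int(dies.sum())).astype("m8[D]")
    alive_through = np.where(death_iv < 0, T - 1, death_iv - 1)

    # --- latent engagement and exposures ------------------------------------
    e = np.empty((P, T))
    A = {tool: np.zeros((P, T), dtype=np.int8) for tool in TOOLS}
    event_offs = np.empty((P, T), dtype=np.int64)
    rho = cfg.engagement_ar
    base_logit = _logit(cfg.exposure_base_rate)
    extra_any_logit = _logit(0.08)
    for t in range(T):
        if t == 0:
            e[:, 0] = rng.standard_normal(P)
        else:
            e[:, t] = rho * e[:, t - 1] + rng.standard_normal(P) * np.sqrt(1 - rho**2)
            if cfg.exposure_feedback:
                e[:, t] += cfg.exposure_feedback * A[cfg.effect_tool][:, t - 1]
        e[:, t] = np.clip(e[:, t], -3.0, 3.0)
        ce = cfg.confounding_strength * e[:, t]
        lag = {tool: (A[tool][:, t - 1] if t else np.zeros(P)) for tool in TOOLS}
        art = rng.random(P) < _sigmoid(base_logit + ce + cfg.exposure_lag_coef * lag["rx_refill_art"])
        extra_any = rng.random(P) < _sigmoid(extra_any_logit + 0.3 * ce)
        A["rx_refill_art"][:, t] = art
        A["rx_refill_any"][:, t] = art | extra_any
        event_offs[:, t] = rng.integers(0, iv_days[t], P)
        # authenticated tools exist only from the IPA date onward
        day = iv_start[t] + event_offs[:, t].astype("m8[D]")
        accessible = has_ipa & (ipa <= day)
        for tool in ("secure_messaging", "view_appointments", "view_labs"):
            A[tool][:, t] = (
                rng.random(P) < _sigmoid(base_logit + ce + cfg.exposure_lag_coef * lag[tool])
            ) & accessible

    # --- outcomes driven by (e, A) at the prior interval ---------------------
    eff_pdc = cfg.true_pdc_effect
    eff_rec = cfg.true_logodds_effects.get("vl_receipt", 0.0)
    eff_sup = cfg.true_logodds_effects.get("vl_suppressed", 0.0)
    a_eff = A[cfg.effect_tool].astype(float)
    # outcome at interval s is driven by engagement and use at s-1 (s=0 has no
    # prior interval: engagement falls back to e[0], exposure to 0)
    e_prev = np.hstack([e[:, [0]], e[:, :-1]])
    a_prev = np.hstack([np.zeros((P, 1)), a_eff[:, :-1]])

    raw_pdc = (
        cfg.pdc_base
        + cfg.pdc_engagement_slope * e_prev
        + eff_pdc * a_prev
        + rng.normal(0, cfg.pdc_noise_sd, (P, T))
    )
    n_clamped = int(((raw_pdc < 0) | (raw_pdc > 1)).sum())
    pdc_t = np.clip(raw_pdc, 0, 1)
    covered = np.round(pdc_t * iv_days[None, :]).astype(int)
    pdc_real = covered / iv_days[None, :]

    receipt = (
        rng.random((P, T))
        < _sigmoid(cfg.receipt_base_logit + cfg.receipt_engagement_slope * e_prev + eff_rec * a_prev)
    ).astype(np.int8)
    supp_new = (
        rng.random((P, T))
        < _sigmoid(
            cfg.suppression_base_logit + cfg.suppression_engagement_slope * e_prev + eff_sup * a_prev
        )
    ).astype(np.int8)

    # baseline measures (6 months before entry)
    has_base_fill = rng.random(P) < cfg.baseline_fill_rate
    base_pdc = np.clip(
        cfg.pdc_base + cfg.pdc_engagement_slope * e[:, 0] + rng.normal(0, cfg.pdc_noise_sd, P), 0, 1
    )
    base_covered = np.maximum(1, np.round(base_pdc * 183).astype(int))
    has_base_lab = rng.random(P) < cfg.baseline_lab_rate
    base_supp = (
        rng.random(P)
        < _sigmoid(cfg.suppression_base_logit + cfg.suppression_engagement_slope * e[:, 0])
    ).astype(np.int8)

    # measured LOCF suppression status per interval (baseline feeds interval 0)
    locf = np.full((P, T), np.nan)
    last = np.where(has_base_lab, base_supp.astype(float), np.nan)
    for t in range(T):
        new = receipt[:, t] == 1
        last = np.where(new, supp_new[:, t].astype(float), last)
        locf[:, t] = last

    # --- fills ---------------------------------------------------------------
    sup_val = cfg.suppression_threshold / 4.0
    unsup_val = cfg.suppression_threshold * 10.0
    f_pid, f_drug, f_cls, f_date, f_sup = [], [], [], [], []

    def _emit_fills(mask, day64, supply, drugs):
        idx = np.where(mask)[0]
        for drug, cls in drugs:
            f_pid.append(pids[idx])
            f_drug.append(np.full(len(idx), drug))
            f_cls.append(np.full(len(idx), cls))
            f_date.append(day64[idx] if day64.shape == (P,) else np.full(len(idx), day64))
            f_sup.append(supply[idx])

    base_day = reg - np.timedelta64(183, "D")
    _emit_fills(
        has_base_fill & (base_covered > 0),
        base_day,
        base_covered,
        [("lamivudine", "NRTI"), ("dolutegravir", "INSTI")],
    )
    for t in range(T):
        obs = (covered[:, t] > 0) & (alive_through >= t - 1)  # stop new fills after death interval
        start_day = np.full(P, iv_start[t])
        _emit_fills(obs, start_day, covered[:, t], [("lamivudine", "NRTI"), ("dolutegravir", "INSTI")])
        # occasional third-class and non-ART fills; they never change the
        # >=2-class day count (see module docstring) but exercise the roster
        extra = obs & (rng.random(P) < 0.15)
        _emit_fills(extra, start_day, np.minimum(covered[:, t], 30), [("efavirenz", "NNRTI")])
        statin = obs & (rng.random(P) < 0.2)
        _emit_fills(statin, start_day, np.full(P, 90), [("atorvastatin", "STATIN")])

    fills = pd.DataFrame(
        {
            "patient_id": np.concatenate(f_pid) if f_pid else np.array([], dtype=object),
            "drug_name": np.concatenate(f_drug) if f_drug else np.array([], dtype=object),
            "drug_class": np.concatenate(f_cls) if f_cls else np.array([], dtype=object),
            "fill_date": _dates(np.concatenate(f_date)) if f_date else np.array([], dtype=object),
            "days_supply": np.concatenate(f_sup).astype(int) if f_sup else np.array([], dtype=int),
        }
    )

    # --- labs ----------------------------------------------------------------
    l_pid, l_date, l_val = [], [], []
    bmask = has_base_lab
    l_pid.append(pids[bmask])
    l_date.append((reg - np.timedelta64(30, "D"))[bmask])
    l_val.append(np.where(base_supp[bmask] == 1, sup_val, unsup_val))
    for t in range(T):
        got = (receipt[:, t] == 1) & (alive_through >= t - 1)
        day = np.full(P, iv_start[t] + np.timedelta64(int(iv_days[t] // 2), "D"))
        l_pid.append(pids[got])
        l_date.append(day[got])
        l_val.append(np.where(supp_new[got, t] == 1, sup_val, unsup_val))
        junk = (rng.random(P) < cfg.uninterpretable_lab_rate) & (alive_through >= t - 1)
        l_pid.append(pids[junk])
        l_date.append(np.full(int(junk.sum()), iv_start[t] + np.timedelta64(10, "D")))
        l_val.append(np.full(int(junk.sum()), np.nan))
    labs = pd.DataFrame(
        {
            "patient_id": np.concatenate(l_pid),
            "test_date": _dates(np.concatenate(l_date)),
            "value": np.concatenate(l_val),
        }
    )

    # --- portal events -------------------------------------------------------
    ev_pid, ev_tool, ev_date = [], [], []
    for t in range(T):
        day = iv_start[t] + event_offs[:, t].astype("m8[D]")
        for tool in TOOLS:
            used = (A[tool][:, t] == 1) & (alive_through >= t - 1)
            ev_pid.append(pids[used])
            ev_tool.append(np.full(int(used.sum()), tool))
            ev_date.append(day[used])
    portal_events = pd.DataFrame(
        {
            "patient_id": np.concatenate(ev_pid),
            "tool": np.concatenate(ev_tool),
            "event_date": _dates(np.concatenate(ev_date)),
        }
    )
    # drop any event after death
    if (death_iv >= 0).any():
        dd = pd.Series(_dates(death_day), index=pids)
        for tab, col in ((portal_events, "event_date"), (fills, "fill_date"), (labs, "test_date")):
            dts = tab["patient_id"].map(dd)
            keep = dts.isna() | (pd.to_datetime(tab[col]) < pd.to_datetime(dts))
            tab.drop(tab.index[~keep], inplace=True)
            tab.reset_index(drop=True, inplace=True)

    # --- ZIP and utilization panels ------------------------------------------
    rur_base = np.where(rng.random(P) < 0.15, "rural", "urban")
    z_rows = []
    c_rows = []
    for t in range(T):
        adi = np.round(np.clip(rng.normal(54, 21, P), 1, 100), 1)
        adi = np.where(rng.random(P) < cfg.adi_missing_rate, np.nan, adi)
        rur = np.where(rng.random(P) < cfg.rurality_missing_rate, "", rur_base)
        z_rows.append(
            pd.DataFrame(
                {
                    "patient_id": pids,
                    "interval_label": intervals[t].label,
                    "rurality": rur,
                    "adi": adi,
                }
            )
        )
        c = pd.DataFrame(
            {
                "patient_id": pids,
                "interval_index": t,
                "interval_label": intervals[t].label,
                "outpatient_visits": rng.poisson(np.exp(1.5 + 0.4 * e[:, t])),
                "hiv_outpatient_visits": rng.poisson(np.exp(0.7 + 0.3 * e[:, t])),
                "inpatient_stays": rng.poisson(np.exp(-1.5 - 0.3 * e[:, t])),
                "comorbidity_index": rng.poisson(1.6, P),
                "housed": (rng.random(P) < _sigmoid(2.0 + 0.8 * e[:, t])).astype(int),
                "depression": (rng.random(P) < 0.29).astype(int),
                "bipolar": (rng.random(P) < 0.05).astype(int),
                "psychoses": (rng.random(P) < 0.04).astype(int),
                "ptsd": (rng.random(P) < 0.11).astype(int),
                "sud": (rng.random(P) < 0.14).astype(int),
                "aud": (rng.random(P) < 0.11).astype(int),
            }
        )
        if cfg.oracle_mode:
            c["engagement"] = e[:, t]
        c_rows.append(c)
    zip_panel = pd.concat(z_rows, ignore_index=True)
    covariate_panel = pd.concat(c_rows, ignore_index=True)

    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "registration_date": _dates(reg),
            "ipa_date": [d if ok else None for d, ok in zip(_dates(ipa), has_ipa)],
            "death_date": [d if iv >= 0 else None for d, iv in zip(_dates(death_day), death_iv)],
            "sex": sex,
            "race_ethnicity": race,
            "birth_year": birth_year,
            "diagnosis_date": _dates(diag),
            "site": site,
            "nonva_care": nonva,
        }
    )

    bookkeeping = {
        "n_patients": P,
        "n_boundary_entrants": int(boundary.sum()),
        "n_with_ipa": int(has_ipa.sum()),
        "n_deaths": int((death_iv >= 0).sum()),
        "n_no_baseline_fill": int((~has_base_fill).sum()),
        "n_no_baseline_lab": int((~has_base_lab).sum()),
        "n_missing_site": int((site == "").sum()),
        "n_baseline_unsuppressed": int(((base_supp == 0) & has_base_lab).sum()),
        "n_clamped_pdc": n_clamped,
        "tool_use_person_periods": {tool: int(A[tool].sum()) for tool in TOOLS},
        "suppression_threshold": cfg.suppression_threshold,
    }
    truth = TruthRecord(
        config=cfg,
        engagement=e,
        exposures=A,
        pdc_target=pdc_real,
        receipt=receipt,
        suppressed_locf=locf,
        alive_through=alive_through,
        bookkeeping=bookkeeping,
    )
    return SyntheticCohort(
        patients=patients,
        fills=fills,
        labs=labs,
        portal_events=portal_events,
        zip_panel=zip_panel,
        covariate_panel=covariate_panel,
        truth=truth,
        intervals=intervals,
    )


def _study_intervals(cfg: GeneratorConfig) -> list[Interval]:
    start = cfg.study_start
    end = start
    for _ in range(cfg.n_intervals):
        end = dt.date(end.year + 1, 4, 1) if end.month == 10 else dt.date(end.year, 10, 1)
    return build_intervals(start, end)


def true_marginal_effect(
    config: GeneratorConfig, n_mc: int = 200_000, tools: tuple[str, ...] | None = None, seed: int | None = None
) -> dict:
    """Monte-Carlo g-computation of the per-tool marginal estimands.

    Potential outcomes are simulated under forced use versus forced non-use of
    each tool at every interval, averaged over the model outcome intervals
    (s = 2 .. T-1, matching the person-period rows the estimator pools).
    Returns, per tool: the additive PDC difference ``pdc``, and odds ratios
    ``vl_receipt_or`` / ``vl_suppressed_or`` of the measured outcomes
    (suppression includes the LOCF measurement process). Tools other than
    ``effect_tool`` have structurally null effects and are reported as such
    without simulation.
    """
    cfg = config
    if tools is None:
        tools = TOOLS
    rng = np.random.default_rng(cfg.seed + 7_654_321 if seed is None else seed)
    intervals = _study_intervals(cfg)
    iv_days = np.array([iv.n_days for iv in intervals])
    T = cfg.n_intervals
    out_ivs = np.arange(2, T)  # outcome intervals pooled by the estimator

    def _regime(force: int, rng):
        a = np.full((n_mc, T), force, dtype=float)
        e = _engagement_paths(cfg, rng, n_mc, a_effect=a)
        e_prev = np.hstack([e[:, [0]], e[:, :-1]])
        a_prev = np.hstack([np.zeros((n_mc, 1)), a[:, :-1]])
        raw = (
            cfg.pdc_base
            + cfg.pdc_engagement_slope * e_prev
            + cfg.true_pdc_effect * a_prev
            + rng.normal(0, cfg.pdc_noise_sd, (n_mc, T))
        )
        pdc = np.round(np.clip(raw, 0, 1) * iv_days[None, :]) / iv_days[None, :]
        rec = rng.random((n_mc, T)) < _sigmoid(
            cfg.receipt_base_logit
            + cfg.receipt_engagement_slope * e_prev
            + cfg.true_logodds_effects.get("vl_receipt", 0.0) * a_prev
        )
        sup = rng.random((n_mc, T)) < _sigmoid(
            cfg.suppression_base_logit
            + cfg.suppression_engagement_slope * e_prev
            + cfg.true_logodds_effects.get("vl_suppressed", 0.0) * a_prev
        )
        base_sup = rng.random(n_mc) < _sigmoid(
            cfg.suppression_base_logit + cfg.suppression_engagement_slope * e[:, 0]
        )
        locf = np.empty((n_mc, T))
        last = base_sup.astype(float)
        for t in range(T):
            last = np.where(rec[:, t], sup[:, t].astype(float), last)
            locf[:, t] = last
        return (
            pdc[:, out_ivs].mean(),
            rec[:, out_ivs].mean(),
            locf[:, out_ivs].mean(),
            pdc[:, out_ivs].std() / np.sqrt(n_mc * len(out_ivs)),
        )

    def _or(p1, p0):
        return (p1 / (1 - p1)) / (p0 / (1 - p0))

    results: dict = {}
    null = {"pdc": 0.0, "vl_receipt_or": 1.0, "vl_suppressed_or": 1.0}
    for tool in tools:
        if tool != cfg.effect_tool:
            results[tool] = dict(null)
            continue
        pdc1, rec1, sup1, se1 = _regime(1, np.random.default_rng(rng.integers(2**31)))
        pdc0, rec0, sup0, se0 = _regime(0, np.random.default_rng(rng.integers(2**31)))
        mc_se = float(np.hypot(se1, se0))
        if mc_se > 0.002:
            warnings.warn(
                f"g-computation Monte-Carlo SE {mc_se:.4f} may be too large; increase n_mc",
                stacklevel=2,
            )
        results[tool] = {
            "pdc": float(pdc1 - pdc0),
            "vl_receipt_or": float(_or(rec1, rec0)),
            "vl_suppressed_or": float(_or(sup1, sup0)),
            "mc_se_pdc": mc_se,
        }
    return results
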