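# portal-msm

Marginal structural models for the longitudinal effect of patient-portal tool
use on HIV care outcomes, built from raw EHR-style event tables.

## The problem

People living with HIV depend on sustained engagement with care: refilling
antiretroviral (ART) prescriptions, getting viral-load tests, staying
virally suppressed. Patient portals offer tools — prescription refill, secure
messaging, viewing appointments, viewing lab results — that may support that
engagement, but portal use is badly confounded: engaged patients both use the
portal more *and* do better, and engagement varies over time and responds to
past behaviour. Naive regressions of outcomes on tool use are therefore
biased. This package implements the standard causal-inference remedy for
time-varying confounding — marginal structural models (MSMs) estimated with
stabilized inverse-probability-of-treatment weights (IPTW) — as a tested,
reusable pipeline, together with a synthetic-EHR generator whose true causal
effects are known, so the whole chain can be validated end to end.

It is a library for epidemiologists and biostatisticians working from Python;
the public API plus the narrative scripts in `examples/` are the interface.

## What it computes

**Person-period cohorts.** Follow-up is discretised into fiscal half-years
(Oct 1–Apr 1, Apr 1–Oct 1). Two overlapping cohorts are built: *refill
access* (entry at portal registration, which unlocks prescription refill) and
*full access* (entry at in-person authentication, which unlocks the other
tools). Patients are screened sequentially — computable baseline adherence,
baseline site, a ZIP-level record, and for viral-load analyses a baseline
viral-load test — with every exclusion counted in a CONSORT-style ledger. A
person-period row at interval *t* enters the models only if the prior
interval supplies the 6-month-lagged exposure and interval *t+1* is fully
observed for the outcome.

**Outcomes.**

- *ART adherence* — proportion of days covered (PDC): the fraction of interval
  days with ≥ 2 distinct ART classes simultaneously on hand, from pharmacy
  fills with same-class stockpiling.
- *Viral-load test receipt* — any interpretable numeric result in the interval.
- *Viral suppression* — the most recent numeric test in the interval
  dichotomised at a threshold (default 200 copies/mL), carried forward through
  test-free intervals (LOCF).

Outcomes are measured in the interval *after* tool use.

**Weights and models.** For each tool A and person-period t, a stabilized
weight

&nbsp;&nbsp;&nbsp;&nbsp;sw<sub>it</sub> = ∏<sub>s≤t</sub>
P(A<sub>is</sub> | baseline, A<sub>i,s−1</sub>) /
P(A<sub>is</sub> | baseline, A<sub>i,s−1</sub>, L<sub>is</sub>)

is formed from two pooled logistic models (L = time-varying covariates),
truncated at the 1st/99th percentiles of the pooled raw distribution and
normalized to mean 1. The outcome MSM is a weighted generalized estimating
equation, clustered by patient with AR(1) working correlation and robust
(sandwich) standard errors, baseline-site fixed effects, and baseline
covariates: identity link for PDC (additive effects, in PDC points) and logit
link for the binary outcomes (reported as odds ratios). The default grid
fits 5 tools × 3 outcomes, each tool in its accessible cohort, plus an
exploratory suppression analysis in the baseline-unsuppressed subgroup.

## Worked example

`python examples/adherence_pdc.py` — one patient, one 182-day interval, two
stockpiled 90-day NRTI fills and one 120-day INSTI fill:

```
interval FY13H1: 2012-10-01 .. 2013-04-01 (182 days)
NRTI-covered days   180  (two 90-day fills stockpiled)
INSTI-covered days  120
days with >=2 ART classes: 120
PDC = 120/182 = 0.6593
```

Only the 120 days with *both* classes on hand count: single-class coverage is
not an ART regimen.

`python examples/full_grid_analysis.py` simulates 1,500 patients with a
planted +0.02 effect of ART-refill use on next-interval PDC (and planted
log-odds effects on the viral-load outcomes) under time-varying confounding,
fits the full grid, and compares against the generator's g-computation truth:

```
rx_refill_art, adherence:      estimate +0.0274 (truth +0.0202; additive PDC points)
rx_refill_art, suppression OR: estimate 1.4818 (g-computation truth 1.4452)
```

i.e. on this single replicate the weighted estimates land near the planted
truth (replicate studies in `tests/test_acceptance.py` quantify bias and CI
coverage), while tools with no planted effect produce intervals covering the
null.

Other examples: `simulate_cohort.py` (the generator and its bookkeeping),
`viral_load_outcomes.py` (receipt + LOCF), `build_cohort_and_weights.py`
(exclusion ledger and weight diagnostics), `tool_use_trends.py` (active-use
trend proportions).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's main artifact from scratch: it simulates a cohort
from the generator's default world at the given seed, builds all four
eligibility panels with their exclusion ledgers, estimates per-cell
stabilized truncated-normalized weights, fits the 20-cell weighted-GEE grid,
and writes `results.csv` and `provenance.json` (including the g-computation
truth for the effect-carrying tool) next to the JSON report at `--out`.
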