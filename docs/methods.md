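# Methods

This note records the statistical model the package implements, the
conventions and numerical choices it fixes, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Study design being modelled

Follow-up is a discrete-time panel of fiscal half-years (anchors October 1
and April 1; intervals are half-open `[start, end)`, so an event on April 1
belongs to the second half). Two cohorts share one registry: *refill access*
enters at portal registration; *full access* enters at in-person
authentication (IPA). The cohorts overlap — a patient who registers and later
authenticates is in the refill cohort from registration and in both from IPA.

A person-period row at interval *t* is model-eligible only when three
temporal conditions hold: (1) baseline measurements exist in the 183 days
before entry; (2) interval *t−1* is a full follow-up interval, so the
6-month-lagged exposure exists (entry on an interval boundary counts that
interval as the first full one; a gap never reaches further back than *t−1*);
(3) interval *t+1* is fully observed — person-time stops at death or the end
of the study window. Outcomes are keyed to *t+1*: adherence and test receipt
explicitly, and the LOCF suppression status is likewise taken at *t+1* so
that every modelled outcome is measured after the exposure interval.

Eligibility screening is sequential and ledgered in CONSORT order: entered in
window; computable baseline adherence (≥ 1 ART-class fill before entry — the
requirement is a *measurable* baseline PDC, not a high one); non-missing
baseline site; ≥ 1 ZIP-level record; for viral-load outcome sets, a numeric
baseline viral-load test in the 183-day pre-entry window. The ledger
satisfies `retained + Σ excluded = input` for any input. The entry window is
inclusive at both boundary dates.

## Outcome derivations

**PDC.** A day is covered when ≥ 2 distinct ART classes are simultaneously on
hand. Same-class refills stockpile: a refill during active supply begins when
the current supply ends (the Pharmacy Quality Alliance convention); supplies
of different classes are independent. Fills straddling interval boundaries
contribute only in-interval days. An eligible patient with zero coverage has
PDC 0.0, not missing. Combination products are handled through the roster: a
drug mapping to multiple classes must be listed per class.

**Test receipt.** 1 iff any test in the interval has an interpretable numeric
value; uninterpretable-only intervals are 0.

**Suppression.** Status = (most recent numeric in-interval value ≤ threshold);
the threshold defaults to 200 copies/mL, is configurable, and a value exactly
at the threshold counts as suppressed. Test-free intervals inherit the last
observed status; intervals before the first test are missing. Two tests on
the same most-recent date are resolved by input order (last record wins) with
a warning — no clinical tie-break is silently encoded.

**Exposures.** Five binary indicators (any refill, ART refill, secure
messaging, view appointments, view labs): 1 iff used at least once in the
interval. Pre-IPA intervals carry structural zeros (never missing) for the
three authenticated tools; recorded pre-IPA events are overwritten with a
warning. The refill pair satisfies `rx_refill_art ≤ rx_refill_any`.

**Covariate missingness** is deterministic: missing ADI is imputed with the
patient's all-interval mean in one pass (equivalent to imputing current,
baseline and lagged uses separately from the same average); patients with no
observed ADI at all are excluded (an extra ledger step). Missing
race/ethnicity is pooled with the small groups into "Unknown/Other"; missing
rurality becomes a per-interval "unknown" level.

## Weights

Per tool, two pooled logistic models estimate the probability of the observed
exposure: the numerator conditions on baseline covariates plus the lagged
exposure, the denominator adds the time-varying covariates; both include a
categorical interval term (standard pooled-MSM practice). The stabilized
weight is the cumulative product of per-interval ratios from the patient's
first model-eligible interval. Raw weights are truncated at the pooled
1st/99th percentiles (linear interpolation between order statistics — the
convention is recorded in output metadata because the bounds depend on it)
and then divided by their mean, so normalized weights average exactly 1.
Weights are re-fit per (tool, outcome-set, cohort) analysis.

Numerical choices: predicted probabilities are clipped to
[1e−6, 1 − 1e−6] before ratio formation; a constant exposure or a diverging
coefficient (|β| > 15 on the logit scale) raises an error naming the
offending term. In the automated grid, categorical terms with an empty
level × exposure cell are pruned before fitting (a positivity guard: such
levels separate a pooled logit exactly; this only binds in tiny subgroups).
Censoring weights are available through the same machinery ("remains
uncensored" in place of the exposure) but are off by default; when enabled
the combined weight is the product of the two raw weights, truncated after
combination.

## Outcome models

The MSM is a weighted GEE on the pooled person-period rows: clusters are
patients, working correlation AR(1) in interval order, robust sandwich
standard errors, baseline-site fixed effects (most frequent site as
reference), and baseline/time-fixed covariates. PDC uses Gaussian variance
with identity link — effects are additive, in PDC points, and predictions are
not clamped to [0, 1]; the binary outcomes use binomial variance with logit
link and are reported as odds ratios with 95% intervals symmetric on the log
scale. No multiple-comparison correction is applied; intervals are reported
for interpretation. The lagged exposure sits in the weight models only by
default (`lagged_exposure_in_outcome` switches it into the outcome model).

Engine: statsmodels GEE with case weights, maximum 50 outer iterations,
relative tolerance 1e−6. One caveat of that engine: the AR(1) dependence
parameter is estimated without the case weights (statsmodels emits a
NotImplementedWarning, which the package silences). This affects efficiency
only — the mean parameters and the sandwich variance do use the weights, and
GEE point estimates remain consistent under a misspecified working
correlation. Empirically the robust CIs achieve nominal coverage in the
package's own null-coverage study.

## The synthetic world

The generator emits the raw tables from one structural model per patient:

- *Engagement* e<sub>t</sub>: stationary AR(1) (autocorrelation 0.7, N(0,1)
  marginals, clipped at ±3) — the time-varying confounder. The pipeline sees
  it through noisy proxies (outpatient visits, housing); `oracle_mode`
  additionally exposes the latent value so estimator tests can adjust for the
  confounder exactly. An optional feedback term lets prior tool use raise
  engagement (default 0, which keeps the forced-regime g-computation estimand
  identical to the per-interval MSM estimand).
- *Tool use*: Bernoulli with log-odds `logit(0.25) + c·e_t + 0.7·A_{t−1}`,
  where c is `confounding_strength` (default 1; 0 severs confounding). The
  ART-refill draw comes first and any-refill is its superset. Authenticated
  tools are masked before the IPA date.
- *Outcomes at interval s* depend on (e<sub>s−1</sub>, A<sub>s−1</sub>):
  next-interval PDC is `0.72 + 0.08·e + β·A + N(0, 0.10²)` clipped to [0, 1]
  (clamp counts recorded; defaults keep clamping ≈ 1–2%, so the additive
  estimand is within ~2% of the planted β), realised by laying down two
  ART-class supply windows covering exactly the target day count — extra
  third-class and non-ART fills are sprinkled in because they provably cannot
  change the ≥ 2-class day count. Receipt and fresh suppression are Bernoulli
  on planted log-odds scales (baselines ≈ 80% and ≈ 88%); suppression is only
  observed when a test occurs, so the pipeline's LOCF is genuinely exercised.
- Registration is on the first interval boundary for half the patients and
  mid-interval otherwise; 70% authenticate (half at the registration visit);
  deaths follow a small per-interval hazard and truncate every event stream.

Only `effect_tool` (default ART refill) carries planted effects (defaults:
+0.02 PDC points; log-odds 0.2 for receipt and 0.4 for suppression,
conditional on engagement). The other four tools are realistic correlated
exposures with structurally null effects — this keeps every per-tool estimand
well defined; analysing several effect-carrying correlated tools one at a
time would not target the planted per-tool values.

`true_marginal_effect` defines the estimands by Monte-Carlo g-computation:
simulate forced use vs forced non-use at every interval, push potential
outcomes through the same measurement process (including LOCF), and average
over the model outcome intervals. For the binary outcomes the estimand is the
marginal odds ratio of the measured outcome — deliberately not the planted
conditional coefficient, since odds ratios are non-collapsible. Demographics
(age, sex, race, site) have no outcome effects in the generator; they are
structural realism for the covariate machinery, which also means
conditioning on them does not move the estimated OR off the marginal one.

What a green test establishes, and what it does not: the generator emulates
the *statistical structure* the estimator assumes — time-varying confounding
through a scalar latent process, correctly specified (in oracle mode) weight
models, planted effects homogeneous across patients. It does not emulate
demographic outcome disparities, multi-dimensional confounding, informative
censoring, measurement error in fills, or real VA cohort sizes; recovery on
this world validates the machinery, not the substantive findings of any real
cohort.

## Known limitations

- Real printed cohort results are not reproducible here: they require the
  underlying registry data. The package reproduces the *structure* (grid
  shape, scales, ledgers), and validates the estimator on synthetic truth.
- PDC with identity link can in principle predict outside [0, 1]; estimates
  are reported as additive contrasts, as is conventional.
- The weight models' exact covariate sets in the motivating design are not
  public; `WeightModelSpec` is fully configurable and the documented default
  (baseline + lag in the numerator, all time-varying covariates added in the
  denominator) is a standard choice.
- With observable proxies only (`oracle_weights=False`), residual
  confounding remains by construction; exact-recovery guarantees hold in
  oracle mode.
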