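"""Generate a synthetic EHR cohort and inspect its raw tables.

The generator emits the five event/registry tables the pipeline consumes plus
a utilization panel, all driven by a latent "engagement" process that
confounds portal-tool use and outcomes. The TruthRecord carries the planted
effects and bookkeeping counts that the rest of the examples check against.
"""

import portal_msm as pm

cfg = pm.GeneratorConfig(n_patients=500, seed=7)
syn = pm.generate_cohort(cfg)

for name, table in syn.tables().items():
    print(f"{name:16s} {len(table):6d} rows   columns: {', '.join(table.columns[:6])}"
          + (" ..." if len(table.columns) > 6 else ""))

bk = syn.truth.bookkeeping
print("\nplanted world:")
print(f"  effect tool              {cfg.effect_tool}")
print(f"  additive PDC effect      {cfg.true_pdc_effect:+.3f} (next-interval PDC points)")
print(f"  log-odds effects         {cfg.true_logodds_effects}")
print(f"  confounding strength     {cfg.confounding_strength} (log-odds of exposure per engagement SD)")
print("\nbookkeeping:")
print(f"  IPA-ed patients          {bk['n_with_ipa']} / {bk['n_patients']}")
print(f"  deaths during follow-up  {bk['n_deaths']}")
print(f"  unsuppressed baselines   {bk['n_baseline_unsuppressed']}")
print(f"  PDC targets clamped      {bk['n_clamped_pdc']} (outside [0,1] before clipping)")
print(f"  tool-use person-periods  {bk['tool_use_person_periods']}")
# Each count above is ground truth the pipeline must reproduce: e.g. the
# cohort module's unsuppressed subgroup should match n_baseline_unsuppressed
# when everyone enters on the interval boundary.
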