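"""Fit the complete tool x outcome marginal-structural-model grid.

Each of the five portal tools is analysed in the cohort where it is
accessible (refill tools from registration, the rest from in-person
authentication), for all three outcomes, with per-cell stabilized truncated
IPTW weights and weighted GEE (AR(1), robust SEs, site fixed effects) — plus
the exploratory suppression analysis in the baseline-unsuppressed subgroup.
The fitted contrasts are then compared with the generator's g-computation
truth.
"""

import warnings

import portal_msm as pm

cfg = pm.GeneratorConfig(n_patients=1500, seed=1, oracle_mode=True)
syn = pm.generate_cohort(cfg)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    results, provenance = pm.run_analysis_grid(syn, pm.AnalysisConfig(oracle_weights=True))

print(results.to_string(index=False, float_format=lambda x: f"{x:.4f}"))

truth = pm.true_marginal_effect(cfg, n_mc=100_000, tools=(cfg.effect_tool,))[cfg.effect_tool]
row_pdc = results.query("tool == @cfg.effect_tool and outcome == 'adherence'").iloc[0]
row_sup = results.query(
    "tool == @cfg.effect_tool and outcome == 'vl_suppression' and not cohort.str.endswith('unsuppressed')"
).iloc[0]
print(f"\n{cfg.effect_tool}, adherence:      estimate {row_pdc.estimate:+.4f} "
      f"(truth {truth['pdc']:+.4f}; additive PDC points)")
print(f"{cfg.effect_tool}, suppression OR: estimate {row_sup.estimate:.4f} "
      f"(g-computation truth {truth['vl_suppressed_or']:.4f})")
print("\nOther tools carry no planted effect: their intervals should usually cover "
      "the null (coefficient 0 / odds ratio 1).")
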