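"""Trends in portal-tool use among registered, living patients.

For each 6-month interval the active-use proportion counts patients who used
a tool on at least two separate days within the trailing year, divided by the
registrants alive at the interval's close — the definition used for
portal-adoption trend reporting.
"""

import portal_msm as pm

syn = pm.generate_cohort(pm.GeneratorConfig(n_patients=800, seed=3))
trend = pm.trend_proportions(syn.portal_events, syn.patients, syn.intervals)

wide = trend.pivot(index="interval_label", columns="tool", values="proportion")
print((100 * wide).round(1).to_string())
print("\nvalues are % of registered living patients with >=2 separate use-days "
      "in the trailing year; two uses on one day do not count")
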