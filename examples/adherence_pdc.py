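"""Proportion-of-days-covered adherence from pharmacy fills.

A day counts toward PDC only when at least two distinct antiretroviral (ART)
classes are simultaneously on hand; same-class refills during active supply
stockpile (the new supply starts when the current one runs out).
"""

import datetime as dt

import pandas as pd

import portal_msm as pm
from portal_msm.simulate import default_roster

roster = default_roster()
intervals = pm.build_intervals(dt.date(2012, 10, 1), dt.date(2013, 10, 1))
iv = intervals[0]  # FY13H1: 182 days

fills = pd.DataFrame(
    [
        # NRTI: two 90-day fills, the second picked up 30 days early -> the
        # supply stockpiles and covers days 1..180 of the interval
        {"patient_id": "P1", "drug_name": "lamivudine", "drug_class": "NRTI",
         "fill_date": iv.start, "days_supply": 90},
        {"patient_id": "P1", "drug_name": "lamivudine", "drug_class": "NRTI",
         "fill_date": iv.start + dt.timedelta(days=60), "days_supply": 90},
        # INSTI: a single 120-day fill -> both classes overlap on days 1..120
        {"patient_id": "P1", "drug_name": "dolutegravir", "drug_class": "INSTI",
         "fill_date": iv.start, "days_supply": 120},
    ]
)

nrti_days = pm.class_coverage_days(fills, iv, "NRTI", roster)
insti_days = pm.class_coverage_days(fills, iv, "INSTI", roster)
res = pm.compute_pdc(fills, iv, roster)

print(f"interval {iv.label}: {iv.start} .. {iv.end} ({iv.n_days} days)")
print(f"NRTI-covered days   {len(nrti_days)}  (two 90-day fills stockpiled)")
print(f"INSTI-covered days  {len(insti_days)}")
print(f"days with >=2 ART classes: {res.covered_days}")
print(f"PDC = {res.covered_days}/{res.interval_days} = {res.pdc:.4f}")
# Expected: NRTI 180, INSTI 120, overlap 120 -> PDC = 120/182 = 0.6593.
# A single class alone never counts: dropping the INSTI fill gives PDC 0.
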