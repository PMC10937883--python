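"""Viral-load test receipt and LOCF suppression from lab results.

Receipt is 1 in any interval with an interpretable numeric result. The
suppression status of an interval comes from its most recent numeric test
(value <= threshold, default 200 copies/mL); intervals without a test inherit
the last observed status (last observation carried forward), and intervals
before the first test are missing.
"""

import datetime as dt

import pandas as pd

import portal_msm as pm

intervals = pm.build_intervals(dt.date(2012, 10, 1), dt.date(2014, 10, 1))

labs = pd.DataFrame(
    [
        # interval 1: two tests; the later (suppressed) one decides the status
        {"patient_id": "P1", "test_date": dt.date(2013, 4, 15), "value": 12000.0},
        {"patient_id": "P1", "test_date": dt.date(2013, 8, 1), "value": 40.0},
        # interval 2: an uninterpretable result only -> receipt 0, status carried
        {"patient_id": "P1", "test_date": dt.date(2013, 11, 1), "value": None},
    ]
)

series = pm.vl_suppression_series(labs, intervals, threshold=200.0)
for iv in intervals:
    receipt = pm.vl_test_receipt(labs, iv)
    status = series[iv.index]
    pretty = {1.0: "suppressed", 0.0: "unsuppressed"}.get(status, "missing")
    print(f"{iv.label}: receipt={receipt}  suppression={pretty}")
# FY13H1 has no test yet -> missing. FY13H2 has tests on 4/15 (12000, above
# threshold) and 8/1 (40): the most recent wins -> suppressed. FY14H1's only
# result is uninterpretable, so receipt is 0 and the suppressed status is
# carried forward, as is FY14H2's.
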