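"""Score one participant by hand: z-scores, chart bins, composite.

Builds a tiny normative table and a handful of raw measurements for a
single adult, then walks them through band lookup, z-scoring, test-
score binning, domain averaging and the composite completeness rule.
"""

import numpy as np
import pandas as pd

from mmcoast import (
    NormBand,
    NormativeTable,
    Participant,
    score_participant,
    toy_charts,
)

table = NormativeTable(
    [
        NormBand("elbow_flexion", "any", 6, 80, "any", 30, 5, +1, unit="lb"),
        NormBand("wrist_extension", "any", 6, 80, "any", 25, 4, +1, unit="lb"),
        NormBand("hip_flexion", "any", 6, 80, "any", 38, 7, +1, unit="lb"),
        NormBand("ankle_dorsiflexion", "any", 6, 80, "any", 30, 6, +1, unit="lb"),
        NormBand("ninehpt", "any", 6, 80, "any", 18, 2.2, -1, unit="s"),
        NormBand("fdt", "any", 6, 80, "any", 26, 4, -1, unit="s"),
        NormBand("ts_eyes_open", "any", 6, 80, "any", 17, 2.5, +1, 20, "s"),
        NormBand("ts_eyes_closed", "any", 6, 80, "any", 13, 2.6, +1, 20, "s"),
        NormBand("sls_eyes_closed", "any", 6, 80, "any", 11, 2.7, +1, 20, "s"),
    ]
)

# two dynamometry trials per muscle (best counts), one timed trial each
rows = [
    ("p1", "elbow_flexion", "dominant", 1, np.nan, 18.0, "lb"),
    ("p1", "elbow_flexion", "dominant", 2, np.nan, 19.5, "lb"),
    ("p1", "wrist_extension", "dominant", 1, np.nan, 12.0, "lb"),
    ("p1", "hip_flexion", "dominant", 1, np.nan, 24.0, "lb"),
    ("p1", "ankle_dorsiflexion", "dominant", 1, np.nan, 21.0, "lb"),
    ("p1", "ninehpt", "dominant", 1, np.nan, 27.0, "s"),
    ("p1", "fdt", "dominant", 1, np.nan, 39.0, "s"),
    ("p1", "ts_eyes_open", "na", 1, np.nan, 8.0, "s"),
    ("p1", "ts_eyes_closed", "na", 1, np.nan, 6.0, "s"),
    ("p1", "sls_eyes_closed", "dominant", 1, np.nan, 4.0, "s"),
    # six-repetition fatigue series at the elbow: 20 lb falling to 16 lb
    *[
        ("p1", "elbow_flexion", "dominant", 1, r, f, "lb")
        for r, f in enumerate(np.linspace(20.0, 16.0, 6), start=1)
    ],
]
meas = pd.DataFrame(
    rows,
    columns=["participant_id", "assessment_id", "side", "trial_index",
             "repetition_index", "value", "unit"],
)

p = Participant("p1", age_years=34.0, sex="female")
comp, results, members = score_participant(p, meas, None, table, toy_charts())

print("per-assessment results:")
for r in sorted(results, key=lambda r: r.assessment_id):
    z = "   n/a" if r.z is None else f"{r.z:6.2f}"
    print(f"  {r.assessment_id:<28} value={r.aggregated_value:7.2f} "
          f"z={z} test_score={members.get(r.assessment_id)}")
print("\ndomain scores:", {k: v for k, v in comp.domain_scores.items()})
print(f"composite = {comp.composite:.3f} "
      f"({comp.n_domains_complete}/5 domains completed)")
print("""
Each z is (value - normative mean)/SD, sign-corrected so negative means
impaired; z < -2 is abnormal.  The fatigue row is the percent decrement
of repetition 6 vs 1 (-20 % here, abnormal beyond -13 %).  Test scores
come from the interval charts, domain scores are member means, and the
composite is the mean of completed domains (higher = more severe).
""")
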