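"""Six-minute-walk analytics: totals, percent predicted, minute slope.

Shows the three expressions of the walk test: total distance, percent
of the published prediction equation, and the mixed-effects
minute-distance slope that quantifies within-test decline.
"""

from mmcoast import (
    MCKAY_FEMALE_3_19,
    CohortSpec,
    Participant,
    WalkRecord,
    generate,
    percent_predicted,
    total_distance,
)
from mmcoast.pipeline import cohort_minute_slope

# one child's walk: distances fall off minute by minute
rec = WalkRecord("girl10", (80.0, 75.0, 72.0, 70.0, 68.0, 66.0))
total = total_distance(rec)
girl = Participant("girl10", 10.0, "female", height_cm=140.0, weight_kg=35.0)
pp = percent_predicted(total, girl, MCKAY_FEMALE_3_19)
print(f"total distance      = {total:.0f} m")
print(f"predicted (female 3-19y equation) = {pp.predicted:.1f} m")
print(f"percent predicted   = {pp.percent:.1f} %")

# cohort-level minute-distance slope from the simulator's walk model
cohort = generate(CohortSpec(), seed=3)
mm_ids = cohort.participants.query("group == 'mm'").participant_id
walks = cohort.walks[cohort.walks.participant_id.isin(mm_ids)]
fit = cohort_minute_slope(walks)
print(f"\nmyopathy cohort minute slope = {fit['slope']:.2f} m/min per minute "
      f"(p = {fit['p_value']:.3f}, n = {fit['n_participants']})")
print(f"model structure: {fit['structure']}, "
      f"residual SD = {fit['resid_var'] ** 0.5:.1f} m")
print("""
A negative slope means each successive minute covers less ground --
exercise intolerance measured without any normative table.  The fit is
a linear mixed model with participant-level random intercepts (and
slopes when supported), so within-participant correlation across the
six minutes is accounted for.
""")
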