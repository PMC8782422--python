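# Methods

This note documents the statistical model behind the package, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices a maintainer
would otherwise have to reverse-engineer.

## Normative z-scores

A raw assessment value *x* is standardised as
`z = orientation · (x − μ)/σ` against a normative band resolved by
(assessment, sex, integer age, side). Design choices:

- **Half-open age bands `[lo, hi)` matched on `floor(age)`** after the
  remap {17→16, 18→20, 19→20}. Published dynamometry norms are keyed
  by integer age (children) or decade (adults) and have no 17–19-year
  bands; flooring-then-remapping makes lookup deterministic and
  reproduces the convention of borrowing the nearest published band.
  The remap table lives in the run configuration, not in code.
- **Orientation is a column of the normative table**, not a hard-coded
  per-assessment rule, so force/count/distance tests (+1) and timed
  tests (−1) share one formula and a user can add assessments without
  touching code.
- **Abnormality is strict**: z < −2 abnormal, z = −2.0 normal. The
  same strictness applies to the fatigue cut-off (< −13 %). Boundary
  behaviour is pinned by tests so any transcription of real chart data
  inherits an explicit convention.
- **σ = 0 bands** (balance holds capped at the ceiling for whole age
  groups) make z undefined. The scoring layer carries an `sd_zero`
  marker and the composite layer scores the raw value through a
  dedicated table keyed on (assessment, sex, age band, raw interval).
- Child-versus-adult protocol differences (shoulder external rotation
  adult-only; knee extension/flexion child-only) are represented purely
  as presence/absence of bands — no code branches.
- Dynamometry is recorded in pounds; a kg↔lb constant (0.45359237)
  is provided for unit reconciliation only.

## Trial aggregation

Protocol documents for the underlying instruments are not public, so
aggregation defaults follow universal dynamometry/dexterity practice:
best (max) of repeated force/hold/count trials, best (min) time for
9HPT and FDT. The rule is overridable per assessment in configuration.

## Fatigue percent decrement

`d = 100·(F₆ − F₁)/F₁` uses only repetitions 1 and 6; longer series
are tolerated but ignored beyond those two. Strength *gains* (d > 0)
are kept unclipped because group summaries are means of signed values.
Elbow flexion is the canonical site; hip flexion shares the same
printed threshold and can be flagged with the same call. The companion
`repetition_z_pair` standardises F₁ and F₆ against the same
non-fatigued-state band: the instrument's interpretation contract is
that a normal first-repetition z with an abnormal sixth indicates
fatigable weakness rather than fixed weakness.

## Composite construction

Chart bins are **data, not code**. The main instrument's published bin
edges are figure content that cannot be shipped; the repo therefore
contains (a) a clearly synthetic toy chart used by tests and the
simulator (z ≥ −2 → 0, [−3,−2) → 1, [−4,−3) → 2, < −4 → 3, and the
analogous decrement chart with edges at −13/−26/−39) and (b) empty CSV
templates for transcribing the real instrument. Bins are lower-closed,
upper-open on the input axis; a boundary value belongs to the bin it
lower-bounds (so z = −4.0 scores 2 with the toy chart). Chart
validation checks full partition of the real line, no overlaps,
non-negative scores, and monotonicity (severity never decreases as the
input worsens).

Domain scores are means of *available* member test scores — missing
members are excluded, not imputed as zero, because the instrument
scores participants with partial data. The composite is the mean of
completed domains, reported only when ≥ 3 domains are complete
(ambulatory) or ≥ 2 (non-ambulatory); otherwise the participant is
flagged not-scorable with a reason. Domain scores are not rounded
before the composite mean. The exercise-intolerance domain uses the
walk test's z-score for chart scoring (charts are defined on z); the
minute-distance slope is reported alongside, not binned.

## Walk-test mixed model

`distance = β₀ + β₁·minute + u₀ᵢ + u₁ᵢ·minute + ε`, minutes coded 1–6
(the intercept extrapolates to "minute 0" and is reported but not
interpreted; β₁ is invariant to the coding). Estimation is REML via
statsmodels `MixedLM`, random intercept + slope by default. Numerical
policy:

- If the random-slope variance is estimated at the boundary
  (< 1e-10), non-finite, or the random-effects covariance is singular,
  the model silently refits with random intercepts only and records
  `structure="random_intercept"`.
- Perfectly noiseless data (residual variance < 1e-12 after absorbing
  participant intercepts and a common slope) short-circuits the
  iterative fit: the exact within-participant least-squares slope is
  returned with zero residual variance (`structure="noiseless"`), with
  p = 0 for a nonzero slope and p = 1 for a zero slope. In the
  balanced random-intercept case this equals the OLS slope of the
  minute means, which the tests assert in closed form.
- Per-participant slopes are β₁ plus the predicted (BLUP) random
  slope, or β₁ for all participants under the intercept-only
  structure.
- Walks stopped before six minutes are fitted as-is; the record keeps
  the minute count so downstream reports can flag them.

Only the female 3–19-year prediction equation ships with coefficients
(−54.9 + 1.1·age + 5.5·height − 2.7·weight); the equation registry CSV
accepts others, and any profile outside an equation's declared sex/age
domain sets a caution flag rather than failing — prediction equations
are known to perform poorly in myopathy cohorts either way.

## Validation statistics

- **ICC**: single-measure, two-way ANOVA mean squares. Default model
  is two-way random effects, absolute agreement (ICC(2,1)) — the
  conservative standard for test–retest designs — with the two-way
  mixed consistency variant (ICC(3,1)) exposed. Confidence limits use
  the F-distribution formulas (Satterthwaite degrees of freedom for the
  absolute model). Negative point estimates are floored at 0 and
  flagged. Known property: as a ratio of mean squares the estimator
  carries an O(1/n) downward finite-sample bias (≈ −0.02 at n = 14,
  ρ = 0.8, two occasions), which matters when averaging estimates over
  many small replicate cohorts.
- **Cronbach's α** uses sample variances; pathological item sets can
  produce α < 0 and the raw value is returned.
- **AUROC** is computed from midranks (Mann–Whitney with half-credit
  ties). Bootstrap CIs are percentile intervals from 2,000 stratified
  (within-group) resamples by default; replicates on which the
  statistic fails are dropped, and more than 50 % failures aborts with
  diagnostics. BCa was considered and rejected to keep the replicate
  count interpretation simple.
- **DeLong's test** uses placement values; a zero estimated variance
  of the AUC difference (e.g. identical markers) returns p = 1 with
  the difference reported.
- **Youden threshold**: candidate cut-points are midpoints between
  adjacent distinct scores plus sentinels beyond the extremes;
  J = sens + spec − 1 is maximised with ties broken toward higher
  specificity, then toward the specificity-favouring extreme. A
  `specificity_weight` parameter generalises J for users who want a
  specificity-weighted variant. All-identical scores return J = 0 and
  no threshold.
- **Correlations**: Pearson p-values via the t-transform; Spearman via
  the t-approximation for n > 10 and exact permutation below.
  Missingness is handled pairwise per statistic.

## Synthetic cohort generator

The generator emulates three groups — confirmed myopathy ("mm"),
symptomatic-but-unconfirmed ("unlikely"), healthy volunteers — with
per-assessment z-distributions, fatigue-decrement distributions, walk
mixed-model parameters, per-group missingness, a non-ambulatory
fraction and test–retest variance components. Defaults are transcribed
from the published group summaries (e.g. MM elbow-flexion z −2.6 ± 2.1,
healthy decrement mean −6.5 %, MM walk slope −0.9 with total distance
≈ 425 m, test–retest ICC 0.81 via σ²_b = 0.27, σ²_w = 0.0633); where a
published value is an SEM it is converted to an SD using the printed
n. The unlikely group's per-muscle strength distributions are not
published; mild impairment (z ≈ −1 ± 1.5) was chosen as clinically
realistic for a symptomatic cohort without confirmed disease.

Construction guarantees exact invertibility: z-draws are
back-transformed through the participant's own band
(`x = μ + s·z·σ`), the emitted trial set contains the target value
plus strictly worse trials so default aggregation recovers it, and the
repetition series realises the drawn decrement exactly. The retest
table is drawn directly from the variance components, so
`expected_icc(spec)` is the generator's true reliability.

What the generator does **not** emulate, and therefore what passing
tests do not show about real data:

- **Distribution shape.** All draws are normal (published summaries
  are means ± SD/SEM); real balance and dexterity scores are heavily
  skewed with ceiling effects. Draws violating physical bounds
  (non-positive force/time, value above a band ceiling) are resampled,
  which truncates the left tail — with the default synthetic norms the
  force floor sits near z = −5, so extreme-weakness tails are
  compressed and realised group means sit slightly above the nominal
  parameter. Sit-to-stand counts are left continuous rather than
  rounded to preserve exact invertibility.
- **Correlation structure.** A single latent severity factor with
  pairwise loading `factor_corr = 0.45` induces inter-assessment and
  walk-intercept correlation; 0.45 is in the middle of the moderate
  pairwise correlations the instrument's domains exhibit. The fatigue
  decrement loads on nothing, mirroring its observed independence from
  the other domains. Real data have richer, assessment-specific
  correlation; the single-factor default makes internal-consistency
  results indicative, not calibrated.
- **The healthy/myopathy decrement overlap.** With the SEM-derived
  SDs (10.1 % vs 13.7 %) the Youden objective for the decrement is
  nearly flat over a wide threshold range, so the empirical optimum
  wanders between roughly −2 % and −13 % across seeds at study-sized
  n. That is a faithful consequence of the published summary
  statistics under normality, not an estimator defect.
- The normative table shipped for simulation is synthetic (plausible
  age-shaped means, SD ≈ 10–25 % of mean, balance ceilings at 20 s);
  the licensed published tables must be transcribed by the user for
  real scoring.

## Problem sizes

The test suite runs the heavy checks at: 500 replicate retest cohorts
of 14 subjects (ICC recovery), 200 replicate walk cohorts of 50
participants (slope recovery), and 100 seeded runs of 200 + 200
participants (group-separation check); the whole suite completes in a
few minutes on one CPU. The acceptance script uses the study's own
group sizes (59/32/25) with 2,000 bootstrap replicates.

## Known limitations

- Chart bins and SD-zero score tables ship only as synthetic fixtures
  and templates; results on real cohorts depend entirely on faithful
  transcription of the licensed instrument tables.
- The ICC small-cohort bias noted above means averaged ICC estimates
  from many small studies will sit a few hundredths below the true
  reliability; single-study confidence intervals are the honest
  summary at n ≈ 14.
- `validate_cohort` computes internal consistency across all scored
  participants it is given; when groups with different severity are
  pooled, between-group separation inflates α. Restrict the input to
  the target population (as `scripts/acceptance.py` does) for an
  interpretable value.
- Non-ambulatory participants are modelled as missing all balance,
  sit-to-stand and walk assessments; the real pattern is less
  absolute.
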