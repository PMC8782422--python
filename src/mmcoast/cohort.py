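"""Synthetic cohort generator for pipeline and clinimetric testing.

No participant-level data are publicly deposited for this instrument,
so every pipeline stage is exercised against synthetic cohorts that
reproduce the *group-level* statistical structure of the clinical
study: a genetically confirmed myopathy group ("mm"), a symptomatic
but genetically unconfirmed group ("unlikely"), and a healthy-volunteer
group ("healthy").

Generation is exactly invertible by the scoring pipeline: per-
assessment z-scores are drawn from the group distribution and
back-transformed through the participant's own normative band
(``value = mean + orientation * z * sd``), six-repetition force series
realise the drawn percent decrement exactly, minute distances follow
the random-intercept/random-slope walk model, and a test-retest table
is drawn from explicit between/within variance components so the true
ICC is known by construction.

Inter-assessment correlation is induced by a single latent severity
factor per participant with loading ``sqrt(factor_corr)`` on each
z-scored assessment; the fatigue decrement deliberately loads on
nothing, mirroring the observed independence of the fatigue domain.
Draws violating physical bounds (nonpositive force or time, value
above a band ceiling) are resampled.

All randomness flows through one seeded generator: identical
``(spec, seed)`` give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .normative import NormBand, NormativeTable

#: Assessments generated as z-draws, with (unit, sidedness).
Z_ASSESSMENTS: dict[str, tuple[str, str]] = {
    "elbow_flexion": ("lb", "dominant"),
    "wrist_extension": ("lb", "dominant"),
    "hip_flexion": ("lb", "dominant"),
    "ankle_dorsiflexion": ("lb", "dominant"),
    "grasp": ("lb", "dominant"),
    "pinch": ("lb", "dominant"),
    "ts_eyes_open": ("s", "na"),
    "ts_eyes_closed": ("s", "na"),
    "sls_eyes_closed": ("s", "dominant"),
    "ninehpt": ("s", "dominant"),
    "fdt": ("s", "dominant"),
    "sts30": ("count", "na"),
}

_TIMED = {"ninehpt", "fdt"}
_BALANCE = {"ts_eyes_open", "ts_eyes_closed", "sls_eyes_closed"}

#: Assessments a non-ambulatory participant cannot complete.
_AMBULATORY_ONLY = {"sts30", "sixmwt"} | _BALANCE


@dataclass(frozen=True)
class WalkModel:
    """Random-intercept/random-slope minute-distance model parameters."""

    intercept_mean: float
    intercept_sd: float
    slope_mean: float
    slope_sd: float
    resid_sd: float


@dataclass(frozen=True)
class GroupSpec:
    """Distributional parameters for one cohort group.

    ``z`` maps assessment_id -> (mean, SD) of the z-score distribution;
    ``decrement`` is the (mean %, SD %) of the elbow-flexion fatigue
    decrement; ``walk`` parameterises the 6MWT minute-distance model.
    """

    z: Mapping[str, tuple[float, float]]
    decrement: tuple[float, float]
    walk: WalkModel
    #: per-assessment missingness overriding the cohort-level default;
    #: completion rates differ sharply by group in the clinical study
    missingness: Mapping[str, float] | None = None
    nsaa_intercept: float = 33.0
    nsaa_slope: float = -3.0  # NSAA points lost per unit of mean severity
    nsaa_sd: float = 3.0
    gdf15: tuple[float, float] = (600.0, 300.0)  # lognormal target mean/SD
    ck: tuple[float, float] = (100.0, 60.0)
    lactate: tuple[float, float] = (1.2, 0.5)


def _mm_group() -> GroupSpec:
    return GroupSpec(
        z={
            "elbow_flexion": (-2.6, 2.1),
            "wrist_extension": (-3.4, 1.7),
            "hip_flexion": (-2.5, 2.3),
            "ankle_dorsiflexion": (-2.4, 2.5),
            "grasp": (-2.1, 1.1),
            "pinch": (-2.5, 2.8),
            "ts_eyes_open": (-3.2, 8.8),
            "ts_eyes_closed": (-2.6, 2.7),
            "sls_eyes_closed": (-0.4, 1.5),
            "ninehpt": (-8.3, 11.2),
            "fdt": (-5.9, 6.0),
            "sts30": (-2.0, 0.8),
        },
        decrement=(-14.7, 10.1),
        walk=WalkModel(74.0, 12.0, -0.9, 2.5, 5.0),
        gdf15=(1655.0, 1700.0),
        ck=(162.3, 123.0),
        lactate=(2.0, 1.4),
    )


def _unlikely_group() -> GroupSpec:
    return GroupSpec(
        z={
            "elbow_flexion": (-1.0, 1.5),
            "wrist_extension": (-1.2, 1.5),
            "hip_flexion": (-1.0, 1.5),
            "ankle_dorsiflexion": (-0.9, 1.5),
            "grasp": (-0.8, 1.2),
            "pinch": (-1.0, 1.5),
            "ts_eyes_open": (-0.6, 6.1),
            "ts_eyes_closed": (-0.5, 1.4),
            "sls_eyes_closed": (0.0, 1.2),
            "ninehpt": (-2.9, 3.9),
            "fdt": (-3.1, 3.4),
            "sts30": (-1.7, 0.9),
        },
        decrement=(-20.0, 15.3),
        walk=WalkModel(87.3, 12.0, -1.39, 7.0, 5.0),
        missingness={
            "ts_eyes_open": 0.0,
            "ts_eyes_closed": 0.0,
            "ninehpt": 0.19,
            "fdt": 0.22,
            "sts30": 0.47,
            "sixmwt": 0.12,
            "decrement": 0.75,
        },
        gdf15=(525.0, 230.0),
        ck=(90.9, 54.0),
        lactate=(1.1, 0.5),
    )


def _healthy_group() -> GroupSpec:
    z = {a: (0.0, 1.0) for a in Z_ASSESSMENTS}
    return GroupSpec(
        z=z,
        decrement=(-6.5, 13.7),
        walk=WalkModel(100.0, 10.0, -0.2, 1.0, 4.0),
        missingness={a: 0.04 for a in (*Z_ASSESSMENTS, "sixmwt", "decrement")},
        gdf15=(400.0, 150.0),
        ck=(80.0, 40.0),
        lactate=(1.0, 0.4),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full parameter set driving :func:`generate`.

    Defaults reproduce the clinical study's printed group summaries
    (sample sizes, per-assessment z means/SDs, decrement means, walk
    totals and slope, test-retest reliability).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"mm": 59, "unlikely": 32, "healthy": 25}
    )
    age_lo: float = 6.0
    age_hi: float = 66.0
    male_fraction: float = 0.44
    groups: Mapping[str, GroupSpec] = field(
        default_factory=lambda: {
            "mm": _mm_group(),
            "unlikely": _unlikely_group(),
            "healthy": _healthy_group(),
        }
    )
    #: pairwise latent correlation between z-scored assessments
    factor_corr: float = 0.45
    #: per-assessment probability of missingness (whole assessment lost)
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {
            "ts_eyes_open": 0.10,
            "ts_eyes_closed": 0.10,
            "sls_eyes_closed": 0.10,
            "ninehpt": 0.10,
            "fdt": 0.25,
            "sts30": 0.30,
            "sixmwt": 0.20,
            "decrement": 0.60,
        }
    )
    non_ambulatory_fraction: float = 0.102
    #: test-retest variance components of the composite (true ICC =
    #: var_between / (var_between + var_within))
    retest_var_between: float = 0.27
    retest_var_within: float = 0.0633
    retest_n: int = 14
    retest_mean: float = 1.3
    n_trials: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.factor_corr < 1:
            raise ConfigError("factor_corr must be in [0, 1)")
        if any(p < 0 or p > 1 for p in self.missingness.values()):
            raise ConfigError("missingness probabilities must be in [0, 1]")
        if self.retest_var_between < 0 or self.retest_var_within < 0:
            raise ConfigError("retest variance components must be >= 0")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ConfigError("group sizes must be >= 0")


def expected_icc(spec: CohortSpec) -> float:
    """The generator's true test-retest ICC, by construction."""
    total = spec.retest_var_between + spec.retest_var_within
    if total == 0:
        raise ConfigError("retest variance components sum to zero")
    return spec.retest_var_between / total


# ---------------------------------------------------------------------------
# synthetic normative reference table
# ---------------------------------------------------------------------------

_AGE_BREAKS = [6.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0]

# per-assessment normative means across the age breaks above, with a
# relative SD; values are synthetic but shaped like published norms
# (strength rising through childhood then declining, children slower on
# timed dexterity).
_NORM_SHAPES: dict[str, tuple[list[float], float, int, float | None]] = {
    # assessment: (means per age bin, sd fraction of mean, orientation, ceiling)
    "elbow_flexion": ([16, 26, 36, 36, 34, 31, 28], 0.20, +1, None),
    "wrist_extension": ([10, 16, 22, 22, 21, 19, 17], 0.20, +1, None),
    "hip_flexion": ([18, 28, 38, 38, 36, 33, 30], 0.20, +1, None),
    "ankle_dorsiflexion": ([14, 22, 30, 30, 28, 26, 24], 0.20, +1, None),
    "grasp": ([25, 45, 70, 72, 70, 65, 58], 0.18, +1, None),
    "pinch": ([8, 12, 16, 16, 15, 14, 13], 0.18, +1, None),
    "ts_eyes_open": ([14, 16, 17, 17, 16, 15, 13], 0.15, +1, 20.0),
    "ts_eyes_closed": ([10, 12, 13, 13, 12, 11, 9], 0.20, +1, 20.0),
    "sls_eyes_closed": ([8, 10, 11, 11, 10, 8, 6], 0.25, +1, 20.0),
    "ninehpt": ([26, 21, 18, 18, 18.5, 19.5, 21], 0.12, -1, None),
    "fdt": ([40, 32, 26, 26, 27, 29, 32], 0.15, -1, None),
    "sts30": ([15, 17, 18, 17, 16, 14, 12], 0.15, +1, None),
    "sixmwt": ([560, 600, 620, 615, 605, 590, 570], 0.10, +1, None),
}


def default_normative_table() -> NormativeTable:
    """Synthetic full-coverage normative table, ages [6, 80), sex 'any'.

    Ships with the generator so the whole pipeline runs without the
    copyrighted published normative datasets; values are plausible but
    synthetic.
    """
    bands = []
    for aid, (means, sd_frac, orient, ceiling) in _NORM_SHAPES.items():
        unit = Z_ASSESSMENTS.get(aid, ("m", "na"))[0] if aid != "sixmwt" else "m"
        for (lo, hi), mu in zip(zip(_AGE_BREAKS, _AGE_BREAKS[1:]), means):
            bands.append(
                NormBand(
                    assessment_id=aid,
                    sex="any",
                    age_lo=lo,
                    age_hi=hi,
                    side="any",
                    norm_mean=float(mu),
                    norm_sd=round(sd_frac * mu, 4),
                    orientation=orient,
                    ceiling=ceiling,
                    unit=unit,
                )
            )
    return NormativeTable(bands)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Generated tables plus the generating truth for recovery tests."""

    participants: pd.DataFrame
    measurements: pd.DataFrame
    walks: pd.DataFrame
    retest: pd.DataFrame
    normative: NormativeTable
    truth: pd.DataFrame  # participant_id, assessment_id, z_drawn / decrement
    spec: CohortSpec
    seed: int

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.measurements.to_csv(out / "measurements.csv", index=False)
        self.walks.to_csv(out / "walks.csv", index=False)
        self.retest.to_csv(out / "retest.csv", index=False)
        self.normative.to_frame().to_csv(out / "normative.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Mu/sigma of a lognormal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_z(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    factor: float,
    loading: float,
    band: NormBand,
) -> tuple[float, float]:
    """Draw a z-score and its raw back-transform, resampling at bounds.

    The z is mean + sd * (loading*factor + sqrt(1-loading^2)*noise); a
    draw is rejected when the raw value would be nonpositive or above
    the band ceiling.  After 200 rejections the draw is clamped.
    """
    resid = math.sqrt(max(0.0, 1.0 - loading**2))
    for _ in range(200):
        z = mean + sd * (loading * factor + resid * rng.standard_normal())
        value = band.norm_mean + band.orientation * z * band.norm_sd
        ceiling_ok = band.ceiling is None or value <= band.ceiling
        if value > 0 and ceiling_ok:
            return z, value
    # pathological spec: clamp to the feasible boundary
    value = band.ceiling if (band.ceiling is not None and value > band.ceiling) else max(
        value, 1e-6
    )
    z = band.orientation * (value - band.norm_mean) / band.norm_sd
    return z, value


def generate(
    spec: CohortSpec | None = None,
    seed: int = 0,
    normative: NormativeTable | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort from a :class:`CohortSpec`.

    Returns participant, measurement, walk and retest tables in the
    exact schemas the scoring pipeline reads, the normative table used
    for back-transformation, and a truth table of drawn z-values and
    decrements for round-trip and recovery testing.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(seed)
    table = normative if normative is not None else default_normative_table()
    loading = math.sqrt(spec.factor_corr)

    participants_rows = []
    measurement_rows = []
    walk_rows = []
    truth_rows = []

    pidx = 0
    for group, n in spec.n_per_group.items():
        gspec = spec.groups[group]
        for _ in range(n):
            pid = f"{group}{pidx:04d}"
            pidx += 1
            age = float(rng.uniform(spec.age_lo, spec.age_hi))
            sex = "male" if rng.random() < spec.male_fraction else "female"
            growth = min(age, 18.0)
            height = float(110 + 3.6 * growth + rng.normal(0, 6))
            bmi = float(np.clip(rng.normal(17.5 + 0.35 * min(age, 30.0), 3.0), 12, 45))
            weight = bmi * (height / 100.0) ** 2
            non_amb = (group == "mm") and (rng.random() < spec.non_ambulatory_fraction)
            factor = float(rng.standard_normal())  # latent severity factor
            missing = dict(spec.missingness)
            if gspec.missingness is not None:
                missing.update(gspec.missingness)

            drawn_z: dict[str, float] = {}
            for aid, (unit, side) in Z_ASSESSMENTS.items():
                if non_amb and aid in _AMBULATORY_ONLY:
                    continue
                if rng.random() < missing.get(aid, 0.0):
                    continue
                mean, sd = gspec.z[aid]
                band = table.resolve_band(aid, sex, age, side)
                z, value = _draw_z(rng, mean, sd, factor, loading, band)
                drawn_z[aid] = z
                truth_rows.append(
                    {"participant_id": pid, "assessment_id": aid, "quantity": "z",
                     "value": z}
                )
                # emit trials: the target value plus strictly worse trials
                # so the default aggregation recovers the target exactly
                worse = value * (1.05 if aid in _TIMED else 0.95)
                trials = [value] + [worse] * (spec.n_trials - 1)
                for t, tv in enumerate(trials, start=1):
                    measurement_rows.append(
                        {
                            "participant_id": pid,
                            "assessment_id": aid,
                            "side": side,
                            "trial_index": t,
                            "repetition_index": "",
                            "value": tv,
                            "unit": unit,
                        }
                    )

            # fatigue repetition series: rep1 from elbow strength, rep6
            # realises the drawn decrement exactly
            if "elbow_flexion" in drawn_z and not (
                rng.random() < missing.get("decrement", 0.0)
            ):
                band = table.resolve_band("elbow_flexion", sex, age, "dominant")
                rep1 = (
                    band.norm_mean
                    + band.orientation * drawn_z["elbow_flexion"] * band.norm_sd
                )
                dmean, dsd = gspec.decrement
                dec = float(rng.normal(dmean, dsd))
                # keep rep6 physically positive
                while rep1 * (1 + dec / 100.0) <= 0:
                    dec = float(rng.normal(dmean, dsd))
                rep6 = rep1 * (1 + dec / 100.0)
                reps = np.linspace(rep1, rep6, 6)
                truth_rows.append(
                    {"participant_id": pid, "assessment_id": "elbow_flexion_decrement",
                     "quantity": "decrement", "value": dec}
                )
                for r, force in enumerate(reps, start=1):
                    measurement_rows.append(
                        {
                            "participant_id": pid,
                            "assessment_id": "elbow_flexion",
                            "side": "dominant",
                            "trial_index": 1,
                            "repetition_index": r,
                            "value": float(force),
                            "unit": "lb",
                        }
                    )

            # 6MWT minute distances from the random-intercept/slope model
            walked = not non_amb and not (
                rng.random() < missing.get("sixmwt", 0.0)
            )
            if walked:
                wm = gspec.walk
                resid_i = math.sqrt(max(0.0, 1.0 - loading**2))
                b0 = wm.intercept_mean + wm.intercept_sd * (
                    loading * factor + resid_i * rng.standard_normal()
                )
                b1 = float(rng.normal(wm.slope_mean, wm.slope_sd))
                minutes = np.arange(1, 7)
                dist = b0 + b1 * minutes + rng.normal(0, wm.resid_sd, 6)
                dist = np.clip(dist, 0.0, None)
                for m, d in zip(minutes, dist):
                    walk_rows.append(
                        {"participant_id": pid, "minute_index": int(m),
                         "distance_m": float(d)}
                    )
                truth_rows.append(
                    {"participant_id": pid, "assessment_id": "sixmwt",
                     "quantity": "slope", "value": b1}
                )

            sev_src = [
                -z for aid, z in drawn_z.items() if aid not in ("grasp", "pinch")
            ]
            severity = float(np.mean(sev_src)) if sev_src else 0.0
            nsaa = float(
                np.clip(
                    gspec.nsaa_intercept
                    + gspec.nsaa_slope * severity
                    + rng.normal(0, gspec.nsaa_sd),
                    0,
                    34,
                )
            )
            gmu, gsd = _lognormal_params(*gspec.gdf15)
            cmu, csd = _lognormal_params(*gspec.ck)
            lmu, lsd = _lognormal_params(*gspec.lactate)
            participants_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "age_years": age,
                    "sex": sex,
                    "height_cm": height,
                    "weight_kg": weight,
                    "dominant_side": "right" if rng.random() < 0.85 else "left",
                    "ambulatory": not non_amb,
                    "nsaa_total": nsaa,
                    "gdf15": float(rng.lognormal(gmu, gsd)),
                    "ck": float(rng.lognormal(cmu, csd)),
                    "lactate": float(rng.lognormal(lmu, lsd)),
                }
            )

    # test-retest composite table from explicit variance components
    retest_rows = []
    sd_b = math.sqrt(spec.retest_var_between)
    sd_w = math.sqrt(spec.retest_var_within)
    mm_ids = [r["participant_id"] for r in participants_rows if r["group"] == "mm"]
    retest_ids = mm_ids[: spec.retest_n]
    for pid in retest_ids:
        b = spec.retest_mean + sd_b * rng.standard_normal()
        for occ in (1, 2):
            retest_rows.append(
                {
                    "participant_id": pid,
                    "occasion": occ,
                    "composite": b + sd_w * rng.standard_normal(),
                }
            )

    return SyntheticCohort(
        participants=pd.DataFrame(participants_rows),
        measurements=pd.DataFrame(measurement_rows),
        walks=pd.DataFrame(walk_rows),
        retest=pd.DataFrame(retest_rows),
        normative=table,
        truth=pd.DataFrame(truth_rows),
        spec=spec,
        seed=seed,
    )
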