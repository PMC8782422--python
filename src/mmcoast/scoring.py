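"""Per-assessment analysis values from raw trial-level measurements.

Three kinds of quantity are produced here:

* aggregated trial values (best force of repeated dynamometry trials,
  best time of repeated dexterity trials, ...) standardised to z-scores
  against the normative table;
* the muscle-fatigue statistic: percent decrement of the sixth versus
  the first dynamometry repetition,
  ``100 * (rep6 - rep1) / rep1``, with < -13 % abnormal (strict) at
  elbow flexion;
* the z-scores of repetition 1 and repetition 6 against the same
  non-fatigued-state normative band, whose contrast (normal first
  repetition, abnormal sixth) is the signature of fatigable weakness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InvalidSeriesError, SDZeroError
from .normative import NormativeTable, flag_abnormal, z_score

#: Strict abnormality cut-off for elbow-flexion percent decrement.
DECREMENT_CUTOFF = -13.0

#: Default per-assessment trial aggregation rules.  ``max`` for forces,
#: counts and balance holds, ``min`` (best time) for timed dexterity.
DEFAULT_AGGREGATION: dict[str, str] = {
    "ninehpt": "min",
    "fdt": "min",
}
DEFAULT_RULE = "max"


@dataclass(frozen=True)
class Participant:
    """Demographic profile needed for normative lookup."""

    participant_id: str
    age_years: float
    sex: str
    height_cm: float | None = None
    weight_kg: float | None = None
    dominant_side: str = "right"
    ambulatory: bool = True


@dataclass(frozen=True)
class MeasurementRecord:
    """One raw observation of one trial of one assessment."""

    participant_id: str
    assessment_id: str
    side: str  # dominant | nondominant | na
    trial_index: int
    value: float
    unit: str = ""
    repetition_index: int | None = None


@dataclass(frozen=True)
class RepetitionSeries:
    """Ordered dynamometry repetition forces for the fatigue protocol.

    The canonical protocol records six repetitions; extra repetitions
    are tolerated but only repetitions 1 and 6 enter the statistic.
    """

    participant_id: str
    muscle_group: str
    side: str
    forces: tuple[float, ...]

    @property
    def rep1(self) -> float:
        return self.forces[0]

    @property
    def rep6(self) -> float:
        if len(self.forces) < 6:
            raise InvalidSeriesError(
                f"{self.participant_id}/{self.muscle_group}: "
                f"only {len(self.forces)} repetitions, need 6"
            )
        return self.forces[5]


@dataclass(frozen=True)
class AssessmentResult:
    """One scored assessment: aggregated value plus optional z."""

    participant_id: str
    assessment_id: str
    side: str
    aggregated_value: float
    z: float | None = None
    abnormal: bool | None = None
    sd_zero: bool = False
    unit: str = ""


def aggregate_trials(
    records: Sequence[MeasurementRecord] | Sequence[float],
    rule: str = "max",
) -> float:
    """Collapse trial values to one analysis value.

    Parameters
    ----------
    records : sequence of records or bare floats
    rule : {"max", "min", "mean", "first"}
        ``max`` best force/hold, ``min`` best (shortest) time,
        ``first`` single-trial assessments.
    """
    values = [
        r.value if isinstance(r, MeasurementRecord) else float(r) for r in records
    ]
    if not values:
        raise InvalidSeriesError("no trial records to aggregate")
    if rule == "max":
        return max(values)
    if rule == "min":
        return min(values)
    if rule == "mean":
        return sum(values) / len(values)
    if rule == "first":
        return values[0]
    raise ValueError(f"unknown aggregation rule {rule!r}")


def aggregation_rule(assessment_id: str, overrides: Mapping[str, str] | None = None) -> str:
    """Aggregation rule for an assessment, honouring config overrides."""
    if overrides and assessment_id in overrides:
        return overrides[assessment_id]
    return DEFAULT_AGGREGATION.get(assessment_id, DEFAULT_RULE)


def score_assessment(
    aggregated_value: float,
    participant: Participant,
    assessment_id: str,
    table: NormativeTable,
    side: str = "any",
    remap_rules: Mapping[int, int] | None = None,
) -> AssessmentResult:
    """Compose band lookup, z-scoring and abnormality flagging.

    An SD = 0 band does not raise: the result carries ``sd_zero=True``
    with ``z=None`` so the composite layer can route the raw value to
    its direct score table.  A missing band propagates
    :class:`~mmcoast.errors.NoBandError`.
    """
    band = table.resolve_band(
        assessment_id, participant.sex, participant.age_years, side, remap_rules
    )
    try:
        z = z_score(aggregated_value, band)
    except SDZeroError:
        return AssessmentResult(
            participant.participant_id,
            assessment_id,
            side,
            aggregated_value,
            z=None,
            abnormal=None,
            sd_zero=True,
            unit=band.unit,
        )
    return AssessmentResult(
        participant.participant_id,
        assessment_id,
        side,
        aggregated_value,
        z=z,
        abnormal=flag_abnormal(z),
        sd_zero=False,
        unit=band.unit,
    )


def percent_decrement(series: RepetitionSeries) -> float:
    """Fatigue statistic: percent change of repetition 6 versus 1.

    ``100 * (rep6 - rep1) / rep1``.  Negative values indicate
    fatigue-related strength loss; positive values (strength gain on
    repetition) are retained unclipped.
    """
    rep1 = series.rep1
    rep6 = series.rep6  # raises if < 6 reps
    if rep1 <= 0:
        raise InvalidSeriesError(
            f"{series.participant_id}/{series.muscle_group}: rep1 must be > 0"
        )
    return 100.0 * (rep6 - rep1) / rep1


def flag_decrement_abnormal(percent: float, cutoff: float = DECREMENT_CUTOFF) -> bool:
    """True iff the decrement is below the cut-off (strict inequality).

    The canonical cut-off of -13 % applies to elbow flexion; hip
    flexion shares the same printed threshold and may be flagged with
    the same call.
    """
    return bool(percent < cutoff)


def repetition_z_pair(
    series: RepetitionSeries,
    participant: Participant,
    table: NormativeTable,
    remap_rules: Mapping[int, int] | None = None,
) -> tuple[float, float]:
    """z-scores of repetitions 1 and 6 against the same strength band.

    Both repetitions are standardised against normative data collected
    in the non-fatigued state, so a normal z at repetition 1 with an
    abnormal z at repetition 6 demonstrates fatigable weakness.
    """
    band = table.resolve_band(
        series.muscle_group,
        participant.sex,
        participant.age_years,
        series.side,
        remap_rules,
    )
    return z_score(series.rep1, band), z_score(series.rep6, band)


def count_weak_muscles(results: Iterable[AssessmentResult]) -> int:
    """Number of distinct muscle groups with z < -2 (dominant side)."""
    weak = {
        r.assessment_id
        for r in results
        if r.z is not None and flag_abnormal(r.z)
    }
    return len(weak)
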