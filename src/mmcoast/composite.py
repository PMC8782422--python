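"""Composite severity score: chart binning, domain means, completeness.

Each scored assessment's z-score (or, for the fatigue domain, its
percent decrement) is converted to an integer test score by an ordered
interval chart; member test scores are averaged to a domain score, and
the mean of completed domain scores is the composite, with higher
values indicating greater disease severity.

Chart bins are *data*, not code: the shipped ``charts_toy.csv`` is a
synthetic fixture whose bin edges are used by the tests and the
simulator, and ``chart_template.csv`` / ``sd_zero_template.csv`` are
empty templates for users to transcribe a real instrument into.  Bins
are lower-closed, upper-open on the input axis.

Completeness: a composite is reported only when at least three domains
are completed for ambulatory participants, or at least two for
non-ambulatory participants; otherwise the participant is flagged
not-scorable with a reason.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ChartError, DataError

#: The five instrument domains and their member assessments
#: (dominant-side only where sides exist).
DEFAULT_DOMAINS: dict[str, tuple[str, ...]] = {
    "strength": (
        "elbow_flexion",
        "wrist_extension",
        "hip_flexion",
        "ankle_dorsiflexion",
    ),
    "fatigue": ("elbow_flexion_decrement",),
    "balance": ("sls_eyes_closed", "ts_eyes_open", "ts_eyes_closed"),
    "dexterity": ("ninehpt", "fdt"),
    "exercise_intolerance": ("sts30", "sixmwt_z"),
}

#: Minimum completed domains required for a composite.
MIN_DOMAINS_AMBULATORY = 3
MIN_DOMAINS_NONAMBULATORY = 2


@dataclass(frozen=True)
class ChartBin:
    """Half-open interval [lower, upper) mapped to a test score."""

    lower: float
    upper: float
    score: float


class ScoreChart:
    """Ordered interval -> score map for z-scores or percent decrements.

    Bins must partition the real line with no gaps or overlaps, carry
    non-negative scores, and be monotone: the score never increases as
    the input increases (worse performance never scores lower).
    """

    def __init__(self, chart_id: str, bins: Iterable[ChartBin], validate: bool = True):
        self.chart_id = chart_id
        self.bins = sorted(bins, key=lambda b: b.lower)
        if validate:
            violations = self.violations()
            if violations:
                raise ChartError(f"chart {chart_id}: " + "; ".join(violations))
        self._lowers = [b.lower for b in self.bins]

    def violations(self) -> list[str]:
        """All partition/monotonicity violations (empty list = valid)."""
        out: list[str] = []
        if not self.bins:
            return ["chart has no bins"]
        if self.bins[0].lower != -math.inf:
            out.append("first bin does not start at -inf")
        if self.bins[-1].upper != math.inf:
            out.append("last bin does not end at +inf")
        for a, b in zip(self.bins, self.bins[1:]):
            if a.upper < b.lower:
                out.append(f"gap between {a.upper} and {b.lower}")
            elif a.upper > b.lower:
                out.append(f"overlap between bins at {b.lower}")
        for b in self.bins:
            if not b.lower < b.upper:
                out.append(f"empty bin [{b.lower},{b.upper})")
            if b.score < 0:
                out.append(f"negative score {b.score}")
        for a, b in zip(self.bins, self.bins[1:]):
            if b.score > a.score:
                out.append(
                    f"score increases with input at {b.lower} "
                    f"({a.score} -> {b.score})"
                )
        return out

    def assign(self, value: float) -> float:
        """Test score of the unique bin containing ``value``."""
        if not math.isfinite(value):
            raise ValueError(f"chart input must be finite, got {value}")
        # rightmost bin whose lower bound <= value; bins are contiguous
        i = bisect.bisect_right(self._lowers, value) - 1
        b = self.bins[i]
        assert b.lower <= value < b.upper
        return b.score

    @property
    def min_score(self) -> float:
        return min(b.score for b in self.bins)

    @property
    def max_score(self) -> float:
        return max(b.score for b in self.bins)


def validate_chart(chart: ScoreChart) -> list[str]:
    """Return the chart's violation list (empty when valid)."""
    return chart.violations()


def load_charts(path: str | Path) -> dict[str, ScoreChart]:
    """Load charts from CSV with columns chart_id,lower,upper,score.

    Empty lower/upper fields are read as -inf/+inf.
    """
    df = pd.read_csv(path)
    required = {"chart_id", "lower", "upper", "score"}
    if not required.issubset(df.columns):
        raise DataError(f"chart file must have columns {sorted(required)}")
    charts: dict[str, ScoreChart] = {}
    for chart_id, grp in df.groupby("chart_id"):
        bins = [
            ChartBin(
                lower=-math.inf if pd.isna(r.lower) else float(r.lower),
                upper=math.inf if pd.isna(r.upper) else float(r.upper),
                score=float(r.score),
            )
            for r in grp.itertuples(index=False)
        ]
        charts[str(chart_id)] = ScoreChart(str(chart_id), bins)
    return charts


class SDZeroTable:
    """Direct raw-value score table for assessments with normative SD 0.

    Rows: assessment_id, sex, [age_lo, age_hi), [raw_value_lo,
    raw_value_hi) -> score.  Used instead of the z-score chart when a
    participant's band has SD = 0 (ceiling effects in balance norms).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {
            "assessment_id",
            "sex",
            "age_lo",
            "age_hi",
            "raw_value_lo",
            "raw_value_hi",
            "score",
        }
        if not required.issubset(frame.columns):
            raise DataError(f"SD-zero table must have columns {sorted(required)}")
        self.frame = frame

    @classmethod
    def from_csv(cls, path: str | Path) -> "SDZeroTable":
        return cls(pd.read_csv(path))

    def lookup(self, assessment_id: str, sex: str, age: float, raw_value: float) -> float:
        df = self.frame
        m = df[
            (df.assessment_id == assessment_id)
            & (df.sex.isin([sex, "any"]))
            & (df.age_lo <= age)
            & (age < df.age_hi)
            & (df.raw_value_lo <= raw_value)
            & (raw_value < df.raw_value_hi)
        ]
        if len(m) == 0:
            raise DataError(
                f"no SD-zero score row for {assessment_id}, sex={sex}, "
                f"age={age}, value={raw_value}"
            )
        if len(m) > 1:
            raise DataError(f"ambiguous SD-zero rows for {assessment_id}")
        return float(m.score.iloc[0])


def assign_test_score(value: float, chart: ScoreChart) -> float:
    """Bin a z-score or percent decrement with the given chart."""
    return chart.assign(value)


def domain_score(member_scores: Sequence[float]) -> float | None:
    """Arithmetic mean of available member test scores.

    Members without data are excluded (not imputed as 0); a domain with
    no scored members is missing (``None``).
    """
    scores = [s for s in member_scores if s is not None]
    if not scores:
        return None
    return sum(scores) / len(scores)


@dataclass
class CompositeResult:
    """Per-participant domain scores and composite severity score."""

    participant_id: str
    domain_scores: dict[str, float | None]
    n_domains_complete: int
    composite: float | None
    scorable: bool
    reason: str = ""


def composite(
    domain_scores: Mapping[str, float | None],
    ambulatory: bool,
    participant_id: str = "",
) -> CompositeResult:
    """Mean of completed domain scores, subject to the completeness rule.

    Ambulatory participants need >= 3 completed domains; non-ambulatory
    participants (unable to walk five steps independently) need >= 2.
    """
    completed = {k: v for k, v in domain_scores.items() if v is not None}
    n = len(completed)
    minimum = MIN_DOMAINS_AMBULATORY if ambulatory else MIN_DOMAINS_NONAMBULATORY
    if n < minimum:
        return CompositeResult(
            participant_id,
            dict(domain_scores),
            n,
            composite=None,
            scorable=False,
            reason=(
                f"only {n} domains completed; "
                f"{'ambulatory' if ambulatory else 'non-ambulatory'} "
                f"minimum is {minimum}"
            ),
        )
    value = sum(completed.values()) / n
    return CompositeResult(
        participant_id, dict(domain_scores), n, composite=value, scorable=True
    )
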