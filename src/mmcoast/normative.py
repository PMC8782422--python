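"""Normative reference bands and z-score standardisation.

Raw motor-assessment values (dynamometry forces, balance hold times,
dexterity completion times, sit-to-stand counts, walk distances) are
standardised against published age/sex normative data as

    z = orientation * (value - norm_mean) / norm_sd

where ``orientation`` is +1 when a larger raw value is better (forces,
hold times, counts, distances) and -1 when a smaller value is better
(timed dexterity tests).  After orientation correction a negative z
always means impairment, and z < -2 is flagged abnormal (strict
inequality: z = -2.0 exactly is classified normal).

Band lookup uses the integer part of the participant's age after an
age-remapping step: published dynamometry norms lack 17-19-year bands,
so by default 17-year-olds are scored against the 16-year band and
18/19-year-olds against the 20-year band.

Bands whose normative SD is 0 (balance holds capped at the ceiling for
entire age groups) cannot yield a z-score; :func:`z_score` raises
:class:`~mmcoast.errors.SDZeroError` and the composite layer routes such
assessments to a direct raw-value score table instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AmbiguousBandError, DataError, NoBandError, SDZeroError

#: Pounds-to-kilograms conversion for dynamometry forces; applied only
#: when a measurement and the normative table disagree on units.
KG_PER_LB = 0.45359237

#: Default integer-age remapping (no published norms for 17-19 y).
DEFAULT_AGE_REMAP: dict[int, int] = {17: 16, 18: 20, 19: 20}

#: Strict abnormality threshold on the z scale.
ABNORMAL_Z = -2.0

_NORM_COLUMNS = [
    "assessment_id",
    "sex",
    "age_lo",
    "age_hi",
    "side",
    "mean",
    "sd",
    "orientation",
    "ceiling",
    "unit",
]


@dataclass(frozen=True)
class NormBand:
    """One normative reference row.

    Attributes
    ----------
    assessment_id : str
        Identifier such as ``elbow_flexion`` or ``ninehpt``.
    sex : str
        ``"male"``, ``"female"`` or ``"any"``.
    age_lo, age_hi : float
        Half-open age interval [age_lo, age_hi) in decimal years.
    side : str
        ``"dominant"``, ``"nondominant"`` or ``"any"``.
    norm_mean, norm_sd : float
        Normative mean and SD in assessment units; ``norm_sd >= 0``.
    orientation : int
        +1 if higher raw values are better, -1 if lower are better.
    ceiling : float or None
        Maximum attainable raw value (e.g. balance hold cap), if any.
    unit : str
        Raw measurement unit (``lb``, ``s``, ``count``, ``m``).
    """

    assessment_id: str
    sex: str
    age_lo: float
    age_hi: float
    side: str
    norm_mean: float
    norm_sd: float
    orientation: int
    ceiling: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.age_lo < self.age_hi:
            raise DataError(
                f"band {self.assessment_id}: age_lo {self.age_lo} must be "
                f"< age_hi {self.age_hi}"
            )
        if self.norm_sd < 0:
            raise DataError(f"band {self.assessment_id}: negative SD")
        if self.orientation not in (+1, -1):
            raise DataError(
                f"band {self.assessment_id}: orientation must be +1 or -1"
            )
        if self.ceiling is not None and self.norm_mean > self.ceiling:
            raise DataError(
                f"band {self.assessment_id}: mean {self.norm_mean} exceeds "
                f"ceiling {self.ceiling}"
            )


def remap_age(age: float, rules: Mapping[int, int] | None = None) -> int:
    """Integer age used for band lookup, after protocol remapping.

    ``floor(age)`` is taken first, then the remap rules are applied to
    the integer age (default: 17->16, 18->20, 19->20).
    """
    if rules is None:
        rules = DEFAULT_AGE_REMAP
    iage = math.floor(age)
    return rules.get(iage, iage)


class NormativeTable:
    """A collection of :class:`NormBand` rows with lookup semantics."""

    def __init__(self, bands: Iterable[NormBand]):
        self.bands: list[NormBand] = list(bands)
        self._check_overlaps()
        self._index: dict[str, list[NormBand]] = {}
        for b in self.bands:
            self._index.setdefault(b.assessment_id, []).append(b)

    def _check_overlaps(self) -> None:
        by_key: dict[tuple, list[NormBand]] = {}
        for b in self.bands:
            by_key.setdefault((b.assessment_id, b.sex, b.side), []).append(b)
        for key, group in by_key.items():
            group = sorted(group, key=lambda b: b.age_lo)
            for a, b in zip(group, group[1:]):
                if b.age_lo < a.age_hi:
                    raise DataError(
                        f"overlapping normative bands for {key}: "
                        f"[{a.age_lo},{a.age_hi}) and [{b.age_lo},{b.age_hi})"
                    )

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormativeTable":
        df = pd.read_csv(path)
        missing = [c for c in _NORM_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"normative table missing columns: {missing}")
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormativeTable":
        bands = []
        for row in df.itertuples(index=False):
            ceiling = getattr(row, "ceiling", None)
            if ceiling is not None and (isinstance(ceiling, float) and math.isnan(ceiling)):
                ceiling = None
            bands.append(
                NormBand(
                    assessment_id=str(row.assessment_id),
                    sex=str(row.sex),
                    age_lo=float(row.age_lo),
                    age_hi=float(row.age_hi),
                    side=str(row.side),
                    norm_mean=float(row.mean),
                    norm_sd=float(row.sd),
                    orientation=int(row.orientation),
                    ceiling=None if ceiling is None else float(ceiling),
                    unit=str(getattr(row, "unit", "")),
                )
            )
        return cls(bands)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "assessment_id": b.assessment_id,
                    "sex": b.sex,
                    "age_lo": b.age_lo,
                    "age_hi": b.age_hi,
                    "side": b.side,
                    "mean": b.norm_mean,
                    "sd": b.norm_sd,
                    "orientation": b.orientation,
                    "ceiling": b.ceiling,
                    "unit": b.unit,
                }
            for b in self.bands]
        )

    def resolve_band(
        self,
        assessment_id: str,
        sex: str,
        age: float,
        side: str = "any",
        remap_rules: Mapping[int, int] | None = None,
    ) -> NormBand:
        """Return the unique band covering a participant.

        The participant's age is floored and remapped before matching
        against the half-open [age_lo, age_hi) intervals.  Bands with
        sex ``"any"`` or side ``"any"`` match any participant.

        Raises
        ------
        NoBandError
            If no band matches (missing normative coverage).
        AmbiguousBandError
            If more than one band matches (malformed table).
        """
        lookup_age = remap_age(age, remap_rules)
        matches = [
            b
            for b in self._index.get(assessment_id, ())
            if b.sex in (sex, "any")
            and b.side in (side, "any")
            and b.age_lo <= lookup_age < b.age_hi
        ]
        if not matches:
            raise NoBandError(
                f"no normative band for {assessment_id!r}, sex={sex}, "
                f"age={age} (lookup {lookup_age}), side={side}"
            )
        if len(matches) > 1:
            raise AmbiguousBandError(
                f"{len(matches)} bands match {assessment_id!r}, sex={sex}, "
                f"age={lookup_age}, side={side}"
            )
        return matches[0]


def resolve_band(
    table: NormativeTable,
    assessment_id: str,
    sex: str,
    age: float,
    side: str = "any",
    remap_rules: Mapping[int, int] | None = None,
) -> NormBand:
    """Functional wrapper around :meth:`NormativeTable.resolve_band`."""
    return table.resolve_band(assessment_id, sex, age, side, remap_rules)


def z_score(value: float, band: NormBand) -> float:
    """Orientation-corrected z-score of a raw value against a band.

    Raises :class:`SDZeroError` when the band's SD is 0 — the caller
    must route such assessments to direct chart scoring.
    """
    if band.norm_sd == 0:
        raise SDZeroError(
            f"band {band.assessment_id} [{band.age_lo},{band.age_hi}) has "
            "SD = 0; z-score undefined"
        )
    return band.orientation * (value - band.norm_mean) / band.norm_sd


def flag_abnormal(z: float) -> bool:
    """True iff z < -2 (strict); z = -2.0 exactly is normal."""
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return bool(z < ABNORMAL_Z)


def lb_to_kg(pounds: float) -> float:
    return pounds * KG_PER_LB


def kg_to_lb(kilograms: float) -> float:
    return kilograms / KG_PER_LB
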