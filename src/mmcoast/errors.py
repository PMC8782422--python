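"""Exception hierarchy for the scoring engine.

Every failure mode that a caller is expected to route on (missing
normative coverage, an SD-of-zero band, malformed configuration) gets
its own class so pipelines can degrade per-assessment instead of
aborting a whole participant.
"""


class MMCoastError(Exception):
    """Base class for all package errors."""


class NoBandError(MMCoastError):
    """No normative band covers the requested (assessment, sex, age, side)."""


class AmbiguousBandError(MMCoastError):
    """More than one normative band matches: the table is malformed."""


class SDZeroError(MMCoastError):
    """The matched band has SD = 0; a z-score is undefined.

    Callers must route the raw value to direct chart-based scoring
    instead of z-based scoring.
    """


class InvalidSeriesError(MMCoastError):
    """A repetition series is unusable (missing rep 1/6 or nonpositive rep 1)."""


class ChartError(MMCoastError):
    """A score chart failed validation (gaps, overlaps, non-monotone scores)."""


class DegenerateDataError(MMCoastError):
    """A statistic is undefined on the supplied data (e.g. zero variance)."""


class ConfigError(MMCoastError):
    """A run configuration is invalid or references missing inputs."""


class DataError(MMCoastError):
    """An input table is malformed (missing columns, unparseable rows)."""
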