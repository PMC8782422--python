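"""Six-minute walk test (6MWT) analytics.

Four complementary summaries of the 6MWT are produced:

* total distance walked in six minutes (metres);
* percent of predicted distance from a registry of published
  predictive equations (prediction = intercept + c_age*age +
  c_height*height + c_weight*weight); prediction equations perform
  poorly in myopathy cohorts, so out-of-domain use raises a caution
  flag rather than an error;
* a normative z-score of the total distance (orientation +1);
* the minute-distance slope: distance_im = b0 + b1*minute + u0_i +
  u1_i*minute + e, a linear mixed-effects model with participant-level
  random intercept and slope, fitted by REML.  The fixed slope b1 is
  the cohort's average change in distance per minute; a negative slope
  quantifies exercise intolerance without requiring normative data.

Minutes are indexed 1-6, so the intercept extrapolates to "minute 0"
and is reported but not interpreted; the slope is invariant to this
coding choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateDataError
from .normative import NormBand, NormativeTable, z_score
from .scoring import Participant

#: Residual variance below which the design is treated as noiseless and
#: the within-participant least-squares slope is returned exactly.
_NOISELESS_TOL = 1e-12


@dataclass(frozen=True)
class WalkRecord:
    """Per-minute distances for one participant's walk test."""

    participant_id: str
    minute_distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.minute_distances):
            raise DataError(f"{self.participant_id}: negative minute distance")

    @property
    def n_minutes(self) -> int:
        return len(self.minute_distances)

    @property
    def complete(self) -> bool:
        return self.n_minutes == 6


def total_distance(record: WalkRecord) -> float:
    """Total distance walked (metres): sum of minute distances."""
    if record.n_minutes == 0:
        raise DataError(f"{record.participant_id}: no minute distances")
    return float(sum(record.minute_distances))


@dataclass(frozen=True)
class PredictiveEquation:
    """A published 6MWT distance prediction equation.

    ``predicted = intercept + c_age*age_years + c_height*height_cm +
    c_weight*weight_kg`` over the declared sex/age domain.
    """

    source: str
    sex: str
    age_lo: float
    age_hi: float
    intercept: float
    c_age: float
    c_height: float
    c_weight: float

    def predict(self, age_years: float, height_cm: float, weight_kg: float) -> float:
        return (
            self.intercept
            + self.c_age * age_years
            + self.c_height * height_cm
            + self.c_weight * weight_kg
        )

    def in_domain(self, sex: str, age_years: float) -> bool:
        return self.sex in (sex, "any") and self.age_lo <= age_years < self.age_hi


#: The one equation whose coefficients are published in full here:
#: females aged 3-19 (McKay et al. normative study).
MCKAY_FEMALE_3_19 = PredictiveEquation(
    source="mckay",
    sex="female",
    age_lo=3.0,
    age_hi=20.0,
    intercept=-54.9,
    c_age=1.1,
    c_height=5.5,
    c_weight=-2.7,
)


def load_equations(path: str | Path) -> list[PredictiveEquation]:
    """Load an equation registry CSV (source,sex,age_lo,age_hi,intercept,
    c_age,c_height,c_weight)."""
    df = pd.read_csv(path)
    required = {
        "source", "sex", "age_lo", "age_hi",
        "intercept", "c_age", "c_height", "c_weight",
    }
    if not required.issubset(df.columns):
        raise DataError(f"equations file must have columns {sorted(required)}")
    return [
        PredictiveEquation(
            source=str(r.source),
            sex=str(r.sex),
            age_lo=float(r.age_lo),
            age_hi=float(r.age_hi),
            intercept=float(r.intercept),
            c_age=float(r.c_age),
            c_height=float(r.c_height),
            c_weight=float(r.c_weight),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class PercentPredicted:
    percent: float
    predicted: float
    caution: bool  # True when the profile lies outside the equation's domain


def percent_predicted(
    total: float,
    participant: Participant,
    equation: PredictiveEquation,
) -> PercentPredicted:
    """Percent of the equation-predicted distance actually walked.

    A profile outside the equation's declared sex/age domain does not
    abort the computation but sets ``caution=True`` in the output;
    prediction equations are unreliable in myopathy cohorts and should
    be interpreted with care even in-domain.
    """
    if participant.height_cm is None or participant.weight_kg is None:
        raise DataError(
            f"{participant.participant_id}: height and weight required for "
            "percent-predicted distance"
        )
    predicted = equation.predict(
        participant.age_years, participant.height_cm, participant.weight_kg
    )
    if predicted <= 0:
        raise DataError(
            f"equation {equation.source} predicts nonpositive distance for "
            f"{participant.participant_id}"
        )
    caution = not equation.in_domain(participant.sex, participant.age_years)
    return PercentPredicted(100.0 * total / predicted, predicted, caution)


def walk_z(
    total: float,
    participant: Participant,
    table: NormativeTable,
    assessment_id: str = "sixmwt",
    remap_rules: Mapping[int, int] | None = None,
) -> float:
    """Normative z-score of the total walk distance (orientation +1)."""
    band = table.resolve_band(
        assessment_id, participant.sex, participant.age_years, "any", remap_rules
    )
    return z_score(total, band)


@dataclass
class SlopeFit:
    """Result of the minute-distance mixed-model fit."""

    slope: float  # cohort fixed slope, m/min per minute index
    intercept: float
    p_value: float  # Wald test of slope = 0
    participant_slopes: dict[str, float]
    var_intercept: float  # between-participant intercept variance
    var_slope: float  # between-participant slope variance (0 if absent)
    resid_var: float
    structure: str  # random_slope | random_intercept | noiseless


def _within_participant_ols(df: pd.DataFrame) -> tuple[float, float, float]:
    """Common slope after absorbing participant intercepts.

    Returns (slope, mean intercept, residual SSE).  This is the exact
    fixed-effects estimator; it is also the degenerate-limit answer
    when residual noise is zero.
    """
    x = df["minute"].to_numpy(float)
    y = df["distance"].to_numpy(float)
    groups = df["participant_id"].to_numpy()
    xd = x.copy()
    yd = y.copy()
    for g in np.unique(groups):
        m = groups == g
        xd[m] -= x[m].mean()
        yd[m] -= y[m].mean()
    sxx = float(xd @ xd)
    if sxx == 0:
        raise DegenerateDataError("all minute indices identical; slope undefined")
    slope = float(xd @ yd) / sxx
    resid = yd - slope * xd
    sse = float(resid @ resid)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept, sse


def minute_slope(
    records: Sequence[WalkRecord] | pd.DataFrame,
    random_slope: bool = True,
) -> SlopeFit:
    """Fit the minute-distance linear mixed-effects model.

    Parameters
    ----------
    records : sequence of WalkRecord, or a long DataFrame with columns
        participant_id, minute, distance.
    random_slope : bool
        Fit participant-level random slopes in addition to random
        intercepts (default).  The model falls back to
        random-intercept-only when the random-slope variance is
        estimated at the boundary or the fit fails to converge.

    Notes
    -----
    Perfectly noiseless data (zero residual after absorbing participant
    intercepts and a common slope) short-circuits the iterative fit and
    returns the exact least-squares slope with zero residual variance.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if isinstance(records, pd.DataFrame):
        df = records[["participant_id", "minute", "distance"]].copy()
    else:
        rows = [
            {"participant_id": r.participant_id, "minute": i + 1, "distance": d}
            for r in records
            for i, d in enumerate(r.minute_distances)
        ]
        df = pd.DataFrame(rows)
    if df["participant_id"].nunique() < 2:
        raise DegenerateDataError("need >= 2 participants for the mixed model")
    if df.groupby("participant_id")["minute"].count().min() < 2:
        raise DegenerateDataError("each participant needs >= 2 minute distances")

    slope0, intercept0, sse = _within_participant_ols(df)
    n = len(df)
    if sse / n < _NOISELESS_TOL:
        # exact recovery: every participant lies on a line with the
        # common slope; intercept heterogeneity is absorbed exactly
        per_part = {
            str(g): slope0 for g in df["participant_id"].unique()
        }
        inter_var = float(
            np.var(
                df.groupby("participant_id")
                .apply(
                    lambda d: d["distance"].mean() - slope0 * d["minute"].mean(),
                    include_groups=False,
                )
                .to_numpy(),
                ddof=0,
            )
        )
        return SlopeFit(
            slope=slope0,
            intercept=intercept0,
            p_value=0.0 if slope0 != 0 else 1.0,
            participant_slopes=per_part,
            var_intercept=inter_var,
            var_slope=0.0,
            resid_var=0.0,
            structure="noiseless",
        )

    endog = df["distance"].to_numpy(float)
    exog = sm.add_constant(df["minute"].to_numpy(float))
    groups = df["participant_id"].to_numpy()

    def _fit(re_formula_cols: np.ndarray, structure: str):
        model = sm.MixedLM(endog, exog, groups=groups, exog_re=re_formula_cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(reml=True, method=["lbfgs", "powell"])
        return model, res

    structure = "random_slope"
    res = None
    if random_slope:
        try:
            model, res = _fit(exog, "random_slope")
            cov = np.asarray(res.cov_re)
            var_slope = float(cov[1, 1])
            # boundary or singular estimate -> random intercept only
            if (
                not np.isfinite(var_slope)
                or var_slope < 1e-10
                or np.linalg.det(cov) <= 0
            ):
                res = None
        except (np.linalg.LinAlgError, ValueError):
            res = None
    if res is None:
        structure = "random_intercept"
        model, res = _fit(exog[:, :1], "random_intercept")

    beta0, beta1 = float(res.params[0]), float(res.params[1])
    p_value = float(res.pvalues[1])
    participant_slopes = {}
    for g, eff in res.random_effects.items():
        vals = np.asarray(eff, dtype=float)
        b1 = float(vals[1]) if structure == "random_slope" and len(vals) > 1 else 0.0
        participant_slopes[str(g)] = beta1 + b1
    cov_re = np.asarray(res.cov_re)
    var_intercept = float(cov_re[0, 0])
    var_slope = float(cov_re[1, 1]) if structure == "random_slope" else 0.0
    return SlopeFit(
        slope=beta1,
        intercept=beta0,
        p_value=p_value,
        participant_slopes=participant_slopes,
        var_intercept=var_intercept,
        var_slope=var_slope,
        resid_var=float(res.scale),
        structure=structure,
    )
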