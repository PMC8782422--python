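"""End-to-end orchestration: raw tables -> composite report -> validation.

``score_cohort`` runs every participant through band lookup,
z-scoring, fatigue-decrement computation, chart binning, domain
averaging and the completeness rule, producing the composite report
and a per-assessment z table.  A participant failing one assessment
(e.g. missing normative coverage) still scores all others.

``validate_cohort`` runs the clinimetric battery on a composite report:
test-retest ICC, Cronbach's alpha across the five domain scores,
correlations with the external functional scale and biomarkers, and
ROC blocks (AUROC with stratified-bootstrap CI, DeLong comparisons,
Youden threshold) for the composite and the biomarkers.  Every
stochastic quantity records its seed in the report.
"""

from __future__ import annotations

import json
import logging

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import clinimetrics as cm
from .composite import (
    DEFAULT_DOMAINS,
    CompositeResult,
    ScoreChart,
    SDZeroTable,
    composite,
    domain_score,
    load_charts,
)
from .errors import DataError, DegenerateDataError, NoBandError
from .normative import NormativeTable
from .scoring import (
    AssessmentResult,
    Participant,
    RepetitionSeries,
    aggregate_trials,
    aggregation_rule,
    percent_decrement,
    score_assessment,
)
from .walk import WalkRecord, minute_slope, total_distance, walk_z

log = logging.getLogger("mmcoast")

_PARTICIPANT_COLS = {"participant_id", "age_years", "sex"}
_MEASUREMENT_COLS = {
    "participant_id", "assessment_id", "side", "trial_index", "value",
}
_WALK_COLS = {"participant_id", "minute_index", "distance_m"}

#: composite members scored from z-charts; the fatigue member uses the
#: percent-decrement chart instead
_Z_MEMBERS = {
    m for members in DEFAULT_DOMAINS.values() for m in members
} - {"elbow_flexion_decrement", "sixmwt_z"}


def toy_charts() -> dict[str, ScoreChart]:
    """The synthetic score charts shipped for tests and simulation."""
    with resources.as_file(
        resources.files("mmcoast.data") / "charts_toy.csv"
    ) as p:
        return load_charts(p)


def toy_sd_zero_table() -> SDZeroTable:
    """The synthetic SD-zero direct-score table shipped for tests."""
    with resources.as_file(
        resources.files("mmcoast.data") / "sd_zero_toy.csv"
    ) as p:
        return SDZeroTable.from_csv(p)


@dataclass
class ScoreReport:
    composite_report: pd.DataFrame
    z_table: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.composite_report.to_csv(out / "composite_report.csv", index=False)
        self.z_table.to_csv(out / "z_table.csv", index=False)
        payload = self.composite_report.to_dict(orient="records")
        (out / "composite_report.json").write_text(
            json.dumps(payload, indent=2, allow_nan=True) + "\n"
        )


def _participant_from_row(row: Any) -> Participant:
    return Participant(
        participant_id=str(row.participant_id),
        age_years=float(row.age_years),
        sex=str(row.sex),
        height_cm=float(row.height_cm) if hasattr(row, "height_cm") else None,
        weight_kg=float(row.weight_kg) if hasattr(row, "weight_kg") else None,
        dominant_side=str(getattr(row, "dominant_side", "right")),
        ambulatory=bool(getattr(row, "ambulatory", True)),
    )


def _require_columns(df: pd.DataFrame, required: set[str], name: str) -> None:
    missing = sorted(required - set(df.columns))
    if missing:
        raise DataError(f"{name} table is missing columns: {missing}")


def score_participant(
    participant: Participant,
    measurements: pd.DataFrame,
    walk: WalkRecord | None,
    normative: NormativeTable,
    charts: Mapping[str, ScoreChart],
    sd_zero_table: SDZeroTable | None = None,
    aggregation_overrides: Mapping[str, str] | None = None,
    remap_rules: Mapping[int, int] | None = None,
) -> tuple[CompositeResult, list[AssessmentResult], dict[str, float]]:
    """Score one participant.

    Returns the composite result, per-assessment z results, and the
    member test scores that fed the domains.
    """
    chart_z = charts["zscore_chart_A"]
    chart_dec = charts["decrement_chart_B"]
    results: list[AssessmentResult] = []
    member_scores: dict[str, float] = {}

    is_rep = measurements["repetition_index"].notna() & (
        measurements["repetition_index"].astype(str).str.strip() != ""
    )
    trials = measurements[~is_rep]
    reps = measurements[is_rep]

    for aid, grp in trials.groupby("assessment_id"):
        if aid not in _Z_MEMBERS and aid not in ("grasp", "pinch"):
            continue
        sided = grp[grp["side"].isin(["dominant", "na", "any"])]
        if sided.empty:
            continue
        rule = aggregation_rule(str(aid), aggregation_overrides)
        value = aggregate_trials(sided["value"].tolist(), rule)
        side = str(sided["side"].iloc[0])
        try:
            res = score_assessment(
                value, participant, str(aid), normative, side, remap_rules
            )
        except NoBandError:
            log.info(
                "%s/%s: no normative band; assessment skipped",
                participant.participant_id, aid,
            )
            continue
        results.append(res)
        if aid not in _Z_MEMBERS:
            continue
        if res.sd_zero:
            if sd_zero_table is None:
                log.info(
                    "%s/%s: SD-zero band and no direct score table; skipped",
                    participant.participant_id, aid,
                )
                continue
            member_scores[str(aid)] = sd_zero_table.lookup(
                str(aid), participant.sex, participant.age_years, value
            )
            log.info(
                "%s/%s: SD-zero band, scored from raw value %.3g",
                participant.participant_id, aid, value,
            )
        else:
            member_scores[str(aid)] = chart_z.assign(res.z)

    # fatigue: dominant elbow-flexion repetition series
    elbow_reps = reps[
        (reps["assessment_id"] == "elbow_flexion")
        & (reps["side"].isin(["dominant", "na", "any"]))
    ].copy()
    if len(elbow_reps) >= 6:
        elbow_reps["repetition_index"] = elbow_reps["repetition_index"].astype(
            float
        )
        elbow_reps = elbow_reps.sort_values("repetition_index")
        series = RepetitionSeries(
            participant.participant_id,
            "elbow_flexion",
            "dominant",
            tuple(float(v) for v in elbow_reps["value"]),
        )
        dec = percent_decrement(series)
        member_scores["elbow_flexion_decrement"] = chart_dec.assign(dec)
        results.append(
            AssessmentResult(
                participant.participant_id,
                "elbow_flexion_decrement",
                "dominant",
                dec,
                z=None,
                abnormal=None,
                unit="%",
            )
        )

    # walk: total distance -> normative z -> z chart
    if walk is not None and walk.n_minutes > 0:
        total = total_distance(walk)
        try:
            z = walk_z(total, participant, normative, remap_rules=remap_rules)
        except NoBandError:
            z = None
        if z is not None:
            member_scores["sixmwt_z"] = chart_z.assign(z)
            results.append(
                AssessmentResult(
                    participant.participant_id,
                    "sixmwt_z",
                    "na",
                    total,
                    z=z,
                    abnormal=z < -2.0,
                    unit="m",
                )
            )

    domains = {
        d: domain_score([member_scores.get(m) for m in members])
        for d, members in DEFAULT_DOMAINS.items()
    }
    comp = composite(domains, participant.ambulatory, participant.participant_id)
    return comp, results, member_scores


def score_cohort(
    participants: pd.DataFrame,
    measurements: pd.DataFrame,
    walks: pd.DataFrame | None,
    normative: NormativeTable,
    charts: Mapping[str, ScoreChart] | None = None,
    sd_zero_table: SDZeroTable | None = None,
    aggregation_overrides: Mapping[str, str] | None = None,
    remap_rules: Mapping[int, int] | None = None,
) -> ScoreReport:
    """Score every participant in a cohort. Deterministic given inputs."""
    _require_columns(participants, _PARTICIPANT_COLS, "participants")
    if len(measurements) > 0:
        _require_columns(measurements, _MEASUREMENT_COLS, "measurements")
    if walks is not None and len(walks) > 0:
        _require_columns(walks, _WALK_COLS, "walks")
    if charts is None:
        charts = toy_charts()
    if "repetition_index" not in measurements.columns:
        measurements = measurements.assign(repetition_index=np.nan)

    meas_by_pid = dict(tuple(measurements.groupby("participant_id")))
    walks_by_pid: dict[str, WalkRecord] = {}
    if walks is not None and len(walks) > 0:
        for pid, grp in walks.groupby("participant_id"):
            grp = grp.sort_values("minute_index")
            walks_by_pid[str(pid)] = WalkRecord(
                str(pid), tuple(float(d) for d in grp["distance_m"])
            )

    comp_rows = []
    z_rows = []
    empty = measurements.iloc[0:0]
    for row in participants.itertuples(index=False):
        p = _participant_from_row(row)
        meas = meas_by_pid.get(p.participant_id, empty)
        comp, results, members = score_participant(
            p,
            meas,
            walks_by_pid.get(p.participant_id),
            normative,
            charts,
            sd_zero_table,
            aggregation_overrides,
            remap_rules,
        )
        comp_rows.append(
            {
                "participant_id": p.participant_id,
                **{d: comp.domain_scores[d] for d in DEFAULT_DOMAINS},
                "n_domains_complete": comp.n_domains_complete,
                "composite": comp.composite,
                "scorable": comp.scorable,
                "reason": comp.reason,
            }
        )
        for r in results:
            z_rows.append(
                {
                    "participant_id": r.participant_id,
                    "assessment_id": r.assessment_id,
                    "side": r.side,
                    "aggregated_value": r.aggregated_value,
                    "z": r.z,
                    "abnormal": r.abnormal,
                    "sd_zero": r.sd_zero,
                    "test_score": members.get(r.assessment_id),
                }
            )
    comp_df = pd.DataFrame(comp_rows)
    z_cols = [
        "participant_id", "assessment_id", "side", "aggregated_value",
        "z", "abnormal", "sd_zero", "test_score",
    ]
    z_df = pd.DataFrame(z_rows, columns=z_cols)
    return ScoreReport(comp_df, z_df)


# ---------------------------------------------------------------------------
# validation battery
# ---------------------------------------------------------------------------


def validate_cohort(
    composite_report: pd.DataFrame,
    participants: pd.DataFrame,
    retest: pd.DataFrame | None = None,
    group_column: str = "group",
    positive_group: str = "mm",
    reference_group: str = "unlikely",
    biomarkers: tuple[str, ...] = ("gdf15", "ck", "lactate"),
    external_scale: str = "nsaa_total",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, Any]:
    """Run the clinimetric validation battery on a scored cohort.

    A statistic whose data requirements are not met is skipped with a
    reason rather than aborting the run.
    """
    report: dict[str, Any] = {"seed": seed, "n_boot": n_boot}
    merged = composite_report.merge(participants, on="participant_id", how="left")
    scored = merged[merged["composite"].notna()]

    # --- test-retest reliability -----------------------------------------
    if retest is not None and len(retest) > 0:
        wide = retest.pivot(
            index="participant_id", columns="occasion", values="composite"
        ).dropna()
        if len(wide) >= 2 and wide.shape[1] >= 2:
            try:
                r = cm.icc(wide.to_numpy())
                report["icc"] = {
                    "icc": r.icc, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
                    "model": r.model, "n": int(len(wide)),
                }
            except DegenerateDataError as e:
                report["icc"] = {"skipped": str(e)}
        else:
            report["icc"] = {"skipped": "need >= 2 subjects with 2 occasions"}

    # --- internal consistency across the five domains --------------------
    domain_cols = list(DEFAULT_DOMAINS)
    items = scored[domain_cols].dropna()
    if len(items) >= 3:
        try:
            report["cronbach_alpha"] = {
                "alpha": cm.cronbach_alpha(items.to_numpy()),
                "n": int(len(items)),
                "k_items": len(domain_cols),
            }
        except DegenerateDataError as e:
            report["cronbach_alpha"] = {"skipped": str(e)}
    else:
        report["cronbach_alpha"] = {
            "skipped": f"only {len(items)} complete five-domain cases"
        }

    # --- correlations with the external scale and biomarkers -------------
    correlations: dict[str, Any] = {}
    for col, method in [(external_scale, "pearson")] + [
        (b, "spearman") for b in biomarkers
    ]:
        if col not in scored.columns:
            correlations[col] = {"skipped": "column absent"}
            continue
        x = scored["composite"].to_numpy(float)
        y = scored[col].to_numpy(float)
        try:
            r, p = cm.correlate(x, y, method)
            correlations[col] = {
                "r": r, "p": p, "method": method,
                "n": int((np.isfinite(x) & np.isfinite(y)).sum()),
            }
        except DegenerateDataError as e:
            correlations[col] = {"skipped": str(e)}
    report["correlations"] = correlations

    # --- discrimination: composite and biomarker ROC blocks --------------
    if group_column in scored.columns:
        two = scored[scored[group_column].isin([positive_group, reference_group])]
        labels = (two[group_column] == positive_group).to_numpy()
        roc_blocks: dict[str, Any] = {}
        delong_scores: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        for name, col in [("composite", "composite")] + [
            (b, b) for b in biomarkers
        ]:
            if col not in two.columns:
                roc_blocks[name] = {"skipped": "column absent"}
                continue
            s = two[col].to_numpy(float)
            ok = np.isfinite(s)
            if labels[ok].sum() == 0 or (~labels[ok]).sum() == 0:
                roc_blocks[name] = {"skipped": "a group is empty"}
                continue
            try:
                r = cm.roc_with_ci(
                    s[ok], labels[ok], higher_is_positive=True,
                    n_boot=n_boot, seed=rng,
                )
            except DegenerateDataError as e:
                roc_blocks[name] = {"skipped": str(e)}
                continue
            roc_blocks[name] = {
                "auc": r.auc, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
                "n_boot": r.n_boot, "threshold": r.threshold,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
                "n": int(ok.sum()),
            }
            delong_scores[name] = np.where(ok, s, np.nan)
        pairs = {}
        names = list(delong_scores)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                sa, sb = delong_scores[a], delong_scores[b]
                ok = np.isfinite(sa) & np.isfinite(sb)
                if labels[ok].sum() == 0 or (~labels[ok]).sum() == 0:
                    continue
                diff, p = cm.delong_compare(sa[ok], sb[ok], labels[ok])
                pairs[f"{a}_vs_{b}"] = {"auc_diff": diff, "p": p}
        report["roc"] = roc_blocks
        report["delong"] = pairs

    return report


def write_validation_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def cohort_minute_slope(walks: pd.DataFrame, **kwargs) -> dict[str, Any]:
    """Convenience wrapper: long walks table -> mixed-model slope block."""
    df = walks.rename(columns={"minute_index": "minute", "distance_m": "distance"})
    fit = minute_slope(df[["participant_id", "minute", "distance"]], **kwargs)
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "p_value": fit.p_value,
        "structure": fit.structure,
        "var_intercept": fit.var_intercept,
        "var_slope": fit.var_slope,
        "resid_var": fit.resid_var,
        "n_participants": len(fit.participant_slopes),
    }
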