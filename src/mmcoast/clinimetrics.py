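"""Reliability and validity statistics for composite-score validation.

Implements the clinimetric battery used to validate a composite motor
outcome: test-retest reliability (single-measure intraclass correlation
from two-way ANOVA mean squares, with F-distribution confidence
limits), internal consistency (Cronbach's alpha across domain scores),
discrimination (AUROC as the Mann-Whitney concordance probability, with
stratified-bootstrap percentile confidence intervals and DeLong's test
for comparing correlated AUCs), threshold selection (Youden's J with a
deterministic specificity-favouring tie-break), and Pearson/Spearman
correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "icc",
    "cronbach_alpha",
    "auroc",
    "bootstrap_ci",
    "delong_compare",
    "youden_threshold",
    "correlate",
    "IccResult",
    "RocResult",
    "YoudenResult",
]


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_lo: float
    ci_hi: float
    model: str
    floored: bool = False  # true when a negative estimate was floored at 0


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for a subjects x occasions grid.

    Returns (MSR rows/subjects, MSC columns/occasions, MSE, n, k).
    """
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(
    matrix: np.ndarray | Sequence[Sequence[float]],
    model: str = "two_way_random_absolute",
    confidence: float = 0.95,
) -> IccResult:
    """Single-measure intraclass correlation of a subjects x occasions grid.

    Parameters
    ----------
    matrix : (n_subjects, k_occasions) array, no missing cells.
    model : str
        ``two_way_random_absolute`` — two-way random effects, absolute
        agreement, single measurement (ICC(2,1); the conservative
        default for test-retest designs), or
        ``two_way_mixed_consistency`` — two-way mixed effects,
        consistency, single measurement (ICC(3,1)).
    confidence : float
        Two-sided confidence level for the F-distribution interval.

    Negative point estimates are floored at 0 and flagged; the
    confidence bounds are clipped to [-1, 1].
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DegenerateDataError("ICC needs >= 2 subjects and >= 2 occasions")
    if np.isnan(x).any():
        raise DegenerateDataError("ICC matrix has missing cells")
    if np.allclose(x, x.flat[0]):
        raise DegenerateDataError("zero total variance; ICC undefined")
    msr, msc, mse, n, k = _two_way_mean_squares(x)
    alpha = 1.0 - confidence

    if model == "two_way_random_absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise DegenerateDataError("zero denominator; ICC undefined")
        est = (msr - mse) / denom
        if mse == 0 and msc == mse:
            lo, hi = est, est
        else:
            # McGraw & Wong F-based interval for ICC(A,1) via the
            # Satterthwaite degrees of freedom v
            a = k * est / (n * (1.0 - est)) if est < 1 else np.inf
            b = 1.0 + k * est * (n - 1) / (n * (1.0 - est)) if est < 1 else np.inf
            if not np.isfinite(a):
                lo, hi = est, est
            else:
                num_v = (a * msc + b * mse) ** 2
                den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / (
                    (n - 1) * (k - 1)
                )
                v = num_v / den_v
                f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = (
                    n * (msr - f_lo * mse)
                    / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
                )
                hi = (
                    n * (f_hi * msr - mse)
                    / (k * msc + (k * n - k - n) * mse + n * f_hi * msr)
                )
    elif model == "two_way_mixed_consistency":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise DegenerateDataError("zero denominator; ICC undefined")
        est = (msr - mse) / denom
        if mse == 0:
            lo, hi = est, est
        else:
            f_obs = msr / mse
            f_lo = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            f_hi = f_obs * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            lo = (f_lo - 1) / (f_lo + k - 1)
            hi = (f_hi - 1) / (f_hi + k - 1)
    else:
        raise ValueError(f"unknown ICC model {model!r}")

    floored = est < 0
    est_out = max(est, 0.0)
    lo = float(np.clip(lo, -1.0, 1.0))
    hi = float(np.clip(hi, -1.0, 1.0))
    return IccResult(icc=float(est_out), ci_lo=lo, ci_hi=hi, model=model, floored=floored)


def cronbach_alpha(matrix: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Cronbach's alpha of a subjects x items grid.

    alpha = k/(k-1) * (1 - sum(item variances) / var(total score)),
    using sample (ddof=1) variances.  Alpha can be negative (or exceed
    the usual [0, 1] reporting range) for pathological item sets; the
    raw value is returned.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise DegenerateDataError("alpha needs >= 3 subjects and >= 2 items")
    if np.isnan(x).any():
        raise DegenerateDataError("alpha matrix has missing cells")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def auroc(
    scores: Sequence[float],
    labels: Sequence[int] | Sequence[bool],
    higher_is_positive: bool = True,
) -> float:
    """Area under the ROC curve as a concordance probability.

    Computed as the Mann-Whitney U statistic over n1*n2 pairs with ties
    counted 1/2, via midranks.  ``higher_is_positive=False`` flips the
    score direction (e.g. more-negative percent decrement indicating
    disease).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("both groups must be non-empty for AUROC")
    if not higher_is_positive:
        s = -s
    ranks = stats.rankdata(s)  # midranks handle ties as half-credit
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_ci(
    statistic: Callable[..., float],
    data: Sequence[np.ndarray] | np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    confidence: float = 0.95,
    stratify: Sequence[int] | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a statistic.

    Parameters
    ----------
    statistic : callable taking the resampled arrays positionally.
    data : one array or a list of equal-length arrays resampled jointly.
    stratify : optional group labels; resampling is then stratified
        (within-group), the convention for ROC statistics so both
        groups stay represented in every replicate.

    Replicates on which the statistic raises are dropped; if more than
    half fail the interval is abandoned with diagnostics.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    arrays = [np.asarray(a) for a in (data if isinstance(data, (list, tuple)) else [data])]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must have the same length")
    if stratify is not None:
        strata = np.asarray(stratify)
        group_idx = [np.flatnonzero(strata == g) for g in np.unique(strata)]
    vals = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        if stratify is None:
            idx = rng.integers(0, n, n)
        else:
            idx = np.concatenate(
                [g[rng.integers(0, len(g), len(g))] for g in group_idx]
            )
        try:
            vals[b] = statistic(*[a[idx] for a in arrays])
        except Exception:
            vals[b] = np.nan
            failures += 1
    if failures > n_boot / 2:
        raise DegenerateDataError(
            f"statistic failed on {failures}/{n_boot} bootstrap replicates"
        )
    ok = vals[~np.isnan(vals)]
    alpha = 1.0 - confidence
    lo, hi = np.percentile(ok, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lo: float
    ci_hi: float
    n_boot: int
    threshold: float | None
    sensitivity: float | None
    specificity: float | None
    higher_is_positive: bool


def roc_with_ci(
    scores: Sequence[float],
    labels: Sequence[int] | Sequence[bool],
    higher_is_positive: bool = True,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> RocResult:
    """AUROC with stratified-bootstrap CI and the Youden threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    auc = auroc(s, y, higher_is_positive)
    lo, hi = bootstrap_ci(
        lambda sc, yy: auroc(sc, yy, higher_is_positive),
        [s, y],
        n_boot=n_boot,
        seed=seed,
        stratify=y,
    )
    yr = youden_threshold(s, y, higher_is_positive)
    return RocResult(
        auc=auc,
        ci_lo=lo,
        ci_hi=hi,
        n_boot=n_boot,
        threshold=yr.threshold,
        sensitivity=yr.sensitivity,
        specificity=yr.specificity,
        higher_is_positive=higher_is_positive,
    )


def _delong_structural_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong V10/V01 placement components for one marker."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    # placement value of each positive against the negative sample
    v10 = np.empty(m)
    for i, xp in enumerate(pos):
        v10[i] = (np.sum(xp > neg) + 0.5 * np.sum(xp == neg)) / n
    v01 = np.empty(n)
    for j, xn in enumerate(neg):
        v01[j] = (np.sum(pos > xn) + 0.5 * np.sum(pos == xn)) / m
    return float(v10.mean()), v10, v01


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int] | Sequence[bool],
    higher_is_positive: bool = True,
) -> tuple[float, float]:
    """DeLong test for equality of two correlated AUCs.

    Both markers must be measured on the same subjects with the same
    labels.  Returns (AUC difference a - b, two-sided p-value).  A zero
    estimated variance of the difference (e.g. identical score vectors)
    yields p = 1.0.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (len(sa) == len(sb) == len(y)):
        raise ValueError("paired scores and labels must share length")
    if y.all() or (~y).all():
        raise DegenerateDataError("both groups must be non-empty")
    if not higher_is_positive:
        sa, sb = -sa, -sb
    auc_a, v10_a, v01_a = _delong_structural_components(sa, y)
    auc_b, v10_b, v01_b = _delong_structural_components(sb, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return float(diff), 1.0
    z = diff / math.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(diff), float(p)


@dataclass(frozen=True)
class YoudenResult:
    threshold: float | None
    sensitivity: float
    specificity: float
    j: float
    degenerate: bool = False


def youden_threshold(
    scores: Sequence[float],
    labels: Sequence[int] | Sequence[bool],
    higher_is_positive: bool = True,
    specificity_weight: float = 1.0,
) -> YoudenResult:
    """Optimal cut-point maximising J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct score
    values (plus sentinels beyond the extremes).  With
    ``higher_is_positive``, a subject is called positive when
    score > threshold; otherwise when score < threshold.  Ties on J are
    broken toward higher specificity, then toward the threshold nearer
    the specificity-favouring extreme.  ``specificity_weight`` w
    generalises the objective to sensitivity + w*specificity - 1.

    All-identical scores are degenerate: J = 0 and no threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("both groups must be non-empty")
    distinct = np.unique(s)
    if len(distinct) == 1:
        return YoudenResult(None, 1.0, 0.0, 0.0, degenerate=True)
    span = distinct[-1] - distinct[0]
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(
        [[distinct[0] - span], mids, [distinct[-1] + span]]
    )
    best = None
    for t in candidates:
        pred_pos = s > t if higher_is_positive else s < t
        sens = float(np.sum(pred_pos & y)) / n_pos
        spec = float(np.sum(~pred_pos & ~y)) / n_neg
        j = sens + specificity_weight * spec - 1.0
        # specificity-favouring extreme: with higher-is-positive, larger
        # thresholds call fewer positives, so prefer larger t; reversed
        # for lower-is-positive.
        extreme_pref = t if higher_is_positive else -t
        key = (j, spec, extreme_pref)
        if best is None or key > best[0]:
            best = (key, float(t), sens, spec, j)
    _, t, sens, spec, j = best
    return YoudenResult(t, sens, spec, j)


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value.

    Pairs with missing values are deleted pairwise.  Pearson p-values
    use the t-transform; Spearman uses the t-approximation for n > 10
    and an exact permutation distribution for small samples.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[ok], ya[ok]
    n = len(xa)
    if n < 3:
        raise DegenerateDataError("correlation needs >= 3 complete pairs")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise DegenerateDataError("zero variance; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    elif method == "spearman":
        if n > 10:
            r, p = stats.spearmanr(xa, ya)
        else:
            res = stats.spearmanr(xa, ya)
            r = res.statistic
            perm = stats.permutation_test(
                (xa,),
                lambda xp: stats.spearmanr(xp, ya).statistic,
                permutation_type="pairings",
                alternative="two-sided",
                n_resamples=np.inf,
            )
            p = perm.pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
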