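"""Reliability/validity statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mmcoast import (
    auroc,
    bootstrap_ci,
    correlate,
    cronbach_alpha,
    delong_compare,
    icc,
    roc_with_ci,
    youden_threshold,
)
from mmcoast.errors import DegenerateDataError

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def icc_oracle_absolute(x):
    """Brute-force two-way ANOVA mean squares -> ICC(2,1)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def alpha_oracle(x):
    x = np.asarray(x, float)
    k = x.shape[1]
    return k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / x.sum(1).var(ddof=1))


def auroc_oracle(scores, labels):
    """All-pairs concordance with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


class TestIcc:
    def test_identical_columns_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        r = icc(x)
        assert r.icc == pytest.approx(1.0)

    def test_constant_offset_consistency_vs_absolute(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        cons = icc(x, model="two_way_mixed_consistency")
        absr = icc(x)
        assert cons.icc == pytest.approx(1.0)
        assert absr.icc < 1.0
        # hand-computed ANOVA mean squares: MSR=2, MSC=1.5, MSE=0
        # ICC(2,1) = 2 / (2 + 2*(1.5-0)/3) = 2/3
        assert absr.icc == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_grids(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.normal(0, 1, size=(5, 2)) + rng.normal(0, 2, size=(5, 1))
            assert icc(x).icc == pytest.approx(
                max(icc_oracle_absolute(x), 0.0), abs=1e-10
            )

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, size=(14, 2)) + rng.normal(0, 2, size=(14, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(14), 2),
                "rater": np.tile([0, 1], 14),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        ours = icc(x)
        absolute = ref.loc["ICC(A,1)"]  # absolute agreement, single measure
        assert ours.icc == pytest.approx(absolute["ICC"], abs=1e-6)
        lo, hi = absolute["CI95"]  # reference rounds its CI to 2 dp
        assert ours.ci_lo == pytest.approx(lo, abs=0.011)
        assert ours.ci_hi == pytest.approx(hi, abs=0.011)
        cons = icc(x, model="two_way_mixed_consistency")
        assert cons.icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-6)

    def test_noise_only_floors_at_zero_with_flag(self):
        rng = np.random.default_rng(1)
        x = np.tile([[5.0, 5.0]], (6, 1)) + rng.normal(0, 1, (6, 2))
        r = icc(x)
        if icc_oracle_absolute(x) < 0:
            assert r.icc == 0.0 and r.floored
        else:
            assert not r.floored

    def test_zero_variance_signals(self):
        with pytest.raises(DegenerateDataError):
            icc(np.full((4, 2), 3.0))

    def test_parameter_recovery_of_variance_ratio(self):
        """Mean ICC over replicates approaches sigma_b^2/(sigma_b^2+sigma_e^2)."""
        rng = np.random.default_rng(12)
        true = 4.0 / (4.0 + 1.0)
        estimates = []
        for _ in range(300):
            subj = rng.normal(0, 2.0, size=(20, 1))
            x = subj + rng.normal(0, 1.0, size=(20, 2))
            estimates.append(icc(x).icc)
        se = np.std(estimates) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - true) < max(2 * se, 0.02)


# ---------------------------------------------------------------------------
# Cronbach's alpha
# ---------------------------------------------------------------------------


class TestCronbachAlpha:
    def test_identical_items(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_hand_computed_negative_alpha(self):
        # items A=(1,2,3), B=(1,2,3), C=(3,2,1): alpha = -3 exactly
        x = np.array([[1, 1, 3], [2, 2, 2], [3, 3, 1]], dtype=float)
        assert cronbach_alpha(x) == pytest.approx(-3.0, abs=1e-12)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=(4000, 5))
        assert abs(cronbach_alpha(x)) < 0.1

    def test_matches_bruteforce_oracle_on_random_grids(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            x = rng.normal(0, 1, (6, 5)) + rng.normal(0, 1, (6, 1))
            assert cronbach_alpha(x) == pytest.approx(alpha_oracle(x), abs=1e-10)

    def test_zero_variance_signals(self):
        with pytest.raises(DegenerateDataError):
            cronbach_alpha(np.full((5, 3), 1.0))


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([3, 4, 5, 1, 2], [1, 1, 1, 0, 0]) == 1.0

    def test_identical_distributions(self):
        assert auroc([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_enumerated_ties(self):
        # MM {2,3} vs Unlikely {1,3}: pairs (2>1)+(3>1)+(2<3)+(3=3)/2 = 2.5/4
        assert auroc([2, 3, 1, 3], [1, 1, 0, 0]) == pytest.approx(0.625)

    def test_direction_flip(self):
        # more-negative decrement indicates disease
        s = [-20, -18, -5, -6]
        y = [1, 1, 0, 0]
        assert auroc(s, y, higher_is_positive=False) == 1.0

    def test_matches_pair_enumeration_on_random_data(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n1, n0 = rng.integers(2, 40), rng.integers(2, 40)
            s = np.concatenate(
                [rng.integers(0, 8, n1) + 0.0, rng.integers(0, 8, n0) - 0.5]
            )
            y = np.concatenate([np.ones(n1), np.zeros(n0)])
            assert auroc(s, y) == pytest.approx(auroc_oracle(s, y), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        s = rng.normal(0, 1, 60)
        y = rng.integers(0, 2, 60)
        if y.sum() in (0, 60):
            y[0] = 1 - y[0]
        assert auroc(np.exp(s), y) == pytest.approx(auroc(s, y), abs=1e-12)

    def test_complement_identity_tie_free(self):
        rng = np.random.default_rng(14)
        s = rng.permutation(40) + 0.0  # distinct scores
        y = np.array([0, 1] * 20)
        assert auroc(s, y) + auroc(-s, y) == pytest.approx(1.0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            auroc([1, 2], [1, 1])


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


class TestBootstrap:
    def test_degenerate_data_zero_width(self):
        lo, hi = bootstrap_ci(np.mean, np.full(10, 2.0), n_boot=100, seed=0)
        assert lo == hi == 2.0

    def test_same_seed_reproduces_exactly(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, 30)
        a = bootstrap_ci(np.mean, data, n_boot=500, seed=77)
        b = bootstrap_ci(np.mean, data, n_boot=500, seed=77)
        assert a == b

    def test_perfectly_separated_auc_ci_is_degenerate(self):
        s = np.array([3.0, 4, 5, 1, 2])
        y = np.array([1, 1, 1, 0, 0])
        lo, hi = bootstrap_ci(
            lambda sc, yy: auroc(sc, yy),
            [s, y],
            n_boot=200,
            seed=5,
            stratify=y,
        )
        assert lo == hi == 1.0

    def test_roc_block_is_seed_stable(self):
        rng = np.random.default_rng(10)
        s = rng.normal(0, 1, 50) + np.r_[np.ones(25), np.zeros(25)]
        y = np.r_[np.ones(25), np.zeros(25)].astype(int)
        a = roc_with_ci(s, y, n_boot=200, seed=9)
        b = roc_with_ci(s, y, n_boot=200, seed=9)
        assert (a.ci_lo, a.ci_hi) == (b.ci_lo, b.ci_hi)
        assert a.ci_lo <= a.auc <= a.ci_hi


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------


class TestDeLong:
    def test_identical_markers_p_one(self):
        rng = np.random.default_rng(15)
        s = rng.normal(0, 1, 40)
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        diff, p = delong_compare(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_informative_vs_random_marker_significant(self):
        rng = np.random.default_rng(16)
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        strong = y * 10.0 + rng.normal(0, 0.1, 40)  # near-perfect marker
        noise = rng.normal(0, 1, 40)
        _, p = delong_compare(strong, noise, y)
        assert p < 0.05

    def test_agrees_with_permutation_oracle(self):
        """Permutation of the marker assignment brackets the DeLong p."""
        rng = np.random.default_rng(17)
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        a = y + rng.normal(0, 1.0, 30)
        b = y + rng.normal(0, 1.5, 30)
        diff, p = delong_compare(a, b, y)
        # oracle: swap marker identity within subjects at random
        observed = abs(auroc(a, y) - auroc(b, y))
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            swap = rng.random(30) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            if abs(auroc(aa, y) - auroc(bb, y)) >= observed - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert abs(p - p_perm) < 0.12  # Monte-Carlo + asymptotic slack


# ---------------------------------------------------------------------------
# Youden threshold
# ---------------------------------------------------------------------------


def youden_oracle(scores, labels, higher_is_positive=True):
    """Exhaustive midpoint scan maximising J with the documented tie-break."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    distinct = np.unique(s)
    span = distinct[-1] - distinct[0]
    cands = np.r_[
        distinct[0] - span, (distinct[:-1] + distinct[1:]) / 2, distinct[-1] + span
    ]
    best = None
    for t in cands:
        pred = s > t if higher_is_positive else s < t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        key = (sens + spec - 1, spec, t if higher_is_positive else -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


class TestYouden:
    def test_perfect_separation_lower_is_positive(self):
        res = youden_threshold(
            [-20, -18, -15, -5, -6, -7],
            [1, 1, 1, 0, 0, 0],
            higher_is_positive=False,
        )
        assert res.j == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert -15 < res.threshold < -7
        # tie-break: nearest the specificity-favouring extreme
        assert res.threshold == pytest.approx(-11.0)

    def test_matches_exhaustive_scan_on_random_data(self):
        rng = np.random.default_rng(18)
        for _ in range(40):
            n1, n0 = rng.integers(3, 25), rng.integers(3, 25)
            s = np.concatenate(
                [rng.normal(1, 1, n1), rng.normal(0, 1, n0)]
            ).round(1)
            y = np.r_[np.ones(n1), np.zeros(n0)].astype(int)
            res = youden_threshold(s, y)
            t, sens, spec = youden_oracle(s, y)
            assert res.threshold == pytest.approx(t)
            assert res.sensitivity == pytest.approx(sens)
            assert res.specificity == pytest.approx(spec)

    def test_all_equal_scores_degenerate(self):
        res = youden_threshold([2.0, 2.0, 2.0, 2.0], [1, 1, 0, 0])
        assert res.degenerate and res.threshold is None and res.j == 0.0


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


class TestCorrelate:
    def test_identity(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, _ = correlate(x, x)
        assert r == pytest.approx(1.0)

    def test_negation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, _ = correlate(x, -x)
        assert r == pytest.approx(-1.0)

    def test_orthogonal_by_construction(self):
        # y is symmetric in x around its centre: exact zero correlation
        x = np.array([-2.0, -1, 0, 1, 2])
        y = x**2
        r, _ = correlate(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2, np.nan, 4, 5])
        y = np.array([2.0, 4, 6, np.nan, 10])
        r, _ = correlate(x, y)
        assert r == pytest.approx(1.0)

    def test_spearman_small_sample_exact_permutation(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        r, p = correlate(x, y, method="spearman")
        rho = stats.spearmanr(x, y).statistic
        assert r == pytest.approx(rho)
        # exact permutation p for n=6 from full enumeration
        assert 0 < p <= 1

    def test_zero_variance_signals(self):
        with pytest.raises(DegenerateDataError):
            correlate([1.0, 1, 1], [1.0, 2, 3])
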