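"""Chart binning, domain means, composite aggregation and completeness."""

import math

import numpy as np
import pytest

from mmcoast import (
    ChartBin,
    ScoreChart,
    SDZeroTable,
    assign_test_score,
    composite,
    domain_score,
    toy_sd_zero_table,
    validate_chart,
)
from mmcoast.errors import ChartError


def make_chart(edges, scores, chart_id="c"):
    """Build a chart from interior edges and per-bin scores (low to high)."""
    bounds = [-math.inf] + list(edges) + [math.inf]
    bins = [
        ChartBin(lo, hi, s) for lo, hi, s in zip(bounds, bounds[1:], scores)
    ]
    return ScoreChart(chart_id, bins)


@pytest.fixture(scope="module")
def chart_a(charts):
    return charts["zscore_chart_A"]


class TestChartAssignment:
    @pytest.mark.parametrize(
        "z, expected",
        [
            (-1.0, 0),
            (-3.5, 2),
            (-4.0, 2),  # lower-closed bins: -4.0 falls in [-4, -3)
            (-2.0, 0),  # abnormality boundary scores 0
            (-2.0000001, 1),
            (-100.0, 3),
            (5.0, 0),
        ],
    )
    def test_toy_z_chart(self, chart_a, z, expected):
        assert assign_test_score(z, chart_a) == expected

    @pytest.mark.parametrize(
        "pct, expected",
        [(-5.0, 0), (-13.0, 0), (-14.0, 1), (-26.0, 1), (-26.5, 2), (-40.0, 3)],
    )
    def test_toy_decrement_chart(self, charts, pct, expected):
        assert assign_test_score(pct, charts["decrement_chart_B"]) == expected

    def test_nonfinite_input_rejected(self, chart_a):
        with pytest.raises(ValueError):
            chart_a.assign(float("nan"))


class TestChartValidation:
    def test_toy_charts_valid(self, charts):
        for c in charts.values():
            assert validate_chart(c) == []

    def test_gap_detected(self):
        bins = [
            ChartBin(-math.inf, -3, 2),
            ChartBin(-2, math.inf, 0),  # gap [-3, -2)
        ]
        with pytest.raises(ChartError, match="gap"):
            ScoreChart("bad", bins)
        assert any(
            "gap" in v for v in ScoreChart("bad", bins, validate=False).violations()
        )

    def test_overlap_detected(self):
        bins = [
            ChartBin(-math.inf, -1, 1),
            ChartBin(-2, math.inf, 0),
        ]
        with pytest.raises(ChartError, match="overlap"):
            ScoreChart("bad", bins)

    def test_score_increasing_with_input_detected(self):
        # severity must not rise as performance improves
        with pytest.raises(ChartError, match="score increases"):
            make_chart([-2], [0, 3])

    def test_negative_score_detected(self):
        with pytest.raises(ChartError, match="negative"):
            make_chart([-2], [1, -1])

    def test_open_ends_required(self):
        bins = [ChartBin(-5, 0, 1), ChartBin(0, 5, 0)]
        v = ScoreChart("bad", bins, validate=False).violations()
        assert any("-inf" in s for s in v) and any("+inf" in s for s in v)


class TestDomainScore:
    def test_mean_of_members(self):
        assert domain_score([2, 1, 1, 0]) == 1.0

    def test_single_member_identity(self):
        assert domain_score([3]) == 3.0

    def test_missing_members_excluded_not_imputed(self):
        assert domain_score([2, None, 4]) == 3.0

    def test_no_members_is_missing(self):
        assert domain_score([None, None]) is None
        assert domain_score([]) is None


class TestCompositeCompleteness:
    def test_three_domains_ambulatory(self):
        r = composite(
            {"a": 1.5, "b": 1.0, "c": 2.0, "d": None, "e": None}, ambulatory=True
        )
        assert r.scorable and r.composite == pytest.approx(1.5)
        assert r.n_domains_complete == 3

    def test_two_domains_non_ambulatory(self):
        r = composite({"a": 2.5, "b": 3.0, "c": None}, ambulatory=False)
        assert r.scorable and r.composite == pytest.approx(2.75)

    def test_two_domains_ambulatory_not_scorable(self):
        r = composite({"a": 1.0, "b": 2.0, "c": None}, ambulatory=True)
        assert not r.scorable and r.composite is None and "minimum is 3" in r.reason

    @pytest.mark.parametrize("ambulatory, minimum", [(True, 3), (False, 2)])
    def test_enumerated_boundary(self, ambulatory, minimum):
        """Exactly the minimum is scorable; one fewer is not."""
        for n in range(0, 6):
            domains = {f"d{i}": 1.0 if i < n else None for i in range(5)}
            r = composite(domains, ambulatory)
            assert r.scorable == (n >= minimum)
            assert r.n_domains_complete == n


class TestCompositeProperties:
    def test_all_zero_inputs_give_zero(self, charts):
        chart = charts["zscore_chart_A"]
        domains = {
            "strength": domain_score([chart.assign(0.0)] * 4),
            "fatigue": domain_score([charts["decrement_chart_B"].assign(-5.0)]),
            "balance": domain_score([chart.assign(1.0)] * 3),
        }
        r = composite(domains, ambulatory=True)
        assert r.composite == 0.0

    def test_monotone_in_member_input(self, charts):
        """Worsening any single z never decreases the composite."""
        chart = charts["zscore_chart_A"]
        rng = np.random.default_rng(7)
        for _ in range(200):
            zs = rng.uniform(-6, 2, size=(5, 2))
            domains = {
                f"d{i}": domain_score([chart.assign(z) for z in row])
                for i, row in enumerate(zs)
            }
            base = composite(domains, True).composite
            i, j = rng.integers(0, 5), rng.integers(0, 2)
            worse = zs.copy()
            worse[i, j] -= rng.uniform(0, 4)
            domains2 = {
                f"d{i}": domain_score([chart.assign(z) for z in row])
                for i, row in enumerate(worse)
            }
            assert composite(domains2, True).composite >= base

    def test_permutation_invariance(self, charts):
        chart = charts["zscore_chart_A"]
        rng = np.random.default_rng(11)
        zs = rng.uniform(-6, 2, size=8)
        members = [chart.assign(z) for z in zs]
        d1 = domain_score(members)
        d2 = domain_score(list(reversed(members)))
        assert d1 == pytest.approx(d2)
        domains = {"a": 1.0, "b": 2.0, "c": 0.5}
        shuffled = dict(reversed(list(domains.items())))
        assert composite(domains, True).composite == pytest.approx(
            composite(shuffled, True).composite
        )

    def test_random_charts_match_bruteforce_oracle(self):
        """Bin search equals an independent linear-scan/mean evaluation."""
        rng = np.random.default_rng(23)
        for _ in range(50):
            n_bins = rng.integers(2, 7)
            edges = np.sort(rng.uniform(-8, 2, n_bins - 1))
            scores = np.sort(rng.integers(0, 6, n_bins))[::-1]
            chart = make_chart(edges, list(map(float, scores)))
            values = rng.uniform(-10, 4, 40)
            for v in values:
                # oracle: linear scan over half-open bins
                expected = None
                bounds = [-math.inf, *edges, math.inf]
                for lo, hi, s in zip(bounds, bounds[1:], scores):
                    if lo <= v < hi:
                        expected = s
                        break
                assert chart.assign(v) == expected


class TestSDZeroTable:
    def test_toy_lookup(self):
        t = toy_sd_zero_table()
        assert t.lookup("ts_eyes_open", "male", 30, 9.0) == 0
        assert t.lookup("ts_eyes_open", "female", 12, 1.5) == 3
        assert t.lookup("ts_eyes_open", "male", 30, 5.0) == 1

    def test_missing_row_is_an_error(self):
        t = toy_sd_zero_table()
        with pytest.raises(Exception):
            t.lookup("sls_eyes_closed", "male", 30, 5.0)
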