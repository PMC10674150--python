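"""Agresti-Coull intervals, event matching, latency quartiles, alert
tables, and channel yields."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom
from statsmodels.stats.proportion import proportion_confint

from geotrigger.evaluate import (
    ChannelReport,
    GoldEvent,
    agresti_coull_interval,
    alert_table,
    detection_summary,
    latency_summary,
    match_events,
    yield_summary,
)

D0 = date(2019, 3, 1)


class TestAgrestiCoull:
    def test_eight_of_nine(self):
        ci = agresti_coull_interval(8, 9)
        assert round(ci.lower, 2) == 0.54
        assert round(ci.upper, 2) == 1.00

    def test_447_of_647(self):
        ci = agresti_coull_interval(447, 647)
        assert round(ci.lower, 3) == 0.654
        assert round(ci.upper, 3) == 0.725

    def test_zero_successes_clips_lower_bound(self):
        ci = agresti_coull_interval(0, 10)
        assert ci.lower == 0.0
        assert ci.upper > 0.0

    def test_all_successes_clips_upper_bound(self):
        assert agresti_coull_interval(10, 10).upper == 1.0

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            agresti_coull_interval(0, 0)

    @given(n=st.integers(min_value=1, max_value=500), frac=st.floats(min_value=0, max_value=1))
    def test_matches_independent_implementation(self, n, frac):
        x = min(n, int(round(frac * n)))
        ci = agresti_coull_interval(x, n)
        lo, hi = proportion_confint(x, n, alpha=0.05, method="agresti_coull")
        assert ci.lower == pytest.approx(max(0.0, lo), abs=1e-12)
        assert ci.upper == pytest.approx(min(1.0, hi), abs=1e-12)
        assert 0.0 <= ci.lower <= ci.point <= ci.upper <= 1.0 or ci.trials == 0

    @pytest.mark.parametrize("n", [10, 100])
    def test_coverage_near_nominal(self, n):
        """Exact coverage (binomial enumeration) within 2 points of 95% at p=0.3."""
        p = 0.3
        cov = sum(
            binom.pmf(x, n, p)
            for x in range(n + 1)
            if agresti_coull_interval(x, n).lower <= p <= agresti_coull_interval(x, n).upper
        )
        assert abs(cov - 0.95) <= 0.02


def _gold(eid, pid, admit_day, stay=2, **kw):
    return GoldEvent(eid, pid, D0 + timedelta(days=admit_day), D0 + timedelta(days=admit_day + stay), **kw)


def _report(rid, pid, channel, report_day, claimed_admit_day):
    return ChannelReport(rid, pid, channel, D0 + timedelta(days=report_day), D0 + timedelta(days=claimed_admit_day))


class TestMatching:
    def test_report_two_days_after_admit_matches_with_latency_two(self):
        gold = [_gold("g1", "p1", 10)]
        matches, surplus = match_events(gold, [_report("r1", "p1", "monthly", 12, 10)])
        assert matches[0].matched["monthly"] and not surplus
        assert matches[0].latency_days["monthly"] == 2

    def test_one_report_for_two_close_events_matches_exactly_one(self):
        gold = [_gold("g1", "p1", 10), _gold("g2", "p1", 24)]
        matches, surplus = match_events(gold, [_report("r1", "p1", "monthly", 40, 10)])
        assert sum(m.matched["monthly"] for m in matches) == 1
        assert matches[0].matched["monthly"]  # nearest admit wins
        assert not surplus

    def test_distant_report_is_surplus(self):
        gold = [_gold("g1", "p1", 10)]
        matches, surplus = match_events(gold, [_report("r1", "p1", "monthly", 45, 40)])
        assert not matches[0].matched["monthly"]
        assert len(surplus) == 1

    def test_cross_participant_reports_never_match(self):
        gold = [_gold("g1", "p1", 10)]
        _, surplus = match_events(gold, [_report("r1", "p2", "monthly", 12, 10)])
        assert len(surplus) == 1

    def test_tie_broken_by_earliest_gold_admit(self):
        gold = [_gold("g1", "p1", 10), _gold("g2", "p1", 14)]
        matches, _ = match_events(gold, [_report("r1", "p1", "monthly", 20, 12)])
        assert matches[0].matched["monthly"] and not matches[1].matched["monthly"]

    @given(order=st.permutations(range(4)))
    def test_result_independent_of_report_ordering(self, order):
        gold = [_gold(f"g{i}", "p1", 10 + 20 * i) for i in range(4)]
        reports = [_report(f"r{i}", "p1", "monthly", 12 + 20 * i, 10 + 20 * i) for i in range(4)]
        shuffled = [reports[i] for i in order]
        base, _ = match_events(gold, reports)
        perm, _ = match_events(gold, shuffled)
        assert [(m.gold_event_id, m.matched["monthly"], m.latency_days["monthly"]) for m in base] == [
            (m.gold_event_id, m.matched["monthly"], m.latency_days["monthly"]) for m in perm
        ]


class TestDetectionSummary:
    def test_eight_of_nine_rate(self):
        gold = [_gold(f"g{i}", "p1", 10 + 20 * i) for i in range(9)]
        reports = [_report(f"r{i}", "p1", "monthly", 12 + 20 * i, 10 + 20 * i) for i in range(8)]
        matches, _ = match_events(gold, reports)
        ci = detection_summary(matches, "monthly")
        assert (ci.successes, ci.trials) == (8, 9)
        assert ci.point == pytest.approx(8 / 9)

    def test_union_counts_any_channel(self):
        gold = [_gold("g1", "p1", 10), _gold("g2", "p1", 40)]
        reports = [_report("r1", "p1", "monthly", 12, 10), _report("r2", "p1", "geofence", 41, 40)]
        matches, _ = match_events(gold, reports)
        assert detection_summary(matches, ("geofence", "monthly")).successes == 2
        assert detection_summary(matches, "monthly").successes == 1

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            detection_summary([], "monthly")


class TestLatencySummary:
    def _matches(self, latencies):
        gold = [_gold(f"g{i}", "p1", 50 * i + 10) for i in range(len(latencies))]
        reports = [
            _report(f"r{i}", "p1", "geofence", 50 * i + 10 + lat, 50 * i + 10)
            for i, lat in enumerate(latencies)
        ]
        matches, _ = match_events(gold, reports)
        return matches

    def test_median_and_iqr(self):
        s = latency_summary(self._matches([1, 2, 3]), "geofence")
        assert (s["median"], s["q1"], s["q3"]) == (2, 1, 3)

    def test_single_value(self):
        s = latency_summary(self._matches([5]), "geofence")
        assert (s["median"], s["q1"], s["q3"]) == (5, 5, 5)

    @pytest.mark.parametrize("lat", [[4, 9, 13, 25, 40], [3, 7, 11, 20], [1, 2, 3, 4, 5, 6, 7]])
    def test_quartiles_match_order_statistic_oracle(self, lat):
        s = latency_summary(self._matches(lat), "geofence")

        def quantile(sorted_xs, q):
            # exhaustive order-statistic definition: average the two
            # straddling values when n*q lands on an integer
            g = len(sorted_xs) * q
            if g == int(g):
                i = int(g)
                return (sorted_xs[i - 1] + sorted_xs[min(i, len(sorted_xs) - 1)]) / 2
            return sorted_xs[int(np.ceil(g)) - 1]

        assert s["q1"] == pytest.approx(quantile(lat, 0.25))
        assert s["median"] == pytest.approx(quantile(lat, 0.50))
        assert s["q3"] == pytest.approx(quantile(lat, 0.75))

    def test_even_sample_median_is_midpoint(self):
        s = latency_summary(self._matches([5, 8]), "geofence")
        assert s["median"] == 6.5

    def test_empty_channel_rejected(self):
        with pytest.raises(ValueError):
            latency_summary(self._matches([1]), "monthly")


class TestAlertTable:
    def test_true_alert_percentage(self):
        alerts = [(10.0, True)] * 55 + [(20.0, False)] * 100
        rows = alert_table(alerts, [0, 210])
        assert rows[0]["n_true"] == 55 and rows[0]["n_total"] == 155
        assert rows[0]["true_alert_pct"] == pytest.approx(100 * 55 / 155)  # 35.48

    def test_high_precision_bin(self):
        rows = alert_table([(400.0, True)] * 14 + [(400.0, False)], [365, 640])
        assert rows[0]["true_alert_pct"] == pytest.approx(100 * 14 / 15)  # 93.33

    def test_empty_bin_is_undefined_not_zero(self):
        rows = alert_table([(10.0, True)], [0, 210, 365])
        assert rows[1]["true_alert_pct"] is None

    def test_alert_outside_bins_rejected(self):
        with pytest.raises(ValueError):
            alert_table([(400.0, True)], [0, 210])

    def test_counts_reconcile(self):
        alerts = [(float(d), d % 3 == 0) for d in range(0, 600, 7)]
        rows = alert_table(alerts, [0, 210, 365, 600])
        assert sum(r["n_total"] for r in rows) == len(alerts)


class TestYield:
    @pytest.mark.parametrize(
        "contacts,confirmed,expected",
        [(171, 9, 9 / 171), (447, 8, 8 / 447), (100, 0, 0.0)],
    )
    def test_yield_values(self, contacts, confirmed, expected):
        assert yield_summary(contacts, confirmed) == pytest.approx(expected)

    def test_zero_contacts_rejected(self):
        with pytest.raises(ValueError):
            yield_summary(0, 0)
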