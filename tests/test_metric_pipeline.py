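"""Aggregation, winsorizing, rounding, bucket checks and the adjustment search."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adwh import (
    Caps,
    ConfigError,
    MetricDefinition,
    adjust,
    aggregate,
    build_histogram,
    cap_value,
    check_buckets,
    format_histogram,
    mask_histogram,
    resolve_caps,
    round_value,
)
from adwh.metric_pipeline import cap_series, nearest_rank_quantile


def _measurements(rows):
    return pd.DataFrame(
        {
            "user_id": [r[0] for r in rows],
            "metric_name": "hr",
            "timestamp": pd.to_datetime([r[1] for r in rows], utc=True),
            "value": [float(r[2]) for r in rows],
        }
    )


class TestAggregate:
    def test_weekly_mean_of_three_values(self):
        m = _measurements(
            [
                ("u1", "2024-01-01T08:00", 62),
                ("u1", "2024-01-03T08:00", 64),
                ("u1", "2024-01-07T08:00", 66),
            ]
        )
        agg = aggregate(m, MetricDefinition("hr", "mean", "week"))
        assert len(agg) == 1
        assert agg["raw_aggregate"].iloc[0] == 64.0
        assert agg["period_start"].iloc[0] == pd.Timestamp("2024-01-01", tz="UTC")

    @pytest.mark.parametrize("mode", ["mean", "median", "most_recent"])
    def test_single_measurement_is_its_own_aggregate(self, mode):
        m = _measurements([("u1", "2024-01-02T10:00", 71.5)])
        agg = aggregate(m, MetricDefinition("hr", mode, "week"))
        assert agg["raw_aggregate"].tolist() == [71.5]

    def test_periods_are_half_open(self):
        # Sunday 23:59:59 belongs to the week; Monday 00:00 starts the next
        m = _measurements(
            [("u1", "2024-01-07T23:59:59", 60), ("u1", "2024-01-08T00:00:00", 80)]
        )
        agg = aggregate(m, MetricDefinition("hr", "mean", "week"))
        starts = sorted(agg["period_start"])
        assert starts == [
            pd.Timestamp("2024-01-01", tz="UTC"),
            pd.Timestamp("2024-01-08", tz="UTC"),
        ]
        assert sorted(agg["raw_aggregate"]) == [60.0, 80.0]

    def test_month_and_day_periods(self):
        m = _measurements(
            [("u1", "2024-02-29T12:00", 60), ("u1", "2024-02-01T00:00", 70)]
        )
        agg_m = aggregate(m, MetricDefinition("hr", "mean", "month"))
        assert len(agg_m) == 1
        assert agg_m["period_start"].iloc[0] == pd.Timestamp("2024-02-01", tz="UTC")
        agg_d = aggregate(m, MetricDefinition("hr", "mean", "day"))
        assert len(agg_d) == 2

    def test_most_recent_takes_value_at_max_timestamp(self):
        m = _measurements(
            [
                ("u1", "2024-01-01T08:00", 62),
                ("u1", "2024-01-05T08:00", 99),
                ("u1", "2024-01-03T08:00", 64),
            ]
        )
        agg = aggregate(m, MetricDefinition("hr", "most_recent", "week"))
        assert agg["raw_aggregate"].tolist() == [99.0]

    def test_empty_input_gives_empty_output(self):
        agg = aggregate(_measurements([]), MetricDefinition("hr"))
        assert agg.empty

    def test_unknown_mode_is_config_error(self):
        with pytest.raises(ConfigError):
            MetricDefinition("hr", aggregation_mode="mode")

    @pytest.mark.parametrize("mode", ["mean", "median", "most_recent"])
    def test_matches_brute_force_grouping(self, mode, small_cohort):
        """All modes against a per-user per-week pure-Python recomputation."""
        m = small_cohort.measurements
        defn = MetricDefinition("resting_heart_rate", mode, "week")
        agg = aggregate(m, defn)
        got = {
            (r.user_id, pd.Timestamp(r.period_start)): r.raw_aggregate
            for r in agg.itertuples()
        }
        groups: dict = {}
        for r in m.itertuples():
            monday = (r.timestamp - pd.Timedelta(days=r.timestamp.weekday())).normalize()
            groups.setdefault((r.user_id, monday), []).append((r.timestamp, r.value))
        assert set(got) == set(groups)
        for key, obs in groups.items():
            values = [v for _, v in obs]
            if mode == "mean":
                expected = sum(values) / len(values)
            elif mode == "median":
                expected = float(np.median(values))
            else:
                expected = max(obs, key=lambda t: t[0])[1]
            assert got[key] == pytest.approx(expected, rel=1e-12)


class TestResolveCaps:
    def test_explicit_caps_pass_through(self):
        agg = pd.DataFrame({"user_id": ["u1"], "raw_aggregate": [70.0]})
        caps = resolve_caps(agg, MetricDefinition("hr", cap_low=50, cap_high=90))
        assert (caps.low, caps.high) == (50.0, 90.0)

    def test_zero_tail_fraction_gives_min_max(self):
        agg = pd.DataFrame({"user_id": list("abcd"), "raw_aggregate": [3.0, 1.0, 4.0, 2.0]})
        caps = resolve_caps(
            agg, MetricDefinition("hr", default_tail_fraction=0.0)
        )
        assert (caps.low, caps.high) == (1.0, 4.0)

    def test_matches_sorted_array_nearest_rank_oracle(self):
        """10,000 distinct sorted values at 2.5% tails: bounds equal the
        values at 1-based ranks ceil(0.025 n) and ceil(0.975 n)."""
        values = np.arange(10_000, dtype=float) + 0.5
        rng = np.random.default_rng(1)
        agg = pd.DataFrame(
            {"user_id": [f"u{i}" for i in range(10_000)],
             "raw_aggregate": rng.permutation(values)}
        )
        caps = resolve_caps(agg, MetricDefinition("hr"))
        s = np.sort(values)
        assert caps.low == s[math.ceil(0.025 * 10_000) - 1]
        assert caps.high == s[math.ceil(0.975 * 10_000) - 1]

    def test_degenerate_all_equal_warns(self):
        agg = pd.DataFrame({"user_id": list("abc"), "raw_aggregate": [5.0] * 3})
        with pytest.warns(UserWarning, match="degenerate"):
            caps = resolve_caps(agg, MetricDefinition("hr"))
        assert caps.low == caps.high == 5.0

    def test_auto_caps_need_data(self):
        empty = pd.DataFrame(columns=["user_id", "raw_aggregate"])
        with pytest.raises(ConfigError):
            resolve_caps(empty, MetricDefinition("hr"))


class TestCapValue:
    @pytest.mark.parametrize(
        "x, expected, direction",
        [(45, 50, "low"), (95, 90, "high"), (70, 70, "none"), (50, 50, "none"), (90, 90, "none")],
    )
    def test_winsorizing_maps_to_bounds(self, x, expected, direction):
        assert cap_value(x, 50, 90) == (expected, direction)

    def test_infinite_sentinels_are_identity(self):
        for x in (-1e300, 0.0, 1e300):
            assert cap_value(x, float("-inf"), float("inf")) == (x, "none")


class TestRoundValue:
    @pytest.mark.parametrize(
        "x, f, expected",
        [
            (64.4, 1, 64.0),
            (67, 10, 70.0),
            (64.5, 1, 65.0),  # exact half: away from zero
            (-64.5, 1, -65.0),
            (2.5, 5, 5.0),
            (0.0, 1, 0.0),
        ],
    )
    def test_nearest_multiple_ties_away_from_zero(self, x, f, expected):
        assert round_value(x, f) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        x=st.floats(-1e6, 1e6, allow_nan=False),
        f=st.sampled_from([0.5, 1.0, 2.0, 5.0, 10.0]),
    )
    def test_idempotent_and_aligned(self, x, f):
        r = round_value(x, f)
        assert round_value(r, f) == r
        assert abs(r / f - round(r / f)) < 1e-9  # exact multiple of the factor
        assert abs(r - x) <= f / 2 + 1e-9 * max(1.0, abs(x))

    @settings(max_examples=200, derandomize=True)
    @given(
        x=st.floats(-200, 200, allow_nan=False),
        lo=st.floats(-100, 0), hi=st.floats(0.1, 100),
    )
    def test_cap_is_idempotent(self, x, lo, hi):
        once, d = cap_value(x, lo, hi)
        again, d2 = cap_value(once, lo, hi)
        assert again == once and d2 == "none"


class TestBuildHistogram:
    def test_distinct_user_semantics(self):
        agg = pd.DataFrame(
            {
                "user_id": ["u1"] * 10,
                "period_start": pd.date_range("2024-01-01", periods=10, tz="UTC"),
                "raw_aggregate": [64.2] * 10,
            }
        )
        defn = MetricDefinition("hr", period="day", cap_low=50, cap_high=90)
        hist = build_histogram(agg, defn, {"u1"})
        assert hist.n_buckets == 1
        (bucket,) = hist.buckets.values()
        assert bucket.distinct_user_count == 1
        assert bucket.record_count == 10

    def test_empty_eligible_set_gives_empty_histogram(self):
        agg = pd.DataFrame(
            {"user_id": ["u1"], "period_start": [pd.Timestamp("2024-01-01", tz="UTC")],
             "raw_aggregate": [64.0]}
        )
        defn = MetricDefinition("hr", cap_low=50, cap_high=90)
        hist = build_histogram(agg, defn, set())
        assert hist.n_buckets == 0
        satisfied, failing = check_buckets(hist)
        assert satisfied and not failing

    def test_counts_match_set_based_recount(self, small_cohort):
        """Random cohort vs a per-bucket pure-Python set recount."""
        defn = MetricDefinition("resting_heart_rate", cap_low=50, cap_high=90)
        agg = aggregate(small_cohort.measurements, defn)
        eligible = set(agg["user_id"][::2])  # every other user
        hist = build_histogram(agg, defn, eligible)
        oracle: dict = {}
        for r in agg.itertuples():
            if r.user_id not in eligible:
                continue
            capped = min(max(r.raw_aggregate, 50.0), 90.0)
            v = round_value(capped, 1.0)
            users, n = oracle.get(v, (set(), 0))
            users.add(r.user_id)
            oracle[v] = (users, n + 1)
        assert {b.value for b in hist.buckets.values()} == set(oracle)
        for b in hist.buckets.values():
            users, n = oracle[b.value]
            assert b.distinct_user_count == len(users)
            assert b.record_count == n

    def test_mass_conservation_and_alignment(self, medium_cohort):
        """Winsorizing never drops records; bucket values are exact multiples
        of the rounding factor."""
        defn = MetricDefinition("resting_heart_rate", cap_low=55, cap_high=75,
                                rounding_factor=2.0)
        agg = aggregate(medium_cohort.measurements, defn)
        eligible = set(agg["user_id"])
        hist = build_histogram(agg, defn, eligible)
        assert hist.total_records == len(agg)
        for idx, b in hist.buckets.items():
            assert b.value == idx * 2.0
        total_wins = sum(b.winsorized_in for b in hist.buckets.values())
        raw = agg["raw_aggregate"]
        assert total_wins == int(((raw < 55) | (raw > 75)).sum())

    def test_tightening_caps_never_decreases_min_count(self, medium_cohort):
        defn = MetricDefinition("resting_heart_rate", cap_low=50, cap_high=90)
        agg = aggregate(medium_cohort.measurements, defn)
        eligible = set(agg["user_id"])
        mins = []
        for lo, hi in [(50, 90), (55, 85), (60, 80), (63, 70)]:
            d = dataclasses.replace(defn, cap_low=lo, cap_high=hi)
            mins.append(build_histogram(agg, d, eligible).min_distinct_user_count())
        assert mins == sorted(mins)

    def test_coarser_rounding_never_increases_bucket_count(self, medium_cohort):
        defn = MetricDefinition("resting_heart_rate", cap_low=50, cap_high=90)
        agg = aggregate(medium_cohort.measurements, defn)
        eligible = set(agg["user_id"])
        counts = []
        for f in (1.0, 2.0, 5.0, 10.0):
            d = dataclasses.replace(defn, rounding_factor=f)
            counts.append(build_histogram(agg, d, eligible).n_buckets)
        assert counts == sorted(counts, reverse=True)


class TestCheckBuckets:
    def _hist(self, counts, threshold):
        agg = pd.DataFrame(
            {
                "user_id": [f"u{v}_{i}" for v, c in counts.items() for i in range(c)],
                "period_start": pd.Timestamp("2024-01-01", tz="UTC"),
                "raw_aggregate": [float(v) for v, c in counts.items() for i in range(c)],
            }
        )
        defn = MetricDefinition(
            "hr", cap_low=min(counts) - 1.0, cap_high=max(counts) + 1.0,
            bucket_threshold=threshold,
        )
        return build_histogram(agg, defn, set(agg["user_id"]))

    def test_28_users_fails_a_30_threshold(self):
        hist = self._hist({60: 40, 61: 28, 62: 45}, 30)
        satisfied, failing = check_buckets(hist)
        assert not satisfied
        assert [(f.value, f.distinct_user_count, f.position) for f in failing] == [
            (61.0, 28, "interior")
        ]

    def test_edge_vs_interior_tagging(self):
        hist = self._hist({60: 5, 61: 40, 62: 3, 63: 40, 64: 2}, 30)
        _, failing = check_buckets(hist)
        positions = {f.value: f.position for f in failing}
        assert positions == {60.0: "edge", 62.0: "interior", 64.0: "edge"}

    def test_all_above_threshold_satisfied(self):
        satisfied, failing = check_buckets(self._hist({60: 31, 61: 30}, 30))
        assert satisfied and failing == []

    def test_threshold_one_is_vacuous(self):
        satisfied, _ = check_buckets(self._hist({60: 1, 61: 1}, 1))
        assert satisfied


class TestMaskHistogram:
    def test_subthreshold_counts_absent_from_output(self):
        hist = TestCheckBuckets()._hist({60: 40, 61: 28, 62: 45}, 30)
        masked = mask_histogram(hist)
        row = next(r for r in masked if r["bucket_value"] == 61.0)
        assert row["distinct_user_count"] == "<30"
        text = format_histogram(masked)
        assert "28" not in text
        assert "<30" in text

    def test_satisfying_histogram_unchanged(self):
        hist = TestCheckBuckets()._hist({60: 40, 61: 45}, 30)
        masked = mask_histogram(hist)
        assert [r["distinct_user_count"] for r in masked] == [40, 45]

    def test_empty_histogram_masks_to_empty(self):
        agg = pd.DataFrame(columns=["user_id", "period_start", "raw_aggregate"])
        defn = MetricDefinition("hr", cap_low=0, cap_high=1)
        assert mask_histogram(build_histogram(agg, defn, set())) == []


class TestAdjust:
    def test_already_satisfying_is_fixed_point(self):
        hist_src = {60: 40, 61: 35, 62: 50}
        agg = pd.DataFrame(
            {
                "user_id": [f"u{v}_{i}" for v, c in hist_src.items() for i in range(c)],
                "period_start": pd.Timestamp("2024-01-01", tz="UTC"),
                "raw_aggregate": [float(v) for v, c in hist_src.items() for i in range(c)],
            }
        )
        defn = MetricDefinition("hr", cap_low=59.0, cap_high=63.0, bucket_threshold=30)
        res = adjust(agg, defn, set(agg["user_id"]))
        assert res.satisfied
        assert res.steps == []
        assert res.final_definition.rounding_factor == defn.rounding_factor

    def test_single_edge_bucket_fixed_by_one_cap_step(self):
        """One low-edge bucket with threshold-1 users: the search must fix it
        with exactly one tighten_cap_low step — the same answer exhaustive
        search over the schedule finds."""
        counts = {60: 29, 61: 40, 62: 40, 63: 40}
        agg = pd.DataFrame(
            {
                "user_id": [f"u{v}_{i}" for v, c in counts.items() for i in range(c)],
                "period_start": pd.Timestamp("2024-01-01", tz="UTC"),
                "raw_aggregate": [float(v) for v, c in counts.items() for i in range(c)],
            }
        )
        defn = MetricDefinition("hr", cap_low=59.5, cap_high=63.5, bucket_threshold=30)
        res = adjust(agg, defn, set(agg["user_id"]))
        assert res.satisfied
        assert [s.action for s in res.steps] == ["tighten_cap_low"]
        assert res.caps.low == 61.0
        # the 29 winsorized users merged into the 61 bucket
        assert res.histogram.buckets[61].distinct_user_count == 69

        # exhaustive oracle: among all (cap-steps, schedule factor) states in
        # search order, the first satisfying state is this one-step capping
        def satisfied_at(lo, factor):
            d = dataclasses.replace(defn, rounding_factor=factor)
            h = build_histogram(agg, d, set(agg["user_id"]), caps=Caps(lo, 63.5))
            return check_buckets(h)[0]

        assert not satisfied_at(59.5, 1.0)
        assert satisfied_at(61.0, 1.0)

    def test_interior_failure_advances_rounding_schedule(self):
        counts = {60: 40, 61: 10, 62: 40}
        agg = pd.DataFrame(
            {
                "user_id": [f"u{v}_{i}" for v, c in counts.items() for i in range(c)],
                "period_start": pd.Timestamp("2024-01-01", tz="UTC"),
                "raw_aggregate": [float(v) for v, c in counts.items() for i in range(c)],
            }
        )
        defn = MetricDefinition("hr", cap_low=59.5, cap_high=62.5, bucket_threshold=30)
        res = adjust(agg, defn, set(agg["user_id"]))
        assert res.satisfied
        assert "increase_rounding" in [s.action for s in res.steps]

    def test_exhausted_search_reports_failure_not_export(self):
        # two users can never satisfy a 30-user threshold
        agg = pd.DataFrame(
            {
                "user_id": ["u1", "u2"],
                "period_start": pd.Timestamp("2024-01-01", tz="UTC"),
                "raw_aggregate": [60.0, 61.0],
            }
        )
        defn = MetricDefinition("hr", cap_low=59.0, cap_high=62.0, bucket_threshold=30)
        res = adjust(agg, defn, {"u1", "u2"})
        assert not res.satisfied
        assert res.steps  # the attempted escalations are logged

    def test_satisfied_result_passes_rebuild_from_scratch(self, medium_cohort):
        """Adjustment soundness: rebuilding the histogram from the final
        definition reproduces a passing check."""
        defn = MetricDefinition("resting_heart_rate", bucket_threshold=30)
        agg = aggregate(medium_cohort.measurements, defn)
        eligible = set(agg["user_id"])
        res = adjust(agg, defn, eligible, measurements=medium_cohort.measurements)
        assert res.satisfied
        fresh_agg = aggregate(medium_cohort.measurements, res.final_definition)
        fresh = build_histogram(
            fresh_agg, res.final_definition, eligible, caps=res.caps
        )
        assert check_buckets(fresh)[0]
        assert fresh.min_distinct_user_count() >= 30

    def test_period_lengthening_engages_when_schedule_exhausted(self):
        """A sparse daily metric that cannot satisfy the threshold at any
        rounding factor escalates to weekly aggregation."""
        rng = np.random.default_rng(5)
        n = 120
        rows = []
        for i in range(n):
            for day in range(7):
                rows.append(
                    (
                        f"u{i:03d}",
                        pd.Timestamp("2024-01-01", tz="UTC") + pd.Timedelta(days=day),
                        float(rng.normal(65, 8)),
                    )
                )
        m = pd.DataFrame(
            {
                "user_id": [r[0] for r in rows],
                "metric_name": "hr",
                "timestamp": [r[1] for r in rows],
                "value": [r[2] for r in rows],
            }
        )
        defn = MetricDefinition(
            "hr", period="day", bucket_threshold=100,
            rounding_schedule=(1.0, 2.0),
        )
        agg = aggregate(m, defn)
        res = adjust(agg, defn, set(m["user_id"]), measurements=m)
        actions = [s.action for s in res.steps]
        assert "lengthen_period" in actions
        assert res.final_definition.period in ("week", "month")


def test_nearest_rank_quantile_bounds():
    s = np.array([1.0, 2.0, 3.0, 4.0])
    assert nearest_rank_quantile(s, 0.0) == 1.0
    assert nearest_rank_quantile(s, 1.0) == 4.0
    assert nearest_rank_quantile(s, 0.5) == 2.0  # ceil(0.5*4)=2
    assert nearest_rank_quantile(s, 0.51) == 3.0


def test_cap_series_matches_scalar(medium_cohort):
    agg = aggregate(medium_cohort.measurements, MetricDefinition("resting_heart_rate"))
    values = agg["raw_aggregate"].to_numpy()[:500]
    capped, direction = cap_series(values, Caps(55.0, 75.0))
    for x, c, d in zip(values, capped, direction):
        assert (c, d) == cap_value(float(x), 55.0, 75.0)
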