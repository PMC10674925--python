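"""CMA9 engine: interval arithmetic, carryover, windows, refill durations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adhertraj import (
    ObservationPeriod,
    assign_refill_durations,
    compute_cma9,
    compute_cma9_windows,
    daily_ratio_vector,
    supply_intervals,
)
from conftest import daily_oracle, random_event_stream, sv_events


class TestDailyRatioVector:
    def test_full_coverage_gives_all_ones(self):
        period = ObservationPeriod(0, 90)
        events = sv_events([(0, 30), (30, 30), (60, 30)])
        assert np.array_equal(daily_ratio_vector(events, period), np.ones(90))

    def test_single_fill_spreads_over_remaining_period(self):
        # one 30-day fill over a 90-day period: every covered day 30/90
        period = ObservationPeriod(0, 90)
        vec = daily_ratio_vector(sv_events([(0, 30)]), period)
        assert np.allclose(vec, 30 / 90)

    def test_carryover_chains_left_to_right(self):
        # 60 d supply at day 0 caps the first 30-day interval at 1 and
        # carries 30 d forward; with the day-30 fill the second interval is
        # also fully covered
        period = ObservationPeriod(0, 90)
        events = sv_events([(0, 60), (30, 30)])
        intervals = supply_intervals(events, period)
        assert intervals[0].ratio == 1.0 and intervals[0].carryover_out == 30.0
        assert intervals[1].ratio == 1.0
        assert np.array_equal(daily_ratio_vector(events, period), np.ones(90))

    def test_no_events_gives_zero_vector(self):
        vec = daily_ratio_vector([], ObservationPeriod(0, 90))
        assert np.array_equal(vec, np.zeros(90))

    def test_days_before_first_fill_are_zero(self):
        vec = daily_ratio_vector(sv_events([(10, 30)]), ObservationPeriod(0, 90))
        assert np.array_equal(vec[:10], np.zeros(10))
        assert np.allclose(vec[10:], 30 / 80)

    def test_same_day_fills_merge_by_summing(self):
        period = ObservationPeriod(0, 60)
        merged = daily_ratio_vector(sv_events([(0, 20), (0, 10)]), period)
        single = daily_ratio_vector(sv_events([(0, 30)]), period)
        assert np.array_equal(merged, single)

    def test_matches_daily_oracle_on_random_streams(self):
        rng = np.random.default_rng(2024)
        period = ObservationPeriod(0, 365)
        for _ in range(200):
            events = random_event_stream(rng, period)
            got = daily_ratio_vector(events, period)
            want = daily_oracle(events, period)
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestComputeCma9:
    def test_two_spaced_fills_worked_example(self):
        # fills day 0 (30 d) and day 60 (30 d) in 90 d:
        # days 0-59 at 30/60, days 60-89 at 1 -> (60*0.5 + 30*1)/90
        period = ObservationPeriod(0, 90)
        cma = compute_cma9(sv_events([(0, 30), (60, 30)]), period)
        assert cma == pytest.approx((60 * 0.5 + 30 * 1.0) / 90, abs=1e-12)

    def test_conservation_closed_form(self):
        # monthly fills days 0..150 over 360 d: no capping, no end overflow,
        # so CMA9 = total supply / period length exactly
        period = ObservationPeriod(0, 360)
        events = sv_events([(d, 30) for d in range(0, 151, 30)])
        assert compute_cma9(events, period) == pytest.approx(180 / 360, abs=1e-15)

    def test_no_fills_is_zero(self):
        assert compute_cma9([], ObservationPeriod(0, 365)) == 0.0

    def test_end_period_overflow_is_discarded(self):
        # 90 d supply filled 30 d before the period end: only 30 d count
        period = ObservationPeriod(0, 365)
        cma = compute_cma9(sv_events([(335, 90)]), period)
        assert cma == pytest.approx(30 / 365, abs=1e-12)

    def test_invalid_period_rejected(self):
        with pytest.raises(ValueError):
            ObservationPeriod(0, 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_added_fills(self, seed):
        # adding any fill never decreases overall CMA9
        rng = np.random.default_rng(seed)
        period = ObservationPeriod(0, 180)
        events = random_event_stream(rng, period)
        base = compute_cma9(events, period)
        extra = sv_events([(int(rng.integers(0, 180)), int(rng.integers(1, 91)))])
        assert compute_cma9(events + extra, period) >= base - 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_conservation_without_capping(self, seed):
        # widely spaced small fills: no interval capped, no end overflow
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        days = np.sort(rng.choice(np.arange(0, 280, 70), size=n, replace=False))
        supplies = rng.integers(1, 31, size=n)
        if days[-1] + supplies[-1] > 365:
            supplies[-1] = 365 - days[-1]
        events = sv_events(zip(days, supplies))
        period = ObservationPeriod(0, 365)
        assert compute_cma9(events, period) == pytest.approx(
            supplies.sum() / 365, abs=1e-12
        )


class TestWindows:
    def test_perfect_monthly_refills_all_windows_one(self):
        # refills every 30 days through day 360 keep every interval covered
        period = ObservationPeriod(0, 365)
        events = sv_events([(d, 30) for d in range(0, 361, 30)])
        traj = compute_cma9_windows(events, period)
        assert len(traj.values) == 12
        assert np.allclose(traj.values, 1.0)

    def test_six_months_then_stop(self):
        # fills months 1-6 (days 0..150), nothing after: first five windows
        # fully covered; the last fill's 30 d spread over days 150-359 at
        # 30/215 (interval runs to period end, day 365)
        period = ObservationPeriod(0, 365)
        events = sv_events([(d, 30) for d in range(0, 151, 30)])
        traj = compute_cma9_windows(events, period)
        assert np.allclose(traj.values[:5], 1.0)
        assert np.allclose(traj.values[5:], 30 / 215)

    def test_single_initial_fill_flat_tail(self):
        period = ObservationPeriod(0, 365)
        traj = compute_cma9_windows(sv_events([(0, 30)]), period)
        assert np.allclose(traj.values, 30 / 365)
        assert traj.overall == pytest.approx(30 / 365)

    def test_window_means_consistent_with_overall(self):
        # window means weighted by window length equal the overall CMA9
        # restricted to the windowed days
        rng = np.random.default_rng(5)
        period = ObservationPeriod(0, 365)
        for _ in range(50):
            events = random_event_stream(rng, period)
            traj = compute_cma9_windows(events, period)
            daily = daily_ratio_vector(events, period)
            assert traj.values.mean() == pytest.approx(daily[:360].mean(), abs=1e-12)
            assert traj.overall == pytest.approx(daily.mean(), abs=1e-12)

    def test_values_stay_in_unit_interval(self):
        rng = np.random.default_rng(6)
        period = ObservationPeriod(0, 365)
        for _ in range(50):
            traj = compute_cma9_windows(random_event_stream(rng, period), period)
            assert ((traj.values >= 0) & (traj.values <= 1)).all()
            assert 0 <= traj.overall <= 1

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            compute_cma9_windows([], ObservationPeriod(0, 365), window_days=0)


class TestAssignRefillDurations:
    def test_fixed30_sets_every_supply(self):
        events = sv_events([(0, 45), (40, 60), (100, 90)])
        out = assign_refill_durations(events, "fixed30")
        assert [e.days_supply for e in out] == [30, 30, 30]

    def test_sampled_keeps_first_fill_and_is_reproducible(self):
        events = sv_events([(d, 30) for d in range(0, 300, 30)])
        a = assign_refill_durations(events, "sampled", rng=np.random.default_rng(3))
        b = assign_refill_durations(events, "sampled", rng=np.random.default_rng(3))
        assert a[0].days_supply == 30
        assert [e.days_supply for e in a] == [e.days_supply for e in b]
        assert set(e.days_supply for e in a) <= {30, 60, 90}

    def test_sampled_durations_uniform_in_the_limit(self):
        events = sv_events([(d, 30) for d in range(10_001)])
        out = assign_refill_durations(events, "sampled", rng=np.random.default_rng(9))
        freqs = np.array(
            [sum(e.days_supply == d for e in out[1:]) for d in (30, 60, 90)]
        ) / 10_000
        assert np.allclose(freqs, 1 / 3, atol=0.02)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            assign_refill_durations(sv_events([(0, 30)]), "weekly")
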