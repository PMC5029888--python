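"""Healing-trajectory statistics: closed forms, properties, generators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woundpatch import (
    WoundSeries,
    decrease_rate,
    group_table,
    half_decrement_day,
    summarize_series,
)
from woundpatch.healing import (
    exponential_half_day,
    exponential_series,
    simulate_cohort,
    summaries_to_frame,
)


def series(obs, **kw):
    return WoundSeries("p1", tuple(obs), **kw)


class TestDecreaseRate:
    def test_examples(self):
        assert decrease_rate(10, 5) == 50.0
        assert decrease_rate(12.57, 12.57) == 0.0
        assert decrease_rate(8.0, 2.0) == 75.0

    def test_negative_when_wound_grew(self):
        assert decrease_rate(5.0, 7.5) == -50.0

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValueError):
            decrease_rate(0.0, 1.0)

    @given(
        st.floats(0.5, 100.0),
        st.floats(0.0, 100.0),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, a0, af, c):
        assert decrease_rate(c * a0, c * af) == pytest.approx(decrease_rate(a0, af), rel=1e-9)


class TestHalfDecrementDay:
    def test_exact_hit_at_observation(self):
        assert half_decrement_day(series([(0, 10), (10, 6), (20, 2)])) == 10.0

    def test_linear_interpolation(self):
        assert half_decrement_day(series([(0, 10), (14, 4)])) == pytest.approx(7.0)

    def test_single_observation_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            half_decrement_day(series([(0, 5)]))

    def test_growing_wound_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            half_decrement_day(series([(0, 5), (10, 6)]))

    def test_non_monotonic_first_crossing_wins(self):
        # threshold 6; crosses between day 10 (8) and day 20 (4), recrosses later
        s = series([(0, 10), (10, 8), (20, 4), (30, 7), (40, 2)])
        assert half_decrement_day(s) == pytest.approx(15.0)

    def test_nearest_mode_snaps_to_visit(self):
        # crossing at day 10.67, bracketed by visits 6 and 20 -> snaps to 6
        s = series([(0, 10), (6, 8), (20, 2)])
        assert half_decrement_day(s, mode="nearest") == 6.0
        # threshold 5.5 crossed at t = 6.46 between visits 2 and 10 -> 10
        s2 = series([(0, 10), (2, 9.9), (10, 2), (20, 1)])
        assert half_decrement_day(s2, mode="nearest") == 10.0

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_time_dilation(self, c):
        base = series([(0, 10), (7, 6), (21, 2)])
        dilated = series([(0, 10), (7 * c, 6), (21 * c, 2)])
        assert half_decrement_day(dilated) == pytest.approx(c * half_decrement_day(base), rel=1e-9)

    @given(
        st.lists(st.floats(0.1, 0.95), min_size=2, max_size=8).map(sorted),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_monotone_series_crossing_interior(self, drops):
        """For a strictly decreasing series the half-decrement day lies
        strictly between day 0 and the final day."""
        areas = [10.0] + [10.0 * (1 - d) for d in drops]
        if len(set(np.round(areas, 12))) != len(areas):
            return  # duplicates would break strict monotonicity
        days = list(np.arange(len(areas)) * 7.0)
        t = half_decrement_day(series(list(zip(days, areas))))
        assert 0.0 < t <= days[-1]

    def test_exponential_recovery_close_to_analytic(self):
        s = exponential_series(a0_cm2=10.0, decay_per_day=0.1, n_weeks=8, noise_cv=0.0)
        analytic = exponential_half_day(0.1, 56.0)
        assert half_decrement_day(s) == pytest.approx(analytic, abs=1.0)


class TestSummarize:
    def test_basic_summary(self):
        s = summarize_series(series([(0, 2.0), (30, 0.5)]))
        assert s.decrease_rate_pct == 75.0
        assert s.half_decrement_day == pytest.approx(15.0)
        assert s.follow_up_days == 30.0
        assert s.n_observations == 2

    def test_flat_series_undefined_half_day(self):
        s = summarize_series(series([(0, 1.0), (10, 1.0)]))
        assert s.decrease_rate_pct == 0.0
        assert s.half_decrement_day is None

    def test_series_validation(self):
        with pytest.raises(ValueError, match="day 0"):
            series([(5, 1.0)])
        with pytest.raises(ValueError, match="increasing"):
            series([(0, 1.0), (0, 0.5)])
        with pytest.raises(ValueError, match="positive"):
            series([(0, 1.0), (5, -0.5)])


class TestGroupTable:
    def test_two_point_sd(self):
        sums = [
            summarize_series(series([(0, 10), (10, 5)])),  # 50%
            summarize_series(series([(0, 10), (10, 3)])),  # 70%
        ]
        tbl = group_table(sums, ["g", "g"])
        assert tbl.loc[0, "n"] == 2
        assert tbl.loc[0, "decrease_mean"] == pytest.approx(60.0)
        assert tbl.loc[0, "decrease_sd"] == pytest.approx(math.sqrt(200), rel=1e-9)

    def test_empty_group_gives_na_row(self):
        sums = [summarize_series(series([(0, 10), (10, 5)]))]
        tbl = group_table(sums + sums, ["a", "a"])
        tbl2 = group_table([], [])
        assert len(tbl2) == 0
        # explicit empty label handling
        tbl3 = group_table(sums, ["a"])
        assert "b" not in set(tbl3["group"])

    def test_undefined_half_days_counted(self):
        sums = [
            summarize_series(series([(0, 10), (10, 5)])),
            summarize_series(series([(0, 10), (10, 10)])),  # flat: undefined
        ]
        tbl = group_table(sums, ["g", "g"])
        assert tbl.loc[0, "n_half_undefined"] == 1

    def test_cohort_recovers_generator_means(self):
        """Seeded cohorts with the two site-group decrease-rate
        distributions: group means (averaged over seeded cohorts of n=30,
        sampling SE per cohort ~2.3) recovered within 3 points."""
        means = {"facial": [], "non_facial": []}
        for seed in range(8):
            tbl = group_table(simulate_cohort(n_per_group=30, seed=seed)).set_index("group")
            for g in means:
                means[g].append(tbl.loc[g, "decrease_mean"])
        assert abs(np.mean(means["facial"]) - 67.05) < 3.0
        assert abs(np.mean(means["non_facial"]) - 53.29) < 3.0

    def test_cohort_sd_and_sizes(self):
        summaries = simulate_cohort(n_per_group=30, seed=2)
        tbl = group_table(summaries).set_index("group")
        assert tbl.loc["facial", "n"] == 30 and tbl.loc["non_facial", "n"] == 30
        # SDs in the right neighborhood of the generator values
        assert 7 < tbl.loc["facial", "decrease_sd"] < 19
        assert 11 < tbl.loc["non_facial", "decrease_sd"] < 26

    def test_summaries_frame_columns(self):
        df = summaries_to_frame(simulate_cohort(n_per_group=3, seed=0))
        assert list(df.columns) == [
            "patient_id",
            "site_class",
            "initial_area_cm2",
            "final_area_cm2",
            "decrease_rate_pct",
            "half_decrement_day",
            "n_obs",
            "follow_up_days",
        ]
        assert len(df) == 6
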