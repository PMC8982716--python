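"""Cleaning operations: gap detection, interpolation, filtering,
extrapolation, time index and the transfer corpus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmdrnn import (
    SimScenario,
    build_transfer_corpus,
    detect_gaps,
    extrapolate_forward,
    fill_gaps_linear,
    inject_missingness,
    median_filter,
    simulate_subject,
    time_index,
)
from tests.helpers import make_series


class TestDetectGaps:
    def test_fully_valid(self, small_series):
        assert detect_gaps(small_series) == []

    def test_zero_readings_form_gap(self):
        g = np.full(40, 120.0)
        g[10:20] = 0.0  # ten zero readings, clinical missing convention
        s = make_series(g)
        assert detect_gaps(s) == [(10, 10)]

    def test_run_length_encoding(self):
        valid = np.ones(12, bool)
        valid[[3, 4, 9]] = False
        s = make_series(np.full(12, 100.0), valid)
        assert detect_gaps(s) == [(3, 2), (9, 1)]

    def test_boundary_gaps(self):
        valid = np.ones(6, bool)
        valid[[0, 5]] = False
        s = make_series(np.full(6, 100.0), valid)
        assert detect_gaps(s) == [(0, 1), (5, 1)]


class TestFillGapsLinear:
    def test_linear_values(self):
        g = np.array([100.0, 0, 0, 0, 0, 150.0])
        valid = g > 0
        out = fill_gaps_linear(make_series(g, valid), max_gap_slots=10)
        np.testing.assert_allclose(out.glucose, [100, 110, 120, 130, 140, 150])
        assert out.valid_mask.all()

    def test_threshold_policy(self):
        g = np.concatenate([[100.0], np.zeros(5), [160.0]])
        s = make_series(g, g > 0)
        out = fill_gaps_linear(s, max_gap_slots=4)  # gap of 5 > cap
        assert not out.valid_mask[1:6].any()
        np.testing.assert_array_equal(out.glucose, g)

    def test_ten_slot_gap_filled(self, small_series):
        broken = inject_missingness(small_series, [206], [10])  # 17:10-18:00
        out = fill_gaps_linear(broken, max_gap_slots=24)
        assert out.valid_mask.all()
        filled = out.glucose[206:216]
        lo = min(small_series.glucose[205], small_series.glucose[216])
        hi = max(small_series.glucose[205], small_series.glucose[216])
        assert ((filled >= lo - 1e-9) & (filled <= hi + 1e-9)).all()

    def test_boundary_gap_unfilled(self):
        g = np.array([0.0, 0, 110, 120])
        s = make_series(g, g > 0)
        out = fill_gaps_linear(s, max_gap_slots=10)
        assert not out.valid_mask[:2].any()

    def test_idempotent_and_preserves_valid(self, small_series):
        broken = inject_missingness(small_series, [50, 300], [4, 8])
        once = fill_gaps_linear(broken, 24)
        twice = fill_gaps_linear(once, 24)
        np.testing.assert_array_equal(once.glucose, twice.glucose)
        keep = broken.valid_mask
        np.testing.assert_array_equal(
            once.glucose[keep], small_series.glucose[keep]
        )


class TestMedianFilter:
    def test_spike_removed(self):
        s = make_series([100, 100, 400, 100, 100])
        out = median_filter(s, 3)
        np.testing.assert_array_equal(out.glucose, np.full(5, 100.0))

    def test_monotone_unchanged(self):
        g = np.linspace(80, 200, 25)
        out = median_filter(make_series(g), 5)
        np.testing.assert_allclose(out.glucose, g)

    def test_even_window_rejected(self, small_series):
        with pytest.raises(ValueError):
            median_filter(small_series, 4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(40, 400), min_size=7, max_size=60), st.integers(0, 3))
    def test_matches_brute_force(self, values, khalf):
        """Shrinking-window running median equals a per-slot sort oracle."""
        w = 2 * khalf + 1
        g = np.asarray(values)
        out = median_filter(make_series(g), w).glucose
        n = len(g)
        for i in range(n):
            k = min(khalf, i, n - 1 - i)
            assert out[i] == pytest.approx(sorted(g[i - k : i + k + 1])[k])

    def test_bounded_by_window(self, small_series):
        out = median_filter(small_series, 5)
        g = small_series.glucose
        for i in range(2, len(g) - 2):
            win = g[i - 2 : i + 3]
            assert win.min() <= out.glucose[i] <= win.max()
        np.testing.assert_array_equal(out.bolus, small_series.bolus)


class TestExtrapolate:
    def test_slope_continuation(self):
        est, flagged = extrapolate_forward([100.0, 110.0], [True, True], 1)
        assert est[0] == pytest.approx(120.0)
        assert not flagged

    def test_constant_history(self):
        est, _ = extrapolate_forward(np.full(8, 140.0), np.ones(8, bool), 3)
        np.testing.assert_allclose(est, 140.0)

    def test_matches_least_squares_oracle(self, rng):
        t = np.arange(12, dtype=float)
        g = 90.0 + 2.5 * t + rng.normal(0, 3, 12)
        est, flagged = extrapolate_forward(g, np.ones(12, bool), 4, trend_slots=6)
        slope, icept = np.polyfit(t[-6:], g[-6:], 1)
        np.testing.assert_allclose(est, icept + slope * np.arange(12, 16), atol=1e-9)
        assert not flagged

    def test_fallback_hold_last(self):
        est, flagged = extrapolate_forward([0.0, 0.0, 130.0],
                                           [False, False, True], 2)
        assert flagged
        np.testing.assert_allclose(est, 130.0)

    def test_causal_ignores_mask_gaps(self):
        """Only trailing *valid* samples drive the trend."""
        g = np.array([500.0, 100.0, 110.0, 120.0])
        mask = np.array([False, True, True, True])
        est, _ = extrapolate_forward(g, mask, 1, trend_slots=3)
        assert est[0] == pytest.approx(130.0)


class TestTimeIndex:
    @pytest.mark.parametrize(
        "ts,expect",
        [
            ("2024-03-01T00:00", 0.0),
            ("2024-03-01T12:00", 0.5),
            ("2024-03-01T23:55", 287 / 288),
            ("2024-03-02T06:00", 0.25),
        ],
    )
    def test_values(self, ts, expect):
        assert time_index(np.datetime64(ts)) == pytest.approx(expect)

    def test_periodic_and_injective(self):
        day1 = [time_index(np.datetime64("2024-01-01T00:00") + i * np.timedelta64(5, "m"))
                for i in range(288)]
        day2 = [time_index(np.datetime64("2024-01-02T00:00") + i * np.timedelta64(5, "m"))
                for i in range(288)]
        assert day1 == day2
        assert len(set(day1)) == 288

    def test_off_grid_rejected(self):
        with pytest.raises(ValueError):
            time_index(np.datetime64("2024-01-01T00:03"))


class TestTransferCorpus:
    def _cohort(self, target_days=5, donor_days=3):
        target = simulate_subject(SimScenario(n_days=target_days, seed=0), "tgt")
        donors = [
            simulate_subject(SimScenario(n_days=donor_days, seed=10 + i), f"d{i}")
            for i in range(5)
        ]
        return target, donors

    def test_shares_and_total_length(self):
        target, donors = self._cohort()
        corpus = build_transfer_corpus(target, donors)
        assert corpus[0] is target
        share = len(target) // 5
        assert all(len(p) == share for p in corpus[1:])
        assert sum(len(p) for p in corpus) == 2 * len(target)

    def test_donor_block_is_final_contiguous(self):
        target, donors = self._cohort()
        corpus = build_transfer_corpus(target, donors)
        share = len(target) // 5
        np.testing.assert_array_equal(
            corpus[1].glucose, donors[0].glucose[-share:]
        )

    def test_short_donor_named_in_error(self):
        target, donors = self._cohort(target_days=5, donor_days=3)
        short = donors[2]
        short.glucose = short.glucose[:100]
        short.bolus = short.bolus[:100]
        short.meal = short.meal[:100]
        short.valid_mask = short.valid_mask[:100]
        with pytest.raises(ValueError, match="d2"):
            build_transfer_corpus(target, donors)
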