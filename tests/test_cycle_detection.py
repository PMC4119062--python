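"""Smoothing, extremum detection, confirmation and cycle segmentation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutatrack import (
    DataError,
    Edit,
    Extreme,
    confirm_extrema,
    detect_extrema,
    detect_northward_maxima,
    moving_average,
    prune_false_extrema,
    read_extremes_review,
    segment_cycles,
    write_extremes_review,
)
from nutatrack.cycle_detection import Axis, Kind

from conftest import make_trajectory


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        out = moving_average([4.0] * 9, 5)
        np.testing.assert_allclose(out, 4.0)

    def test_window_one_is_identity(self):
        s = [1.0, -2.0, 3.5, 0.0]
        np.testing.assert_allclose(moving_average(s, 1), s)

    def test_edges_use_truncated_windows(self):
        out = moving_average([0, 3, 0, 3, 0], 3)
        np.testing.assert_allclose(out, [1.5, 1, 2, 1, 1.5])

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            moving_average([1, 2, 3, 4, 5], window)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            moving_average([1, 2, 3], 5)

    def test_mean_preserved_on_constant_and_linear_series(self):
        lin = np.arange(11, dtype=float)
        assert moving_average(lin, 5).mean() == pytest.approx(lin.mean())
        const = np.full(11, 2.5)
        assert moving_average(const, 5).mean() == pytest.approx(2.5)


class TestDetectExtrema:
    def test_sampled_sine_matches_argmax_oracle(self):
        # two full periods, 40 samples each
        n, period = 80, 40
        s = np.sin(2 * np.pi * np.arange(n) / period)
        ext = detect_extrema(s)
        maxima = [e.index for e in ext if e.kind is Kind.MAXIMUM]
        minima = [e.index for e in ext if e.kind is Kind.MINIMUM]
        # oracle: argmax/argmin over each half-period window
        expected_max = [int(np.argmax(s[:period])), period + int(np.argmax(s[period:]))]
        expected_min = [
            int(np.argmin(s[: period + period // 2])),
            period + int(np.argmin(s[period:])),
        ]
        assert maxima == expected_max
        assert minima == expected_min

    def test_monotone_series_has_no_extrema(self):
        assert detect_extrema([1.0, 2.0, 3.0, 4.0]) == []

    def test_plateau_collapses_to_midpoint(self):
        ext = detect_extrema([0, 1, 1, 1, 0])
        assert len(ext) == 1
        assert ext[0].index == 2 and ext[0].kind is Kind.MAXIMUM

    def test_even_plateau_breaks_toward_earlier_sample(self):
        ext = detect_extrema([0, 1, 1, 0])
        assert [e.index for e in ext] == [1]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_extrema([1.0, 2.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=3,
            max_size=60,
        )
    )
    def test_extrema_alternate_and_are_sorted(self, series):
        ext = detect_extrema(series)
        kinds = [e.kind for e in ext]
        idx = [e.index for e in ext]
        assert idx == sorted(idx)
        assert all(a != b for a, b in zip(kinds[:-1], kinds[1:]))

    @pytest.mark.parametrize("window", [1, 3, 5, 7])
    def test_noiseless_sinusoid_maxima_spacing_within_one_sample(self, window):
        period = 30  # samples; window <= period/4
        n = 5 * period
        s = np.sin(2 * np.pi * np.arange(n) / period)
        sm = moving_average(s, window)
        maxima = [e.index for e in detect_extrema(sm) if e.kind is Kind.MAXIMUM]
        spacings = np.diff(maxima)
        assert np.all(np.abs(spacings - period) <= 1)


class TestPruneFalseExtrema:
    def test_noise_doublets_are_removed(self):
        period = 40
        n = 4 * period
        rng = np.random.default_rng(5)
        s = np.sin(2 * np.pi * np.arange(n) / period) + rng.normal(0, 0.05, n)
        cand = detect_extrema(s)
        pruned = prune_false_extrema(cand, s)
        maxima = [e for e in pruned if e.kind is Kind.MAXIMUM]
        assert len(maxima) == 4
        kinds = [e.kind for e in pruned]
        assert all(a != b for a, b in zip(kinds[:-1], kinds[1:]))

    def test_clean_extrema_survive(self):
        period = 40
        s = np.sin(2 * np.pi * np.arange(3 * period) / period)
        cand = detect_extrema(s)
        assert prune_false_extrema(cand, s) == cand


class TestConfirmExtrema:
    def _cands(self):
        return [
            Extreme(index=i, axis=Axis.Y, kind=Kind.MAXIMUM) for i in (5, 20, 35, 50, 65)
        ]

    def test_no_edits_accepts_all(self):
        out = confirm_extrema(self._cands())
        assert len(out) == 5 and all(e.accepted for e in out)

    def test_reject_edit_removes_one(self):
        out = confirm_extrema(self._cands(), [Edit("reject", 35)])
        assert [e.index for e in out] == [5, 20, 50, 65]

    def test_insert_keeps_strict_ordering(self):
        out = confirm_extrema(self._cands(), [Edit("insert", 27)])
        assert [e.index for e in out] == [5, 20, 27, 35, 50, 65]

    def test_edit_on_unknown_index_is_an_error(self):
        with pytest.raises(DataError):
            confirm_extrema(self._cands(), [Edit("reject", 999)])


class TestSegmentCycles:
    def _traj(self, n=70):
        xs = np.zeros(n)
        ys = np.cos(2 * np.pi * np.arange(n) / 30.0)
        return make_trajectory(np.column_stack([xs, ys]))

    def _maxima(self, indices):
        return [
            Extreme(index=i, axis=Axis.Y, kind=Kind.MAXIMUM, accepted=True)
            for i in indices
        ]

    def test_n_maxima_give_n_minus_one_cycles(self):
        cycles = segment_cycles(self._traj(), self._maxima([0, 30, 60]))
        assert [c.index for c in cycles] == [1, 2]

    def test_consecutive_cycles_share_their_boundary_point(self):
        traj = self._traj()
        c1, c2 = segment_cycles(traj, self._maxima([10, 30, 50]))
        assert c1.points[-1] is traj.points[30]
        assert c2.points[0] is traj.points[30]
        # partition: union covers the slice between first and last maxima
        assert len(c1.points) + len(c2.points) - 1 == 41

    def test_fewer_than_two_maxima_yield_no_cycles(self):
        assert segment_cycles(self._traj(), self._maxima([30])) == []

    def test_boundaries_must_be_y_maxima(self):
        bad = [
            Extreme(index=10, axis=Axis.Y, kind=Kind.MINIMUM, accepted=True),
            Extreme(index=40, axis=Axis.Y, kind=Kind.MAXIMUM, accepted=True),
        ]
        with pytest.raises(DataError):
            segment_cycles(self._traj(), bad)


class TestReviewFile:
    def test_round_trip(self, tmp_path):
        ext = [
            Extreme(index=4, axis=Axis.Y, kind=Kind.MAXIMUM, accepted=True),
            Extreme(index=19, axis=Axis.Y, kind=Kind.MINIMUM, accepted=False),
            Extreme(index=33, axis=Axis.Y, kind=Kind.MAXIMUM, accepted=True),
        ]
        p = tmp_path / "review.csv"
        write_extremes_review(ext, p)
        assert read_extremes_review(p) == ext


class TestDetectNorthwardMaxima:
    def test_finds_all_interior_maxima_of_noisy_oscillation(self):
        period, n = 36, 190
        rng = np.random.default_rng(11)
        t = np.arange(n)
        ys = 10 * np.cos(2 * np.pi * t / period) + rng.normal(0, 0.1, n)
        xs = 10 * np.sin(2 * np.pi * t / period) + rng.normal(0, 0.1, n)
        traj = make_trajectory(np.column_stack([xs, ys]))
        _, accepted = detect_northward_maxima(traj, window=5)
        assert len(accepted) == 5  # maxima at samples ~0,36,...,180; edges excluded
        for e, true_idx in zip(accepted, (36, 72, 108, 144, 180)):
            assert abs(e.index - true_idx) <= 1
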