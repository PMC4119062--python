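"""Ellipse fitting and the six per-cycle parameters."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutatrack import (
    Direction,
    FitError,
    TimedPoint,
    analyze_cycle,
    axis_angle,
    cycle_direction,
    fit_ellipse,
    fold_angle,
    path_length,
    period_minutes,
    rate,
    shape_coefficient,
    signed_area,
)
from nutatrack.core_io import Frame, Unit
from nutatrack.cycle_detection import Axis, Cycle, Extreme, Kind
from nutatrack.util import round_half_up

from conftest import ellipse_points


def make_cycle(xy, interval_min=5.0, index=1):
    t0 = datetime(2013, 7, 30, 18, 0)
    pts = [
        TimedPoint(t0 + timedelta(minutes=i * interval_min), float(x), float(y))
        for i, (x, y) in enumerate(xy)
    ]
    start = Extreme(index=0, axis=Axis.Y, kind=Kind.MAXIMUM, accepted=True)
    end = Extreme(index=len(pts) - 1, axis=Axis.Y, kind=Kind.MAXIMUM, accepted=True)
    return Cycle(
        index=index,
        start_ext=start,
        end_ext=end,
        points=pts,
        units=Unit.MILLIMETRES,
        frame=Frame.GEOGRAPHIC,
    )


class TestFitEllipse:
    def test_exact_axis_aligned_samples(self):
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([20 * np.cos(t), 10 * np.sin(t)])
        fit = fit_ellipse(pts)
        assert fit.semi_major == pytest.approx(20.0, rel=1e-9)
        assert fit.semi_minor == pytest.approx(10.0, rel=1e-9)
        assert fit.center == pytest.approx((0.0, 0.0), abs=1e-9)
        assert abs(fit.major_axis[1]) < 1e-9  # long axis along x

    def test_rigid_motion_moves_the_fit_rigidly(self):
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([20 * np.cos(t), 10 * np.sin(t)])
        theta = math.radians(30)
        R = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        moved = pts @ R.T + np.array([5.0, -3.0])
        fit = fit_ellipse(moved)
        assert fit.semi_major == pytest.approx(20.0, rel=1e-9)
        assert fit.semi_minor == pytest.approx(10.0, rel=1e-9)
        assert fit.center == pytest.approx((5.0, -3.0), abs=1e-8)
        expected_axis = R @ np.array([1.0, 0.0])
        cosang = abs(np.dot(fit.major_axis, expected_axis))
        assert cosang == pytest.approx(1.0, abs=1e-9)

    def test_small_radial_noise_recovers_axes_within_5_percent(self):
        t = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            radial = 1.0 + rng.normal(0, 0.01, t.size)
            pts = np.column_stack(
                [20 * radial * np.cos(t), 10 * radial * np.sin(t)]
            )
            fit = fit_ellipse(pts)
            assert fit.semi_major == pytest.approx(20.0, rel=0.05)
            assert fit.semi_minor == pytest.approx(10.0, rel=0.05)

    def test_fewer_than_five_points_rejected(self):
        with pytest.raises(FitError):
            fit_ellipse(np.array([[0, 0], [1, 1], [2, 0], [1, -1]]))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(FitError):
            fit_ellipse(pts)


class TestShapeCoefficient:
    def test_circle_is_one(self):
        fit = fit_ellipse(ellipse_points(10, 10 - 1e-9, n=24))
        assert shape_coefficient(fit) == pytest.approx(1.0, abs=1e-6)

    def test_two_to_one_ellipse_is_half(self):
        fit = fit_ellipse(ellipse_points(20, 10, n=24))
        assert shape_coefficient(fit) == pytest.approx(0.5, rel=1e-9)

    def test_very_narrow_ellipse_is_about_a_tenth(self):
        fit = fit_ellipse(ellipse_points(100, 10, n=24))
        assert shape_coefficient(fit) == pytest.approx(0.1, rel=1e-9)


class TestAxisAngle:
    @pytest.mark.parametrize(
        "angle_deg, expected",
        [(0.0, 0.0), (-45.0, -45.0), (60.0, 60.0)],
    )
    def test_convention_north_zero_east_negative(self, angle_deg, expected):
        fit = fit_ellipse(ellipse_points(20, 8, n=24, angle_deg=angle_deg))
        assert axis_angle(fit) == pytest.approx(expected, abs=1e-6)

    def test_east_west_axis_folds_to_90(self):
        # a pure EW axis sits on the fold seam: the fitted vector may come
        # out at either +-90 within float error, both meaning the same axis
        for src in (90.0, -90.0):
            fit = fit_ellipse(ellipse_points(20, 8, n=24, angle_deg=src))
            assert abs(axis_angle(fit)) == pytest.approx(90.0, abs=1e-6)

    def test_alternative_fold_maps_ew_axis_to_minus_90(self):
        fit = fit_ellipse(ellipse_points(20, 8, n=24, angle_deg=90.0))
        assert axis_angle(fit, fold_high_inclusive=False) == pytest.approx(
            -90.0, abs=1e-6
        )

    def test_fold_angle_range(self):
        assert fold_angle(135.0) == -45.0
        assert fold_angle(-90.0) == 90.0
        assert fold_angle(-90.0, fold_high_inclusive=False) == -90.0


class TestDirection:
    def test_increasing_polar_angle_is_ccw(self):
        pts = ellipse_points(10, 10 - 1e-9, n=24, ccw=True)
        assert cycle_direction(pts, fit_ellipse(pts)) is Direction.CCW

    def test_reversed_points_are_cw(self):
        pts = ellipse_points(10, 10 - 1e-9, n=24, ccw=True)[::-1]
        assert cycle_direction(pts, fit_ellipse(pts)) is Direction.CW

    def test_figure_eight_is_indeterminate(self):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        # two lobes of opposite orientation: signed areas cancel
        pts = np.column_stack([np.sin(2 * t) * 10, np.sin(t) * 10])
        assert cycle_direction(pts, fit_ellipse(pts)) is Direction.INDETERMINATE

    def test_degenerate_point_set_is_indeterminate(self):
        pts = np.zeros((6, 2))
        assert cycle_direction(pts) is Direction.INDETERMINATE

    def test_signed_area_of_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert signed_area(sq) == pytest.approx(1.0)
        assert signed_area(sq[::-1]) == pytest.approx(-1.0)


class TestScalarMetrics:
    def test_period_is_end_minus_start(self):
        c = make_cycle(ellipse_points(10, 5, n=27), interval_min=5.0)
        assert period_minutes(c) == pytest.approx(130.0)

    def test_path_length_of_collinear_points(self):
        c = make_cycle([(0, 0), (3, 4), (6, 8)])
        assert path_length(c) == pytest.approx(10.0)

    def test_path_length_of_closed_unit_square(self):
        c = make_cycle([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert path_length(c) == pytest.approx(4.0)

    def test_path_length_matches_manual_segment_sum(self):
        pts = ellipse_points(20, 10, n=36)
        closed = np.vstack([pts, pts[:1]])
        manual = sum(
            math.dist(p, q) for p, q in zip(closed[:-1], closed[1:])
        )
        c = make_cycle(closed)
        assert path_length(c) == pytest.approx(manual, rel=1e-12)

    @pytest.mark.parametrize(
        "length, period, printed",
        [(84, 180, 0.47), (118, 180, 0.66), (0, 100, 0.0)],
    )
    def test_rate_reproduces_printed_values(self, length, period, printed):
        assert round_half_up(rate(length, period), 2) == printed

    def test_zero_period_rejected(self):
        with pytest.raises(ValueError):
            rate(10, 0)


class TestAnalyzeCycle:
    def test_known_synthetic_cycle_recovered(self):
        pts = ellipse_points(15, 6, n=30, angle_deg=-40.0, ccw=False)
        closed = np.vstack([pts, pts[:1]])
        m = analyze_cycle(make_cycle(closed, interval_min=5.0))
        assert m.period_min == pytest.approx(150.0)
        assert m.shape == pytest.approx(0.4, abs=1e-6)
        assert m.angle_deg == pytest.approx(-40.0, abs=1e-6)
        assert m.direction is Direction.CW
        # internal consistency: rate x period == length pre-rounding
        assert m.rate_mm_per_min * m.period_min == pytest.approx(m.length_mm)

    def test_four_point_cycle_reports_timing_but_no_shape(self):
        m = analyze_cycle(make_cycle([(0, 1), (1, 0), (0, -1), (-1, 0)]))
        assert m.shape is None and m.angle_deg is None
        assert m.period_min == pytest.approx(15.0)
        assert m.length_mm > 0

    def test_reversal_flips_direction_and_nothing_else(self):
        pts = ellipse_points(12, 7, n=28, angle_deg=30.0)
        m_fwd = analyze_cycle(make_cycle(pts))
        m_rev = analyze_cycle(make_cycle(pts[::-1]))
        assert {m_fwd.direction, m_rev.direction} == {Direction.CW, Direction.CCW}
        assert m_fwd.length_mm == pytest.approx(m_rev.length_mm)
        assert m_fwd.shape == pytest.approx(m_rev.shape)
        assert m_fwd.angle_deg == pytest.approx(m_rev.angle_deg)

    def test_near_circular_angle_flagged_unreliable(self):
        pts = ellipse_points(10, 9.8, n=30)
        m = analyze_cycle(make_cycle(pts))
        assert m.shape > 0.95 and m.angle_unreliable
        assert m.angle_deg is not None  # still reported


class TestRigidMotionInvariance:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        theta=st.floats(min_value=-180, max_value=180),
        tx=st.floats(min_value=-50, max_value=50),
        ty=st.floats(min_value=-50, max_value=50),
    )
    def test_shape_length_invariant_angle_shifts(self, theta, tx, ty):
        pts = ellipse_points(18, 9, n=24, angle_deg=-30.0)
        rad = math.radians(theta)
        R = np.array(
            [[math.cos(rad), -math.sin(rad)], [math.sin(rad), math.cos(rad)]]
        )
        moved = pts @ R.T + np.array([tx, ty])
        f0, f1 = fit_ellipse(pts), fit_ellipse(moved)
        assert shape_coefficient(f1) == pytest.approx(
            shape_coefficient(f0), abs=1e-8
        )
        # a CCW rotation by theta increases the N-referenced angle by theta
        # (a north axis rotated CCW leans west, which is positive)
        expected = fold_angle(axis_angle(f0) + theta)
        diff = abs(axis_angle(f1) - expected) % 180.0
        assert min(diff, 180.0 - diff) < 1e-6
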