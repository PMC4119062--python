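"""Shared fixtures: small trajectories, calibrations and ellipse samplers."""

from __future__ import annotations

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from nutatrack import (
    CalibrationConfig,
    Frame,
    TimedPoint,
    Trajectory,
    Unit,
)

T0 = datetime(2013, 7, 30, 18, 0)


def make_trajectory(
    xy, start=T0, interval_min=5.0, units=Unit.MILLIMETRES, frame=Frame.GEOGRAPHIC
) -> Trajectory:
    pts = [
        TimedPoint(start + timedelta(minutes=i * interval_min), float(x), float(y))
        for i, (x, y) in enumerate(xy)
    ]
    return Trajectory(points=pts, units=units, frame=frame, plant_id="test")


def ellipse_points(
    a, b, n=36, angle_deg=0.0, center=(0.0, 0.0), ccw=True, phase=0.0
) -> np.ndarray:
    """Sample an ellipse with long axis ``angle_deg`` from north (E < 0)."""
    alpha = math.radians(angle_deg)
    v = np.array([-math.sin(alpha), math.cos(alpha)])
    w = np.array([-v[1], v[0]])
    phis = phase + (1 if ccw else -1) * np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.array(
        [np.asarray(center) + a * math.cos(p) * v + b * math.sin(p) * w for p in phis]
    )


@pytest.fixture
def identity_calibration() -> CalibrationConfig:
    """1 mm per px, no growth, origin at (0,0), y already north-up."""
    return CalibrationConfig(
        frame_width_mm=600.0,
        frame_width_px=600.0,
        camera_distance_mm=2000.0,
        height_start_mm=0.0,
        height_end_mm=0.0,
        t_start=T0,
        t_end=T0 + timedelta(hours=63),
        origin_px=(0.0, 0.0),
        y_axis="up",
    )


@pytest.fixture
def growth_calibration() -> CalibrationConfig:
    """Realistic setup: 300 mm frame over 600 px, plant growing 45 -> 114 mm."""
    return CalibrationConfig(
        frame_width_mm=300.0,
        frame_width_px=600.0,
        camera_distance_mm=2000.0,
        height_start_mm=45.0,
        height_end_mm=113.625,
        t_start=T0,
        t_end=T0 + timedelta(hours=63),
        origin_px=(300.0, 300.0),
        y_axis="down",
    )
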