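"""Pixel-to-millimetre conversion with top-view perspective correction.

A camera mounted above the pot images the apex of an organ that grows toward
it. Under a pinhole model the magnification at height ``h`` above the ground
scales as ``D / (D - h)`` where ``D`` is the camera-to-ground distance, so
the millimetres-per-pixel scale shrinks linearly from the ground calibration
as the plant elongates:

    scale(h) = (frame_width_mm / frame_width_px) * (D - h) / D

Only the plant height at the start and end of the experiment is measured;
height at intermediate frames is linearly interpolated. After scaling, the
image y axis (downward) is flipped so that y is north-positive and x remains
east-positive — the geographic frame in which all downstream parameters
(angle, direction) are defined.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, asdict
from datetime import datetime
from pathlib import Path
from typing import Tuple

import yaml

from .core_io import Frame, TimedPoint, Trajectory, Unit
from .errors import ConfigError, StateError

logger = logging.getLogger(__name__)


@dataclass
class CalibrationConfig:
    """Geometry of the recording setup.

    Parameters
    ----------
    frame_width_mm : float
        Physical width of the camera frame at ground level (mm), from filming
        a millimetre scale in the pot.
    frame_width_px : float
        Frame width in pixels.
    camera_distance_mm : float
        Camera-to-ground distance (mm).
    height_start_mm, height_end_mm : float
        Plant height at the start and end of the experiment (mm).
    t_start, t_end : datetime
        Timestamps bounding the experiment (height interpolation range).
    origin_px : tuple of float
        Pixel coordinates of the chosen origin, e.g. the organ base; the
        calibrated trajectory is expressed relative to this point.
    y_axis : {"down", "up"}
        Direction of increasing y in the *input* image. Standard image
        coordinates are "down"; they are flipped to north-up internally.
    """

    frame_width_mm: float
    frame_width_px: float
    camera_distance_mm: float
    height_start_mm: float
    height_end_mm: float
    t_start: datetime
    t_end: datetime
    origin_px: Tuple[float, float] = (0.0, 0.0)
    y_axis: str = "down"

    def __post_init__(self) -> None:
        if self.frame_width_mm <= 0 or self.frame_width_px <= 0:
            raise ConfigError("frame width must be positive")
        if self.camera_distance_mm <= 0:
            raise ConfigError("camera distance must be positive")
        for h in (self.height_start_mm, self.height_end_mm):
            if not (0 <= h < self.camera_distance_mm):
                raise ConfigError(
                    f"plant height {h} mm outside [0, camera distance "
                    f"{self.camera_distance_mm} mm)"
                )
        if self.t_start >= self.t_end:
            raise ConfigError("t_start must precede t_end")
        if self.y_axis not in ("down", "up"):
            raise ConfigError(f"y_axis must be 'down' or 'up', got {self.y_axis!r}")
        self.origin_px = (float(self.origin_px[0]), float(self.origin_px[1]))

    @property
    def ground_scale(self) -> float:
        """mm per pixel at ground level."""
        return self.frame_width_mm / self.frame_width_px

    def content_hash(self) -> str:
        """Short stable digest of the configuration, for run logging."""
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_calibration(path: str | Path) -> CalibrationConfig:
    """Load a :class:`CalibrationConfig` from a YAML mapping file."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a YAML mapping")
    try:
        kwargs = dict(raw)
        for key in ("t_start", "t_end"):
            if isinstance(kwargs.get(key), str):
                kwargs[key] = datetime.fromisoformat(kwargs[key])
        if "origin_px" in kwargs:
            kwargs["origin_px"] = tuple(float(v) for v in kwargs["origin_px"])
        return CalibrationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_calibration(config: CalibrationConfig, path: str | Path) -> None:
    data = asdict(config)
    data["t_start"] = config.t_start.isoformat(sep=" ")
    data["t_end"] = config.t_end.isoformat(sep=" ")
    data["origin_px"] = list(config.origin_px)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def plant_height_at(t: datetime, config: CalibrationConfig) -> float:
    """Plant height (mm) at time ``t``, linearly interpolated.

    Heights are measured only at the start and end of the experiment;
    elongation in between is assumed linear. Times outside the experiment
    window are clamped to the nearest endpoint with a logged warning.
    """
    if t < config.t_start or t > config.t_end:
        logger.warning(
            "time %s outside experiment window [%s, %s]; clamping",
            t,
            config.t_start,
            config.t_end,
        )
        t = min(max(t, config.t_start), config.t_end)
    span = (config.t_end - config.t_start).total_seconds()
    frac = (t - config.t_start).total_seconds() / span
    return config.height_start_mm + frac * (
        config.height_end_mm - config.height_start_mm
    )


def scale_at_height(config: CalibrationConfig, h_mm: float) -> float:
    """Millimetres per pixel for an object ``h_mm`` above ground.

    Pinhole optics: an object nearer the camera subtends more pixels, so the
    physical extent per pixel decreases as ``(D - h) / D``.
    """
    if not (0 <= h_mm < config.camera_distance_mm):
        raise ValueError(
            f"height {h_mm} mm must lie in [0, camera distance "
            f"{config.camera_distance_mm} mm)"
        )
    return config.ground_scale * (config.camera_distance_mm - h_mm) / config.camera_distance_mm


def apply_calibration(traj: Trajectory, config: CalibrationConfig) -> Trajectory:
    """Convert a pixel trajectory to millimetres in the geographic frame.

    Each point is translated so the configured origin maps to (0, 0), scaled
    by the perspective-corrected mm/px factor at the plant's interpolated
    height at that frame, and the y axis is flipped when the input image has
    y increasing downward, so the result is east-positive / north-positive.
    """
    if traj.units is not Unit.PIXELS or traj.frame is not Frame.IMAGE:
        raise StateError(
            "apply_calibration expects a pixel trajectory in the image frame; "
            f"got {traj.units.value}/{traj.frame.value}"
        )
    ox, oy = config.origin_px
    ysign = -1.0 if config.y_axis == "down" else 1.0
    out = []
    for p in traj.points:
        s = scale_at_height(config, plant_height_at(p.t, config))
        out.append(TimedPoint(p.t, (p.x - ox) * s, ysign * (p.y - oy) * s))
    return traj.with_points(out, units=Unit.MILLIMETRES, frame=Frame.GEOGRAPHIC)


def invert_calibration(traj: Trajectory, config: CalibrationConfig) -> Trajectory:
    """Exact inverse of :func:`apply_calibration` (mm/geographic -> px/image).

    Used to render synthetic millimetre trajectories as the pixel
    coordinates a camera would record, perspective inflation included.
    """
    if traj.units is not Unit.MILLIMETRES or traj.frame is not Frame.GEOGRAPHIC:
        raise StateError(
            "invert_calibration expects a millimetre trajectory in the "
            f"geographic frame; got {traj.units.value}/{traj.frame.value}"
        )
    ox, oy = config.origin_px
    ysign = -1.0 if config.y_axis == "down" else 1.0
    out = []
    for p in traj.points:
        s = scale_at_height(config, plant_height_at(p.t, config))
        px = p.x / s + ox
        py = ysign * p.y / s + oy
        if not (0 <= px <= config.frame_width_px):
            logger.warning("point at %s maps outside the frame (x=%.1f px)", p.t, px)
        out.append(TimedPoint(p.t, px, py))
    return traj.with_points(out, units=Unit.PIXELS, frame=Frame.IMAGE)


__all__ = [
    "CalibrationConfig",
    "load_calibration",
    "save_calibration",
    "plant_height_at",
    "scale_at_height",
    "apply_calibration",
    "invert_calibration",
]
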