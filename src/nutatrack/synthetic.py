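"""Ground-truthed synthetic circumnutation recordings.

No public raw-coordinate recordings of circumnutating seedlings exist, so
the pipeline is validated against generated trajectories with known
per-cycle parameters. The generator emulates what a top-view time-lapse of
a circumnutating hypocotyl looks like after digitisation: an apex tracing
an ellipse of configurable shape and orientation around a slowly drifting
centre, sampled every five minutes (the standard frame interval), with
isotropic Gaussian jitter modelling manual-click / tracking error. The
ellipse's long axis may precess from cycle to cycle to produce rosette-like
composite paths.

Each cycle starts exactly at its northward maximum, matching the cycle
definition used by the analysis (boundaries at successive northward bends),
and the generator returns the exact per-cycle truth alongside the
trajectory. A short lead-in and tail (default one quarter period) are
emitted around the cycles so that the first and last boundary maxima are
interior samples a derivative-sign-change detector can find.

What this emulates — and what it does not: real recordings show
growth-driven drift, cycle-to-cycle period and amplitude variability (both
configurable here), but also occasional pauses, non-elliptic lobes and
camera disturbances that no parametric generator reproduces. Recovery on
synthetic data therefore demonstrates correctness of the measurement
chain, not performance on every real recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .calibration import CalibrationConfig, invert_calibration
from .core_io import (
    CycleMetrics,
    Direction,
    Frame,
    TimedPoint,
    Trajectory,
    Unit,
)
from .cycle_metrics import fold_angle
from .errors import ConfigError

DEFAULT_START = datetime(2020, 1, 1, 18, 0)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording.

    ``period_minutes`` and ``direction`` accept either a single value used
    for every cycle or one value per cycle. Angles follow the geographic
    convention (N = 0, E = -90, W = +90); ``rosette_rotation_deg_per_cycle``
    precesses the long axis by that many degrees each cycle.
    """

    n_cycles: int = 5
    period_minutes: Union[float, Sequence[float]] = 150.0
    semi_major_mm: float = 15.0
    semi_minor_mm: float = 9.0
    axis_angle_deg: float = 0.0
    direction: Union[str, Sequence[str]] = "CCW"
    center_start_mm: tuple[float, float] = (0.0, 0.0)
    center_drift_mm_per_min: tuple[float, float] = (0.0, 0.0)
    rosette_rotation_deg_per_cycle: float = 0.0
    noise_sd_mm: float = 0.0
    frame_interval_min: float = 5.0
    seed: int = 0
    start_time: datetime = field(default_factory=lambda: DEFAULT_START)
    lead_in_min: Optional[float] = None
    tail_min: Optional[float] = None
    plant_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if any(p <= 0 for p in self.periods):
            raise ConfigError("all periods must be positive")
        if not (self.semi_major_mm >= self.semi_minor_mm > 0):
            raise ConfigError("need semi_major >= semi_minor > 0")
        if self.noise_sd_mm < 0:
            raise ConfigError("noise_sd_mm must be >= 0")
        if self.frame_interval_min <= 0:
            raise ConfigError("frame_interval_min must be > 0")
        for d in self.directions:
            if d not in ("CW", "CCW"):
                raise ConfigError(f"direction must be CW or CCW, got {d!r}")

    @property
    def periods(self) -> list[float]:
        p = self.period_minutes
        if isinstance(p, (int, float)):
            return [float(p)] * self.n_cycles
        p = [float(v) for v in p]
        if len(p) != self.n_cycles:
            raise ConfigError(
                f"got {len(p)} periods for {self.n_cycles} cycles"
            )
        return p

    @property
    def directions(self) -> list[str]:
        d = self.direction
        if isinstance(d, str):
            return [d] * self.n_cycles
        d = [str(v) for v in d]
        if len(d) != self.n_cycles:
            raise ConfigError(
                f"got {len(d)} directions for {self.n_cycles} cycles"
            )
        return d


def load_spec(path: str | Path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from a YAML mapping file."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a YAML mapping")
    kwargs = dict(raw)
    if isinstance(kwargs.get("start_time"), str):
        kwargs["start_time"] = datetime.fromisoformat(kwargs["start_time"])
    for key in ("center_start_mm", "center_drift_mm_per_min"):
        if key in kwargs:
            kwargs[key] = tuple(float(v) for v in kwargs[key])
    try:
        return SyntheticSpec(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _cycle_geometry(spec: SyntheticSpec, k: int):
    """Axis vectors and northward-maximum phase for cycle k."""
    alpha = math.radians(
        spec.axis_angle_deg + k * spec.rosette_rotation_deg_per_cycle
    )
    # long-axis unit vector under the N=0, E=-90 convention
    v = np.array([-math.sin(alpha), math.cos(alpha)])
    w = np.array([-v[1], v[0]])  # 90 deg CCW from v: increasing phase = CCW
    a, b = spec.semi_major_mm, spec.semi_minor_mm
    phi_star = math.atan2(b * w[1], a * v[1])  # phase of the northward maximum
    return v, w, phi_star


def _position(spec: SyntheticSpec, t_min: float, boundaries: np.ndarray) -> np.ndarray:
    """Noiseless apex position at t (minutes from the first cycle start)."""
    periods = spec.periods
    k = int(np.clip(np.searchsorted(boundaries, t_min, side="right") - 1, 0, spec.n_cycles - 1))
    tau = t_min - boundaries[k]
    v, w, phi_star = _cycle_geometry(spec, k)
    sgn = 1.0 if spec.directions[k] == "CCW" else -1.0
    phi = phi_star + sgn * 2 * math.pi * tau / periods[k]
    a, b = spec.semi_major_mm, spec.semi_minor_mm
    center = np.asarray(spec.center_start_mm) + np.asarray(
        spec.center_drift_mm_per_min
    ) * t_min
    return center + a * math.cos(phi) * v + b * math.sin(phi) * w


def generate_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, list[CycleMetrics]]:
    """Generate a recording and its exact per-cycle ground truth.

    Returns a calibrated (millimetre, geographic-frame) trajectory sampled
    at the spec's frame interval, and one :class:`CycleMetrics` per cycle
    whose length is the noiseless polyline length over that cycle's frames
    (the quantity the analysis estimates at the same sampling).
    """
    dt = spec.frame_interval_min
    periods = spec.periods
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])  # cycle starts
    total = boundaries[-1]

    def default_pad(period: float) -> float:
        return math.floor(period / 4.0 / dt) * dt

    lead = default_pad(periods[0]) if spec.lead_in_min is None else spec.lead_in_min
    tail = default_pad(periods[-1]) if spec.tail_min is None else spec.tail_min

    times = np.arange(-lead, total + tail + dt / 2.0, dt)
    clean = np.array([_position(spec, t, boundaries) for t in times])
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd_mm, size=clean.shape)

    t0 = spec.start_time  # timestamp of the first emitted frame
    points = [
        TimedPoint(t0 + timedelta(minutes=float(t + lead)), float(x), float(y))
        for t, (x, y) in zip(times, noisy)
    ]
    traj = Trajectory(
        points=points,
        units=Unit.MILLIMETRES,
        frame=Frame.GEOGRAPHIC,
        plant_id=spec.plant_id,
    )

    truth: list[CycleMetrics] = []
    cycle_start_time = t0 + timedelta(minutes=float(lead))
    for k, period in enumerate(periods):
        mask = (times >= boundaries[k] - 1e-9) & (times <= boundaries[k + 1] + 1e-9)
        seg = clean[mask]
        length = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))
        start = cycle_start_time + timedelta(minutes=float(boundaries[k]))
        end = cycle_start_time + timedelta(minutes=float(boundaries[k + 1]))
        alpha = fold_angle(
            spec.axis_angle_deg + k * spec.rosette_rotation_deg_per_cycle
        )
        truth.append(
            CycleMetrics(
                index=k + 1,
                start=start,
                end=end,
                period_min=period,
                length_mm=length,
                rate_mm_per_min=length / period,
                shape=spec.semi_minor_mm / spec.semi_major_mm,
                angle_deg=alpha,
                direction=Direction(spec.directions[k]),
            )
        )
    return traj, truth


def render_to_pixels(
    traj_mm: Trajectory, calib: CalibrationConfig
) -> Trajectory:
    """Project a millimetre trajectory to the pixel coordinates a camera
    would record: perspective inflation with plant height, y-axis flip and
    origin offset — the exact inverse of calibration."""
    return invert_calibration(traj_mm, calib)


__all__ = [
    "SyntheticSpec",
    "load_spec",
    "generate_trajectory",
    "render_to_pixels",
    "DEFAULT_START",
]
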