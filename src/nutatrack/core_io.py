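"""Domain types and trajectory / cycle-table CSV input-output.

A recording is a time series of apex positions digitised from top-view
time-lapse frames: one row per frame holding a timestamp and planar x, y
coordinates. Coordinates arrive in pixels in the image frame (y grows
downward) and are converted by :mod:`nutatrack.calibration` to millimetres
in a geographic frame where x is east-positive and y is north-positive.

Per-cycle results are serialised to a CSV whose column layout matches the
conventional circumnutation parameter table: cycle number, start / end /
middle timestamps, period (min), length (mm), rate (mm min^-1), shape
coefficient, ellipse angle (degrees) and rotation direction (CW / CCW / ?).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .util import round_half_up, round_half_up_int

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M"

CYCLE_TABLE_COLUMNS = [
    "Numero",
    "Start",
    "End",
    "Middle",
    "Period",
    "Length",
    "Rate",
    "Shape",
    "Angle",
    "Direction",
]


class Unit(str, enum.Enum):
    PIXELS = "pixels"
    MILLIMETRES = "millimetres"


class Frame(str, enum.Enum):
    #: raw image coordinates: y increases downward
    IMAGE = "image"
    #: geographic coordinates: x east-positive, y north-positive
    GEOGRAPHIC = "geographic"


class Direction(str, enum.Enum):
    CW = "CW"
    CCW = "CCW"
    INDETERMINATE = "?"


@dataclass(frozen=True)
class TimedPoint:
    """One video-frame observation of the organ apex."""

    t: datetime
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DataError(f"non-finite coordinate at {self.t}: ({self.x}, {self.y})")


@dataclass
class Trajectory:
    """An ordered apex path with a unit system and coordinate frame."""

    points: Sequence[TimedPoint]
    units: Unit = Unit.PIXELS
    frame: Frame = Frame.IMAGE
    plant_id: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise DataError(
                f"trajectory needs at least 2 points, got {len(self.points)}"
            )
        for i in range(1, len(self.points)):
            if self.points[i].t <= self.points[i - 1].t:
                raise DataError(
                    f"timestamps must be strictly increasing: row {i + 1} "
                    f"({self.points[i].t}) does not follow row {i} "
                    f"({self.points[i - 1].t})"
                )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> list[datetime]:
        return [p.t for p in self.points]

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of coordinates."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    def minutes_since_start(self) -> np.ndarray:
        t0 = self.points[0].t
        return np.array(
            [(p.t - t0).total_seconds() / 60.0 for p in self.points], dtype=float
        )

    def with_points(
        self,
        points: Sequence[TimedPoint],
        units: Optional[Unit] = None,
        frame: Optional[Frame] = None,
    ) -> "Trajectory":
        return Trajectory(
            points=list(points),
            units=units if units is not None else self.units,
            frame=frame if frame is not None else self.frame,
            plant_id=self.plant_id,
        )


@dataclass
class CycleMetrics:
    """The six per-cycle circumnutation parameters plus timing.

    ``shape`` and ``angle_deg`` are ``None`` when the ellipse fit failed
    (fewer than five points or a degenerate scatter); period, length, rate
    and direction are always defined. ``angle_unreliable`` flags near-circular
    cycles (shape > 0.95) where the major-axis orientation is poorly
    constrained but still reported.
    """

    index: int
    start: datetime
    end: datetime
    period_min: float
    length_mm: float
    rate_mm_per_min: float
    shape: Optional[float]
    angle_deg: Optional[float]
    direction: Direction
    angle_unreliable: bool = False
    middle: datetime = field(init=False)

    def __post_init__(self) -> None:
        if self.period_min <= 0:
            raise DataError(f"cycle {self.index}: period must be positive")
        if self.length_mm < 0:
            raise DataError(f"cycle {self.index}: negative path length")
        if self.shape is not None and not (0.0 < self.shape <= 1.0 + 1e-9):
            raise DataError(f"cycle {self.index}: shape {self.shape} outside (0, 1]")
        self.middle = cycle_middle(self.start, self.period_min)


def cycle_middle(start: datetime, period_min: float) -> datetime:
    """Midpoint timestamp of a cycle, floored to whole minutes.

    A 155-min cycle starting 23:10 has its true midpoint at 00:27.5 and is
    reported as 00:27.
    """
    mid = start + timedelta(minutes=period_min / 2.0)
    return mid.replace(second=0, microsecond=0)


def frame_timestamp(
    start_time: datetime, frame_index: int, interval_minutes: float
) -> datetime:
    """Timestamp of frame ``frame_index`` in a constant-interval recording."""
    if frame_index < 0:
        raise ValueError(f"frame_index must be >= 0, got {frame_index}")
    if interval_minutes <= 0:
        raise ValueError(f"interval_minutes must be > 0, got {interval_minutes}")
    return start_time + timedelta(minutes=frame_index * interval_minutes)


def _parse_timestamp(raw: str, fmt: Optional[str], row: int) -> datetime:
    raw = str(raw).strip()
    if fmt is not None:
        try:
            return datetime.strptime(raw, fmt)
        except ValueError as exc:
            raise DataError(f"row {row}: unparseable timestamp {raw!r}") from exc
    try:
        return datetime.fromisoformat(raw)
    except ValueError as exc:
        raise DataError(f"row {row}: unparseable timestamp {raw!r}") from exc


def read_trajectory_csv(
    path: str | Path,
    *,
    timestamp_col: str = "timestamp",
    x_col: str = "x",
    y_col: str = "y",
    timestamp_format: Optional[str] = None,
    units: Unit = Unit.PIXELS,
    frame: Frame = Frame.IMAGE,
    plant_id: Optional[str] = None,
) -> Trajectory:
    """Read an apex trajectory from a CSV of per-frame rows.

    The file must have a header naming the timestamp and coordinate columns
    (names configurable). Timestamps are accepted in ISO-8601
    ``YYYY-MM-DD HH:MM`` by default; pass ``timestamp_format`` (a strptime
    pattern) for other dialects. Rows are kept in file order after verifying
    that timestamps strictly increase.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001 - surface as a format problem
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in (timestamp_col, x_col, y_col):
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing column {col!r}; found {list(df.columns)}"
            )
    if len(df) < 2:
        raise DataError(f"{path}: trajectory needs at least 2 rows, got {len(df)}")

    points: list[TimedPoint] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, rec))
        t = _parse_timestamp(row[timestamp_col], timestamp_format, i)
        try:
            x = float(row[x_col])
            y = float(row[y_col])
        except (TypeError, ValueError) as exc:
            raise DataError(
                f"{path}: row {i}: unparseable coordinate "
                f"({row[x_col]!r}, {row[y_col]!r})"
            ) from exc
        if not (math.isfinite(x) and math.isfinite(y)):
            raise DataError(f"{path}: row {i}: non-finite coordinate ({x}, {y})")
        points.append(TimedPoint(t, x, y))

    for i in range(1, len(points)):
        if points[i].t <= points[i - 1].t:
            raise DataError(
                f"{path}: row {i + 1}: timestamp {points[i].t} does not "
                f"strictly follow row {i} ({points[i - 1].t})"
            )
    return Trajectory(
        points=points,
        units=units,
        frame=frame,
        plant_id=plant_id if plant_id is not None else path.stem,
    )


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the standard ``timestamp,x,y`` layout."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "x", "y"])
        for p in traj.points:
            w.writerow([p.t.strftime(TIMESTAMP_FORMAT), repr(p.x), repr(p.y)])


def _fmt_opt(value: Optional[float], ndigits: int) -> str:
    if value is None:
        return ""
    if ndigits == 0:
        return str(round_half_up_int(value))
    return f"{round_half_up(value, ndigits):.{ndigits}f}"


def format_cycle_row(m: CycleMetrics) -> list[str]:
    """Render one cycle at table precision: period/length/angle as integers,
    rate/shape at two decimals, direction as CW / CCW / ?."""
    return [
        str(m.index),
        m.start.strftime(TIMESTAMP_FORMAT),
        m.end.strftime(TIMESTAMP_FORMAT),
        m.middle.strftime(TIMESTAMP_FORMAT),
        str(round_half_up_int(m.period_min)),
        str(round_half_up_int(m.length_mm)),
        _fmt_opt(m.rate_mm_per_min, 2),
        _fmt_opt(m.shape, 2),
        _fmt_opt(m.angle_deg, 0),
        m.direction.value,
    ]


def write_cycle_table(
    metrics: Iterable[CycleMetrics], path: str | Path
) -> None:
    """Export per-cycle parameters as CSV in the standard table layout."""
    rows = list(metrics)
    if not rows:
        raise DataError("no cycles to write")
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CYCLE_TABLE_COLUMNS)
        for m in rows:
            w.writerow(format_cycle_row(m))


def read_cycle_table(path: str | Path) -> list[CycleMetrics]:
    """Read a per-cycle parameter table written by :func:`write_cycle_table`.

    Values come back at table precision (integer minutes and mm, two-decimal
    rate and shape); ``middle`` is recomputed from start and period.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in CYCLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out: list[CycleMetrics] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, rec))

        def opt(name: str) -> Optional[float]:
            v = row[name]
            if v is None or (isinstance(v, float) and math.isnan(v)) or str(v) == "":
                return None
            return float(v)

        try:
            m = CycleMetrics(
                index=int(row["Numero"]),
                start=_parse_timestamp(row["Start"], TIMESTAMP_FORMAT, i),
                end=_parse_timestamp(row["End"], TIMESTAMP_FORMAT, i),
                period_min=float(row["Period"]),
                length_mm=float(row["Length"]),
                rate_mm_per_min=float(row["Rate"]),
                shape=opt("Shape"),
                angle_deg=opt("Angle"),
                direction=Direction(str(row["Direction"]).strip()),
            )
        except (KeyError, ValueError) as exc:
            raise DataError(f"{path}: row {i}: {exc}") from exc
        out.append(m)
    if not out:
        raise DataError(f"{path}: empty cycle table")
    return out


__all__ = [
    "TIMESTAMP_FORMAT",
    "CYCLE_TABLE_COLUMNS",
    "Unit",
    "Frame",
    "Direction",
    "TimedPoint",
    "Trajectory",
    "CycleMetrics",
    "cycle_middle",
    "frame_timestamp",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_cycle_table",
    "read_cycle_table",
    "format_cycle_row",
]
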