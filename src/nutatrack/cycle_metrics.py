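"""Per-cycle circumnutation parameters.

Six parameters describe one cycle of the apex trajectory:

* **period** (min) — time between the two northward maxima bounding the cycle;
* **length** (mm) — path length traced by the apex over the cycle;
* **rate** (mm min^-1) — length divided by period;
* **shape** — short-axis / long-axis ratio of the ellipse fitted to the
  cycle points: 1 for a circular cycle, about 0.1 for a very narrow one;
* **angle** (degrees) — orientation of the fitted ellipse's long axis
  relative to geographic north-south: N = 0, axes leaning east are
  negative (E = -90), leaning west positive (W = +90);
* **direction** — clockwise (CW) or counter-clockwise (CCW) rotation of the
  apex viewed from above, or indeterminate (?) when the trajectory does not
  enclose appreciable signed area (e.g. figure-eights).

The ellipse is fitted by direct least squares on the algebraic distance
under the ellipse-specific constraint 4ac - b^2 = 1 (Fitzgibbon-Pilu-Fisher),
using the numerically stable partitioned formulation of the generalized
eigenproblem: the naive 6x6 scatter-matrix eigenproblem is ill-conditioned,
so the quadratic and linear coefficient blocks are solved separately and
only a well-behaved 3x3 eigenproblem remains. Points are centred and
rescaled internally for conditioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core_io import CycleMetrics, Direction, Frame, Unit
from .cycle_detection import Cycle
from .errors import FitError, StateError

#: cycles with shape above this are close enough to circular that the
#: major-axis orientation is poorly constrained; the angle is still
#: reported but flagged unreliable.
ANGLE_UNRELIABLE_SHAPE = 0.95

#: |signed area| / fitted-ellipse area below which rotation is called
#: indeterminate: lobes of opposite handedness largely cancel.
DEFAULT_INDETERMINATE_RATIO = 0.2


@dataclass(frozen=True)
class EllipseFit:
    """An ellipse as conic coefficients plus derived geometry.

    ``conic`` holds (a, b, c, d, e, f) of
    ``a x^2 + b xy + c y^2 + d x + e y + f = 0`` normalised so that
    ``4ac - b^2 = 1``. ``major_axis`` is a unit vector along the long axis
    in the geographic frame (sign arbitrary: an axis is undirected).
    """

    conic: Tuple[float, float, float, float, float, float]
    center: Tuple[float, float]
    semi_major: float
    semi_minor: float
    major_axis: Tuple[float, float]

    def __post_init__(self) -> None:
        a, b, c, *_ = self.conic
        if 4 * a * c - b * b <= 0:
            raise FitError("conic is not an ellipse (4ac - b^2 <= 0)")
        if not (self.semi_major >= self.semi_minor > 0):
            raise FitError("semi-axes must satisfy major >= minor > 0")

    @property
    def area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor


def _conic_geometry(
    conic: Sequence[float],
) -> tuple[Tuple[float, float], float, float, Tuple[float, float]]:
    """Center, semi-axes and major-axis direction of a central conic."""
    a, b, c, d, e, f = conic
    det = 4 * a * c - b * b
    if det <= 0:
        raise FitError("fitted conic is not an ellipse")
    xc = (b * e - 2 * c * d) / det
    yc = (b * d - 2 * a * e) / det
    # conic value at the center; points on the ellipse satisfy
    # (p - c)^T Q (p - c) = -mu with Q the quadratic-form matrix
    mu = a * xc * xc + b * xc * yc + c * yc * yc + d * xc + e * yc + f
    Q = np.array([[a, b / 2.0], [b / 2.0, c]])
    evals, evecs = np.linalg.eigh(Q)
    if mu >= 0 or np.any(evals <= 0):
        raise FitError("degenerate or imaginary ellipse")
    axes = np.sqrt(-mu / evals)  # eigh sorts ascending -> axes descending
    major = float(axes[0])
    minor = float(axes[1])
    vec = evecs[:, 0]  # eigenvector of the smaller eigenvalue = long axis
    return (float(xc), float(yc)), major, minor, (float(vec[0]), float(vec[1]))


def _normalize_conic(conic: np.ndarray) -> Tuple[float, ...]:
    a, b, c = conic[0], conic[1], conic[2]
    det = 4 * a * c - b * b
    if det <= 0:
        raise FitError("solution is not an ellipse (4ac - b^2 <= 0)")
    out = conic / math.sqrt(det)
    # the constraint fixes the conic only up to sign; pick a > 0 so that
    # points inside the ellipse give negative conic values
    if out[0] < 0:
        out = -out
    return tuple(float(v) for v in out)


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit (stable partitioned formulation).

    Minimises the algebraic distance ``sum_i (a x_i^2 + ... + f)^2`` subject
    to ``4ac - b^2 = 1``, which forces an elliptic solution and makes the
    minimiser unique up to sign. Requires at least five points with
    non-degenerate scatter.

    Parameters
    ----------
    points : (n, 2) array
        Cycle coordinates (any planar frame; the fit is equivariant under
        rigid motions).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 5:
        raise FitError(f"ellipse fit needs >= 5 points, got {n}")

    # condition: centre on the centroid, scale to unit RMS radius
    mean = pts.mean(axis=0)
    centred = pts - mean
    scale = math.sqrt((centred**2).sum(axis=1).mean())
    if scale <= 0:
        raise FitError("all points coincide")
    u = centred[:, 0] / scale
    v = centred[:, 1] / scale

    D1 = np.column_stack([u * u, u * v, v * v])
    D2 = np.column_stack([u, v, np.ones(n)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("rank-deficient scatter (collinear points?)") from exc
    M = S1 + S2 @ T
    # premultiply by C1^-1 where C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.vstack([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    # the elliptic solution has 4ac - b^2 > 0; exactly one eigenvector does
    cond = (
        4 * evecs[0] * evecs[2] - evecs[1] ** 2
    )
    candidates = np.nonzero((cond > 0) & np.isfinite(evals.real))[0]
    if candidates.size == 0:
        raise FitError("no elliptic solution (degenerate point set)")
    k = candidates[np.argmin(np.abs(evals[candidates]))] if candidates.size > 1 else candidates[0]
    a1 = np.real(evecs[:, k])
    a2 = T @ a1
    A, B, C = a1
    D, E = a2[0], a2[1]
    F = a2[2]

    # undo the normalisation: u = (x - mx)/s, v = (y - my)/s
    mx, my = mean
    s = scale
    a = A / s**2
    b = B / s**2
    c = C / s**2
    d = (-2 * A * mx - B * my) / s**2 + D / s
    e = (-B * mx - 2 * C * my) / s**2 + E / s
    f = (
        (A * mx * mx + B * mx * my + C * my * my) / s**2
        - (D * mx + E * my) / s
        + F
    )
    conic = _normalize_conic(np.array([a, b, c, d, e, f]))
    center, major, minor, vec = _conic_geometry(conic)
    return EllipseFit(
        conic=conic,
        center=center,
        semi_major=major,
        semi_minor=minor,
        major_axis=vec,
    )


def period_minutes(cycle: Cycle) -> float:
    """Cycle duration in minutes, end minus start timestamp."""
    start = cycle.points[0].t
    end = cycle.points[-1].t
    return (end - start).total_seconds() / 60.0


def path_length(cycle: Cycle) -> float:
    """Distance covered by the apex: the polyline length of the cycle slice."""
    if cycle.units is not None and cycle.units is not Unit.MILLIMETRES:
        raise StateError(
            f"path length requires calibrated (mm) points, got {cycle.units}"
        )
    xy = np.array([[p.x, p.y] for p in cycle.points])
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def rate(length_mm: float, period_min: float) -> float:
    """Mean apex speed over the cycle, mm per minute."""
    if period_min <= 0:
        raise ValueError(f"period must be positive, got {period_min}")
    return length_mm / period_min


def shape_coefficient(fit: EllipseFit) -> float:
    """Short-axis / long-axis ratio of the fitted ellipse, in (0, 1]."""
    return fit.semi_minor / fit.semi_major


def fold_angle(deg: float, *, fold_high_inclusive: bool = True) -> float:
    """Fold an undirected-axis angle into (-90, 90] (or [-90, 90))."""
    if fold_high_inclusive:
        while deg <= -90.0:
            deg += 180.0
        while deg > 90.0:
            deg -= 180.0
    else:
        while deg < -90.0:
            deg += 180.0
        while deg >= 90.0:
            deg -= 180.0
    return deg


def axis_angle(fit: EllipseFit, *, fold_high_inclusive: bool = True) -> float:
    """Long-axis orientation relative to geographic north, in degrees.

    North is 0; axes leaning east are negative, west positive (E = -90,
    W = +90). The axis is undirected, so the value is folded into a
    half-open 180-degree range: ``(-90, 90]`` by default, ``[-90, 90)``
    with ``fold_high_inclusive=False``.
    """
    vx, vy = fit.major_axis
    ang = -math.degrees(math.atan2(vx, vy))
    return fold_angle(ang, fold_high_inclusive=fold_high_inclusive)


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of the polygon closed by joining last to first.

    In the east-right / north-up frame viewed from above, positive area
    means counter-clockwise traversal.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


def cycle_direction(
    points: np.ndarray,
    fit: Optional[EllipseFit] = None,
    indeterminate_ratio: float = DEFAULT_INDETERMINATE_RATIO,
) -> Direction:
    """Rotation sense of the cycle polygon viewed from above.

    The shoelace signed area decides CW (negative) vs CCW (positive). When
    a fitted ellipse is available the cycle is called indeterminate if the
    net enclosed area is a small fraction of the ellipse area — the
    signature of self-cancelling lobes rather than a genuine loop. Without
    a fit, only an (essentially) zero net area is indeterminate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3 or np.allclose(pts, pts[0]):
        return Direction.INDETERMINATE
    area = signed_area(pts)
    if fit is not None:
        if abs(area) / fit.area < indeterminate_ratio:
            return Direction.INDETERMINATE
    else:
        span = pts.max(axis=0) - pts.min(axis=0)
        bbox = float(span[0] * span[1])
        if bbox == 0 or abs(area) < 1e-12 * max(bbox, 1.0):
            return Direction.INDETERMINATE
    return Direction.CCW if area > 0 else Direction.CW


def analyze_cycle(
    cycle: Cycle,
    *,
    indeterminate_ratio: float = DEFAULT_INDETERMINATE_RATIO,
    fold_high_inclusive: bool = True,
) -> CycleMetrics:
    """All six parameters for one cycle.

    Period, length, rate and timing always succeed; if the ellipse fit
    fails (under five points, collinear scatter) shape and angle are
    reported as undefined and the direction falls back to the bare polygon
    orientation — one bad cycle never aborts the recording.
    """
    if cycle.frame is not None and cycle.frame is not Frame.GEOGRAPHIC:
        raise StateError("cycle metrics require the geographic frame")
    period = period_minutes(cycle)
    length = path_length(cycle)
    xy = np.array([[p.x, p.y] for p in cycle.points])
    shape: Optional[float] = None
    angle: Optional[float] = None
    unreliable = False
    try:
        fit = fit_ellipse(xy)
    except FitError:
        fit = None
    if fit is not None:
        shape = min(shape_coefficient(fit), 1.0)
        angle = axis_angle(fit, fold_high_inclusive=fold_high_inclusive)
        unreliable = shape > ANGLE_UNRELIABLE_SHAPE
    direction = cycle_direction(xy, fit, indeterminate_ratio)
    return CycleMetrics(
        index=cycle.index,
        start=cycle.points[0].t,
        end=cycle.points[-1].t,
        period_min=period,
        length_mm=length,
        rate_mm_per_min=rate(length, period),
        shape=shape,
        angle_deg=angle,
        direction=direction,
        angle_unreliable=unreliable,
    )


__all__ = [
    "ANGLE_UNRELIABLE_SHAPE",
    "DEFAULT_INDETERMINATE_RATIO",
    "EllipseFit",
    "fit_ellipse",
    "period_minutes",
    "path_length",
    "rate",
    "shape_coefficient",
    "axis_angle",
    "fold_angle",
    "signed_area",
    "cycle_direction",
    "analyze_cycle",
]
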