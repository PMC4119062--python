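"""Cycle segmentation: smoothing, extrema detection and confirmation.

A circumnutation cycle is delimited by two successive *northward maxima* —
local maxima of the geographic y (north-south) coordinate series. The
series is first smoothed with a centred moving average to suppress
frame-to-frame jitter, then extrema are found where the discrete derivative
changes sign: rising-to-falling gives a maximum, falling-to-rising a
minimum. Runs of equal smoothed values (plateaus) are collapsed to a single
extremum at the run midpoint.

Smoothing is used *only* to locate extrema: cycle slices index the original
calibrated points and every downstream metric (path length, ellipse fit)
uses the unsmoothed coordinates, because averaging systematically deflates
path length.

Confirmation replaces the interactive review step of desktop trackers with
a file-based one: candidate extrema are written to a small CSV that can be
hand-edited (accept / reject / insert) and re-read. The default automatic
policy accepts all y-maxima after discarding low-persistence pairs —
adjacent maximum/minimum pairs whose vertical swing is a small fraction of
the typical swing, which are the sign-flip doublets measurement noise
creates near flat peaks and which a human reviewer would reject on sight.
"""

from __future__ import annotations

import csv
import enum
import logging
import statistics
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import Trajectory
from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 5
DEFAULT_REL_PERSISTENCE = 0.2


class Axis(str, enum.Enum):
    X = "x"
    Y = "y"


class Kind(str, enum.Enum):
    MAXIMUM = "maximum"
    MINIMUM = "minimum"


@dataclass(frozen=True)
class Extreme:
    """A candidate or accepted extremum of one coordinate series."""

    index: int
    axis: Axis
    kind: Kind
    accepted: bool = False


@dataclass
class Cycle:
    """One circumnutation cycle: the slice between two accepted y-maxima.

    ``points`` includes both boundary points; consecutive cycles share their
    boundary sample.
    """

    index: int
    start_ext: Extreme
    end_ext: Extreme
    points: Sequence  # TimedPoint slice, boundary-inclusive
    units: "object" = None  # Unit of the source trajectory
    frame: "object" = None  # Frame of the source trajectory

    def __post_init__(self) -> None:
        if self.end_ext.index <= self.start_ext.index:
            raise DataError("cycle end extreme must follow its start extreme")
        for e in (self.start_ext, self.end_ext):
            if e.kind is not Kind.MAXIMUM or e.axis is not Axis.Y:
                raise DataError("cycle boundaries must be northward (y) maxima")


def moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Centred moving mean; the window truncates to available samples at
    the edges, so output length equals input length.

    ``window`` must be odd and positive; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    arr = np.asarray(series, dtype=float)
    if window > arr.size:
        raise ValueError(f"window {window} exceeds series length {arr.size}")
    return (
        pd.Series(arr).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def detect_extrema(smoothed: Sequence[float], axis: Axis = Axis.Y) -> list[Extreme]:
    """Extrema of a smoothed series by discrete-derivative sign change.

    A +/- sign change emits a maximum, -/+ a minimum. Zero-difference runs
    (plateaus) are collapsed: the extremum sits at the plateau midpoint,
    ties broken toward the earlier sample. Monotone series yield no extrema.
    """
    arr = np.asarray(smoothed, dtype=float)
    if arr.size < 3:
        raise ValueError(f"series must have >= 3 samples, got {arr.size}")
    diffs = np.diff(arr)
    signs = np.sign(diffs)
    nz = np.nonzero(signs)[0]
    out: list[Extreme] = []
    for a, b in zip(nz[:-1], nz[1:]):
        sa, sb = signs[a], signs[b]
        if sa == sb:
            continue
        # plateau spans samples a+1 .. b; midpoint floors toward earlier
        idx = (a + 1 + b) // 2
        kind = Kind.MAXIMUM if sa > 0 else Kind.MINIMUM
        out.append(Extreme(index=int(idx), axis=axis, kind=kind))
    return out


def prune_false_extrema(
    extremes: Sequence[Extreme],
    series: Sequence[float],
    min_swing: Optional[float] = None,
    rel_persistence: float = DEFAULT_REL_PERSISTENCE,
    swing_percentile: float = 90.0,
) -> list[Extreme]:
    """Drop low-persistence extreme pairs produced by residual noise.

    Adjacent maximum/minimum pairs whose value difference (swing) is below
    ``min_swing`` are removed together, smallest swing first, preserving
    alternation. When ``min_swing`` is not given it defaults to
    ``rel_persistence`` times a high percentile (default 90th) of the
    candidate swings, making the criterion scale-free: genuine cycles swing
    by roughly twice the north-south amplitude while noise doublets swing
    by a few noise standard deviations. A high percentile rather than the
    median anchors the scale on the genuine swings even when doublets
    outnumber them, as happens for nearly east-west narrow ellipses whose
    north-south projection is small.
    """
    ext = sorted(extremes, key=lambda e: e.index)
    if len(ext) < 2:
        return list(ext)
    arr = np.asarray(series, dtype=float)
    if min_swing is None:
        swings = [
            abs(arr[b.index] - arr[a.index]) for a, b in zip(ext[:-1], ext[1:])
        ]
        min_swing = rel_persistence * float(np.percentile(swings, swing_percentile))
    while len(ext) >= 2:
        swings = [
            abs(arr[b.index] - arr[a.index]) for a, b in zip(ext[:-1], ext[1:])
        ]
        k = int(np.argmin(swings))
        if swings[k] >= min_swing:
            break
        del ext[k : k + 2]
    return ext


def refine_extreme_indices(
    extremes: Sequence[Extreme],
    series: Sequence[float],
    half_width: int = 3,
) -> list[Extreme]:
    """Re-locate each extremum by a local quadratic fit, snapped to a frame.

    The raw sign-change index only uses the ordering of neighbouring
    samples; fitting a parabola to the smoothed values within
    ``half_width`` frames of the candidate pools their magnitudes and cuts
    the variance of the peak location under noise. The refined vertex is
    rounded to the nearest sample index (cycle boundaries are frames), and
    kept only if the result preserves the strict ordering of extrema.
    """
    arr = np.asarray(series, dtype=float)
    ext = sorted(extremes, key=lambda e: e.index)
    refined: list[Extreme] = []
    for pos, e in enumerate(ext):
        lo = max(e.index - half_width, 0)
        hi = min(e.index + half_width + 1, arr.size)
        if hi - lo < 3:
            refined.append(e)
            continue
        xs = np.arange(lo, hi, dtype=float)
        coeffs = np.polyfit(xs, arr[lo:hi], 2)
        concave_ok = (
            coeffs[0] < 0 if e.kind is Kind.MAXIMUM else coeffs[0] > 0
        )
        if not concave_ok:
            refined.append(e)
            continue
        vertex = -coeffs[1] / (2 * coeffs[0])
        vertex = min(max(vertex, e.index - half_width), e.index + half_width)
        idx = int(round(vertex))
        prev_idx = refined[-1].index if refined else -1
        next_idx = ext[pos + 1].index if pos + 1 < len(ext) else arr.size
        if prev_idx < idx < next_idx:
            refined.append(replace(e, index=idx))
        else:
            refined.append(e)
    return refined


@dataclass(frozen=True)
class Edit:
    """One review action: accept or reject a candidate, or insert a new
    extremum at a sample index."""

    action: str  # "accept" | "reject" | "insert"
    index: int
    axis: Axis = Axis.Y
    kind: Kind = Kind.MAXIMUM


def confirm_extrema(
    candidates: Sequence[Extreme],
    edits: Iterable[Edit] = (),
    *,
    default_accept: bool = True,
) -> list[Extreme]:
    """Apply a review edit list to candidate extrema.

    With no edits the default policy accepts every candidate (callers
    normally pass y-maxima only). Edits may flip acceptance of an existing
    candidate or insert a new extremum; the result is sorted with strictly
    increasing indices.
    """
    by_index: dict[tuple[int, Axis], Extreme] = {
        (e.index, e.axis): replace(e, accepted=default_accept) for e in candidates
    }
    for ed in edits:
        if ed.action == "insert":
            by_index[(ed.index, ed.axis)] = Extreme(
                index=ed.index, axis=ed.axis, kind=ed.kind, accepted=True
            )
            continue
        key = (ed.index, ed.axis)
        if key not in by_index:
            raise DataError(
                f"edit {ed.action!r} references no candidate at index {ed.index} "
                f"(axis {ed.axis.value})"
            )
        by_index[key] = replace(by_index[key], accepted=(ed.action == "accept"))
    out = sorted(
        (e for e in by_index.values() if e.accepted), key=lambda e: e.index
    )
    for a, b in zip(out[:-1], out[1:]):
        if b.index <= a.index:
            raise DataError("accepted extremes must have strictly increasing indices")
    return out


def segment_cycles(
    trajectory: Trajectory, accepted_y_maxima: Sequence[Extreme]
) -> list[Cycle]:
    """Split a trajectory into cycles between consecutive accepted y-maxima.

    N maxima yield N-1 cycles, numbered from 1; each boundary sample belongs
    to both adjacent cycles. Fewer than two maxima yield no cycles (with a
    logged warning) — the recording is too short or too irregular to
    segment.
    """
    maxima = sorted(accepted_y_maxima, key=lambda e: e.index)
    if len(maxima) < 2:
        logger.warning(
            "need >= 2 accepted northward maxima to form a cycle, got %d",
            len(maxima),
        )
        return []
    cycles = []
    for k, (a, b) in enumerate(zip(maxima[:-1], maxima[1:]), start=1):
        cycles.append(
            Cycle(
                index=k,
                start_ext=a,
                end_ext=b,
                points=list(trajectory.points[a.index : b.index + 1]),
                units=trajectory.units,
                frame=trajectory.frame,
            )
        )
    return cycles


REVIEW_COLUMNS = ["index", "axis", "kind", "accepted"]


def write_extremes_review(extremes: Sequence[Extreme], path: str | Path) -> None:
    """Write candidate extrema to an editable review CSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(REVIEW_COLUMNS)
        for e in sorted(extremes, key=lambda e: (e.axis.value, e.index)):
            w.writerow([e.index, e.axis.value, e.kind.value, int(e.accepted)])


def read_extremes_review(path: str | Path) -> list[Extreme]:
    """Read back a (possibly hand-edited) extremes review CSV."""
    path = Path(path)
    out: list[Extreme] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(REVIEW_COLUMNS) - set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {REVIEW_COLUMNS}")
        for i, row in enumerate(reader, start=1):
            try:
                out.append(
                    Extreme(
                        index=int(row["index"]),
                        axis=Axis(row["axis"]),
                        kind=Kind(row["kind"]),
                        accepted=bool(int(row["accepted"])),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise DataError(f"{path}: row {i}: {exc}") from exc
    return out


def detect_northward_maxima(
    trajectory: Trajectory,
    window: int = DEFAULT_WINDOW,
    *,
    rel_persistence: float = DEFAULT_REL_PERSISTENCE,
    min_swing: Optional[float] = None,
    refine_half_width: Optional[int] = None,
    min_amplitude_mm: float = 1e-6,
) -> tuple[list[Extreme], list[Extreme]]:
    """Smooth the north-south series, detect extrema and auto-confirm maxima.

    Returns ``(candidates, accepted_maxima)`` where candidates are all
    extrema of the smoothed y series (for the review file) and accepted
    maxima are the persistence-pruned, quadratically refined y-maxima used
    for segmentation. ``refine_half_width`` defaults to a fifth of the
    median spacing between detected maxima (at least ``window // 2 + 1``
    frames): the cosine-like peak region is parabolic over roughly that
    span, and a wider fit localises flat noisy peaks better.
    """
    y = trajectory.xy[:, 1]
    if float(np.ptp(y)) < min_amplitude_mm:
        # sub-micrometre oscillation carries no information at the scale of
        # digitised apex coordinates: report no usable extremes
        logger.warning(
            "north-south amplitude %.3g mm below %.3g mm; no cycles detected",
            float(np.ptp(y)),
            min_amplitude_mm,
        )
        return [], []
    smoothed = moving_average(y, window)
    candidates = detect_extrema(smoothed, Axis.Y)
    pruned = prune_false_extrema(
        candidates, smoothed, min_swing=min_swing, rel_persistence=rel_persistence
    )
    maxima = [e for e in pruned if e.kind is Kind.MAXIMUM]
    if refine_half_width is None:
        refine_half_width = window // 2 + 1
        if len(maxima) >= 2:
            spacing = statistics.median(
                b.index - a.index for a, b in zip(maxima[:-1], maxima[1:])
            )
            refine_half_width = max(refine_half_width, round(spacing / 5))
    if refine_half_width > 0:
        pruned = refine_extreme_indices(pruned, smoothed, refine_half_width)
        maxima = [e for e in pruned if e.kind is Kind.MAXIMUM]
    accepted = confirm_extrema(maxima)
    return candidates, accepted


__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_REL_PERSISTENCE",
    "Axis",
    "Kind",
    "Extreme",
    "Cycle",
    "Edit",
    "moving_average",
    "detect_extrema",
    "prune_false_extrema",
    "refine_extreme_indices",
    "confirm_extrema",
    "segment_cycles",
    "detect_northward_maxima",
    "write_extremes_review",
    "read_extremes_review",
]
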