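"""Per-plant and per-group aggregation of cycle metrics.

A plant (seedling) is summarised by the arithmetic means of its per-cycle
parameters and by the percentage of cycles rotating clockwise,
counter-clockwise or indeterminately. A treatment group is summarised by
the per-parameter mean and standard error over its plants, with two-sample
t-tests between groups reported at the conventional significance tiers
(p < 0.05, p < 0.01, p < 0.00001).

Angle means are plain arithmetic means of the signed degrees (undefined
angles excluded), not circular means — the axis convention already folds
angles into a single 180-degree range, and the arithmetic mean is what the
reference tables use. Percentages are rounded half-up to integers, so a
row may sum to 99-101.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core_io import CycleMetrics, Direction
from .errors import DataError
from .util import round_half_up, round_half_up_int

SIGNIFICANCE_TIERS = ((1e-5, "p<0.00001"), (0.01, "p<0.01"), (0.05, "p<0.05"))


@dataclass
class PlantSummary:
    """Mean cycle parameters and direction percentages for one plant."""

    plant_id: str
    n_cycles: int
    mean_period_min: float
    mean_length_mm: float
    mean_rate_mm_per_min: float
    mean_shape: Optional[float]
    mean_angle_deg: Optional[float]
    cw_pct: float
    ccw_pct: float
    ind_pct: float
    hypocotyl_length_mm: Optional[float] = None


@dataclass
class GroupSummary:
    """Per-parameter mean and standard error over the plants of one group."""

    n_plants: int
    mean: dict[str, float]
    se: dict[str, float]


def direction_percentages(
    directions: Sequence[Direction],
) -> tuple[float, float, float]:
    """(cw, ccw, indeterminate) percentages, each rounded half-up to integer.

    Independent rounding means the three values may sum to 99-101.
    """
    if not directions:
        raise DataError("no directions to summarise")
    n = len(directions)
    cw = sum(1 for d in directions if d is Direction.CW)
    ccw = sum(1 for d in directions if d is Direction.CCW)
    ind = n - cw - ccw
    return (
        round_half_up(cw / n * 100),
        round_half_up(ccw / n * 100),
        round_half_up(ind / n * 100),
    )


def plant_summary(
    metrics: Sequence[CycleMetrics],
    plant_id: str = "",
    hypocotyl_length_mm: Optional[float] = None,
) -> PlantSummary:
    """Summarise one plant's cycles by arithmetic means and direction counts.

    Undefined shapes/angles (failed ellipse fits) are excluded from their
    means; if no cycle has a defined value the mean is ``None``.
    """
    if not metrics:
        raise DataError("plant summary needs at least one cycle")
    shapes = [m.shape for m in metrics if m.shape is not None]
    angles = [m.angle_deg for m in metrics if m.angle_deg is not None]
    cw, ccw, ind = direction_percentages([m.direction for m in metrics])
    return PlantSummary(
        plant_id=plant_id,
        n_cycles=len(metrics),
        mean_period_min=float(np.mean([m.period_min for m in metrics])),
        mean_length_mm=float(np.mean([m.length_mm for m in metrics])),
        mean_rate_mm_per_min=float(np.mean([m.rate_mm_per_min for m in metrics])),
        mean_shape=float(np.mean(shapes)) if shapes else None,
        mean_angle_deg=float(np.mean(angles)) if angles else None,
        cw_pct=cw,
        ccw_pct=ccw,
        ind_pct=ind,
        hypocotyl_length_mm=hypocotyl_length_mm,
    )


_GROUP_FIELDS = {
    "hypocotyl_length_mm": lambda s: s.hypocotyl_length_mm,
    "period_min": lambda s: s.mean_period_min,
    "length_mm": lambda s: s.mean_length_mm,
    "rate_mm_per_min": lambda s: s.mean_rate_mm_per_min,
    "shape": lambda s: s.mean_shape,
    "angle_deg": lambda s: s.mean_angle_deg,
    "cw_pct": lambda s: s.cw_pct,
    "ccw_pct": lambda s: s.ccw_pct,
    "ind_pct": lambda s: s.ind_pct,
}


def standard_error(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) over the square root of n."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DataError("standard error needs at least two values")
    return float(arr.std(ddof=1) / math.sqrt(arr.size))


def group_summary(summaries: Sequence[PlantSummary]) -> GroupSummary:
    """Mean and SE of every parameter over the plants of one group."""
    if len(summaries) < 2:
        raise DataError("group summary needs at least two plants")
    mean: dict[str, float] = {}
    se: dict[str, float] = {}
    for name, getter in _GROUP_FIELDS.items():
        values = [getter(s) for s in summaries if getter(s) is not None]
        if len(values) < 2:
            continue
        mean[name] = float(np.mean(values))
        se[name] = standard_error(values)
    return GroupSummary(n_plants=len(summaries), mean=mean, se=se)


def significance_tier(p_value: float) -> str:
    """Map a p-value to the coarsest conventional tier it clears."""
    for threshold, label in SIGNIFICANCE_TIERS:
        if p_value < threshold:
            return label
    return "ns"


def two_sample_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    *,
    welch: bool = False,
) -> tuple[float, float, str]:
    """Two-sample t-test between group values.

    Student's pooled-variance test by default (the classical choice);
    ``welch=True`` drops the equal-variance assumption. Returns
    ``(t, p, tier)`` where the tier is one of p<0.00001, p<0.01, p<0.05
    or ns. Two degenerate identical groups give t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0, "ns"
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), significance_tier(float(p))


GROUP_TABLE_COLUMNS = [
    "Seedling",
    "Hypocotyl length (mm)",
    "Period (min)",
    "Length (mm)",
    "Rate (mm min-1)",
    "Shape",
    "Angle (deg)",
    "cw%",
    "ccw%",
    "?%",
]

# display precision per column: (decimals for per-plant and Mean/SE rows)
_PRECISION = [0, 0, 0, 2, 2, 0, 0, 0, 0]


def _render(value: Optional[float], nd: int) -> str:
    if value is None:
        return ""
    if nd == 0:
        return str(round_half_up_int(value))
    return f"{round_half_up(value, nd):.{nd}f}"


def write_group_table(
    summaries: Sequence[PlantSummary],
    path: str | Path,
    group: Optional[GroupSummary] = None,
) -> None:
    """Write the per-plant table plus Mean and SE rows as CSV."""
    if not summaries:
        raise DataError("no plant summaries to write")
    if group is None and len(summaries) >= 2:
        group = group_summary(summaries)
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(GROUP_TABLE_COLUMNS)
        for s in summaries:
            fields = [getter(s) for getter in _GROUP_FIELDS.values()]
            w.writerow(
                [s.plant_id]
                + [_render(v, nd) for v, nd in zip(fields, _PRECISION)]
            )
        if group is not None:
            for label, source in (("Mean", group.mean), ("SE", group.se)):
                w.writerow(
                    [label]
                    + [
                        _render(source.get(name), nd)
                        for name, nd in zip(_GROUP_FIELDS, _PRECISION)
                    ]
                )


__all__ = [
    "PlantSummary",
    "GroupSummary",
    "direction_percentages",
    "plant_summary",
    "group_summary",
    "standard_error",
    "significance_tier",
    "two_sample_ttest",
    "write_group_table",
    "GROUP_TABLE_COLUMNS",
]
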