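"""Trajectory rendering to SVG.

The calibrated path is drawn north-up / east-right as a polyline whose
colour runs from red (start) to blue (end), the usual way circumnutation
trajectories are displayed, or coloured per cycle. Fitted ellipses, their
major axes and a compass rose can be overlaid. The geographic y-up frame
is mapped to SVG's y-down coordinates at write time, and compass labels
are baked into the document so orientation mistakes are impossible.

Output is deterministic: identical inputs produce byte-identical SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .core_io import Trajectory
from .cycle_detection import Cycle
from .cycle_metrics import EllipseFit
from .errors import DataError

_CYCLE_PALETTE = [
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
    "#a65628", "#f781bf", "#666666",
]


@dataclass
class RenderOptions:
    color_mode: str = "time_gradient"  # or "per_cycle"
    show_ellipses: bool = False
    show_axes: bool = False
    show_compass: bool = True
    mm_per_svg_unit: float = 1.0
    margin_svg_units: float = 20.0
    stroke_width: float = 1.2

    def __post_init__(self) -> None:
        if self.mm_per_svg_unit <= 0:
            raise ValueError("mm_per_svg_unit must be positive")
        if self.color_mode not in ("time_gradient", "per_cycle"):
            raise ValueError(f"unknown color_mode {self.color_mode!r}")


def _gradient_color(frac: float) -> str:
    """Red (start) to blue (end)."""
    r = int(round(255 * (1 - frac)))
    b = int(round(255 * frac))
    return f"#{r:02x}00{b:02x}"


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def render_trajectory_svg(
    trajectory: Trajectory,
    cycles: Optional[Sequence[Cycle]] = None,
    fits: Optional[Sequence[Optional[EllipseFit]]] = None,
    options: Optional[RenderOptions] = None,
) -> str:
    """Render a calibrated trajectory (plus optional overlays) as SVG 1.1.

    Returns the SVG document as a string. ``fits`` aligns with ``cycles``;
    ``None`` entries (failed fits) are skipped.
    """
    opts = options or RenderOptions()
    if len(trajectory.points) == 0:
        raise DataError("empty trajectory")
    xy = trajectory.xy
    scale = 1.0 / opts.mm_per_svg_unit
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    m = opts.margin_svg_units
    width = (xmax - xmin) * scale + 2 * m
    height = (ymax - ymin) * scale + 2 * m

    def to_svg(x: float, y: float) -> tuple[float, float]:
        # geographic y-up -> SVG y-down
        return ((x - xmin) * scale + m, (ymax - y) * scale + m)

    parts: list[str] = []
    parts.append(
        '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    parts.append(
        f'<rect x="0" y="0" width="{_fmt(width)}" height="{_fmt(height)}" '
        'fill="white"/>'
    )

    n = len(xy)
    if opts.color_mode == "per_cycle" and not cycles:
        # no segmentation available: one neutral polyline over the whole path
        coords = " ".join(
            "{},{}".format(_fmt(px), _fmt(py))
            for px, py in (to_svg(x, y) for x, y in xy)
        )
        parts.append(
            f'<polyline points="{coords}" fill="none" stroke="#444444" '
            f'stroke-width="{_fmt(opts.stroke_width)}"/>'
        )
    elif opts.color_mode == "time_gradient":
        # one short segment per frame pair so the colour can vary along time
        for i in range(n - 1):
            x1, y1 = to_svg(*xy[i])
            x2, y2 = to_svg(*xy[i + 1])
            color = _gradient_color(i / max(n - 2, 1))
            parts.append(
                f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" '
                f'y2="{_fmt(y2)}" stroke="{color}" '
                f'stroke-width="{_fmt(opts.stroke_width)}" '
                'stroke-linecap="round"/>'
            )
    else:
        for c in cycles:
            color = _CYCLE_PALETTE[(c.index - 1) % len(_CYCLE_PALETTE)]
            coords = " ".join(
                "{},{}".format(_fmt(px), _fmt(py))
                for px, py in (to_svg(p.x, p.y) for p in c.points)
            )
            parts.append(
                f'<polyline points="{coords}" fill="none" stroke="{color}" '
                f'stroke-width="{_fmt(opts.stroke_width)}"/>'
            )

    if cycles and fits and (opts.show_ellipses or opts.show_axes):
        for c, fit in zip(cycles, fits):
            if fit is None:
                continue
            cx, cy = to_svg(*fit.center)
            ang = math.degrees(math.atan2(fit.major_axis[1], fit.major_axis[0]))
            if opts.show_ellipses:
                # SVG rotation is clockwise in screen coords = -ang in
                # geographic coords
                parts.append(
                    f'<ellipse cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
                    f'rx="{_fmt(fit.semi_major * scale)}" '
                    f'ry="{_fmt(fit.semi_minor * scale)}" fill="none" '
                    'stroke="#333333" stroke-width="0.8" '
                    f'transform="rotate({_fmt(-ang)} {_fmt(cx)} {_fmt(cy)})"/>'
                )
            if opts.show_axes:
                vx, vy = fit.major_axis
                x1, y1 = to_svg(
                    fit.center[0] - vx * fit.semi_major,
                    fit.center[1] - vy * fit.semi_major,
                )
                x2, y2 = to_svg(
                    fit.center[0] + vx * fit.semi_major,
                    fit.center[1] + vy * fit.semi_major,
                )
                parts.append(
                    f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" '
                    f'y2="{_fmt(y2)}" stroke="#1f6fd0" stroke-width="0.8" '
                    'stroke-dasharray="3,2"/>'
                )

    if opts.show_compass:
        r = m * 0.45
        ccx, ccy = m * 0.55, m * 0.55
        parts.append(
            f'<g font-family="sans-serif" font-size="{_fmt(r * 0.8)}" '
            'fill="#222222" text-anchor="middle">'
        )
        parts.append(
            f'<line x1="{_fmt(ccx)}" y1="{_fmt(ccy + r * 0.7)}" '
            f'x2="{_fmt(ccx)}" y2="{_fmt(ccy - r * 0.7)}" stroke="#222222" '
            'stroke-width="0.8"/>'
        )
        parts.append(
            f'<line x1="{_fmt(ccx - r * 0.7)}" y1="{_fmt(ccy)}" '
            f'x2="{_fmt(ccx + r * 0.7)}" y2="{_fmt(ccy)}" stroke="#222222" '
            'stroke-width="0.8"/>'
        )
        for label, dx, dy in (
            ("N", 0.0, -r),
            ("S", 0.0, r * 1.35),
            ("E", r, r * 0.3),
            ("W", -r, r * 0.3),
        ):
            parts.append(
                f'<text x="{_fmt(ccx + dx)}" y="{_fmt(ccy + dy)}">{label}</text>'
            )
        parts.append("</g>")

    parts.append("</svg>")
    return "\n".join(parts)


__all__ = ["RenderOptions", "render_trajectory_svg"]
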