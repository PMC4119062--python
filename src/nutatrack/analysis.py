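"""End-to-end analysis: calibrated trajectory in, per-cycle metrics out.

Thin orchestration over the detection and metric modules, so that library
users, the command line and the tests all run the identical pipeline:
smooth the north-south series, detect and confirm northward maxima,
segment into cycles, and compute the six parameters per cycle from the
raw (unsmoothed) calibrated points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .calibration import CalibrationConfig, apply_calibration
from .core_io import CycleMetrics, Trajectory, Unit
from .cycle_detection import (
    Axis,
    Cycle,
    DEFAULT_REL_PERSISTENCE,
    DEFAULT_WINDOW,
    Extreme,
    Kind,
    detect_northward_maxima,
    segment_cycles,
)
from .cycle_metrics import DEFAULT_INDETERMINATE_RATIO, analyze_cycle


@dataclass
class AnalysisResult:
    trajectory: Trajectory  # calibrated trajectory the metrics refer to
    candidates: list[Extreme]  # all detected y-extrema (for review files)
    accepted: list[Extreme]  # confirmed northward maxima
    cycles: list[Cycle]
    metrics: list[CycleMetrics]


def analyze_trajectory(
    trajectory: Trajectory,
    calibration: Optional[CalibrationConfig] = None,
    *,
    window: int = DEFAULT_WINDOW,
    rel_persistence: float = DEFAULT_REL_PERSISTENCE,
    min_swing: Optional[float] = None,
    accepted_extremes: Optional[Sequence[Extreme]] = None,
    indeterminate_ratio: float = DEFAULT_INDETERMINATE_RATIO,
    fold_high_inclusive: bool = True,
) -> AnalysisResult:
    """Run the full pipeline on one recording.

    A pixel-frame trajectory requires ``calibration``; a millimetre,
    geographic-frame trajectory is analysed as-is. Pass
    ``accepted_extremes`` (e.g. from a hand-edited review file) to override
    the automatic confirmation of northward maxima.
    """
    if trajectory.units is Unit.PIXELS:
        if calibration is None:
            raise ValueError("pixel trajectory requires a calibration config")
        trajectory = apply_calibration(trajectory, calibration)
    candidates, auto_accepted = detect_northward_maxima(
        trajectory,
        window,
        rel_persistence=rel_persistence,
        min_swing=min_swing,
    )
    if accepted_extremes is not None:
        accepted = sorted(
            (
                e
                for e in accepted_extremes
                if e.accepted and e.axis is Axis.Y and e.kind is Kind.MAXIMUM
            ),
            key=lambda e: e.index,
        )
    else:
        accepted = auto_accepted
    cycles = segment_cycles(trajectory, accepted)
    metrics = [
        analyze_cycle(
            c,
            indeterminate_ratio=indeterminate_ratio,
            fold_high_inclusive=fold_high_inclusive,
        )
        for c in cycles
    ]
    return AnalysisResult(
        trajectory=trajectory,
        candidates=candidates,
        accepted=list(accepted),
        cycles=cycles,
        metrics=metrics,
    )


__all__ = ["AnalysisResult", "analyze_trajectory"]
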