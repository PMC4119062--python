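"""Generate a synthetic circumnutation recording and recover its parameters.

Builds a 63-hour-style top-view recording (5-minute frames) of an apex
tracing a drifting, tilted ellipse, runs the cycle-detection pipeline and
prints the detected per-cycle table next to the generator's ground truth.
A close match on period / shape / angle / direction demonstrates the
whole measurement chain: smoothing, northward-maximum segmentation,
ellipse fitting and orientation analysis.
"""

from nutatrack import SyntheticSpec, analyze_trajectory, generate_trajectory
from nutatrack.core_io import format_cycle_row

spec = SyntheticSpec(
    n_cycles=5,
    period_minutes=175.0,        # minutes per cycle
    semi_major_mm=18.0,
    semi_minor_mm=10.0,          # shape coefficient 10/18 ~ 0.56
    axis_angle_deg=-11.0,        # long axis leaning slightly east of north
    direction="CCW",
    center_drift_mm_per_min=(0.004, 0.002),
    noise_sd_mm=0.18,            # 1% of the semi-major axis
    seed=14,
)

trajectory, truth = generate_trajectory(spec)
result = analyze_trajectory(trajectory)

header = "  ".join(
    f"{h:>16s}" if i < 4 else f"{h:>8s}"
    for i, h in enumerate(
        ["Numero", "Start", "End", "Middle", "Period", "Length", "Rate",
         "Shape", "Angle", "Dir"]
    )
)
print(f"detected {len(result.metrics)} cycles (truth: {len(truth)})\n")
print(header)
for m in result.metrics:
    row = format_cycle_row(m)
    print("  ".join(f"{v:>16s}" if i < 4 else f"{v:>8s}" for i, v in enumerate(row)))

print("\nground truth per cycle:")
print("  period 175 min, shape 0.56, angle -11 deg, direction CCW")
print(
    "\nEach detected period should sit within one 5-min frame of 175, the\n"
    "shape within ~0.02 and the angle within a few degrees of truth; the\n"
    "rotation direction must match exactly."
)
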