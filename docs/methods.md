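# Methods

This note documents the models, conventions and numerical choices behind
`nutatrack`, and what the synthetic validation does and does not show.

## Coordinate frames and calibration

Input trajectories are per-frame apex positions in image pixels (y
increasing downward). The analysis frame is *geographic*: x east-positive,
y north-positive, the view from above with north up. Calibration applies,
per point,

```
p_mm = scale(h(t)) · (p_px − origin_px),   y negated if the image y axis points down
```

with the pinhole perspective scale

```
scale(h) = (frame_width_mm / frame_width_px) · (D − h) / D
```

where `D` is the camera-to-ground distance and `h` the plant height at the
frame's timestamp. The inputs are the three quantities a user can actually
measure: frame width at ground level (from filming a ruler in the pot),
camera distance, and plant height at the start and end of the experiment.

Choices and caveats:

* **Pinhole model.** Similar-triangles optics is the minimal model
  consistent with those inputs; lens distortion is out of scope. Because
  only the relative scale matters, the model is exact for a centred
  thin-lens camera and a small field of view. Absolute millimetre values
  near large `h` carry the model's error, shared by all cycles of a
  recording; the shape, angle and direction parameters are scale-invariant
  and unaffected.
* **Height over time.** Only two heights are available, so `h(t)` is
  linearly interpolated (hypocotyl elongation over ~63 h is close to
  linear at this scale) and clamped, with a logged warning, outside the
  experiment window.
* **Origin.** The configured origin pixel (e.g. the organ base) maps to
  (0, 0) mm for any configuration.

## Cycle segmentation

The north–south (y) series is smoothed with a centred moving average
(default window **5 frames** = 25 min at 5-min sampling; configurable and
logged). At the series edges the window truncates to the available
samples, so output length equals input length. Smoothing is used *only*
to locate extrema: all metrics are computed from the raw calibrated
points, because averaging systematically shortens path length.

Extrema are detected where the first difference of the smoothed series
changes sign: + → − yields a maximum, − → + a minimum. Runs of exactly
equal values (plateaus) collapse to the run midpoint, ties toward the
earlier sample. A cycle is the inclusive slice between two successive
accepted *northward maxima*; N maxima give N − 1 cycles, consecutive
cycles sharing their boundary sample.

Three refinements make the automatic path robust where a human reviewer
would otherwise intervene:

* **Persistence pruning.** Near a flat, noisy peak the derivative can
  flip sign more than once, producing spurious maximum/minimum doublets.
  Adjacent extreme pairs whose vertical swing is below a fraction
  (default 0.2) of the 90th-percentile candidate swing are removed,
  smallest first. The percentile anchors the scale on genuine swings
  (≈ twice the north–south amplitude) even when doublets outnumber them,
  which happens for narrow ellipses whose long axis lies nearly east–west
  so the north–south projection is small.
* **Quadratic peak refinement.** The raw sign-change index uses only the
  ordering of neighbouring samples. Each surviving extremum is re-located
  by fitting a parabola to the smoothed series within an adaptive
  half-width (a fifth of the median maxima spacing, minimum
  `window // 2 + 1` frames) and snapping the vertex to the nearest frame.
  The cosine-like peak region is parabolic over that span, so the fit is
  unbiased while pooling many samples' magnitudes; Monte-Carlo at the
  worst studied conditions (shape 0.1, axis nearly east–west, 1% noise)
  shows it removes essentially all one-frame boundary jitter. Cycle
  boundaries remain sample indices — periods stay quantised to the frame
  interval, matching the tabulated convention.
* **Amplitude floor.** Recordings whose total north–south extent is below
  1 µm are reported as cycle-free: oscillation below the digitisation
  scale carries no information.

Manual review is file-based rather than graphical: detected candidates are
written to a CSV (`index,axis,kind,accepted`) which can be hand-edited and
fed back; the edit list supports accept, reject and insert.

## Per-cycle parameters

* **Period** = end − start timestamps, minutes. **Length** = polyline
  length of the raw cycle slice, millimetres. **Rate** = length / period;
  `rate × period = length` holds exactly before display rounding.
* **Ellipse fit.** Direct least squares on the algebraic distance subject
  to `4ac − b² = 1`, which guarantees an elliptic solution. The naive 6×6
  generalized eigenproblem is ill-conditioned, so the partitioned
  formulation is used: the quadratic-coefficient block is solved through a
  3×3 eigenproblem and the linear block recovered by back-substitution.
  Points are centred on their centroid and scaled to unit RMS radius
  before fitting; the conic is transformed back afterwards. The conic sign
  is fixed by `a > 0`. Center, semi-axes and axis directions come from the
  eigendecomposition of the quadratic form. Fits with fewer than five
  points, collinear scatter, or a non-elliptic/degenerate solution raise a
  fit error; the pipeline then reports shape and angle as undefined for
  that cycle and continues.
* **Shape** = semi-minor / semi-major ∈ (0, 1]: 1 is circular, ≈ 0.1 a
  very narrow ellipse.
* **Angle** = −atan2(vₓ, v_y) of the major-axis unit vector, folded into
  (−90°, 90°] (the axis is undirected): N = 0°, east-leaning negative,
  west-leaning positive, so a pure east–west axis reports +90°. The
  alternative fold [−90°, 90°) is available since the convention at the
  seam is not fixed by any tabulated value. For near-circular cycles
  (shape > 0.95) the orientation is poorly constrained; the angle is still
  reported but flagged `angle_unreliable` rather than suppressed, since
  published tables print angles even at shape 0.96.
* **Direction** from the shoelace signed area of the cycle polygon closed
  last-to-first: positive (counter-clockwise in the east-right/north-up
  frame, viewed from above) → CCW, negative → CW. When
  |signed area| / (π·a·b) of the fitted ellipse falls below a threshold
  (default 0.2, configurable) the rotation is *indeterminate* (`?`):
  opposite-handed lobes largely cancel, as in figure-eights. Without a
  fit, only an essentially zero net area is indeterminate.
* **Middle timestamp** = start + period/2, floored to the whole minute.

## Summary statistics

Per plant: arithmetic means of period, length, rate, shape and angle over
cycles (undefined shapes/angles excluded) and direction percentages
rounded half-up to integers — the three percentages may sum to 99–101 and
are reported as-is. Angle averaging is arithmetic on the signed degrees,
not circular; this matches how the tabulated per-seedling angles reduce to
their printed means. Per group: mean and SE = `sd(n−1)/√n` per parameter.
Between groups: Student's pooled-variance two-sample *t*-test by default
(the classical reading of an unqualified "t-test"), Welch via a flag, with
tiers ns / p < 0.05 / p < 0.01 / p < 0.00001.

Display rounding is half-up at the printed precision (periods and lengths
to integers, rates and shapes to two decimals, angles to integer degrees);
internal values keep full precision.

## Synthetic recordings

The generator emulates a digitised top-view recording: the apex is a
drifting centre plus an ellipse point at phase 2π·t/P (sign per rotation
direction), the long axis at a configurable geographic angle optionally
precessing per cycle (rosette trajectories), sampled at the frame interval
(default 5 min) with isotropic Gaussian noise in millimetres modelling
click/tracking jitter. Phase origin is chosen so each cycle starts exactly
at its northward maximum, aligning ground truth with the cycle definition;
a lead-in and tail (default a quarter period, rounded to whole frames) are
emitted so the boundary maxima are interior samples a sign-change detector
can find. Output is deterministic under a fixed seed, and the exact
per-cycle truth (period, noiseless sampled length, shape, angle,
direction) is returned alongside the trajectory. An inverse-calibration
renderer projects millimetre trajectories to pixel coordinates, including
perspective inflation, for end-to-end tests.

**Validation study.** The packaged recovery study generates 50 recordings
of 6 cycles each: periods drawn from the 5-minute grid in 130–240 min,
shape coefficients uniform in 0.1–1.0, long-axis angles uniform across
(−90°, 90°], both rotation directions, semi-major axes 10–25 mm (the scale
of sunflower hypocotyl circumnutation), and noise of 1% of the semi-major
axis. Under these conditions the pipeline recovers the exact cycle count
in every recording, every period within one frame, shape within ±0.015,
angle within ±3° (scored where true shape ≤ 0.9) and direction on every
cycle. Centre drift is excluded from this study — it genuinely distorts a
single-cycle ellipse (the fitted shape/angle then describe the drifted
loop, not the generating ellipse) — but is exercised separately for cycle
count and period recovery.

**What this does and does not show.** Passing synthetic recovery
demonstrates the correctness of the measurement chain under the stated
conditions. Real recordings additionally contain pauses, non-elliptic
lobes, irregular cycle-to-cycle variation and occasional camera
disturbance that no parametric generator reproduces; for such recordings
the extremes review file exists precisely so a human can override the
automatic confirmation.

## Known limitations

* The perspective model ignores lens distortion and off-centre principal
  points; calibration accuracy degrades for wide-angle close-range setups.
* Period resolution is one frame interval by construction.
* Angle is meaningless for near-circular cycles; it is flagged, not
  suppressed.
* The indeterminate-direction threshold (0.2 of the ellipse area) is a
  design choice; no tabulated criterion exists to pin it.
* Timestamps are naive local times; recordings spanning daylight-saving
  transitions should use a fixed offset.
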