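# Methods

This note records the models, parameter choices and numerical decisions
behind `octlens`, and what the phantom-based validation does and does not
establish.

## Problem setting

An AS-OCT B-scan of a scleral-lens wearer shows up to three bright,
roughly horizontal boundaries: the outer and inner limits of the lens body
(a thin band) and the anterior corneal/scleral surface (a thicker, brighter
band). Depending on where the scan cuts the eye, the lens either vaults the
cornea (central), approaches it toward one side (lateral/peripheral), or
rests on the tissue so only two boundaries remain (extreme / landing zone).
The quantity of clinical interest is the per-column clearance between the
lens inner surface and the cornea.

## Phantom generator

The generator is the package's study-condition definition, not a test
fixture. Defaults: 400×300 px, lens band 8 px thick at gray level 140,
cornea band 11 px at 235, background 8; parabolic geometry
`row(c) = apex + curvature·(c − w/2)²` with lens curvature 3·10⁻⁴ px⁻¹ and
cornea curvature 6·10⁻⁴ px⁻¹; apex vault 40 px. Batch generation draws each
image's geometry from realistic ranges (apex row 70–110, vault 25–55 px,
rotation 0–4° central, 8–25° lateral, 15–40° extreme) from per-item seeds
derived from the base seed.

Decisions worth recording:

* **Band cross-section.** Bands are rendered with error-function edges
  (softness σ = 1.2 px) rather than a Gaussian bump over the whole band:
  with a Gaussian cross-section the maximum vertical gradient of a thick
  band sits at mid ± σ, noticeably away from the half-maximum boundary, so
  no single "true edge" would exist for both gradient-based detection and
  half-maximum reasoning. With erf edges the maximum gradient and the
  half-maximum coincide exactly with the stated boundary, which makes the
  analytic ground truth unambiguous while keeping a realistic gradient
  width.
* **Speckle.** Multiplicative mean-one log-normal noise,
  `pixel × exp(N(−σ²/2, σ))` with σ = 0.2 by default, so the expected image
  equals the noiseless render (the σ²/2 offset removes the log-normal mean
  bias). Clipping to [0, 255] biases only pixels near the top of the range.
* **Band thicknesses** are kept below the 21-px top-hat kernel so the
  morphological opening removes the bands entirely and the top-hat
  transform preserves their full contrast. In the extreme scenario the
  lens and tissue bands are adjacent; their combined thickness (~19 px)
  stays just under the kernel for the same reason.
* **Rotation** resamples the image bilinearly about the centre onto an
  expanded canvas; the ground-truth curves are transformed analytically
  through the same affine map and re-expressed as one row per integer
  column of the output frame, so rasterisation never touches the truth.
* **Extreme geometry.** The lens rests flat on the tissue, so the
  clearance between the available lens curve (the outer limit) and the
  tissue surface equals the lens wall thickness everywhere. A tapering
  landing zone where the outer limit meets the tissue surface at a point is
  not modelled.

What the phantom does not emulate: real speckle correlation, depth-dependent
attenuation, specular central artifacts, eyelid/iris structures, motion.
Passing phantoms therefore demonstrates correctness of the algorithms under
controlled conditions, not clinical performance.

## Preprocessing

Median 7×7 first (impulse rejection; also the main speckle reducer),
then Perona–Malik diffusion with the exponential conduction function,
κ = 12 gray levels, dt = 0.2, 15 iterations, in flux form with Neumann
boundaries — the update is conservative, so the global mean is preserved to
float precision. κ sits well above the post-median background noise
gradients (a few gray levels) and well below genuine band-edge gradients
(≥ 25–40), which is what lets diffusion flatten speckle without eroding the
weakest edge in the pipeline, the lens–tissue interface of extreme scans.

Orientation: a global magnitude-weighted histogram of gradient directions
(36 bins of 5°, bins centred so 0° is a bin centre), circular mode with
parabolic sub-bin refinement; the image is rotated by the negated estimate
only when it exceeds a 5° dead band (central scans pass through
unrotated). On lateral phantoms the estimate includes the layers' intrinsic
tilt on top of the frame rotation — that is the desired behaviour, since
the goal is horizontal layers, not a zeroed frame angle.

## Localization

Canny (scikit-image) with hysteresis thresholds 90/120 on the 8-bit Sobel
scale and σ = kernel/3. The per-row edge-count profile's forward difference
is thresholded adaptively at mean + 2·SD; consecutive trigger rows merge
into areas, and an area qualifies only if it accumulates edge pixels worth
≥ 20 % of the image width. Tracing applies three criteria per column:
candidates need ≥ 3 edge neighbours in a 5×5 window and a local intensity
at ≥ 90 % of the image's Otsu level (measured over a window reaching into
the band, because a boundary pixel itself sits on the dark side of its
edge); among survivors the one closest to the least-squares extrapolation
of the last 10 columns wins; with no survivor the trace extrapolates, gaps
re-fill linearly once the far side is found, and more than 30 consecutive
unsupported columns end the trace (the unsupported tail is dropped). Two
guards proved necessary on noisy phantoms and are part of the smoothness
criterion: a per-column row jump is capped at 3 px, and while a gap is
open, reacquisition must land within 3 px of the predicted continuation —
otherwise a parallel boundary 8 px away captures the trace.

Close boundaries (lens wall, or lens-on-tissue interface) often merge into
a single profile area once curvature and residual tilt spread their rows;
when only one curve can be traced, a restricted search below it recovers
the second boundary. The cornea is the curve with the most intensity mass
in the 12 rows beneath it. The lens inner limit is the strongest negative
vertical derivative below the outer limit within a bounded depth (25 px,
additionally capped 3 px short of the cornea so the tissue's far edge can
never masquerade as the lens wall); columns without signal reuse the
running median band width. If fewer than 10 % of columns carry direct
signal, or the inner limit stays within 2 px of the cornea over more than
80 % of shared columns, the image is classified two-layer. The fraction of
columns separating by more than 2 px is kept as the classification
confidence and later feeds the ROC.

## Snake

One node per column, vertical moves only (layers are single-valued per
column after rotation). Energy: α·Σ(Δrow)² + β·Σ(second differences)² +
edge weight · Σ P(node), with P the Gaussian-smoothed (σ = 2) gradient
magnitude, negated and normalized to [−1, 0]. The constant horizontal
component of the first difference is omitted (an additive constant).
Defaults α = 50, β = 20, edge weight 1 — at this operating point the snake
is predominantly a smoother of the already edge-accurate preliminary
curves, which is its role in the pipeline.

Update scheme: nodes are processed in three interleaved strides (stride 3),
so simultaneously updated nodes never share an energy term and every
accepted move strictly lowers the total energy — the energy trace is
non-increasing by construction. Within a node's move window (± 2 px) the
energy is quadratic in the row plus the piecewise-linear interpolated
potential, so the per-cell constrained minimizer is computed analytically;
the descent is exact coordinate descent rather than an integer-grid scan.
This matters for the stiffness property (higher β must not increase the
output's bending energy): a discrete scan stalls on a step-size floor whose
height grows with β, which inverts the expected ordering, whereas at the
exact per-node minimum the classic exchange argument applies once runs are
iterated to convergence. Convergence: fewer than 1 % of nodes moving (or
none, when `conv_tol = 0`), capped at 400 iterations by default.

## Distances

Vertical: same-column row difference (fast, biased on tilted flanks —
reported as-is because that bias is the paradigm's documented limitation).
Normal: least-squares tangent over a 10-column window, ray cast toward the
cornea, exact ray–segment intersection (no pixel stepping, no quantisation
bias); undefined (NaN) when the ray leaves the cornea's span. Nearest:
coarse scan of every 10th vertex inside a ±50-column window around the
vertical projection, then exact point-to-segment distances on the segments
around the two best coarse basins and around the projection; ties break
toward the smaller column. Refining against segments rather than vertices
is required for the ordering invariant — the normal paradigm returns
sub-pixel intersection points, and a vertex-only nearest search could
exceed it by up to the half-sample spacing. The coarse/refine decomposition
is exact for curves whose undulation period exceeds the coarse step; that
premise (smooth, snake-refined boundaries) is the same one that justifies
restricting the search window at all.

Distances are in pixels; a pixel size in µm can be attached and is a pure
scale factor. The scanner's physical pixel pitch is not assumed anywhere.

## Differential evolution

rand/1/bin with F = 0.8, CR = 0.9 defaults (F's admissible range is
[0, 2]); population > 4 enforced; donors are clipped to the bounds and
snapped to each parameter's grid (kernels odd 3–31, windows 3–15, α and β
1–100, edge weight 0.1–5 in 0.1 steps, Canny limits 10–250 in steps of 10).
Selection keeps the trial on ties. Stop criteria: a generation cap
(default 200) or 30 generations without the best fitness improving by more
than 10⁻³. The segmentation fitness is the mean per-curve MAE in px with a
100 px penalty per failed or misclassified image; a fitness evaluation that
raises counts as +∞, so the incumbent survives. The Canny ordering
constraint (low ≤ high) is repaired by swapping inside the
vector-to-config adapter.

## Evaluation

Curve errors are per-column row differences over the shared span (columns
outside the overlap are excluded and counted). Classification treats
three-layer scans as the positive class; the published description of the
confusion-matrix cells for this task is internally contradictory, and the
sensitivity wording ("positive images … with the three layers") is the
reading adopted here. AUC is the Mann–Whitney pairwise statistic with ties
at one half, computed over the inner-limit distinctness confidence.

## Problem sizes used in the checks

The validation scripts use 400×300 px phantoms: a 60-image mixed batch for
classification statistics, 100 noiseless phantoms for the paradigm ordering
invariant, 1000 random curve/column cases for the nearest-point oracle, 100
random snake runs for energy descent, and DE benchmarks with a population
of 20 over 200 generations (sphere) and 100 generations (gridded
quadratic). These sizes give stable statistics while keeping a full run in
the low minutes on one core.

## Known limitations

* The two-layer (extreme) interface between lens and tissue is the
  lowest-contrast edge in the pipeline; under default speckle its trace is
  the least accurate output (errors of a few px against sub-pixel
  elsewhere), mirroring the method's known weakness in extreme regions of
  real scans.
* The row-profile area detector presumes near-horizontal layers; rotation
  correction must land within a few degrees, which the HOG estimator
  delivers for the phantom family but is untested on heavily curved
  pathology.
* Vertical-paradigm values on rotated originals inherit the paradigm's
  tilt bias by design; results are mapped back to the original frame
  before measuring.
* The DE fitness is an operationalization (mean MAE + failure penalty);
  the original tuning objective for the published parameter set is not
  stated anywhere and may differ.
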