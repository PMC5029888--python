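# Methods

This note documents the models, numerical choices, and limitations behind
`woundpatch`. Everything quantitative stated here is computed by the test
suite or the example scripts; nothing is quoted from external data.

## Scene model and synthetic renderer

The renderer exists so that every pipeline stage can be validated against
analytic ground truth. It models a **planar scene** (the wound plane,
z = 0, units of cm) containing:

- a wound of known analytic area — a circle (πr²), an ellipse (πab), or a
  star-shaped "blob" r(φ) = r₀(1 + Σₖ aₖ cos(kφ + φₖ)) whose area is taken
  from the shoelace sum of a 4096-vertex polygon;
- the 3×3 color patch (cell 0.7 cm, gross 2.1 cm), coplanar with the wound,
  as the method requires in practice.

The camera is an **ideal pinhole** (no lens distortion — real phone optics
are uncharacterized and distortion correction is out of scope) at distance
d from a look-at point on the plane, optical axis meeting the plane at
elevation θ; θ = 90° is fronto-parallel. Rendering is inverse mapping
(each pixel back-projected to the plane) with 2×2 supersampling, so edges
are anti-aliased symmetrically and carry no net bias. Global illumination
is a per-channel gain triple; sensor noise is i.i.d. Gaussian per channel
after the gain, clamped to [0,1] — the simplest model that still stresses
both the color normalization and the segmentation. Identical
(scene, camera, seed) triples give bit-identical images.

The default validation scene is the circular defect of **12.57 cm²**. Note
this corresponds to a radius of 2 cm (π·2² = 12.566); the defect is
sometimes described by its "2 cm" dimension, which is consistent with the
area only as a radius. The area value is treated as authoritative because
the whole error analysis clusters around it.

What the renderer deliberately does *not* emulate: skin texture, specular
highlights, non-planar (curved limb) wound beds, shadows, lens distortion,
and motion blur. Passing tests therefore demonstrate correctness of the
geometry, color, and segmentation machinery — not robustness to every
clinical imaging artifact.

## Patch detection

Detection is color-driven: pixels near any of the nine reference colors
(Euclidean distance in sRGB, threshold 0.30 with adaptive retries at 0.22
and 0.15) are grouped; the patch is the connected region showing at least
7 of the 9 distinct reference colors that does not touch the image border.
Before matching, the image is white-patch normalized (each channel divided
by its 99.9th percentile, floored at 0.25) so a global tint with gains in
roughly [0.7, 1.3] cannot defeat the threshold. The outer quadrilateral is
the maximum-area 4-vertex subset of the region's convex hull; the 4-fold
rotation ambiguity is resolved by sampling the nine cell colors under each
cyclic corner labeling and keeping the labeling whose affine color fit to
the references has the smallest residual.

**Sub-pixel corner refinement** matters more than any other accuracy knob:
the homography extrapolates from the 2.1 cm patch to a wound several
patch-widths away, so corner error is amplified in the recovered scale.
Each border side is refined by sampling intensity profiles perpendicular
to the side, locating the edge as the baseline-subtracted centroid of the
color-gradient magnitude around its peak (0.125 px steps, search window
±2 px), fitting a line through the crossings, and intersecting adjacent
lines; two passes. On synthetic captures across the 30–50 cm / 30–90°
grid this leaves ≤ 0.25 px corner error and sub-percent area error.

The nine reference colors are not prescribed by the method itself; the
shipped default (red, green, blue, cyan, magenta, yellow, black, white,
mid-gray, arranged asymmetrically so orientation is unambiguous) is
user-overridable via `patch.colors`. Pairwise distances must be ≥ 0.2 for
detection to stay well posed.

## Homography and rectification

The image-to-patch-plane homography is estimated by the four-point **direct
linear transform**: the exactly determined 8×8 linear system from the four
outer-corner correspondences (least squares when more points are given).
Degenerate configurations (three collinear points) are rejected. Tests
hold the solution against an independent SVD-based DLT (null vector of the
2n×9 system) to 0.1 px.

Rectification warps the image (bilinear) by the homography composed with a
metric scaling, so the patch becomes an axis-aligned square at
`rectify.px_per_cm` (default 100 px/cm, i.e. 0.1 mm/px). The contract
supports rectifying the full warped footprint of the frame, but the
measurement pipeline rectifies a window of `rectify.margin_cm` (default
8 cm) around the patch: at grazing angles the full footprint approaches
the plane horizon and the raster size diverges, while the wound must in
any case lie near the patch. Pixels whose bilinear support falls outside
the captured frame are filled with the image-border median color so no
seam edge can attract the snake.

Planarity is assumed throughout, as the method's protocol instructs the
patch be placed in the wound plane; out-of-plane wound beds bias the scale
and are a documented limitation, not an error.

## Color normalization

A **3×4 affine map** (3×3 gain block + offset per channel) is fitted by
least squares from the nine observed cell means (inner 60% of each cell,
sampled in the rectified frame where cells are axis-aligned) to the
reference colors, then applied per pixel and clamped. Nine observations
determine the 12 parameters with enough redundancy to be stable, and the
full gain block captures channel cross-talk that a diagonal model misses.
Cells with a channel at the sensor ceiling that also misfit an initial
all-pairs fit are dropped (when ≥ 5 well-posed pairs remain): clipping
violates the affine model. All color math is in the image's native sRGB
encoding — no linearization; this is a dialect choice, applied
consistently to both the fit and the application.

Normalization runs after rectification (cell sampling is a plain crop
there); the stage order is recorded in every measurement report.

## Segmentation: K-means seeding + GVF snake

- **Seeding.** K-means (k = 2, RGB features, 10 restarts, seeded; the
  patch region is masked to the border-median color and excluded) splits
  wound from skin. The wound cluster is the one farthest in color from
  the image-border median (the border is presumed normal skin); ties go to
  the smaller cluster, wounds being the minority area. A cluster closer
  than 0.05 to the skin color means there is nothing to segment
  ("no wound candidate found"). The initial contour is the convex hull of
  the largest connected component, pushed outward by 5% of its equivalent
  diameter — GVF snakes converge reliably onto a boundary from outside.
- **Edge map.** f = |∇(G_σ ∗ gray)|, min–max normalized; σ = 1 px at the
  default 100 px/cm scale.
- **GVF.** The field (u, v) starts at ∇f and iterates
  u ← u + dt(μ∇²u − (u − f_x)(f_x² + f_y²)) (likewise v), Neumann
  boundaries, μ = 0.2 (the canonical literature value; the method's own
  description does not print it), dt = 1 ≤ 1/(4μ) for stability, capped at
  80·(max side)/64 iterations or a 1e-4 max-update tolerance. The
  diffusion runs on a crop around the wound candidate (bounding box + 25%)
  — identical field where it matters, at a fraction of the cost. Grids up
  to 64² run in float64 (oracle-grade); larger grids run in float32, where
  memory bandwidth dominates and the 1e-4 tolerance is far above float32
  resolution.
- **Snake.** Semi-implicit evolution with the fixed parameters α = 0.2,
  β = 0.2, γ = 1.0, κ = 0.5; cyclic pentadiagonal stiffness; bilinear force
  sampling; resampling to 2 px vertex spacing every 10 iterations;
  collapse below 8 vertices or 20 px² is an error. Convergence is declared
  when the mean vertex displacement drops below `tol_px = 0.001` with
  `max_iter = 2000`. These two values are deliberately tighter than a
  first guess of (0.01, 500): with the fixed force weights the far-field
  GVF drift is ~0.005 px/iteration, so a 0.01 px threshold can declare
  convergence while the contour is still ~20 px from the boundary on
  weak-edged, heavily foreshortened captures. The cost of the tighter
  tolerance is a few seconds per image.

Known behavioral limits, demonstrated in the tests: sharp corners are
rounded by the rigidity term (a couple of px), and very deep, narrow
cavities can "unzip" adjacent straight edges — the concavity-following
hallmark is exercised on a smooth horseshoe where the contour tracks the
full boundary to < 2 px.

## Measurement

Wound area is the **shoelace polygon area of the final sub-pixel contour**
times scale², not a pixel count — polygon area avoids boundary
quantization bias. The L×W baseline is computed as the sides of the
minimum-area bounding rectangle (rotating calipers over hull-edge
orientations). This caliper convention reproduces the classical biases of
the ruler method exactly — 4/π (≈ +27%) for a circle, ×2 for a right
triangle, exact for axis-aligned rectangles — which a principal-axis
definition does not. Error rates are signed percentages
100·(measured − truth)/truth.

The validation study renders n replicates per (distance, angle) cell with
replicate seeds derived from a master seed by fixed offsets, measures
each, and tabulates per-cell means; cells where all replicates fail are
recorded as NA with the reason. With noise σ = 0.01 and 3 replicates the
simulated grid stays within about ±1% — comfortably inside the few-percent
envelope expected of the physical method — with the largest errors at the
most oblique, most distant captures, as expected from scale amplification
of corner error.

## Longitudinal statistics

Degree of decrease = 100·(A₀ − A_f)/A₀, with A_f the last observation (no
extrapolation). The half-decrement day interpolates linearly between the
bracketing visits by default (`nearest` snaps to the closer visit day);
linear interpolation is the minimal assumption between sparse dressing
visits, and for a non-monotonic series the **first** crossing counts — the
earliest clinically meaningful milestone. Group tables report n, mean, and
sample SD (n−1), with undefined half-days excluded and counted.

The synthetic cohort generator draws per-patient decrease rates from
normal distributions truncated to (0, 100] — facial ≈ N(67, 12.5²),
non-facial ≈ N(53, 18²) — and builds each patient an exponential series
consistent with the drawn rate, so half-decrement days follow from the
same ground truth. At n = 30 per group the sampling SE of a group mean is
≈ 2.3 points; recovery tests therefore average group means over several
seeded cohorts rather than gambling on a single draw.

## Problem sizes and runtime

Defaults were chosen so a full single-image measurement (800×600 capture,
100 px/cm rectification, ~2 cm wound) takes a handful of seconds on one
core, and the complete 9-cell × 3-replicate validation grid about three
minutes. The synthetic cohort and healing-series checks are instantaneous.

## Known limitations

- Planar-scene assumption: curved wound beds bias areas low or high
  depending on geometry; no correction is attempted.
- Single wound per image: the largest candidate component wins.
- Color features only: granulation/slough/epithelium are not
  distinguished, and no healing score is derived from color.
- The affine color model cannot undo channel clipping; saturated captures
  degrade gracefully (clipped cells are excluded from the fit) but lose
  accuracy.
- The renderer's noise and illumination models are simple; real-world
  robustness beyond them (shadows, speculars, texture) is untested by
  design.
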