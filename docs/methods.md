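# Methods

## Measurement model

The morphometry pipeline assumes a nearly fronto-parallel photograph of
opaque, roughly convex slices on a uniform backplate, with exactly one
rectangular reference card of known physical size in frame. Under these
assumptions a single scalar scale (pixels per mm) relates image and world,
so no perspective correction is attempted; out-of-plane tilt and lens
distortion translate directly into measurement bias and are out of scope.

Stages and their parameters:

* **Grayscale** — BT.601 luminance (0.299 R + 0.587 G + 0.114 B), rounded
  to integers.
* **Gaussian blur** — separable, normalized kernel, symmetric ("reflect")
  borders; default 5 × 5, σ = 1.0 px. Large enough to suppress mild sensor
  noise, small enough not to shift high-contrast edges.
* **Edge extraction** — Sobel gradient magnitude, direction-quantized
  non-maximum suppression, hysteresis with thresholds (T_low, T_high),
  defaults 50/150 on the 8-bit Sobel scale (a common Canny operating point;
  a step of ≥ 60 intensity levels stays comfortably above T_high after
  blur). NMS uses a one-sided tie-break (strictly greater than the previous
  neighbour along the gradient, ≥ the next) so an ideal step edge thins to
  exactly one pixel instead of vanishing on the tie.
* **Contours** — edge rings are morphologically closed (3 × 3, one
  iteration) to bridge 1-px NMS gaps, hole-filled, and the outer boundary of
  each filled component is traced at sub-pixel resolution; contours are
  ordered by descending enclosed area. Measurement needs closed polygons,
  which is why contours come from filled regions rather than the raw edge
  mask.
* **Card identification** — the contour whose minimum-area-rectangle aspect
  ratio lies within 10 % (relative) of 38/26 ≈ 1.4615; among several
  candidates the largest area wins. Identification is purely geometric, so
  card and slices may have any intensities.
* **Calibration** — ppm = short rectangle side / 26 mm. The 38-mm side is a
  consistency cross-check; disagreement beyond 3 % raises a warning flag on
  the result rather than an error, because the aspect-ratio gate has
  already bounded the inconsistency.
* **Slice measurement** — long/short diameter from the minimum-area rotated
  rectangle, area from the shoelace polygon area. The rotated rectangle is
  used instead of the axis-aligned bounding box because axis-aligned
  extents overestimate rotated slices and are not rotation invariant; the
  axis-aligned values are still attached to each measurement for
  comparison. Contours under 400 px² are discarded as specks.
* **Reporting** — Error% = |pred − actual|/actual × 100, Acc% = 100 −
  Error%, printed at one decimal with ties rounded up (the convention of
  the published comparison table this package bundles). Two accuracy cells
  of that published table are internally inconsistent with the formula at
  one decimal (object 4 long: 94.3 printed vs 94.4 computed; object 16
  long: 99.0 vs 99.1); `peonyqc.datasets` keeps the printed values and
  flags the two cells, and the implementation follows the formula.

## Synthetic scenes

The generator emulates the acquisition geometry the measurement model
assumes: uniform backplate (level 20 by default), bright quasi-elliptical
slices (level 200), one 26 × 38 mm card at a distinct level (150) so that
aspect ratio — not intensity — must identify it, additive Gaussian sensor
noise (σ = 3 by default, mild controlled-indoor-imaging noise), and shapes
drawn with a 1-px anti-aliasing ramp so edge localisation shows realistic
sub-pixel error rather than staircase-exact rasterisation. `random_scene`
draws 3–6 ellipses with axes 10–30 mm at 10–14 px/mm on a 1280 × 1600 px
canvas (a working area of roughly 10 × 13 cm), rejection-sampling positions
so circumscribed circles keep a 2-mm gap.

What the generator does **not** emulate — slice surface texture, defects
(cracks, mold, insect holes), shading gradients, perspective, touching or
overlapping slices — bounds what passing tests show: they validate the
geometry and calibration chain, not robustness to real-world segmentation
difficulty. Recovery on these scenes (scale within 1 %, mean diameter error
≤ 2 %, area ≤ 5 %) is deliberately held to a tighter standard than the ≤ 5 %
reported for real photographs, since clean synthetic scenes remove most
sources of error.

## Neural blocks

All operators are NumPy forward passes (inference only: no losses, label
assignment or training loops).

* **Difference convolutions.** Each branch is parameterised by a raw k × k
  kernel and reduced to an equivalent vanilla kernel: center-difference
  subtracts the kernel sum at the center tap; horizontal/vertical subtract
  the column-/row-mirrored kernel; the adaptive pattern subtracts an
  angularly permuted copy (defined for 3 × 3, following the
  detail-enhanced-convolution lineage, and isolated behind
  `transform_kernel` so it can be swapped). Merging is the elementwise sum
  of the five transformed kernels; the merged-vs-parallel agreement is the
  module's core contract and is tested across 50 seeded configurations at
  1e-5 relative.
* **FCA.** The channel-axis 1-D convolution uses width k = 3 with circular
  padding (the minimal local-context choice; configurable). The "diagonal
  matrix" of the global branch is a learnable per-channel scaling. The two
  summaries fused in the final sigmoid are taken as the row-mean and
  column-mean of the cross-correlation matrix M — a design choice, since
  only M and the fusion are pinned down by the construction; each summary
  then reflects one branch's view of the cross-correlation.
* **Shared head.** Hidden width after the 1×1 reduce defaults to 64;
  nonlinearity SiLU; group norm with 16 groups. Sharing one DEConv+GN block
  and one cls/reg head pair across the three levels (strides 8/16/32) makes
  the parameter count strictly smaller than a per-level equivalent, which
  is asserted as a property. A per-level learnable scalar on the regression
  logits compensates the shared head for stride differences.
* **Box decoding.** Each side of a box is a softmax distribution over
  `reg_max` = 16 bins; the decoded distance is the expectation in grid
  units times the level stride, offset from the cell-center anchor. A
  greedy IoU NMS (threshold 0.45) is provided for emitting discrete
  detections from the pipeline.
* **Detection metrics.** Greedy score-descending matching per image and
  class (IoU ≥ 0.5, each ground truth used once, IoU ties to the lowest
  ground-truth index), 0/0 ratios defined as 0, all-point interpolated AP
  (precision envelope integrated over recall), and unweighted class-mean
  mAP. The evaluator convention matters at the third decimal on small sets;
  the all-point rule is the modern single-stage-detector convention.

The pipeline's detection branch needs per-level feature maps; when run
directly on an image it uses a fixed (non-learned) image-pyramid
featurization — stride-pooled intensities tiled across channels — which
exercises the head end to end but carries no semantics; meaningful
detections require externally supplied feature maps or weights.

## Numerical choices and degenerate inputs

Minimum-area rectangles come from rotating calipers on the convex hull;
collinear point sets raise instead of returning a zero-width rectangle.
Empty edge masks yield empty contour lists; an image without an in-tolerance
card raises a calibration error naming the closest aspect ratio seen.
Scene specs validate that shapes stay ≥ 3 px inside the frame (edges must
close) and that circumscribed circles do not intersect (merged contours
would silently corrupt the ground truth). Softmax in box decoding is
max-shifted; group norm uses ε = 1e-5. Test problem sizes (16 × 16 feature
maps, ≤ 8 channels, 20 scenes at ≈ 2 Mpx) keep the full suite and the
reproduction script to a few minutes on one CPU core while leaving every
contract representative.

## Known limitations

Touching slices merge into one contour (no watershed splitting); color is
discarded before segmentation; the 26 × 38 mm card constant matches the
printed reference size (a real Chinese ID card is larger — the constant is
configurable); grade assignment from diameters is out of scope, as the
grading standards are not numerically specified; trained-model detection
quality is not reproducible here and only the arithmetic of the published
ablation summaries is checked.
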