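# Methods

This note records the models, conventions and numerical choices behind
posekin, and what its synthetic tests do and do not demonstrate about real
data.

## Skeleton schema

The canonical skeleton has 25 keypoints indexed 0–24 (see
`posekin/data/skeleton25.yaml`). The index order — including the asymmetric
foot ordering (19 right toe, 20 right heel vs 23 left heel, 24 left toe) — is
frozen for annotation-file compatibility and is validated, not normalized.
Eleven left/right symmetry pairs cover all sided landmarks; nose, neck and
spine are the three fixed points of the mirror map, which is an involution by
construction.

Per-keypoint OKS falloff constants kᵢ default to the published COCO sigmas
for the 17 joints with direct analogs; the eight additional keypoints inherit
the constant of the nearest anatomical analog (neck → shoulder 0.079,
spine → hip 0.107, thumb/pinky → wrist 0.062, heel/toe → ankle 0.089). These
are priors about annotation variance, not measured values for this skeleton;
they are overridable per keypoint in the schema YAML, and a uniform-k
variant (`OKSParams.uniform`) is available when comparability with
constant-falloff evaluations matters.

## Annotation format

One text file per image, one line per person:
`class cx cy w h x1 y1 v1 … x25 y25 v25 [score]` — 80 fields for ground
truth, 81 with a trailing confidence for predictions. Coordinates are
normalized to [0, 1], origin top-left, y down; boxes are center-size.
Visibility follows the COCO convention (0 unlabeled, 1 labeled-occluded,
2 visible); real-valued flags are accepted on read and written back as
integers. Out-of-range visible keypoints are a hard error by default — a
`clip` option downgrades this to a warning, because silent clipping hides
annotation bugs. Files are written with 6-decimal fixed formatting, so
read∘write is the identity within 5·10⁻⁷ per field and write∘read is the
exact identity on files.

## Joint angles

`angle_at` implements the arccos of the normalized dot product of the two
joint vectors, with the cosine clamped to [−1, 1] to absorb floating-point
overshoot near collinearity; the result lives in [0°, 180°] and is invariant
under endpoint swap, uniform scaling about the vertex and rigid motion. The
test oracle is the independent |atan2(cross, dot)| form; the two agree to
better than 10⁻⁹ degrees over random triples.

Angles are always measured in pixel coordinates: on a non-square image,
normalized coordinates apply an anisotropic scaling that shears every angle,
so `measure()` requires the pose to be converted with `to_pixels` first.
Invisible (v = 0) or coincident keypoints make a measurement invalid rather
than raising, so batch measurement over imperfect detections never aborts.

The clinical catalog covers: neck (nose–neck–spine), elbow flexion
(shoulder–elbow–wrist), knee flexion (hip–knee–ankle), hip flexion
(shoulder–hip–knee, same side), and trunk inclination at the spine between
the neck and the virtual midpoint of the two hips. Trunk inclination and
pelvic tilt are marked *provisional*: the measurements are clinically
standard but no landmark-triple convention exists for this skeleton, so the
triples are package choices. `assess()` ships with an empty reference-range
table — acceptable joint angles depend on the exercise, the patient and the
camera plane, and inventing default medical cut-offs would be worse than
requiring the clinician to supply them.

## Evaluation

Matching is greedy one-to-one: predictions in descending confidence order,
each claiming the unmatched ground truth of highest similarity at or above
the threshold; similarity ties go to the lower ground-truth id and score
ties to input order, making the matcher fully deterministic. Greedy matching
can be suboptimal; the property suite checks it never exceeds the
exhaustive-assignment optimum on small instances.

AP uses 101-point interpolated precision (the COCO convention): the
precision envelope max_{r′≥r} p(r′) sampled on a uniform 101-point recall
grid. The alternative exact all-point interpolation is kept in the tests as
an oracle; for a monotone envelope the two differ by at most the grid
spacing, and the tests bound the discrepancy at 0.05. mAP@[0.5:0.95]
averages AP over the ten thresholds 0.50:0.05:0.95. Precision/recall/F1 are
reported from aggregate counts at threshold 0.5.

The OKS exponent is dᵢ²/(2·area·kᵢ²) with area = ground-truth box
width × height in pixels (the COCO s² convention). Because "object scale"
can also be read with the area itself as s, a `scale_mode` switch provides
the squared-area variant; the default is the COCO reading.

`pose_error` implements the plain mean squared keypoint distance over all
25 keypoints with no visibility masking — the loss-style definition taken
literally. Since an unmasked mean is meaningless when unlabeled keypoints
sit at placeholder coordinates, a `visible_only` flag provides the masked
variant; both are exercised in tests.

The keypoint confusion matrix is 25×26 (last column = missed): for each
annotated ground-truth keypoint, the nearest predicted keypoint of *any*
index within `radius_frac × max(box w, box h)` claims the cell; the default
radius fraction is 0.1, an assignment-rule choice of this package.
Left/right identity swaps appear as mass on (i, mirror(i)) cells and are
summarized by `symmetry_swap_rate`.

## Augmentation

Photometric operators never touch coordinates; geometric operators move
pixels, keypoints and boxes through one shared affine map. Named operators
need concrete transfer functions, which the recipe itself does not pin down;
the package uses the standard definitions and records every sampled
parameter in a provenance record:

- brightness: additive offset, fraction of full scale (default ±15%);
- exposure: multiplicative gain on gamma-linearized intensity (γ = 2.2);
  the global range is kept as printed (magnitude 0.1%–10%, random sign)
  and the box-local variant as ±10% — the two ranges are deliberately not
  reconciled;
- hue: fractional rotation of the HSV hue wheel (±15%); saturation: gain in
  HSV (±25%); grayscale: luminance replicated to three channels, applied to
  15% of images;
- blur: Gaussian σ = 2.5 px and 3/5/7 box kernels as *independent* knobs,
  since the recipe is ambiguous about their combination;
- noise: exactly round(frac·#pixels) pixels (default 0.1%) replaced by
  uniform random colors drawn without replacement, with a forced change if
  a sampled color equals the original — the altered-pixel count is exact;
- contrast: per-channel min–max stretch (constant channels pass through),
  global histogram equalization, or tile-local adaptive equalization;
- resize to a configurable target (default 560×140, kept as the pipeline's
  printed resolution despite its unusual aspect ratio) via stretch,
  fill-with-center-crop, or fit-with-black/white padding; center-crop sets
  keypoints pushed out of frame to v = 0.

Rotation/translation augmentation is deliberately excluded: no parameter
ranges exist for it anywhere in the recipe, and inventing them would change
the study conditions. Per-image RNG streams are derived from
(seed, image index), so results are reproducible independently of batch
order.

## Occlusion ablation

Peripheral ablation fills a border band of `border_frac` (default 0.2) of
each dimension; central ablation fills the rectangle spanned by the shoulder
and hip keypoints padded by `core_pad_frac` (default 0.1), requiring those
four keypoints to be annotated. Fill is black by default and configurable.
Masks touch nothing outside the declared region (bit-exact tests).

Displacement between baseline and occluded predictions is the plain
Euclidean distance per keypoint. The MRE report averages *relative*
displacement per keypoint over images; since the printed formula is absolute
while the reported magnitudes are clearly normalized, the normalizer is an
explicit choice: baseline bounding-box diagonal by default, with image
diagonal and box max-side as alternatives. The harness takes any
image → Pose provider, so a jittered-oracle double stands in for a detector
in tests.

## Synthetic generator

The stick figure is built by forward kinematics from the spine: each
segment's direction is the rotation of the direction back to its parent
joint by the requested interior angle, with the rotation sense mirrored
between sides. Requested angles (neck, shoulder abduction, elbow, hip and
knee flexion per side) are therefore realized *exactly*, and measurement
recovers them to 10⁻⁶ degrees — the random-spec sampling ranges stay a few
degrees clear of 0°/180°, where arccos conditioning degrades. Hand (thumb,
pinky) and foot (toe, heel) landmarks sit at fixed offsets from wrist and
ankle; eyes at fixed lateral offsets from the nose.

Segment lengths default to textbook body-segment proportions scaled to a
≈190 px standing figure in a 256×256 frame. Boxes are tight around visible
keypoints padded 5%. Datasets are split 80/10/10 by a seeded permutation.
Surrogate predictions add i.i.d. Gaussian jitter of σ px per coordinate
(clamped to the frame), giving Rayleigh-distributed displacements with mean
σ√(π/2) — the closed form the statistics tests check at n = 10,000. With
σ = 0 the prediction record equals the ground truth plus a confidence of
1.0, which is the exact perfect-prediction limit the evaluation suite
asserts (all metrics exactly 1.0 on 50 generated images).

What the generator does *not* emulate: photographic texture, backgrounds,
limb self-occlusion, perspective foreshortening, multi-person interaction
and annotation noise. Passing tests therefore validate the *computational*
stack — formats, geometry, metrics, masks — not the perception performance
of any detector on real images.

## Problem sizes

Default test and acceptance runs use 50-image synthetic datasets, 10,000
random triples/displacements for oracle and distribution checks, and
200 random instances for the matching-optimality bound; these sizes give
Monte-Carlo standard errors well inside the asserted tolerances (e.g.
≈0.013 px on the Rayleigh mean at n = 10,000, asserted at 0.06).

## Known limitations

- All geometry is 2D; out-of-plane motion biases every angle toward the
  camera projection, and no correction is attempted.
- The greedy matcher is not the Hungarian optimum; it matches the common
  evaluation practice and is bounded by the optimality tests.
- OKS constants for the eight non-COCO keypoints are anatomical-analog
  priors, not fitted values.
- The skeleton is fixed at 25 keypoints; converting COCO-17 annotations
  requires mapping the 17 shared joints and leaving the rest unlabeled
  (v = 0), which the format supports but no dedicated converter implements.
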