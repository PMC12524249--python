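# Methods

This note records the models, conventions and design choices behind
`dualview`, in the order a user meets them.

## Coordinate conventions

World coordinates are right-handed with Z up; Z = 0 is the pen floor
(the slatted floor is the calibration reference plane); the pen occupies
`[0, width] × [0, depth]` meters.  Pixels are 0-based, origin top-left,
x right, y down.  Boxes are `(x_left, y_top, w, h)`; the box centre is
`(x_left + w/2, y_top + h/2)`.  A camera is `K·[R|T]` with zero skew and
no lens distortion; `R, T` map world to camera coordinates, so the
camera centre is `−Rᵀ·T`.

## Camera calibration

`calibrate` minimizes the sum of squared reprojection errors over all
correspondences of all cameras jointly, with rotations parameterized as
axis-angle vectors, using Levenberg–Marquardt (`scipy.optimize.
least_squares`, method `lm`).  Iteration stops when the decrease in E
falls below 1e−10 (via `ftol`) or after 200 iterations; the result is
clamped to the initialization if the optimizer ever returned a worse E.
Correspondences behind a camera contribute a large finite residual
during optimization (so LM remains usable near cheirality violations)
and +inf in the reported error.

Identifiability with floor-only (coplanar) points:

- Full free intrinsics are not determined by coplanar points; the
  default mode therefore fixes the principal point to the image centre
  and enforces `fx = fy`, optimizing one focal length plus extrinsics.
  `fix_intrinsics` freezes K entirely (≥ 4 points per camera instead of
  ≥ 6).
- Even the single focal length is unidentifiable for a *fronto-parallel*
  camera over the plane (focal and height compensate exactly); it is
  identifiable for oblique views.  The test suite covers both cases.
- Collinear world points leave a rotation unconstrained and raise a
  degenerate-geometry error up front.

Because the floor frame is absolutely measured there is no gauge
freedom, so parameter recovery is tested directly: perturbing the true
extrinsics by 5° / 0.1 m and re-optimizing against noiseless floor
points returns E at numerical zero and held-out projections within
1e−4 px.

No distortion model is included; this is a documented limitation, not an
oversight — the mapping chain below is exact only up to it.

## Cross-view mapping and matching

The transform of a top-down detection into the panoramic view is
realized as the ground-plane chain

```
P2 = project_pan( backproject_to_plane( centre(P1), cam_top, h ) )
```

which is exact for points on the plane Z = h and realizes the rigid
world-frame relation between the two cameras.  A literal 2D
rigid/similarity mode (`fit_rigid_2d` / `apply_rigid_2d`, Umeyama
alignment) is provided for comparison; applied directly to pixels it is
only an approximation between non-parallel views.

- **Mapping plane height** defaults to the body-centre height 0.35 m
  rather than the floor, because detection-box centres sit at body
  height; `plane_height=0` reproduces the floor-plane description
  exactly.  The body height itself is a configurable stand-in (sources
  on the pen geometry do not state one).
- **Normalized distance** is pixel distance divided by the panoramic
  image diagonal, making thresholds like 0.025 resolution-independent.
  (How the original system normalized — diagonal, width or area — is
  not stated anywhere; this is this package's documented choice.)
- **Matching** is nearest-neighbour with strict-inequality acceptance
  (`d < threshold`); equidistant candidates break ties toward the
  lowest index, for determinism.  No candidates ⇒ rejection at +inf.
- **Tag-loss rule**: a tag-not-visible detection counts as a tag-loss
  query only if its box keeps ≥ 1 px margin from all four image
  borders; an animal truncated by the frame edge may simply carry its
  tag outside the view.

Evaluation over a query set: `coverage` = matched fraction,
`rejection_rate` = rejected fraction, `mapping_accuracy` = correct /
all queries, `matching_accuracy` = correct / matched (NaN, flagged,
when everything was rejected).  A match is correct when the IoU between
the matched box and the query's true panoramic box reaches the IoU
threshold (default 0.5).  `n_attempted` equals `n_total`: every query
initiates mapping.  It always holds that
`mapping_accuracy ≤ min(coverage, matching_accuracy)`.

Because the matched set at threshold t is nested inside the matched set
at any t' > t, coverage is monotone non-decreasing in the threshold by
construction.  Matching accuracy *tends* to decline with the threshold
(larger thresholds admit sloppier matches) but is not a theorem: in
scenes with crossing animals, a dropped panoramic detection can leave a
nearby wrong candidate as the nearest neighbour at tiny distance, which
lifts the error rate of the very small matched sets at the low end of
the sweep.  The pipeline therefore computes its threshold sweep on the
daytime-stationary condition, where this confounder is absent and the
decline is clean; the behaviour of active scenes is visible in the
per-condition reports.

## Synthetic pen simulator

The simulator reproduces the *statistical structure* of a dual-camera
gilt-pen recording setup, not its appearance:

- Pen 5.3 × 6.0 m with 35 agents, 5 untagged (defaults); a ceiling
  camera 3.4 m above the feeding-area centre looking straight down
  (1920 × 1080, focal 1500 px — covering only part of the pen, as a
  feeding-area camera does), and an oblique camera at the midpoint
  above one side (height 2.6 m, focal 900 px) aimed so its frustum
  covers the whole pen.
- Agents move by waypoint seeking at a per-agent cruise speed drawn
  from (0.15, 1.0] m/s; stationary agents have exactly zero speed;
  mixed agents alternate stationary/active bouts of 2–8 s.  This is a
  plausibility model — real pig motion statistics (speeds, rest bouts)
  are not published for this setting, and no behavioural inference
  should be read into it.
- A detection is the axis-aligned bounding box of the projected corner
  hull of a 0.9 × 0.35 m body rectangle at body-centre height, oriented
  along the travel heading.  With zero noise, the top-down box centre
  equals the direct projection of the body centre exactly (the
  straight-down view is affine on the body plane); the oblique view's
  box centre carries a small perspective offset from the centre
  projection — this is the main intrinsic error source of the mapping
  experiments.
- Noise regimes: day = 2 px edge jitter, 3 % dropout; night = double
  both (4 px, 6 %).  The doubling reproduces the qualitative day/night
  degradation of overhead livestock footage without claiming measured
  values.  Tagged animals are mislabelled tag-not-visible with
  probability 0.08 (an occluded ear tag).
- What the simulator does **not** model: occlusion between bodies,
  motion blur, appearance, lens distortion, detector confidence
  structure.  Passing tests therefore validate the geometry, matching
  and evaluation machinery — not detector performance on real video.

SSIM de-duplication (`filter_redundant_frames`) is a greedy scan that
keeps a frame iff its SSIM against the last kept frame is below the
threshold (default 0.78), using scikit-image's SSIM.

## Motion attention

The kernel follows the chain residual → embedding → guidance → biased
attention:

`Dt = |Ft − Ft−1|`; `Et = ReLU(W·Dt + b)` (1×1 convolution); `Et` is
flattened row-major (row index `h·W + w`) to `Et_flat ∈ R^{N×d}`;
`Ms = row-softmax(Et_flat·Et_flatᵀ)` (the Gram matrix reading of the
pairwise position-similarity construction); and
`As = row-softmax(Q·Kᵀ/√d_k + α·Ms)`, `Ys = As·V`.

Choices: single-head by default (the guidance construction is
headless); all softmaxes use max-subtraction; α defaults to 1.0 and is
swept in tests (no canonical value exists); flattening order is fixed
and documented because `Ms` indexing must match the flattening of `X`.
The sequence-domain pass (`sequence_motion_weighting`) applies the same
biased attention to a concatenated template/search sequence carrying
sinusoidal positional encoding; the guidance matrix may be recomputed
on the sequence or reused — both are accepted, since the original
description does not fix this.  Weights are user-supplied or
seeded-random: the module is a verified computational kernel with
loop-level oracle tests, not a learner.

## Channel pruning

Channel importance is `|γ|` of the BatchNorm scale, sparsified in
training by the L1 penalty `λ·Σ|γ|` (the penalty is implemented with
absolute values, per its description as L1 regularization; λ's
reference value is 0.005).  Pruning removes the `floor(rate·C)`
lowest-`|γ|` channels per prunable layer — never below `min_channels`
(default 1) — and updates consumer layers' input-channel counts.  A
global-threshold mode pools all prunable channels instead; whether the
original procedure was per-layer or global is unspecified, so both are
shipped with per-layer as default.

Accounting conventions (so analytic counts are reproducible by hand):
params = `k²·C_in·C_out + 2·C_out` per layer; FLOPs count a
multiply–accumulate as 2, i.e. `2·k²·C_in·C_out·H·W`, with stride 1 and
same padding so the spatial size is constant.  The spec graph must be a
DAG in which each layer has one producer (chains and consumer trees);
multi-input fusion layers are out of scope.

The dead-channel equivalence theorem — removing channels with
`γ = β = 0` and zeroed downstream weights changes nothing — is verified
on an executable toy Conv–BN–ReLU stack with a reference numpy forward
pass.  `sparsity_descent_demo` illustrates the L1 pressure as proximal
soft-thresholding on γ alone; full sparsity training would need the
task loss and its network and is out of scope.

## Tracking metrics

`Success(θ)` is the fraction of frames with IoU ≥ θ (θ = 0.5 default).
`Precision` is the mean Euclidean distance between predicted and
ground-truth box centres in pixels.  `Norm-Precision` divides that
distance by the frame *area* A — dimensionally odd but implemented
literally as the default because that is how the source formula is
printed, while its prose says "normalized by target size"; a `√A` mode
is provided, and neither is claimed as the original intent.  In literal
mode `precision = norm_precision · A` exactly.

Frames present in the truth but missing from the predictions count as
Success failures (a tracker must be penalized for losing the target)
and are excluded from the two distance means, with the excluded count
reported.  Multi-object metrics (MOTA/IDF1) are out of scope.

## Determinism and problem sizes

Every operation is a pure function of its inputs and an explicit seed;
the pipeline derives per-stage child seeds from the experiment seed by
fixed offsets, so stages are independently reproducible and a re-run
writes byte-identical outputs.  Default experiment sizes — 35 agents,
100–500 frames at 1 fps, 50-instance oracle sweeps, 1,000-frame jitter
tracks — were chosen so the full suite and the acceptance script each
run in seconds on one CPU while keeping binomial/Rayleigh test
intervals tight.

## Known limitations

- No lens distortion; real dome cameras would need one, and the
  plane-chain mapping inherits any unmodelled distortion as bias.
- The detection surrogate cannot reproduce detector-specific failure
  modes (confusion between adjacent animals, mask errors); mapping
  accuracies reported here characterize the geometry under the stated
  noise, not a trained detector.
- Matching uses box centres only; appearance re-identification and
  mask-overlap tests are out of scope.
- The waypoint motion model is not calibrated to real pig behaviour.
- Sparsity *training* of γ is demonstrated, not performed on a real
  detector.
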