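# dualview

A geometry and evaluation toolkit for dual-camera livestock monitoring.

In group pens, pigs are identified by ear tags, and a lost tag breaks the
link between an animal and its production, health and pedigree records.
A practical camera setup for finding the affected animal pairs a
**localized top-down view** (a ceiling camera over the feeding area,
where tags are clearly visible, but which covers only part of the pen)
with a **panoramic oblique view** (an elevated side camera covering the
whole pen, used for continuous tracking).  The open problem between the
two cameras is geometric: a tag-loss detection made in the top-down view
must be *mapped* into the panoramic view and *matched* to the right
animal there, with a rejection rule so that an uncertain mapping is
dropped rather than mislabelled.

`dualview` implements that cross-view machinery and everything needed to
exercise it end to end without farm video:

- **scene_sim** — a synthetic pen simulator: waypoint-seeking agents in
  a 5.3 × 6.0 m pen (35 animals, 5 untagged by default), two camera
  models, day/night detection-noise regimes, MOT-17-style CSV I/O, and
  SSIM-based frame de-duplication.
- **camera_geometry** — the pinhole model `s·(u,v,1)ᵀ = K·[R|T]·(X,Y,Z,1)ᵀ`,
  the reprojection-error objective
  `E = Σᵢ Σⱼ ‖(uⱼᵢ,vⱼᵢ) − π(Kⱼ,Rⱼ,Tⱼ,Xᵢʷ)‖²`, and joint two-camera
  Levenberg–Marquardt calibration from measured floor (Z = 0) points.
- **crossview_mapping** — the tag-loss decision rule (a tag-not-visible
  box must keep a ≥ 1 px margin from every image border), the
  ground-plane mapping chain (back-project the top-down box centre onto
  the shared reference plane, re-project through the panoramic camera),
  nearest-neighbour matching on diagonal-normalized pixel distance with
  threshold rejection, and the mapping statistics: matching accuracy,
  coverage, mapping accuracy, rejection rate.
- **motion_attention** — motion-biased attention as a verified numeric
  kernel: frame residual `Dt = |Ft − Ft−1|`, a 1×1-conv + ReLU motion
  embedding, the guidance matrix `Ms = softmax(Et_flat·Et_flatᵀ)`, and
  the biased attention `As = softmax(Q·Kᵀ/√d_k + α·Ms)`, `Ys = As·V`,
  in both the spatial and the sequence domain.
- **channel_pruning** — BatchNorm-γ channel importance with the L1
  sparsity penalty `λ·Σ|γ|`, per-layer (or global) structured pruning
  at a given rate, analytic parameter/FLOP accounting, and an
  executable toy Conv–BN–ReLU network that verifies the dead-channel
  equivalence theorem.
- **tracking_eval** — single-object-tracking metrics: Success(θ)
  (IoU-thresholded frame fraction), Norm-Precision (centre error
  normalized by frame area, with a √A alternate mode) and Precision
  (mean pixel centre error), with per-condition (day/night) reports.
- **pipeline** / CLI — the end-to-end experiment:
  simulate → calibrate → map → match → evaluate, per
  {day, night} × {stationary, active} condition, plus a
  normalized-distance threshold sweep.

## Worked example

```python
from dualview.pipeline import ExperimentConfig, run_experiment

results = run_experiment(ExperimentConfig(seed=1, n_frames=100))
day = results["mapping_per_condition"]["day_stationary"]
night = results["mapping_per_condition"]["night_active"]
print(f"day/stationary : mapping accuracy {day['mapping_accuracy']:.3f}, "
      f"coverage {day['coverage']:.3f}, rejection {day['rejection_rate']:.3f}")
print(f"night/active   : mapping accuracy {night['mapping_accuracy']:.3f}, "
      f"coverage {night['coverage']:.3f}, rejection {night['rejection_rate']:.3f}")
print(f"calibration    : final E = {results['calibration']['final_error_px2']:.2e} px^2")
```

prints

```
day/stationary : mapping accuracy 0.975, coverage 0.975, rejection 0.025
night/active   : mapping accuracy 0.959, coverage 0.959, rejection 0.041
calibration    : final E = 1.50e-25 px^2
```

Reading this: on a noisy simulated daytime scene, 97.5 % of tag-loss
queries raised in the top-down view were mapped to the correct animal in
the panoramic view at the default normalized-distance threshold 0.025
and IoU 0.5; 2.5 % were rejected by the threshold rather than
mismatched.  The night regime (double pixel jitter and dropout) degrades
both numbers, and calibration recovers deliberately perturbed camera
extrinsics to numerical zero reprojection error.  The detector is a
*synthetic surrogate* (simulator ground truth plus noise, dropout and
tag-visibility labels) — no CNN is trained here.

The same experiment is available from a shell:

```bash
dualview run-experiment --out out/ --seed 1
dualview simulate --out sim/ --seed 1 --n-frames 50
dualview attention-demo --size 4x4x8 --seed 0
```

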