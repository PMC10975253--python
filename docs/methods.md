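# Methods

`orchardcount` implements a tracking-by-detection pipeline for counting
fruit in multi-camera UAV footage of orchard rows, together with a
declarative model of the detector architecture and a synthetic flight
generator used to exercise every stage without field data. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Box decoding

The detector head is anchor-based. For a grid cell `(cx, cy)` on a feature
map of stride `s` and an anchor prior `(pw, ph)`, raw logits
`(tx, ty, tw, th)` decode as

    bu = (σ(tx) + cx) · s        bw = pw · e^tw
    bv = (σ(ty) + cy) · s        bh = ph · e^th

so the centre is confined to its cell and sizes are positive by
construction. Box confidence is `σ(objectness) · max σ(class_scores)`.
Encoding (the inverse map) is exact wherever the centre lies strictly
inside the cell; the round trip is tested to 1e-9. Anchors are retuned for
orchard scenes: small `(80,70) (75,75) (85,100)`, medium
`(95,110) (130,110) (115,125)` per feature map, with the classic large
priors `(116,90) (156,198) (373,326)`; the per-map base box sizes are
20/40/80 on a 640-px input (strides 8/16/32). Externally supplied
detections are scale-classified by the COCO-convention area cutoffs 32² and
96² px² (configurable); detections decoded in-house carry the scale of the
anchor set that produced them.

## Detector graph and parameter accounting

The architecture is represented as an ordered list of layer specifications
(conv, focus, BottleneckCSP-v1, squeeze-and-excitation, upsample, concat,
detect head) rather than a framework module, so the trainable parameter
count is a closed form and plumbing is validated without weights.
Structural features:

- **Focus stem.** The input image is sliced into four 2×2 parity
  sub-images concatenated channel-wise (3×640×640 → 12×320×320, a lossless
  permutation of pixels), then convolved with 32 3×3 kernels, batch
  normalized, and passed through Hardswish.
- **BottleneckCSP-v1.** The cross-stage-partial block splits the feature
  map into a transformed path (1×1 conv, residual bottlenecks) and a 1×1
  shortcut path joined by concatenation. The v1 variant removes the
  transition convolution that the original block applied to the transformed
  path before the concatenation; the saving is exactly `c_hidden²`
  parameters per block with all widths unchanged. (Removing the shortcut
  conv instead would *grow* the follow-up convolution, which contradicts
  the block's stated purpose; see the tests for the closed-form
  comparison.)
- **SE blocks.** Squeeze-and-excitation channel attention at the ends of
  the stride-16 and stride-32 backbone stages and in the bottom-up neck.
  The squeeze ratio defaults to 4: with the block placement fixed, the
  ratio is the one free structural constant, and 4 lands the analytic total
  at 6,534,294 parameters, within 0.25% of the published model budget
  (6.52×10⁶); ratio 16 would undershoot by ~1%.
- **Merges.** The neck's skip connections are exactly layer 5→18, 8→14 and
  13→24; the outputs of layers 14 and 21 are combined at layer 22, and
  layer 23 feeds the medium-object head — the scale on which orchard fruit
  predominantly falls. Concat layers may declare a per-input rescale
  (nearest ×2 up, 2×2 mean-pool down) so these routings are geometrically
  consistent; a standalone upsample layer is used where the layer order
  permits one.

Bias policy: convolutions followed by batch norm carry no bias; detect
heads (1×1 convs to `3·(5+classes)` channels) do. Counting rules: conv
`ci·co·k²` (+`2·co` for its BN), BN `2·c`, SE `2·c²/r + c + c/r`, heads
`ci·co + co`. The analytic total is cross-checked in the tests against a
brute-force count over actually instantiated weight arrays.

Inference (`arch.predict`) is a plain numpy forward pass (im2col
convolutions) supporting random or externally supplied weights keyed by
layer index; it exists for shape/contract verification and small-scale
decoding tests, not speed. NMS is greedy by confidence with an IOU
threshold of 0.45 (configurable; the value is a convention, not a measured
constant). The default detection confidence threshold is 0.5.

## Stream synchronization and the quality gate

Frames are aligned by nearest timestamp against the slowest stream; the
default tolerance is half the slowest frame interval, and tuples whose
worst pairwise gap exceeds it are skipped and counted. Composites are
built by vertical stacking in camera order (top camera first) with
linearly blended overlap strips; the per-camera region map supports exact
back-projection (≤0.5 px).

SSIM uses the standard constants `C1=(0.01·255)²`, `C2=(0.03·255)²` on
8-bit luminance (ITU-R BT.601 weights) with a uniform 7×7 window; PSNR is
`10·log10(255²/MSE)` capped at 100 dB for identical images. A composite's
indices are the **minimum** over its overlap-strip pairs — the merge
quality is only observable where sources disagree, and the minimum is the
conservative choice. The gate marks a composite *distorted* only when
**both** SSIM < 0.50 **and** PSNR < 30 dB (strict inequalities); a frame
failing exactly one condition is accepted with a borderline warning.
Quality-report averages are plain arithmetic means and labelled as such.

## Tracking

Each track keeps an 8-dimensional state `(x, y, γ, h, vx, vy, vγ, vh)` —
box centre, width/height ratio, height, and per-frame rates — under a
linear constant-velocity Kalman filter. Noise scales follow
tracking-by-detection convention, proportional to box height: measurement
std `h/20` for positions and `0.1` for γ; process std `h/20` (pose) and
`h/160` (velocity). Covariances are re-symmetrized (with a warning) if
numerics degrade; a singular innovation covariance is ridge-regularized.
Predicted means are floored (`γ ≥ 1e-3`, `h ≥ 1` px) so extrapolation on
noisy short tracks cannot leave the physical domain.

Association distances:

- `d1` — minimum cosine distance between the detection's unit-norm
  appearance descriptor and the track's gallery of up to 100 descriptors
  (FIFO eviction). Empty galleries score the maximal distance 2.
- `d2` — squared Mahalanobis distance of the detection's `(x, y, γ, h)`
  from the Kalman prediction under the innovation covariance.

Both are gated (`d1 ≤ t1`, `d2 ≤ t2`, admissibility is the product of the
two gates) and combined convexly: `c = λ·d1 + (1−λ)·d2`. Defaults:
`t2 = 9.4877` (the χ² 0.95 quantile at 4 dof, the standard gate for a
4-dimensional measurement), `t1 = 0.2`, `λ = 0.5`; all configurable. The
gated matrix is resolved by the Hungarian algorithm with inadmissible
cells masked by a large sentinel, and the solver is validated against
exhaustive minimum-cost permutation on small matrices.

The per-frame cascade runs three passes: (A) active tracks, grouped by
increasing consecutive misses, matched by the gated combined cost; (A′)
tentative tracks matched the same way — they carry descriptors from their
first observation, and without this pass two objects with overlapping
boxes swap owners through the descriptor-blind IOU sweep and fragment into
multiple confirmed tracks; (B) all remaining tracks and detections matched
greedily by maximal IOU subject to `IOU ≥ 0.3`, which catches detections
whose appearance is genuinely novel (e.g. lighting changes).

Lifecycle: a new detection spawns a *tentative* track; `n_init = 3`
consecutive hits promote it to *active* (this is the moment it is counted);
a tentative track is discarded on its first miss; an active track becomes
*inactive* after `max_age = 30` consecutive misses. Ids are never reused.
A track active for 100 consecutive hits is flagged `confirmed_unique`,
freezing it against re-identification merges.

The default appearance descriptor is an L2-normalized 8×8×4 HSV histogram
(256-dim) of the box crop; any unit-norm embedding can be attached to a
detection instead. Note that colour histograms of visually similar fruit
are themselves similar, so appearance-based deduplication (below) is most
discriminative with stronger embeddings; the simulator's synthetic
descriptors model that regime.

## Counting

Detections on each composite are filtered first: small-scale boxes
(background-row fruit) and boxes whose centre leaves the operational zone
(the full canvas minus a configurable margin, default 0) are excluded and
tallied by reason. Cross-camera duplicates are collapsed **before**
tracking so one fruit seen by two or three cameras yields one track: within
a declared overlap strip (membership padded by half a box height),
detections from different cameras are merged when IOU ≥ 0.6; when both
carry descriptors, cosine similarity ≥ 0.9 is also required and the
geometric floor relaxes to 0.3, because the appearance term then does the
discrimination and localization jitter cannot split a genuine duplicate.
The highest-confidence member survives; the number suppressed accumulates
into the `multi_camera_once` tally.

The registry is append-only: a track is registered at its
tentative→active transition (with type, last velocity, uid, status and
registration frame) and flipped to inactive when tracking ends — never
removed. `counted` is the registry size, which is therefore monotone
during a run and idempotent under replay.

## Evaluation metrics

Precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, F1 (harmonic mean), and FNR
`FN/(FN+TP)` are reported on the percent scale with one-decimal rounding
in reports. FPR `FP/(FP+TN)` requires a true-negative count, which is
undefined for pure detection; it is computed only when the caller supplies
a negative-candidate count and withheld otherwise (no surrogate).
Detection↔truth matching is greedy highest-IOU one-to-one at `IOU ≥ 0.5`.
AP is the trapezoidal area under the precision-recall curve, with the
curve sorted by recall and anchored at recall 0 with its first precision
value; mAP is the (optionally count-weighted) mean over categories.

## The simulator: what it emulates and what it does not

The generator stands in for field data whose originals are not deposited.
It emulates a slender-spindle apple row — trees every 2 m, rows 4 m apart,
3.5 m tall, 200 fruits per tree in season, fruit radius 4 cm — with fruits
sampled uniformly inside per-tree crown ellipsoids (fruiting zone 1.5–3.0 m
above ground), and the three-camera rig at mount heights 1.2/2.2/3.2 m
with pitches +25°/0°/−20°. Working distance (1.2 m) and vertical FOV
(34°) are package choices made once so that those heights and pitches tile
the fruiting zone with two overlap strips; at 640×480 this gives a pixel
scale of ~654 px/m and ~52-px fruit boxes (medium scale). The default
pass speed is 0.5 m/s at 20 fps (2.5 cm, ~16 px of apparent motion per
frame).

Geometry is a **planar-face model**: each camera images a vertical band of
the row plane (band centre from pinhole intersection of the central ray,
common pixel scale `f/d`). Consequences worth stating plainly:

- Cross-camera parallax and stitching error are *not* modelled: a fruit in
  an overlap band projects to coincident composite positions in both
  cameras, perturbed only by the jitter noise term. Passing dedup tests
  therefore shows the mechanism is correct under calibrated-mosaic
  conditions, not that mosaicking of deep canopies is solved.
- Occlusion is a per-fruit Bernoulli state with Markov persistence 0.8
  (streaks along the flight axis, mimicking foliage), not geometric
  ray-casting.
- Rendered frames are shaded disks on seeded texture — sufficient for
  histogram descriptors and SSIM/PSNR plumbing, not photorealism.
- Synthetic appearance descriptors are random unit vectors per fruit
  (32-dim), i.e. maximally discriminative; real embeddings are weaker.

Noise presets: `none` (all zero — the ground-truth stream is complete and
exact), and `cloudy` (`miss_prob 0.14` per emission plus 5% streaky
occlusion for a net ~18% miss rate, one spurious box per composite frame
for a ~15% false-positive share, 2 px centre/size jitter, 0.03 descriptor
noise). These rates approximate overcast-weather detector error levels and
are a stress fixture, not a reproduction of any field measurement; measured
over ten seeded replicates they give detection precision ≈ 82%, recall
≈ 81%, count recovery within ±12% of truth, and exact duplicate
accounting.

## Problem sizes

The reference counting scenario is 5 trees × 10 fruits (50 fruits, ~420
composite frames, ~3 s per run); test-suite inference runs the graph at
64-px input where shapes, not content, are under test. These sizes are the
package's own defaults for its bundled experiments; all are configurable.

## Known limitations

- The tracker assumes near-linear apparent motion; aggressive UAV
  manoeuvres or gusts (rolling shutter, motion blur) are out of scope.
- Appearance-gated dedup degrades toward pure-IOU behaviour when
  descriptors are weakly discriminative (e.g. colour histograms of
  uniformly red fruit).
- `counted` measures unique tracked objects that ever confirmed; it is not
  a yield estimate (no extrapolation to unseen canopy, no per-tree
  attribution).
- Training, augmentation and deployable weight export are non-goals; the
  architecture module is a specification and verification tool.
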