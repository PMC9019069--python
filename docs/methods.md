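# Methods

## Scope and design

`echoasd` implements a three-stage screening pipeline for secundum atrial
septal defects on color Doppler echo frames: view routing, parallel atrium
segmentation and defect-candidate detection, and deterministic
septum-region refinement. The stages are independent modules behind a thin
orchestrator (`echoasd.pipeline.run_case`); stage 2's two components are
order-free per frame and may run concurrently without changing the output.

All networks are built on `echoasd.nn`, a compact reverse-mode autodiff and
layer toolkit over numpy (im2col convolutions, batch normalisation,
pooling, nearest-neighbour upsampling, focal/Dice/KL losses, SGD/Adam).
Keeping the numerical core in the package makes every training run
single-threaded CPU-reproducible: a fixed seed fixes initialisation, data
order and hence the trained weights bit-for-bit.

## Stage 1 — view identification by distillation

Five classes with fixed codes (alphabetical, "other" last): A4C 0, LPS4C 1,
sax_basal 2, subAS 3, other 4; argmax ties resolve to the lowest code.

* **Student**: standard 34-layer residual network; 21,287,237 parameters
  with a 5-class head; 3.66 G multiply–accumulates at 224×224 (1 MAC is
  counted per convolution/affine product; pooling, normalisation and
  activations are excluded). Input resolution 224 is the package default
  for accounting since both architectures are conventionally specified
  there.
* **Teacher**: 200-layer split-attention network (radix 2, deep 64-wide
  stem, average-pool downsampling); 70.2 M parameters with the canonical
  1000-class head, which is the configuration used for the parameter-ratio
  statement (teacher/student ≈ 3.3 > 3).
* **Distillation objective**:
  `w · T² · KL(softmax(z_t/T) ‖ softmax(z_s/T)) + (1−w) · CE(z_s, y)`,
  defaults T = 4, w = 0.5 (configurable; the T² factor keeps KL gradients
  comparable across temperatures). Training is two-phase: joint KL+CE
  epochs, then CE-only fine-tuning (60/40 split of the epoch budget by
  default). The teacher is frozen during distillation and unused at
  inference.
* **Augmentation**: horizontal flip, vertical flip (each with probability
  0.5) and a "polar" rotation about the fan apex — taken as
  (W/2, 0.04·H), matching the sector rendering — with angle uniform in
  ±15°. Apex-centered rotation is an interpretation of transducer
  rotation; it preserves the sector's pixel count up to interpolation and
  boundary clipping.

## Stage 2a — atrium segmentation

U-Net encoder–decoder; four variants for ablation: `plain_unet`,
`unet_dense`, `unet_dual_attention`, `dense_dual_attention`. Architectural
defaults: 5 encoder levels, base width 64, dense blocks of 2/4/8 dense
layers (growth 32) at encoder levels 2–4, dual attention at the bottleneck
only. The decoder upsamples by nearest-neighbour followed by convolution
(chosen over bilinear interpolation for exact, simple gradients in the
numpy core; functionally a standard U-Net decoder choice). Classes default
to {background, LA, RA}; a 5-class mode adds LV/RV supervision for frames
where ventricles appear — refinement only consumes LA/RA.

Dual attention: position branch re-weights each spatial location by a
softmax over query–key affinities of 1×1-conv projections (C/8 channels);
channel branch re-weights each channel by a softmax over channel–channel
inner products; each branch adds a learned-gain residual and the block
output is the elementwise sum of the branches. The vectorised
implementation is tested against a direct two-loop computation.

Training loss: cross-entropy plus per-class soft Dice (1 − mean Dice with
smoothing 1.0). Desk-scale configurations append two normalised coordinate
channels to the input: left/right atrium identity is positional, and small
models with limited context need explicit coordinates to break the
left–right symmetry. This is an input-feature choice, not an architecture
change, and is off by default at full scale.

## Stage 2b — defect-candidate detection

Anchor-free per-location detection: backbone → feature pyramid (default
P3–P5, strides 8/16/32) → shared heads emitting a class logit, a
centerness logit and four distances (l, t, r, b) obtained as
`exp(scale_level · reg) · stride` (non-negative by construction).
Assignment: a location inside a ground-truth box is positive at the level
whose size range contains max(l, t, r, b) — ranges (0, 64], (64, 128],
(128, ∞) for P3–P5 — with ties across boxes resolved to the smallest area.
Centerness target is `sqrt(min(l,r)/max(l,r) · min(t,b)/max(t,b))`. Losses:
focal (α 0.25, γ 2) over all locations, −log IoU over positives, BCE on
centerness; all normalised by the positive count. Inference confidence is
`sigmoid(cls) · sigmoid(ctr)`; decoding inverts the distance encoding
exactly; greedy IoU-threshold NMS (0.4) merges duplicates. The score
threshold defaults to 0.05 so downstream ROC sweeps and the 0.95 image
call remain possible; the clinical cut-off is applied at call time, not in
the detector.

The desk-scale backbone is a reduced residual net (stem width 8); the full
configuration is reachable through `DetConfig`.

## Stage 3 — septum-region refinement and calls

* `convex_hull_mask`: hull of foreground **pixel centers** via Andrew's
  monotone chain in exact integer arithmetic, rasterised by half-plane
  tests with boundary pixels included. Degenerate inputs (1 point,
  collinear sets) are handled explicitly. Equivalence with a brute-force
  half-plane oracle is verified exhaustively on all 8×8 masks with ≤ 4
  foreground pixels.
* `extract_septum`: `hull(LA ∪ RA) − (LA ∪ RA)`, then binary dilation with
  a disk (default radius 5 px at 256 px, scaled linearly with image size)
  as a decision margin. A missing chamber raises a `MissingChamberError`
  naming it — a segmentation-failure signal the pipeline converts into
  "refinement skipped, candidates kept, frame flagged" rather than
  silently dropping candidates.
* `filter_candidates`: keep a box iff the septum band covers ≥
  `min_overlap_frac` (default 0.2) of the box's rasterised area. The
  fraction rule approximates "any meaningful overlap" while staying
  tunable; output is always a subset, so refinement can only remove
  detections (precision can rise; recall cannot).
* Calls: frame positive iff best surviving confidence ≥ cutoff (default
  0.95; a 0.9432 candidate is negative); case positive iff the fraction of
  positive target-view frames ≥ 0.6. Whether the case rule should be a
  frame fraction or a pooled confidence is genuinely open; the fraction
  reading is implemented and configurable.

## Metrics

Exact closed forms for accuracy, recall, precision, specificity, F1;
zero-denominator metrics are reported as `None`, never as 0. Dice on binary
masks; undefined when both masks are empty. ROC by sweeping the unique
scores with "score ≥ threshold ⇒ positive" (consistent with the 0.95
rule), AUC by trapezoid — verified to equal the Mann–Whitney statistic.
Youden cut-point maximises J with ties broken toward the higher threshold
(within a 1e−12 float tolerance). 95 % CIs use Wilson intervals and paired
before/after comparisons use McNemar's exact test; both are documented
approximations — reasonable standard choices where the exact construction
is not pinned down — and are not part of any acceptance surface.

## Phantom generator

Emulates what the pipeline needs and nothing more: a bright fan sector
(apex top-center), dark elliptical chambers with echogenic walls, a thin
septal gap, multiplicative Gaussian speckle (sd 10 gray levels at
mid-gray), and pure-channel-saturated red/blue jets crossing the septum on
positive frames (the detector must learn a color+location cue).
View-specific layouts: subAS = two atria side by side; A4C = four chambers
(atria deep); LPS4C = the four-chamber layout rotated 20–30°; sax_basal =
circle wrapped by a crescent; other = random distractor blobs. Four-chamber
frames carry both ventricles 70 % of the time and a single ventricle
otherwise, populating the content groups used by the grouped Dice table.

Dataset generation is deterministic: class counts by largest-remainder
apportionment (each within ±1 of its quota) and exactly ⌊n·rate⌋ positives
assigned to the first indices of a seeded shuffle of the jet-eligible
(target-view) samples — "other" frames have no septum to cross.

Not modelled: beamforming, attenuation, cardiac-cycle motion,
motion-blurred frames, anatomical variation beyond ellipse jitter. Passing
benchmarks therefore demonstrate that the implementation trains and
composes correctly on cleanly separable geometry; they say nothing about
clinical performance.

## Desk-scale benchmark conditions

All in `echoasd.benchmarks`; single CPU, fully seeded:

| benchmark | data | model | epochs | measure |
|---|---|---|---|---|
| view | 5 × 200 train / 5 × 50 val, 64 px | reduced residual student, proxy teacher | 10 (+4 teacher) | validation accuracy |
| segmentation | 200 train / 50 test target-view, 64 px | dense-dual-attention, width 8, depth 4, growth 8, coord channels | 20 | held-out mean LA/RA Dice |
| detection | 300 train / 50 test positives, 256 px | width-8 backbone, P3–P5 | 10 | jet recall at IoU 0.3 |
| refinement | 200 frames, ground-truth masks | — (deterministic) | — | precision gain / recall drop |

Detection runs at the native 256 px because the scaled jet (24×12 px)
must exceed the P3 stride for the level-range assignment to see it; at
128 px nearly half the boxes receive no positive location. The full
ResNet-34/ResNeSt-200 pair is kept for accounting and is constructible and
runnable, but the training benchmarks use the reduced models above — the
distillation, segmentation and detection code paths are identical at both
scales.

## Numerical notes and limitations

* float32 throughout; batch-norm uses running statistics in eval mode, so
  inference is deterministic.
* `count_macs` verifies the module tree (any layer owning parameters other
  than conv/affine/batch-norm raises) and counts during a real forward
  pass, so stride/padding arithmetic is never duplicated.
* Halving the classifier input does not quarter the MACs exactly: odd
  feature maps round up in the deepest stage (ratio ≈ 0.263 at 112 vs 224).
* The pipeline trusts predicted views by default
  (`use_ground_truth_views=False`); routing errors propagate to the
  frame-call denominator exactly as they would in deployment.
* The injected-false-positive refinement benchmark isolates stage-3
  geometry by using ground-truth masks; with predicted masks a failed
  segmentation falls back to unrefined candidates and a warning flag.
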