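# Methods

This note documents the models, conventions and numerical choices behind
`echoviews`: what each stage assumes, which knobs matter, and what the
synthetic experiments do and do not demonstrate.

## Synthetic phantom videos

Real echocardiography loops are not redistributable, so every experiment
runs on generated phantoms that keep the *structure* of the problem while
abstracting the anatomy.

**Geometry.** Each frame is a sector fan (apex at top-center, 75°
aperture, radius 0.88 of the frame; pixels outside the fan are exactly 0)
containing 2–4 bright-walled, dark-interior ellipses — "chambers" — on a
mid-gray background (level 0.35). Ellipse axes pulsate sinusoidally over a
cardiac cycle (amplitude 0.06, default 16 frames/cycle, phase-offset per
chamber). Default frame size is 256×256 so the resize path in
preprocessing is non-trivial.

**View classes.** A view class is a chamber layout. Separability is by
construction: the chamber count cycles with `class_id % 3`, and within a
count group the anchor chamber sits on a circle around the sector center
at an angle set by `class_id // 3`; per-coordinate jitter is ±0.015, so
anchors of same-count classes stay ≥ 0.18 frame-fractions apart. Layouts
are a pure function of `(class_id, seed)`. Ten layouts are known classes;
two more are reserved for the novel-category unknowns and never trained on.

**Unknown subcategories.** `novel_category`: a reserved layout at normal
quality. `poor_quality`: a known layout with visibility forced to ≤ 0.1,
leaving essentially texture-only frames. `multiple_views`: the layout
switches to a different known class at a frame index drawn uniformly from
[T/4, 3T/4).

**Quality model.** Four degradation knobs in [0,1] plus a speckle
strength: visibility scales wall/interior contrast; centering displaces
the layout by up to 0.22 of the frame (direction drawn per clip);
gain deviation darkens the image globally (multiplier `1 − 0.5·g` —
under-gain only, keeping the pixel statistics a monotone function of the
knob, which a linear quality head can recover); depth error shrinks the
layout (`1 − 0.45·d` — under-scaling only, same rationale). Speckle is
multiplicative log-normal noise (σ = 0.3 by default), normalized to unit
mean, the standard first-order ultrasound texture model. The ground-truth
quality is the fixed convex combination

    q = 0.4·visibility + 0.2·(1−centering) + 0.2·(1−gain) + 0.2·(1−depth),

so it always lies in [0,1] and is monotone in every knob. The weights are
arbitrary but frozen: any monotone combination would do for
parameter-recovery experiments, and fixing them makes tests reproducible.

**Splits.** Training holds known views only (routine acquisitions:
visibility 0.75–1.0, other knobs 0–0.15); validation and test add all
three unknown subcategories at a configured fraction of the known count
(default 0.3, at least one clip per subcategory). Split seeds are
`master + {0,1,2}` so splits are reproducibly disjoint while sharing the
layout seed. The outlier-exposure flag adds unknown clips to the training
split collapsed to a single `outlier` label. Quality-rated sets sample the
knobs over wide ranges (visibility 0.15–1, others 0–0.6/0.7) so the
ground-truth score covers most of [0,1].

**What the phantoms do not model:** wave propagation, transducer physics,
anatomical appearance, ECG overlays, inter-observer label noise.
Passing results show the *method* works when classes are learnable and
quality is encoded in the pixels; they say nothing about clinical
difficulty, where class overlap and rater disagreement dominate.

## Preprocessing and augmentation

Frames are converted to single-channel [0,1] by the unweighted RGB mean
(equivalent to averaging an RGB input layer's weights into one channel),
resized to height 224 with preserved aspect ratio (separable bilinear,
pixel-center aligned, edge-clamped), then center-cropped to 224×224;
post-resize widths below the target are symmetrically zero-padded rather
than stretched. An optional crop rectangle (applied first) stands in for
metadata-driven removal of vendor overlays.

Training augmentation is a cascade of five transforms, each applied with
independent probability 0.5, in fixed order: rotation (uniform ±25°),
gamma correction (γ uniform in [0.5, 2]), resized crop (scale uniform in
[0.2, 2] about a random center), elastic distortion (α = 2 px displacement,
Gaussian-smoothed with σ = 8 px), and additive Gaussian noise (σ = 0.01).
All frames of one clip share a single parameter draw — per-frame warps
would destroy the temporal consistency the video-level averaging relies
on. Geometric fills are 0 (background black), interpolation is bilinear,
and outputs are clipped to [0,1]. Training samples 8 frames per clip
uniformly without replacement (with replacement only when the clip is
shorter); at test time the full frame sequence is used.

## Frame classifier and training

The desk-scale backbone is a small CNN written in NumPy: input average
pool (factor 4), four blocks of [3×3 conv, stride 2 → group norm (8
channels/group) → ReLU] with widths D/8, D/4, D/2, D (default D = 128),
global average pooling (the non-negative penultimate embedding), and a
linear map to C logits (C+1 with outlier exposure). Optional weight
standardization of conv filters and a batch-norm variant exist behind the
backbone config; a ResNet-50-v2 option is reserved for full-scale
replication and intentionally not provided by the NumPy engine. All
backward passes are hand-written and checked against central finite
differences (worst error < 1e-9 in float64 on the test problems).

Training: softmax cross-entropy over frames, AdamW with decoupled weight
decay 0.01, β = (0, 0.999), ε = 1e-8; class-balanced sampling (class
uniform, then clip uniform, with replacement; the collapsed outlier class
is treated as one more class); an epoch is ⌈N/batch⌉ iterations with
batches of 16 videos × 8 frames. The full-scale schedule (300 epochs, lr
1e-4, ÷10 after epochs 150 and 250) is the default config; the desk-scale
benchmark overrides it (12 epochs, lr 1e-3, drops at 60%/85%, no
augmentation — the phantom classes are clean enough that augmentation is
unnecessary at this scale). All randomness flows from one recorded seed;
the final-epoch model is kept (no best-epoch selection), with the whole
per-epoch log stored in the checkpoint manifest.

## Anomaly scores and threshold calibration

All scores are sign-oriented so rejection is always "score below
threshold", and the boundary accepts (`S ≥ δ`). Max logit ignores the
outlier slot of an exposed model. Feature entropy uses the natural log on
the sum-normalized embedding and is negated; an all-zero embedding maps to
the minimum −log D with a warning. Candidate thresholds are midpoints
between consecutive sorted unique scores plus ∓∞ sentinels — this
exhausts every distinct accept/reject partition, so the calibrated δ is
exactly optimal on the calibration set. Ties break toward the smaller
candidate, mildly favoring acceptance. Two criteria are implemented:
maximum full-set accuracy (default; sensitive to the unknown-view
prevalence of the validation set) and the mean of OSCR and specificity
(prevalence-invariant alternative). A validation set without unknowns
makes the default criterion degenerate; the calibrator then warns and
falls back to δ = −∞.

## Evaluation metrics

All threshold-swept curves reuse the same candidate grid and the same
`S ≥ δ` convention as calibration. OSCR and the accept/reject ROC are
integrated by the trapezoidal rule over the sweep; the latter equals the
Mann–Whitney statistic (ties count 1/2), which the tests verify by pair
counting. The one-vs-one known-view ROC-AUC averages, for every unordered
class pair, the two directional AUCs computed from each class's own logit
(a config choice — the pairing is score-convention sensitive and logits
are the package default), then averages pairs unweighted, keeping the
statistic class-distribution agnostic. The open-set confusion matrix is
(C+1)×(C+1) with the unknown subcategories collapsed into the last
reference row and rejections in the last column; per-subcategory ROC
reports drop the other two subcategories before computing the curve.
Spearman correlation uses average ranks on ties and refuses constant
inputs.

## Quality head

Lasso on unstandardized embeddings (an optional standardization flag
defaults off so the minimized objective is exactly the stated penalized
loss; the intercept sign convention is the standard residual
`w·l̄ + b − y`). The α grid is 50 log-spaced values from the smallest α
that zeroes all weights (max |X_cᵀy_c|/N) down four decades; selection is
the minimal mean out-of-fold MSE over a seeded shuffled K-fold partition
(fivefold default, no one-standard-error rule), followed by a refit on all
data. Constant labels short-circuit to `w = 0, b = mean(y)` with a
warning. Predictions are clamped to [0,1]; bins are poor [0, 0.25],
fair (0.25, 0.5], good (0.5, 0.75], excellent (0.75, 1] — boundaries
belong to the lower bin. The solver is scikit-learn's coordinate descent;
tests pin it to the single-feature soft-threshold closed form (1e-8) and
an independent coordinate-descent oracle (1e-6 in objective).

## Benchmark problem sizes

The default end-to-end benchmark trains 10 known classes × 50 clips
(12 frames each, 256×256 rendered, 224×224 input) for 12 epochs, and fits
the quality head on 50 quality-rated clips per class with 15 per class
held out. These sizes were chosen as the package's desk-scale study
conditions: large enough that closed-set accuracy saturates and the
max-logit score cleanly separates poor-quality and novel-category
unknowns, small enough to run in a few minutes on one CPU. The
outlier-exposure comparison uses a smaller matched setup (6 classes × 20
clips, 8 epochs) since it needs two trainings.

## Known limitations

* The phantom task is much easier than clinical view classification:
  metrics near 1.0 on the benchmark reflect task cleanliness, not
  expected clinical performance.
* The NumPy engine targets clarity and testability, not throughput; there
  is no GPU path and no pretrained backbone.
* Gain and depth degradations are one-directional (under-gain,
  under-scaling); over-gain saturation artifacts are not modeled.
* The multiple-views subcategory contains exactly one layout switch per
  clip; real drifting acquisitions vary continuously.
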