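# Methods

This note records the model, the synthetic-data design, the numerical
choices, and the limitations of the `organnet` package.

## Region partitioning

The tiling is computed purely from image dimensions (no landmarks or
segmentation): with round-half-up written `rnd`,

* `r_tip = H - rnd(H/5)` — top of the tip band (region A, full width);
* `r_mid = rnd(2H/5)` — bottom of the root band;
* `c_left = rnd(W/5)`, `c_right = W - c_left` — the margin strip edges
  (region B), enforced symmetric so the tiling is exact;
* region D is rows `[0, r_mid)` × the central columns, region C is rows
  `[r_mid, r_tip)` × the central columns.

Coordinates are 0-based with half-open intervals, rows increasing downward.
Round-half-up on H/5, 2H/5 and W/5 plus the symmetry constraint guarantees
that the four regions are pairwise disjoint and cover all H·W pixels for
every H, W ≥ 5; below 5×5 some region would be empty and the input is
rejected.  The margin strips span only the rows above the tip band (the
non-overlapping reading of the region description), and region B is
returned as one image with the left strip and right strip concatenated
side by side, which keeps the downstream model interface uniform; the
concatenation order means a horizontal flip of the source image simply
flips the concatenated B crop.

## OrganNet

Five feature backbones with disjoint parameters: a full-image branch whose
pooled features feed four independent 2-layer MLP heads (tip → 2 outputs
for heart and lung, margins → liver, center → spleen, root → kidney), and
four region branches each feeding one such head.  Region crops are resized
(with aspect distortion) to the backbone input size.  All scalar outputs
pass through a logistic, so the two paths of each organ produce
probabilities; the published decision rule thresholds the average at 0.5,
which only makes sense on the probability scale, so squashing is applied
*before* averaging (averaging pre-sigmoid logits and squashing afterwards
is the plausible alternative; it changes fused scores but not the
qualitative behavior).  The threshold is strict (`score > 0.5`; exactly
0.5 maps to healthy).

Backbones: the default is a structure-faithful 101-layer bottleneck
residual network (7×7 stem, max-pool, stages of 3/4/23/3 bottleneck blocks
with batchnorm, 2048 features); a `"small"` backbone (three stride-2
3×3 convs, 32 features, no batchnorm) targets 64×64 inputs and trains in
seconds on one CPU.  All experiments and tests in this repository use the
small backbone; the deep backbone is constructible and runs forward, but
training it on CPU is impractical and nothing here depends on it.  MLP
head depth/width (one hidden layer, 32–64 units) is a minimal choice; it
is configurable.

The whole network stack (im2col convolution with backprop, batchnorm,
max/global-average pooling, residual blocks, AdamW with decoupled weight
decay) is a self-contained numpy implementation in `organnet.nn`,
gradient-checked in the test suite against float64 finite differences.

## Loss and metrics

The asymmetric loss is implemented in its minimizable (negated focal)
form, `-(1-p)^γ log p` for positives and `-p^γ log(1-p)` for negatives; a
single γ applies to both branches by default (an optional `gamma_neg`
splits them).  γ defaults to 2.0, the standard focusing value;
probabilities are clamped to `[1e-7, 1-1e-7]` before logarithms, and
gradients are zeroed where the clamp is active.  The batch objective is
the mean over samples of the sum over the five organs, applied to **all
ten** head outputs during training (each head supervised by its organ's
labels); fusion is used only at inference.  Joint supervision keeps one
optimizer run and lets the ablation's single-region networks reuse the
same head code trained in isolation.

Metrics follow the standard confusion-count definitions with "positive" =
"unhealthy".  Zero-denominator precision/recall are reported as 0.0 and
flagged in the report's warnings; metrics on all-zero counts raise.  Macro
averages are unweighted means over the five organs.

## Training harness

AdamW with decoupled weight decay (default 1e-2), learning rate 5e-4 and
batch size 64 at study scale (224×224 inputs).  The CPU test preset
(`TrainConfig.small`) uses 64×64 inputs, 8 epochs and learning rate 2e-3:
at desk scale a run is only a few hundred optimizer steps, too few for the
study-scale learning rate to move a freshly initialized network off the
label prior.  Horizontal-flip augmentation is applied conceptually before
partitioning; because each region crop of the flipped image equals the
flipped crop (with margin strips swapping inside the concatenated B
image), it is implemented as a width-flip of the precomputed branch
inputs, keeping margin semantics consistent.  No learning-rate schedule or
early stopping is applied by default.  All randomness (initialization,
shuffling, flips, data generation) flows from explicit integer seeds;
runs are bit-reproducible.

The ablation protocol trains six configurations under one shared
schedule — the full-image baseline (one backbone, four heads, thresholding
its own scores), the four single-region networks, and OrganNet — and
tabulates per-organ accuracy and F1 on the test split, with cells
undefined where a network does not predict an organ.  The baseline uses
the same four-head layout as the full branch of OrganNet (a single
five-output head is the alternative reading; the four-head variant keeps
the comparison architecture-matched).

## Grad-CAM

For an organ and branch, the gradient of the organ's pre-sigmoid score is
taken with respect to the branch's last convolutional feature maps; maps
are weighted by their spatially averaged gradients, rectified, normalized
to a maximum of 1 (an identically zero map — e.g. from a zeroed head — is
returned as-is), and bilinearly upsampled to the original image grid (full
branch) or the branch input grid (region branches).  Because the pooled
features are the spatial mean of the last maps, the spatially averaged
gradient equals the head's feature gradient divided by the map area, which
the implementation exploits.  The normalized map is invariant to positive
rescaling of the score.  `cam_region_mass` quantifies localization as the
fraction of total heatmap mass inside a region; for an all-zero map it
returns 0 by policy.

## Synthetic cohorts

The generator emulates a clinical tongue-photograph cohort whose raw data
are not public.  What it reproduces:

* per-organ marginal unhealthy prevalences (`"clinical"` preset:
  2103/2739/2938/4616/3111 out of 4,645 for heart/lung/liver/spleen/kidney)
  and the 3,455/295/895 train/val/test split proportions;
* region-localized cues: spots and reddened body for heart (lower half of
  the tip band — the tip proper), spots and fur patches for lung (upper
  half of the tip band), toothmarks and spots on the margins for liver,
  cracks and fur patches in the center for spleen and at the root for
  kidney.  Feature menus are a renderable reduction of the region-feature
  diagnostic map; the full TCM feature taxonomy (19 kinds) is not
  implemented as distinct renderers.  Toothmarks are placed on the margin
  strips for liver; their TCM reading as primarily a spleen sign is
  represented only through the spleen menu, keeping the label-region
  consistency invariant testable.

Organ labels are sampled independently per organ (only marginals of the
real cohort are known; co-morbidity correlations are not modeled).
Feature sizes and contrasts are chosen so the cues are clearly visible at
the 64×64 test scale — spots of 3–5% of the image side, cracks three
pixels wide, high-contrast colors against the tongue body — because a
generator whose cues vanish under 8× downsampling cannot exercise the
pipeline it exists to test.  Per-image nuisance variation (tongue geometry
and base-color jitter, Gaussian pixel noise) is included so the task is
not color-lookup trivial.

What it does **not** emulate: photorealistic texture, lighting or camera
variation, annotator disagreement, correlated organ statuses, or features
whose physical location differs from their diagnostic region.  Passing
tests on synthetic cohorts therefore demonstrate that the pipeline learns
and localizes region-planted signal, not that it would reach any
particular accuracy on clinical images.

Every placement is recorded in a ledger of (kind, organ, bounding box)
entries; an organ's label is 1 iff the ledger holds at least one of its
features, and every bounding box lies inside the organ's region (heart
boxes within the lower half of the tip band).  A `placement="uniform"`
control mode scatters features anywhere on the tongue, deliberately
breaking the region-label link for negative-control experiments.

## Problem sizes

Tests run at deliberately small scale, chosen as the package's own
desk-scale defaults: 64×64 images, the small backbone, cohorts of 240–2,000
samples, and 1–8 epochs.  The fusion-vs-baseline property is evaluated on
five seeded 2,000-sample cohorts; the Grad-CAM localization property on 50
positive test images of a trained model.  The study-scale configuration
(4,645 images at 224×224, deep backbone) is available as presets
(`CohortSpec.clinical`, default `OrganNetConfig`/`TrainConfig`).

## Known limitations

* Averaging probabilities rather than pre-sigmoid logits is a documented
  interpretation of the published decision rule, not the only one.
* The deep residual backbone is structure-faithful but has no pretrained
  weights; transfer-learning behavior is out of scope.
* The generator's independence assumption across organs means fusion
  benefits measured here may differ from cohorts with correlated organ
  statuses.
* Tongue detection/segmentation from raw photographs is out of scope; the
  partitioner assumes a pre-segmented, roughly centered tongue.
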