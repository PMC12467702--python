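# Methods

`maaseg` implements a two-stage weakly supervised pipeline for binary
gland segmentation in H&E histology, supervised only by per-patch
image-level labels.

## Problem setting

Whole-slide gland images of size W×H are cropped into 112×112 patches
with a 56-pixel stride.  Per-axis window starts are the stride multiples
that keep the window inside the image plus one clamped final start at
`dim − 112`, which guarantees full coverage and equals the closed-form
per-axis count `ceil((dim − 112)/56) + 1` for every axis length that is
not a multiple of 112 (for multiples the closed form under-counts by the
clamped tail window; the sliding construction is authoritative).  Each
patch carries a two-bit weak label `[gland present, background
present]` derived from the ground-truth mask: this is the only
supervision the first stage ever sees.

## Stage 1 — CAM generation and refinement

**Encoder.** A six-layer hierarchical transformer.  Each layer is an
overlapping patch-merging convolution (kernel 7/stride 4 in layer 1,
kernel 3/stride 2 afterwards; padded, so spatial sizes follow ceiling
division and the layer scales are 1/4, 1/8, 1/16, 1/32, 1/64, 1/128 of
the input), followed by two repetitions of (efficient self-attention,
Mix-FFN).  Self-attention reduces its key/value token set spatially by
per-layer ratios (8, 4, 2, 1, 1, 1 by default) with a strided
convolution.  The Mix-FFN embeds a 3×3 convolution between the 1×1
expansion and contraction, which injects the local positional
information; the encoder has no positional-embedding parameters.
Channel depths, head counts and reduction ratios are configuration; the
`tiny` preset (channels 8…48) is the desk-scale default, `base`
(64…320) a GPU-scale configuration.  All networks here are trained with
the package's own NumPy reverse-mode autodiff core (`maaseg.nn`), which
implements exactly the ops these models need (checked against central
finite differences in the test suite).

**Multi-level attention fusion.** Features from layers 3, 5 and 6 are
bilinearly upsampled to the layer-3 resolution S (1/16 scale),
projected to a common width by learned 1×1 convolutions, and summed.  A
1×1 head maps the fused map to per-class score rasters
[gland, background]; global average pooling gives the image logits.
Training minimises per-class binary cross-entropy on the pooled logits
(SGD, momentum 0.9, cosine-annealed learning rate 0.002 → 0, batch 16,
weight decay 1e-3), with random horizontal/vertical flips (p = 0.5),
random crops at ratio 0.7–1.0 resized back, and per-channel
normalisation by dataset statistics.  Weight decay matters here beyond
regularisation: unconstrained logits grow without bound once the
classification loss saturates, and the induced per-patch offsets in the
score raster drown the spatial signal that the CAM normalisation needs.
Two further choices make small-batch training robust: the classifier
head is zero-initialised (initial logits are exactly zero, so the first
steps are well-scaled regardless of the encoder's activation
magnitudes), and every trainer clips the global gradient norm at 5 —
without clipping, occasional loss spikes can collapse a run into
majority-class predictions from which the annealed schedule never
recovers.

**CAM.** The class activation map is the head's response before
pooling, rectified at zero and min-max normalised per class to [0, 1]
(a zero-range channel maps to all zeros, keeping the confidence
thresholds well defined).

**Restart ensembling.** Patch classification is essentially perfect for
every training restart, but *where* a from-scratch run places its
within-patch raster structure varies with the restart — the attention
layers let image-level evidence appear anywhere in the raster.  The CAM
stage therefore supports training several independently seeded restarts
(``cam.n_models``; the desk preset uses 3) whose raw rasters are
averaged: restart-specific structure cancels while the consistent class
evidence remains.  Fused features are concatenated across members for
the affinity descriptors.

**Tile-level reassembly.** Per-patch min-max normalisation is
well-behaved only when the patch actually contains both classes with
reasonable area: a patch that clips a thin gland sliver is guaranteed a
spurious full-scale "gland" region, because some pixel always
normalises to 1.  The refinement stage therefore works at whole-tile
scale: raw (unrectified) head rasters of all patches are bilinearly
upsampled to patch resolution, averaged over overlaps by the stitcher,
and rectified + min-max normalised once per tile.  Overlap averaging of
raw rasters also converts patch-level classification evidence (each
patch's global offset) into coarse spatial evidence at stride
granularity.  Fused features are stitched the same way and downsampled
to the tile's 1/16-scale CAM grid.  A tile whose every patch has a
negative gland logit gets an all-zero foreground map — a CAM is only
meaningful for classes the classifier detects in the image.

**Confidence labels.** Foreground scores are thresholded per pixel:
argmax foreground class where the top score ≥ β_h = 0.6, background (0)
where it is ≤ β_l = 0.3, uncertain (255) otherwise; boundaries are
inclusive on both branches.  The rule optionally admits a competing
background channel (argmax → 0); the refinement pipeline uses the
foreground-only form, since with nearly every training patch containing
background the background bit is almost never discriminative and its
channel is unconstrained.

**Affinity learning.** Unordered pixel pairs within Euclidean radius
r = 8 (on the CAM grid) whose confidence labels are both certain form a
positive set R+ (equal labels) and negative set R− (unequal); pairs
touching an uncertain pixel are discarded.  A three-layer perceptron
(hidden width 32) maps the concatenated descriptors of the two pixels —
per-pixel z-scored fused features plus a learned 8-dimensional embedding
of the confidence label {0, foreground, 255} — to one scalar,
symmetrised over the pair order.  The loss is the mean of sigmoid(A)
over R− plus the mean of 1 − sigmoid(A) over R+, so minimisation pushes
positive-pair affinities up and negative ones down.  (A sign-flipped
variant of this loss — penalising high affinity on positive pairs —
is sometimes written down by mistake; the implementation uses the
orientation consistent with the loss's purpose.)  Training: SGD, lr 0.01,
momentum 0.9, 300 steps of up to 2048 pairs subsampled per tile,
cycling through tiles.

**Pixel-adaptive refinement (PAR).** Iterative local smoothing: each
pixel's score becomes a convex combination of its 8-neighbours at
dilations {1, 2, 4, 8} (halved at CAM resolution), weighted by a
normalised `exp(−‖ΔRGB‖²/2σ_rgb² − d²/2σ_pos²)` kernel with
σ_rgb = 0.1 on [0, 1] intensities and σ_pos = 6 px, 10 iterations.
Convexity keeps each channel inside its input range.

**Random walk.** Affinities on the walk support are mapped through a
sigmoid, raised to the Hadamard power β = 2 and assembled into
T = row-normalise(A∘β + I); the identity term is a self-loop whose
weight is one minus the normalised neighbour mass, so zero-affinity
pixels keep their scores and T is always row-stochastic.  Scores are
propagated t times per class and clipped to [0, 1].  Locality matters:
the supervision radius r = 8 is sized for CAM rasters tens of pixels
across, so the walk support is truncated to min(r, raster/4) — a no-op
at whole-slide scale, where a 775-px image gives a 49-px raster — and
t must keep t·radius below the raster diameter or the walk converges
toward its global stationary distribution and erases the map.  The
library default is t = 16 (whole-slide scale); the desk preset uses
t = 2 for its ~11×11 rasters.

**Renormalisation.** PAR and the walk are averaging operators: they
contract the score range, which would push true background above β_l.
Since a refined score map is still a CAM, its min-max normalisation is
re-established after each smoothing stage before any thresholding.

**Final pseudo-labels.** Per tile: PAR at CAM resolution → confidence
labels (these also supervise the affinity perceptron) → random walk →
bilinear upsampling to tile resolution → PAR against the full-resolution
RGB image → renormalise → re-threshold to {0, 1, 255}.  Pseudo-labels
are stored as PNG with palette {0 → 0, 1 → 128, 255 → 255} and cropped
back into patches for stage 2.

## Stage 2 — segmentation with online easy example mining

The segmentation network is a small pyramid-pooling CNN: a strided
residual stem to 1/4 scale, average pooling to {1, 2, 3, 6} grids
projected by 1×1 convolutions and upsampled back, concatenated, fused by
a 3×3 convolution and classified per pixel, then bilinearly upsampled to
input resolution.  Channel LayerNorms after each convolution keep
from-scratch SGD stable at practical learning rates.  A deeper backbone
is a configuration choice; the desk preset has width 32.

Per-pixel cross-entropy is computed over valid (non-255) pixels only;
255 pixels contribute neither loss nor gradient.  When a pseudo-label
map contains more than one class, each pixel's loss is re-weighted by
`w = softmax(−L) / mean(softmax(−L))` computed over the valid pixels of
that image (unit mean by construction; losses clamped at 50 before the
softmax so outliers cannot underflow every weight).  The weights are
constants with respect to the gradient: they re-scale supervision, they
are not an adversarial objective.  With a single class the plain mean
cross-entropy is used.  The softmax scope is per image by default
(batch-size invariant); a per-batch scope is a config switch.

Mining that starts from random predictions is self-defeating: whichever
class wins the first few steps makes the other class's pixels high-loss,
and the exponential weighting then suppresses them permanently.  The
trainer therefore runs a plain cross-entropy warmup (default 100
iterations) before enabling the re-weighting.  Training: SGD at a fixed
learning rate, random flips, per-channel normalisation.

Inference tiles an image with the same 112/56 grid, averages the
per-patch foreground probabilities over overlaps, and thresholds at
0.5.  Evaluation computes per-image foreground IoU and Dice on the
stitched predictions and reports mean ± sample (n−1) standard deviation
in percent; Dice = 2·IoU/(1+IoU) identically, and the empty-vs-empty
convention is 1.0 (it never occurs on gland-bearing tiles).

## Synthetic data

The generator renders H&E-like tiles: eosin-pink stroma, glands as
randomly rotated ellipses with a hematoxylin-purple epithelial ring
around a pale lumen (lumen semi-axes are `lumen_ratio = 0.45` of the
gland's), Gaussian per-channel noise clipped to [0, 255].  Placement is
rejection sampling with a bounding-circle disjointness test (≤ 100
attempts per gland, then the gland is skipped); the placed ellipse
parameters are recorded so tests can check mask areas analytically.
Everything is a pure function of the `SyntheticSpec` (seeded
`default_rng`), so
datasets are bit-reproducible.  Defaults follow the whole-slide-like
setting: 775×522 px, 6 glands, radii 30–60 px, `noise_sigma = 0`.

With `noise_sigma = 0` the three tissue classes are exactly linearly
separable in RGB.  That is deliberate: it makes mask recovery from
image-level labels well-posed at desk scale, so end-to-end tests probe
the pipeline's machinery rather than the encoder's capacity.  What the
synthetic tiles do *not* emulate: nuclear and luminal texture, stain
variation and overlap, blurred or broken gland boundaries, touching
glands, instance identity.  Passing the recovery tests therefore shows
the two stages are wired and trained correctly, not that the tiny
presets would reach published accuracy on real slides — the published
operating point additionally needs the real dataset, a pretrained deep
backbone and the full training schedules.

## The desk-scale study

`maaseg.pipeline.desk_study` runs the whole pipeline in minutes on one
CPU: 48 training tiles of 112×112 px (gland counts cycling 0–2, radii
20–45 px, noiseless) and 20 evaluation tiles of the same size (1–2
glands).  Training tiles are deliberately single patches that contain
both tissue classes: per-patch CAM min-max normalisation is reliable
exactly when a patch is class-balanced, and larger synthetic tiles at
this scale often place a gland into every one of their few patches,
removing the background anchor and leaving the (seed-dependent)
within-patch raster structure to decide the labels.  Stage 1 trains
three tiny-encoder restarts for 30 epochs each (batch 16, lr 0.002) and
ensembles their rasters; the affinity perceptron trains for 300 steps
(walk t = 2, see above);
stage 2 trains the width-32 pyramid network for 300 iterations (batch 8,
lr 0.05 — a from-scratch rate; the published fixed rate of 5e-4
presumes a pretrained backbone).  It reports stage-1 gland-bit training
accuracy, the paired per-tile comparison of refined vs raw thresholded
CAM labels (foreground IoU over certain pixels), and the final stitched
segmentation IoU/Dice.  `scripts/acceptance.py` re-runs exactly this
study from scratch at a given seed.

## Numerical and design notes

- Bilinear resampling uses half-pixel centres everywhere (checked
  against `skimage.transform.resize(order=1)`); constants are preserved
  exactly, and label maps are only ever produced by thresholding
  resampled *scores*, never by resampling labels.
- Softmax and log-softmax subtract the per-row maximum;
  binary cross-entropy uses the softplus form with gradient σ(z) − y.
- Min-max normalisation of a constant channel yields all zeros (the
  "no evidence" reading).
- Stitching averages raw scores, not hard labels: deterministic and
  smooth at seams.
- One global seed fans out as `seed + stage_index`; every stochastic
  component (generator, parameter init, batching, augmentation, pair
  subsampling) derives from it, so a run is reproducible end to end and
  single stages can be deleted and recomputed.
- Checkpoints are versioned `.npz` bundles of parameter arrays plus the
  dataset normalisation statistics.

## Known limitations

Binary segmentation only (no instance separation, no multi-class
variant); the affinity stage assumes the initial CAMs are at least
coarsely correct — it sharpens and propagates, it cannot invert a CAM
that localises the wrong tissue; per-patch CAM min-max normalisation is
unreliable for patches with extreme class imbalance (mitigated, not
eliminated, by tile-level reassembly); the NumPy training core is
single-threaded BLAS-bound and meant for desk-scale models, not for
reproducing full-scale training runs.
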