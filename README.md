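# maaseg — weakly supervised gland segmentation from image-level labels

Pixel-accurate gland segmentation in H&E-stained colorectal histology
normally requires dense expert annotation.  `maaseg` implements a
two-stage weakly supervised alternative that needs only a two-bit label
per 112×112 image patch — *is there gland tissue?* *is there
background?* — and produces full segmentation masks:

1. **CAM generation and refinement.**  A six-layer hierarchical
   transformer encoder is trained as a multi-label classifier on the
   patch bits.  Feature maps from layers 3, 5 and 6 are aligned
   (bilinear upsampling + 1×1 projection) and summed into a fused
   representation F_multi = Σ_{i∈{3,5,6}} F̃_i, from which a 1×1 head
   emits class activation maps (CAMs).  Initial pseudo-labels come from
   confidence thresholding — per pixel, argmax class if max score ≥ β_h,
   background if ≤ β_l, ignore (255) otherwise, with β_l = 0.3 and
   β_h = 0.6 — and are refined by a learned pixel-pair affinity model
   (3-layer MLP over pairs within radius r = 8), pixel-adaptive
   refinement (RGB/position kernel smoothing) and random-walk
   propagation through the row-stochastic transition built from the
   affinities.
2. **Segmentation with OEEM.**  A pyramid-pooling segmentation network
   trains on the refined pseudo-labels under online easy example
   mining: per-pixel cross-entropy re-weighted by
   w = softmax(−L)/mean(softmax(−L)) over each image's valid pixels, so
   reliable (low-loss) supervision dominates and pseudo-label noise is
   suppressed.  Pixels labelled 255 are excluded everywhere.

Evaluation stitches per-patch predictions back to whole images
(overlap-averaged) and reports foreground IoU = |X∩Y|/|X∪Y| and
Dice = 2|X∩Y|/(|X|+|Y|) = 2·IoU/(1+IoU) as mean ± sd in percent.

The package is aimed at method developers: every stage is a library
function with a thin `maa` CLI on top, all networks run on plain NumPy
(a built-in reverse-mode autodiff core), and a synthetic H&E-like gland
generator makes the entire pipeline trainable and testable on one CPU
in minutes, with no dataset download.  Real whole-slide patch data can
be substituted for the synthetic tiles via the config
(`train_images_dir` / `eval_images_dir`).

## Worked example

Run the desk-scale study — synthetic tiles, tiny presets, full
two-stage training — end to end:

```python
from maaseg.pipeline import desk_study

metrics = desk_study(seed=0, out_dir="runs/desk")
print({k: round(v, 2) if isinstance(v, float) else v
       for k, v in metrics.items()})
```

which trains everything from scratch (≈ 4–5 minutes on one CPU) and
prints:

```
{'gland_accuracy': 1.0, 'n_train_patches': 48, 'raw_pseudo_iou': 0.41,
 'refined_pseudo_iou': 0.92, 'refinement_wins': 20, 'n_eval_tiles': 20,
 'mean_iou': 95.9, 'std_iou': 2.77, 'mean_dice': 97.89, 'std_dice': 1.48}
```

Reading the numbers: the stage-1 classifier recovers the gland bit on
every training patch (`gland_accuracy` 1.0); thresholding the raw CAMs
gives pseudo-labels with foreground IoU 0.41 against the true masks,
which affinity refinement lifts to 0.92, improving all 20 evaluation
tiles; the segmentation network trained on those pseudo-labels reaches
95.9 % mean foreground IoU (97.9 % Dice) on the stitched evaluation
tiles — consistent with the Dice↔IoU identity
2·0.959/(1+0.959) ≈ 0.979.

The same pipeline is scriptable stage by stage:

```bash
maa run-all --out-dir runs/demo --seed 0        # or individual stages:
maa synth --out-dir runs/demo
maa tile --out-dir runs/demo
maa train-cam --out-dir runs/demo
maa make-cam --out-dir runs/demo
maa refine --out-dir runs/demo
maa train-seg --out-dir runs/demo
maa infer --out-dir runs/demo
maa eval --out-dir runs/demo
```

Each stage writes its artifacts and a manifest under `--out-dir`;
re-running skips completed stages, and deleting a stage directory
recomputes exactly that stage.  A YAML config (`--config`) controls
every knob (tiling geometry, encoder preset, thresholds β_l/β_h, radius
r, walk parameters, training schedules); defaults are the published
operating values (patch 112/stride 56, β_l 0.3, β_h 0.6, r 8, stage
learning rates 0.002 and 0.0005, batches 16 and 32).

See `docs/methods.md` for the model details, the synthetic-data design
and its limits, and the numerical choices.

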