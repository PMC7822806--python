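# liverseg

2.5D convolutional liver and tumor segmentation for abdominal CT — a tested,
reusable implementation of the full slice-wise pipeline: Hounsfield
calibration and windowing, contrast enhancement, stacked-slice (2.5D)
sampling with class balancing, SegNet-style encoder–decoder networks with
long- and short-range skip connections, largest-component post-processing,
and challenge-style evaluation metrics.

**Who it is for.**  Researchers in medical image analysis who want a
transparent, dependency-light reference for the 2.5D segmentation recipe —
to study its parameter choices (stack size, contrast enhancement, network
depth), to test pre/post-processing behaviour with exact oracles, or to
prototype on synthetic data before touching clinical volumes.  Everything
runs on a single CPU; a built-in phantom generator makes the whole pipeline
exercisable with no external dataset.

## The method

A CT volume `V` with header calibration `(a, b)` is normalized per voxel:

    HU = a · raw + b                            (scanner calibration)
    g  = 255 · (clamp(HU, −250, 250) + 250)/500  window [−250, 250] → [0, 255]

The network input is a stack of `k ∈ {1,3,5,7,9}` adjacent axial slices; the
output is the center slice's 3-class score map (background / liver / tumor).
Training uses SGD (momentum 0.9, lr 0.001 ×0.1 every 5 epochs, 20 epochs)
on the slices that contain all three classes, with inverse-frequency class
weights

    w_c = N / n_c

in a weighted pixelwise cross-entropy.  At inference every slice is
segmented, and the 3D result is cleaned by keeping the largest 26-connected
liver∪tumor component, smoothing it morphologically, and masking everything
outside it.  Evaluation reports Dice per case (mean ± sd), pooled "global"
Dice, surface Hausdorff distance in mm, pixel recall, and lesion recall at
50 % component IoU.

Two architectures are provided: `net01` (one encoder–decoder with residual
blocks, max-unpooling, and concat+1×1 long skips) and `net02` (two such
components in sequence with dense cross-component skips).  The networks and
their training loop are implemented directly on NumPy with hand-written
reverse-mode gradients — no deep-learning framework required; all layer
gradients are verified against finite differences in the test suite.

## Worked example

Train and evaluate the desk-scale study entirely from Python:

```python
from liverseg.pipeline import phantom_learning_study

summary = phantom_learning_study(seed=1)   # ~3 minutes on one CPU
for key in ("dice_per_case_liver", "dice_per_case_tumor",
            "dice_global_liver", "recall_at_50_overlap"):
    print(f"{key}: {summary[key]:.4f}")
```

which prints (seed 1):

```
dice_per_case_liver: 0.9776
dice_per_case_tumor: 0.7396
dice_global_liver: 0.9776
recall_at_50_overlap: 0.9333
```

i.e. on 5 held-out phantoms the trained tiny Net01 overlaps 97.8 % of the
liver (Dice), 74 % of tumor tissue, and detects 93 % of the individual
lesions at the 50 % IoU criterion.  The same study is scriptable from the
shell:

```bash
liverseg simulate --n 25 --seed 1 --out cohort/
liverseg train --data cohort/ --out net.ckpt --seed 1
liverseg segment cohort/case_020.nii pred.nii --checkpoint net.ckpt
liverseg evaluate preds/ truths/ --out metrics.csv
liverseg experiment --experiment stack_size --levels 1,3 --seed 0 --out exp.csv
```

The `experiment` command reproduces the three parameter studies (stack size,
contrast enhancement, network depth) at configurable toy scale, emitting a
per-level mean ± sd Dice / Hausdorff comparison table.

## Layout

```
src/liverseg/
  volume_io.py     NIfTI I/O, HU calibration, window normalization
  enhancement.py   basic / histogram-equalization / gamma / bilateral
  sampling.py      2.5D stacks, slice filter, class weights, augmentation
  nn.py            NumPy layers with reverse-mode gradients
  network.py       Net01 / Net02 encoder–decoders
  training.py      SGD + momentum, lr schedule, weighted cross-entropy
  postprocess.py   slice-wise inference, largest-component mask, smoothing
  metrics.py       Dice, Hausdorff, recall, lesion recall, report tables
  phantom.py       synthetic CT-like phantom cohorts
  pipeline.py      experiment harness and end-to-end studies
  cli.py           liverseg {simulate,preprocess,train,segment,evaluate,experiment}
```

See `docs/methods.md` for the full model description, parameter rationale,
and known limitations.
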