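# Methods

## Problem and pipeline

`liverseg` segments liver and liver tumors in contrast-enhanced abdominal CT
using a slice-wise ("2.5D") convolutional approach.  A CT volume is a 3D
field of Hounsfield-unit (HU) intensities; the segmentation target is a
voxel-aligned label volume over {0 background, 1 liver, 2 tumor}.  The
pipeline has four stages:

1. **Image normalization.**  Stored scanner values are calibrated to HU with
   the linear header rescale `HU = a * raw + b`.  Intensities are then
   windowed to `[-250, 250]` HU — the fat/soft-tissue range relevant to the
   liver — and mapped linearly onto the grayscale range `[0, 255]`.  The
   normalized values stay real-valued; quantizing to 8-bit here would round
   twice once enhancement follows.
2. **2.5D sampling.**  The unit of network input is a stack of `k` adjacent
   axial slices (k odd, supported values 1/3/5/7/9); the prediction target is
   the center slice's label map.  This gives the 2D network through-plane
   context at far lower cost than 3D convolution.
3. **Training.**  SGD with momentum 0.9, initial learning rate 0.001 dropped
   by 0.1 every 5 epochs, 20 epochs total.  Class imbalance is addressed
   twice: training slices lacking any of the three classes are discarded
   (undersampling), and the loss weights each class by inverse frequency,
   `w_c = N / n_c`, counted over the filtered training slices (that is the
   population the loss actually sees).
4. **Inference and post-processing.**  Every slice of a test volume is
   segmented (no filter at inference), per-pixel argmax with ties broken
   toward the lower class id, slices restacked to 3D.  Post-processing then
   (a) takes the largest 26-connected component of liver∪tumor as the liver
   mask, (b) smooths it by morphological closing-then-opening with a
   radius-1 spherical element, (c) zeroes all labels outside the mask.
   Using liver∪tumor as foreground means interior tumors cannot split the
   liver component; the filter exists to delete detached false positives.

## Network architectures

Both networks are SegNet-style encoder–decoders over `(k, H, W)` stacks,
emitting 3 class scores per pixel at full resolution.

* **Net01** — one encoder + one decoder, default depth 3 with channel widths
  (32, 64, 128) scaled from `base_channels` (tests and the desk-scale study
  use the reduced profile 8/16/32).  Each stage is a residual block: two 3×3
  conv + batch-norm layers with an additive short skip (1×1 conv + BN
  projection when widths change — the normalized projection keeps skip
  magnitudes comparable and avoids channels dying at initialization), ReLU
  activations.  Down-sampling is 2×2 max-pooling with argmax indices;
  up-sampling is index-guided max-unpooling (config-switchable to a 2×2
  transposed convolution, or to nearest-neighbor replication, which is the
  checkerboard-free choice).  Each decoder stage receives the matching
  encoder stage's output through a long-range skip: channel concatenation
  followed by a 1×1 "adaptive" convolution that reconciles widths.
* **Net02** — two encoder–decoder components in sequence; the second encoder
  consumes the first decoder's features, and dense long-range bridges carry
  the first component's encoder features into the second component's decoder
  (added to its own skips before the concat-fuse).  At equal base width
  Net02 strictly contains Net01's layer inventory, so its parameter count is
  strictly larger.

Exact layer widths/counts for these architectures are not canonical; the
defaults above are this package's own profile and everything is exposed in
`NetworkConfig`.  Both short- and long-range skips have ablation switches.
The networks are implemented directly on NumPy with hand-written
reverse-mode gradients (`liverseg.nn`); convolutions are evaluated as
tensor contractions over sliding-window views so the arithmetic stays in
BLAS, and all layer gradients are verified against central differences in
the test suite.

## Loss

Class-weighted pixelwise cross-entropy, averaged over pixels: each pixel
contributes `w_y * (-log p_y)`.  Chosen as the standard semantic-segmentation
loss for this network family; the weighting satisfies
`sum_c n_c * w_c = C * N` over present classes, so the effective gradient
scale is about `C` times the unweighted loss regardless of imbalance.

## Synthetic phantoms

The generator emulates exactly the structure the pipeline assumes: an
ellipsoidal liver of soft-tissue intensity (90 HU, texture SD 15) in a darker
noisy background (−100 HU, SD 15), 1–3 spherical hypodense tumors (30 HU)
strictly inside the liver, liver-intensity distractor blobs with background
label placed away from the liver (they exercise the largest-component
filter), anisotropic spacing (1.5 × 1.5 × 5 mm), and a raw encoding
`raw = (HU − b)/a` with `(a, b) = (1, −1024)` so calibration does real work.
The default grid is 64 × 64 × 24 voxels.  The intensity regime was chosen so
that the `[-250, 250]` window keeps all three classes separated by several
noise SDs; it is a fixture, not a claim about real livers.  Cohorts randomize
liver size/position per case from per-case seeds recorded in a manifest.

What the phantoms deliberately lack: neighboring organs of similar intensity,
contrast-agent phases, partial-volume boundary blur, scanner artifacts, and
the large anatomical variability of real patients.  Tests passing on
phantoms therefore demonstrate that the machinery (preprocessing, sampling,
optimization, post-processing, metrics) is correct and that the networks can
learn the task at desk scale — they do not predict clinical accuracy on real
CT, which requires the real challenge data and GPU-scale training.

## Desk-scale study sizes

The bundled end-to-end study trains the reduced Net01 profile (channels
8/16/32, k = 3) on 20 phantom cases and evaluates on 5 held-out cases, with
the full 20-epoch schedule, batch size 4; about 180 slice stacks survive the
undersampling filter per epoch.  These sizes give stable learning on a single
CPU while keeping the whole study in the low minutes.  The experiment harness
defaults are smaller still (toy cohorts, shallow profile) because it trains
one model per level.

## Numerical choices and edge cases

* Axial slices are indexed along the last array axis, 0-based; one fixed
  convention throughout.
* Stack construction at volume boundaries uses replicate (nearest-slice)
  padding, keeping intensity statistics realistic versus zero padding.
* Argmax ties at inference resolve to the lower class id (determinism).
* Dice of two empty masks is defined as 1 (affects tumor-free cases).
* Hausdorff distance is computed between surface voxels (6-neighborhood
  surface definition) in physical mm via KD-trees, and is an error on empty
  masks.  It is reported in mm (voxel units without spacing); no percentage
  normalization of Hausdorff values is defined or used.
* Lesion detection for recall-at-overlap uses component-wise IoU ≥ 0.5 over
  26-connected tumor components; intersection-over-truth is available as a
  config switch.
* Files without scale/intercept headers calibrate with (1, 0) and a logged
  warning.
* Class weights are fixed over the training set, not recomputed per batch.
* Augmentation draws one transform per sample — optional left-right
  reflection, rotation ±10°, isotropic scale 0.9–1.1, translation ±10 px —
  applied identically to all stack planes (bilinear) and the label map
  (nearest-neighbor).  Randomness comes from per-epoch substreams of the
  training seed, so runs are bit-reproducible.
* Batch normalization uses batch statistics in training and running averages
  at inference; batch size defaults to 4 (2 in the tiniest test profiles).

## Known limitations

* No resampling to a common voxel grid; volumes are processed at native
  spacing.
* Single multiclass network (background/liver/tumor); no liver-then-tumor
  cascade.
* 2D convolutions only; no 3D or hybrid variants.
* The NumPy backend is single-threaded BLAS-bound; it is sized for desk-scale
  studies, not for training on the full challenge dataset.
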