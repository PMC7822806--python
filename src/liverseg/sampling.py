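"""2.5D stacked-slice sampling, class balancing and augmentation.

A 2.5D sample is a stack of ``k`` adjacent axial slices (k odd); the network
predicts the segmentation of the **center** slice only, so the stack provides
3D context at 2D convolution cost.  Stacks at the first/last slices of a
volume are completed by replicate padding (nearest existing slice).

Class balancing combines two mechanisms:

* an undersampling slice filter — only slices whose label map contains all
  three classes (background, liver, tumor) are used for training, the rest
  are discarded;
* per-class loss weights ``w_c = N / n_c`` with ``N`` the total pixel count
  over the selected training slices and ``n_c`` the pixel count of class c,
  so rarer classes cost more per mis-classified pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, NormalizedVolume, VALID_LABELS


@dataclass
class SliceStack:
    """Ordered k-slice stack (bottom -> top); prediction target is the center."""

    planes: np.ndarray  # shape (k, H, W)
    center_index_in_volume: int
    k: int

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 3:
            raise ValueError("planes must be a (k, H, W) array")
        if self.k % 2 == 0:
            raise ValueError(f"stack size k must be odd, got {self.k}")
        if self.planes.shape[0] != self.k:
            raise ValueError(f"expected {self.k} planes, got {self.planes.shape[0]}")

    @property
    def center_plane(self) -> np.ndarray:
        return self.planes[self.k // 2]


@dataclass
class ClassWeights:
    """Per-class loss weights w_c = N / n_c (inverse class frequency)."""

    weights: dict[int, float]

    def __post_init__(self) -> None:
        for c, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"class weight for class {c} must be > 0, got {w}")

    def as_array(self, num_classes: int = 3) -> np.ndarray:
        """Dense weight vector; classes absent from the mapping get weight 0
        (they never occur in the training labels, so the value is inert)."""
        arr = np.zeros(num_classes, dtype=np.float64)
        for c, w in self.weights.items():
            arr[c] = w
        return arr


@dataclass
class AugmentParams:
    """Random geometric augmentation ranges, symmetric around the identity.

    One transform — a composition of an optional left-right reflection, a
    rotation, an isotropic scale and a translation, each drawn uniformly from
    its range — is applied identically to every plane of a stack and to its
    label map.
    """

    allow_reflection: bool = True
    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_px: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_deg < 0 or self.translation_px < 0:
            raise ValueError("rotation and translation ranges must be >= 0")
        lo, hi = self.scale_range
        if lo <= 0 or hi <= 0:
            raise ValueError(f"scale range must be positive, got {self.scale_range}")
        if lo > hi:
            raise ValueError(f"scale range must satisfy lo <= hi, got {self.scale_range}")

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(allow_reflection=False, rotation_deg=0.0, scale_range=(1.0, 1.0), translation_px=0.0)


def select_training_slices(labels: LabelVolume) -> list[int]:
    """Undersampling filter: keep exactly the slice indices whose 2D label map
    contains background, liver *and* tumor; all other slices are discarded."""
    kept = []
    for z in range(labels.n_slices):
        sl = labels.labels[:, :, z]
        present = set(np.unique(sl).tolist())
        if present >= {0, 1, 2}:
            kept.append(z)
    return kept


def build_stack(vol: NormalizedVolume, center: int, k: int) -> SliceStack:
    """Extract the k-slice stack centered at ``center`` (replicate padding at
    the volume boundary).  The middle plane is the slice at ``center``, exactly."""
    if k % 2 == 0 or k < 1:
        raise ValueError(f"stack size k must be a positive odd integer, got {k}")
    n = vol.n_slices
    if not 0 <= center < n:
        raise IndexError(f"center slice {center} out of range [0, {n})")
    half = (k - 1) // 2
    idx = np.clip(np.arange(center - half, center + half + 1), 0, n - 1)
    planes = np.stack([vol.voxels[:, :, int(i)] for i in idx], axis=0)
    return SliceStack(planes=planes, center_index_in_volume=center, k=k)


def compute_class_weights(
    label_slices: list[np.ndarray] | np.ndarray,
    classes: tuple[int, ...] = (0, 1, 2),
) -> ClassWeights:
    """Inverse-frequency class weights over the given training label maps.

    ``w_c = N / n_c`` with N the total pixel count; a requested class with no
    pixels raises (its weight would be infinite).
    """
    if isinstance(label_slices, np.ndarray):
        label_slices = [label_slices]
    if not label_slices:
        raise ValueError("no label slices given")
    counts = np.zeros(max(classes) + 1, dtype=np.int64)
    total = 0
    for sl in label_slices:
        sl = np.asarray(sl)
        counts_sl = np.bincount(sl.ravel().astype(np.int64), minlength=len(counts))
        counts += counts_sl[: len(counts)]
        total += sl.size
    weights = {}
    for c in classes:
        if counts[c] == 0:
            raise ValueError(f"class {c} has zero pixels in the training labels")
        weights[c] = total / counts[c]
    return ClassWeights(weights=weights)


def _draw_transform(params: AugmentParams, rng: np.random.Generator):
    reflect = bool(params.allow_reflection and rng.random() < 0.5)
    angle = rng.uniform(-params.rotation_deg, params.rotation_deg)
    scale = rng.uniform(*params.scale_range)
    t = rng.uniform(-params.translation_px, params.translation_px, size=2)
    return reflect, angle, scale, t


def _affine_matrix(shape, reflect, angle_deg, scale, translation):
    """Output->input affine (matrix, offset) about the image center, as used
    by scipy.ndimage.affine_transform."""
    h, w = shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    refl = np.diag([1.0, -1.0 if reflect else 1.0])  # left-right flip
    fwd = (rot @ refl) * scale
    inv = np.linalg.inv(fwd)
    offset = c - inv @ (c + np.asarray(translation))
    return inv, offset


def augment(
    stack: SliceStack,
    label: np.ndarray,
    params: AugmentParams,
    rng: np.random.Generator,
) -> tuple[SliceStack, np.ndarray]:
    """Apply one random geometric transform to a stack and its label map.

    Images are interpolated bilinearly, labels nearest-neighbor, so no new
    label classes can appear.  Out-of-frame pixels are filled by edge
    replication for images and background for labels.
    """
    label = np.asarray(label)
    if label.shape != stack.planes.shape[1:]:
        raise ValueError(
            f"label shape {label.shape} does not match stack planes {stack.planes.shape[1:]}"
        )
    reflect, angle, scale, t = _draw_transform(params, rng)
    if scale <= 0:
        raise ValueError(f"degenerate scale {scale}")
    if not reflect and angle == 0.0 and scale == 1.0 and not np.any(t):
        return stack, label  # identity draw: skip interpolation entirely
    matrix, offset = _affine_matrix(label.shape, reflect, angle, scale, t)
    planes = np.stack(
        [
            ndimage.affine_transform(p, matrix, offset=offset, order=1, mode="nearest")
            for p in stack.planes
        ],
        axis=0,
    )
    new_label = ndimage.affine_transform(
        label.astype(np.int16), matrix, offset=offset, order=0, mode="constant", cval=0
    )
    out_stack = SliceStack(
        planes=np.clip(planes, 0.0, 255.0),
        center_index_in_volume=stack.center_index_in_volume,
        k=stack.k,
    )
    return out_stack, new_label
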