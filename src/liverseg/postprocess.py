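"""Slice-wise volume segmentation and 3D post-processing.

A full CT volume is segmented one axial slice at a time: each slice becomes
the center of a k-plane stack, the network scores it, and per-pixel argmax
(ties toward the lower class id) yields the slice labels; the slices are then
restacked into a 3D label volume.

Post-processing cleans that volume in three steps:

1. a liver mask is taken as the largest 3D connected component of the
   foreground (liver ∪ tumor, so interior tumors cannot split the component);
2. the mask surface is smoothed by morphological closing then opening with a
   spherical structuring element;
3. the mask filters the segmentation — every voxel outside it reverts to
   background, removing false-positive liver/tumor islands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .network import SegmentationNetwork
from .sampling import build_stack
from .volume_io import NormalizedVolume

_STRUCTURES = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


@dataclass
class SegmentationVolume:
    """3D predicted label volume over {0, 1, 2} with provenance."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("SegmentationVolume requires a 3D label array")


def segment_volume(
    network: SegmentationNetwork,
    vol: NormalizedVolume,
    k: int | None = None,
    batch_size: int = 8,
) -> SegmentationVolume:
    """Segment every axial slice of ``vol`` with k-plane stacks."""
    if k is None:
        k = network.cfg.in_planes
    if k != network.cfg.in_planes:
        raise ValueError(
            f"network expects stacks of {network.cfg.in_planes} planes, requested k={k}"
        )
    n = vol.n_slices
    out = np.empty(vol.voxels.shape, dtype=np.int16)
    for start in range(0, n, batch_size):
        centers = range(start, min(start + batch_size, n))
        planes = np.stack([build_stack(vol, c, k).planes for c in centers])
        pred = network.predict_batch(planes)  # argmax, ties toward lower class
        for j, c in enumerate(centers):
            out[:, :, c] = pred[j]
    return SegmentationVolume(
        labels=out,
        spacing=vol.spacing,
        provenance={"k": k, "variant": network.cfg.variant},
    )


def largest_component_mask(seg: SegmentationVolume, connectivity: int = 26) -> np.ndarray:
    """Largest 3D connected component of the foreground (classes 1 and 2).

    Returns an all-false mask for an empty foreground.  Ties between equally
    large components resolve to the component labeled first (lowest label id).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    fg = seg.labels > 0
    if not fg.any():
        return np.zeros(seg.labels.shape, dtype=bool)
    cc, n = ndimage.label(fg, structure=_STRUCTURES[connectivity])
    sizes = np.bincount(cc.ravel())
    sizes[0] = 0
    return cc == int(np.argmax(sizes))


def apply_mask(seg: SegmentationVolume, mask: np.ndarray) -> SegmentationVolume:
    """Set every voxel outside ``mask`` to background; inside voxels unchanged."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != seg.labels.shape:
        raise ValueError(f"mask shape {mask.shape} does not match segmentation {seg.labels.shape}")
    out = np.where(mask, seg.labels, 0).astype(seg.labels.dtype)
    return SegmentationVolume(labels=out, spacing=seg.spacing, provenance=dict(seg.provenance))


def _ball(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz**2 + yy**2 + xx**2 <= r**2


def smooth_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological closing then opening with a spherical element; radius 0 is identity."""
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    ball = _ball(radius)
    closed = ndimage.binary_closing(mask, structure=ball)
    return ndimage.binary_opening(closed, structure=ball)


def postprocess(
    seg: SegmentationVolume,
    connectivity: int = 26,
    smooth_radius: int = 1,
) -> SegmentationVolume:
    """Full chain: largest component -> surface smoothing -> mask filter."""
    mask = largest_component_mask(seg, connectivity=connectivity)
    mask = smooth_mask(mask, radius=smooth_radius)
    out = apply_mask(seg, mask)
    out.provenance.update({"postprocessed": True, "connectivity": connectivity, "smooth_radius": smooth_radius})
    return out
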