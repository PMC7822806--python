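"""Per-slice contrast enhancement variants.

Four methods are supported, applied to window-normalized slices in [0, 255]:

``basic``
    Windowing alone (identity here — the window/normalize step already ran).
``histeq``
    Histogram equalization over 256 bins on [0, 255], computed per slice:
    the method depends on the slice's own histogram, so each image gets its
    own intensity remapping.
``gamma``
    Power-law correction ``255 * (img / 255) ** gamma``.
``bilateral``
    Edge-preserving bilateral smoothing (Gaussian in both the spatial and the
    intensity domain), range preserved.

Enhancement is applied before slice stacking so that every plane of a 2.5D
stack receives the same treatment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.restoration import denoise_bilateral

logger = logging.getLogger(__name__)

ENHANCEMENT_METHODS = ("basic", "histeq", "gamma", "bilateral")


@dataclass
class EnhancementConfig:
    method: str = "basic"
    gamma_value: float = 0.8
    bilateral_sigma_spatial: float = 2.0  # pixels
    bilateral_sigma_range: float = 20.0  # intensity units on [0, 255]

    def __post_init__(self) -> None:
        if self.method not in ENHANCEMENT_METHODS:
            raise ValueError(
                f"unknown enhancement method {self.method!r}; expected one of {ENHANCEMENT_METHODS}"
            )
        if self.gamma_value <= 0:
            raise ValueError(f"gamma_value must be > 0, got {self.gamma_value}")
        if self.bilateral_sigma_spatial <= 0 or self.bilateral_sigma_range <= 0:
            raise ValueError("bilateral sigmas must be > 0")


def _check_range(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"enhance expects a 2D slice, got {img.ndim}D")
    if img.size and (img.min() < -1e-9 or img.max() > 255.0 + 1e-9):
        raise ValueError("enhance expects values in [0, 255]")
    return np.clip(img, 0.0, 255.0)


def _histogram_equalize(img: np.ndarray) -> np.ndarray:
    # 256-bin CDF mapping on [0, 255]; output rescaled back onto [0, 255].
    bins = np.floor(img).astype(np.int64).clip(0, 255)
    hist = np.bincount(bins.ravel(), minlength=256)
    cdf = np.cumsum(hist).astype(np.float64)
    cdf_min = cdf[cdf > 0][0] if np.any(cdf > 0) else 0.0
    denom = cdf[-1] - cdf_min
    if denom <= 0:  # constant image: equalization is a no-op
        return img.copy()
    lut = (cdf - cdf_min) / denom * 255.0
    return lut[bins]


def enhance(img: np.ndarray, cfg: EnhancementConfig) -> np.ndarray:
    """Enhance one 2D slice in [0, 255]; output is again within [0, 255]."""
    img = _check_range(img)
    if cfg.method == "basic":
        return img
    if cfg.method == "gamma":
        return 255.0 * (img / 255.0) ** cfg.gamma_value
    if cfg.method == "histeq":
        return np.clip(_histogram_equalize(img), 0.0, 255.0)
    if cfg.method == "bilateral":
        out = denoise_bilateral(
            img / 255.0,
            sigma_color=cfg.bilateral_sigma_range / 255.0,
            sigma_spatial=cfg.bilateral_sigma_spatial,
        )
        return np.clip(out * 255.0, 0.0, 255.0)
    raise ValueError(f"unknown enhancement method {cfg.method!r}")  # pragma: no cover


def enhance_volume(vol, cfg: EnhancementConfig):
    """Apply :func:`enhance` independently to every axial slice of a volume."""
    from .volume_io import NormalizedVolume

    out = np.empty_like(vol.voxels)
    for z in range(vol.n_slices):
        out[:, :, z] = enhance(vol.voxels[:, :, z], cfg)
    return NormalizedVolume(
        voxels=out, window_lo=vol.window_lo, window_hi=vol.window_hi, spacing=vol.spacing
    )
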