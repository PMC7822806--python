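"""Volumetric CT / label I/O, Hounsfield calibration and window normalization.

Axis convention used throughout the package: a volume is a 3D array indexed
``(row, col, slice)`` — axial slices are taken along the **last** axis, and all
slice indices are 0-based.

CT scanners store intensities as raw integers; the affine rescale
``HU = a * raw + b`` (slope/intercept from the file header) recovers calibrated
Hounsfield units, where water is ~0 HU and air ~-1000 HU.  For liver work the
HU range is then windowed to [-250, 250] (fat / soft tissue) and mapped
linearly onto the grayscale range [0, 255].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

LABEL_BACKGROUND = 0
LABEL_LIVER = 1
LABEL_TUMOR = 2
VALID_LABELS = frozenset((LABEL_BACKGROUND, LABEL_LIVER, LABEL_TUMOR))


@dataclass
class CTVolume:
    """Calibrated CT volume in Hounsfield units.

    Parameters
    ----------
    voxels : 3D float array of HU intensities.
    spacing : per-axis physical voxel size in mm, all entries > 0.
    calib_a, calib_b : the multiplicative / additive calibration factors that
        were applied to the stored values (kept for provenance).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    calib_a: float = 1.0
    calib_b: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"CTVolume requires a 3D array, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CTVolume voxels must be finite after calibration")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]


@dataclass
class LabelVolume:
    """Integer segmentation volume over {0 background, 1 liver, 2 tumor}."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"LabelVolume requires a 3D array, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise ValueError("labels must be integers")
            self.labels = rounded.astype(np.int16)
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(f"labels contain values outside {{0,1,2}}: {sorted(present - VALID_LABELS)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[2]


@dataclass
class NormalizedVolume:
    """Window-normalized volume with grayscale values in [0, 255].

    ``window_lo`` maps to 0 and ``window_hi`` to 255.  Values are kept
    real-valued (not quantized to 8 bit) so downstream enhancement does not
    suffer double rounding.
    """

    voxels: np.ndarray
    window_lo: float = -250.0
    window_hi: float = 250.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"NormalizedVolume requires a 3D array, got {self.voxels.ndim}D")
        if self.voxels.size and (self.voxels.min() < -1e-9 or self.voxels.max() > 255.0 + 1e-9):
            raise ValueError("NormalizedVolume values must lie in [0, 255]")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    def get_slice(self, index: int) -> np.ndarray:
        return self.voxels[:, :, index]


def calibrate_hu(raw: np.ndarray, a: float, b: float) -> np.ndarray:
    """Apply the linear intensity calibration ``HU = a * raw + b``.

    ``a`` and ``b`` are the rescale slope and intercept from the image header.
    """
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError(f"calibration factors must be finite, got a={a}, b={b}")
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw intensities must be finite")
    return a * raw + b


def window_normalize(
    hu: np.ndarray,
    lo: float = -250.0,
    hi: float = 250.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> NormalizedVolume:
    """Clamp HU values to ``[lo, hi]`` and map linearly onto [0, 255].

    The map is monotone non-decreasing: ``lo -> 0``, ``hi -> 255``, values
    outside the window saturate.
    """
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got lo={lo}, hi={hi}")
    hu = np.asarray(hu, dtype=np.float64)
    clipped = np.clip(hu, lo, hi)
    gray = (clipped - lo) * (255.0 / (hi - lo))
    return NormalizedVolume(voxels=gray, window_lo=lo, window_hi=hi, spacing=spacing)


def _spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def read_volume(path: str | Path) -> CTVolume:
    """Read a 3D NIfTI image and return a calibrated :class:`CTVolume`.

    The NIfTI ``scl_slope`` / ``scl_inter`` header fields play the role of the
    (a, b) calibration factors; files lacking them default to (1, 0) with a
    logged warning.  Voxel spacing is taken from the header zooms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"could not read NIfTI header of {path}: {exc}") from exc
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.ndim}D")
    header = img.header
    slope = getattr(img.dataobj, "slope", None)
    inter = getattr(img.dataobj, "inter", None)
    if slope is None or inter is None or not np.isfinite([slope, inter]).all():
        logger.warning("%s: no scale/intercept in header, assuming (a, b) = (1, 0)", path)
        slope, inter = 1.0, 0.0
    # read the unscaled stored values and calibrate explicitly so the (a, b)
    # provenance is recorded on the CTVolume
    if hasattr(img.dataobj, "get_unscaled"):
        raw_unscaled = np.asanyarray(img.dataobj.get_unscaled())
    else:  # pragma: no cover - in-memory images
        raw_unscaled = np.asanyarray(img.dataobj)
    hu = calibrate_hu(raw_unscaled, float(slope), float(inter))
    spacing = tuple(float(z) for z in header.get_zooms()[:3])
    return CTVolume(voxels=hu, spacing=spacing, calib_a=float(slope), calib_b=float(inter))


def read_labels(path: str | Path) -> LabelVolume:
    """Read a 3D NIfTI label image (values in {0, 1, 2})."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label image, got {img.ndim}D")
    labels = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(labels=np.rint(labels).astype(np.int16), spacing=spacing)


def write_raw_volume(
    raw: np.ndarray,
    a: float,
    b: float,
    spacing: tuple[float, float, float],
    path: str | Path,
) -> None:
    """Write stored (uncalibrated) values with (a, b) as the header slope/intercept.

    ``read_volume`` on the result recovers ``a * raw + b`` in HU.
    """
    raw = np.asarray(raw)
    if raw.ndim != 3:
        raise ValueError(f"expected a 3D raw array, got {raw.ndim}D")
    img = nib.Nifti1Image(raw.astype(np.float32), affine=_spacing_affine(spacing))
    img.header.set_zooms(spacing)
    img.header.set_slope_inter(float(a), float(b))
    nib.save(img, str(Path(path)))


def write_volume(vol: CTVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI, spacing in the header; labels stored as int16."""
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int16)
        spacing = vol.spacing
    elif isinstance(vol, CTVolume):
        data = vol.voxels.astype(np.float32)
        spacing = vol.spacing
    else:
        raise TypeError(f"write_volume accepts CTVolume or LabelVolume, got {type(vol).__name__}")
    img = nib.Nifti1Image(data, affine=_spacing_affine(spacing))
    img.header.set_zooms(spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"could not write volume to {path}: {exc}") from exc
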