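"""Synthetic abdominal-CT-like phantoms for exercising the whole pipeline.

A phantom is an ellipsoidal "liver" of soft-tissue intensity inside a darker
noisy background, with zero or more spherical/ellipsoidal hypodense "tumors"
strictly inside the liver, optional non-liver soft-tissue distractor blobs
(liver-like intensity, background label — they exercise the
largest-component post-processing filter), anisotropic voxel spacing, and a
raw intensity encoding ``raw = (HU - b) / a`` so the calibration step has
real work to do.

Default intensities: background -100 HU, liver 90 HU, tumor 30 HU, Gaussian
texture noise with SD 15 HU.  These are fixture parameters chosen so that
the [-250, 250] HU window keeps all three classes distinct — not claims
about real livers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, write_raw_volume, write_volume


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 24)  # (rows, cols, slices)
    spacing: tuple[float, float, float] = (1.5, 1.5, 5.0)  # mm, anisotropic
    liver_center: tuple[float, float, float] | None = None  # None -> grid center
    liver_semiaxes: tuple[float, float, float] = (22.0, 26.0, 9.0)  # voxels
    liver_hu: float = 90.0
    liver_texture_sd: float = 15.0
    tumor_count_range: tuple[int, int] = (1, 3)
    tumor_radius_range: tuple[float, float] = (2.5, 5.0)  # voxels
    tumor_hu: float = 30.0  # hypodense relative to liver
    background_hu: float = -100.0
    noise_sd: float = 15.0
    distractor_count: int = 2
    distractor_radius_range: tuple[float, float] = (2.0, 4.0)
    allow_touching_tumors: bool = False
    calib_a: float = 1.0  # raw-encoding slope
    calib_b: float = -1024.0  # raw-encoding intercept
    rng_seed: int = 0

    def __post_init__(self) -> None:
        shape = np.asarray(self.shape)
        if len(self.shape) != 3 or np.any(shape < 4):
            raise ValueError(f"shape must be 3 axes of at least 4 voxels, got {self.shape}")
        center = np.asarray(self.center)
        semi = np.asarray(self.liver_semiaxes)
        if np.any(center - semi < -0.5) or np.any(center + semi > shape - 0.5):
            raise ValueError("liver ellipsoid does not fit inside the grid")
        if self.tumor_radius_range[0] > self.tumor_radius_range[1]:
            raise ValueError("tumor radius range inverted")
        if self.tumor_radius_range[1] >= min(self.liver_semiaxes):
            raise ValueError("tumors must be smaller than the liver ellipsoid")
        for hu in (self.liver_hu, self.tumor_hu, self.background_hu):
            if not -1024 <= hu <= 3000:
                raise ValueError(f"intensity {hu} outside the plausible HU range [-1024, 3000]")
        if self.calib_a == 0:
            raise ValueError("calibration slope a must be nonzero")

    @property
    def center(self) -> tuple[float, float, float]:
        if self.liver_center is not None:
            return self.liver_center
        return tuple((s - 1) / 2.0 for s in self.shape)


@dataclass
class Phantom:
    """One synthetic case: raw stored values + calibration, labels, and the
    distractor mask (for validating the post-processing filter)."""

    raw: np.ndarray
    calib_a: float
    calib_b: float
    labels: LabelVolume
    distractor_mask: np.ndarray
    tumor_count: int

    @property
    def hu(self) -> np.ndarray:
        return self.calib_a * self.raw + self.calib_b


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.indices(shape, dtype=np.float64)
    acc = np.zeros(shape)
    for g, c, s in zip(grids, center, semiaxes):
        acc += ((g - c) / s) ** 2
    return acc <= 1.0


def generate_phantom(cfg: PhantomConfig) -> Phantom:
    """Generate one phantom, deterministic given ``cfg.rng_seed``.

    Tumors are placed strictly inside the liver (their label 2 overrides the
    liver's label 1); distractor blobs get liver-like intensity but keep
    label 0.  By default tumors are rejected when they would touch an earlier
    tumor, so the number of 3D lesion components is exactly ``tumor_count``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    shape = cfg.shape
    center = np.asarray(cfg.center)
    semi = np.asarray(cfg.liver_semiaxes)
    liver = _ellipsoid_mask(shape, center, semi)

    labels = np.zeros(shape, dtype=np.int16)
    labels[liver] = 1

    n_tumors = int(rng.integers(cfg.tumor_count_range[0], cfg.tumor_count_range[1] + 1))
    if n_tumors > 0 and np.any(1.0 - (cfg.tumor_radius_range[0] + 1.0) / semi <= 0):
        raise ValueError("tumor larger than the liver ellipsoid")
    placed = 0
    tumor_total = np.zeros(shape, dtype=bool)
    attempts = 0
    while placed < n_tumors and attempts < 200:
        attempts += 1
        r = rng.uniform(*cfg.tumor_radius_range)
        # sample a center well inside the liver: ellipsoid coordinates scaled
        # so the tumor ball of radius r fits within the liver surface
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        frac = rng.uniform(0, 0.8) ** (1 / 3)
        margin = 1.0 - (r + 1.0) / semi
        if np.any(margin <= 0):
            continue  # this draw is too large for the (possibly shrunken) liver
        tc = center + u * frac * margin * semi
        tumor = _ellipsoid_mask(shape, tc, (r, r, r))
        if not tumor.any() or not np.all(liver[tumor]):
            continue
        if not cfg.allow_touching_tumors and placed > 0:
            dilated = ndimage.binary_dilation(tumor, structure=np.ones((3, 3, 3)))
            if np.any(tumor_total & dilated):
                continue
        tumor_total |= tumor
        placed += 1
    labels[tumor_total] = 2

    distract = np.zeros(shape, dtype=bool)
    for _ in range(cfg.distractor_count):
        for _try in range(50):
            r = rng.uniform(*cfg.distractor_radius_range)
            if np.any(np.asarray(shape) - r - 1 <= r + 1):
                continue  # blob cannot fit along some axis of a small grid
            dc = rng.uniform(low=r + 1, high=np.asarray(shape) - r - 1)
            blob = _ellipsoid_mask(shape, dc, (r, r, r))
            # distractors must not touch the liver (they emulate other organs)
            if np.any(ndimage.binary_dilation(blob, structure=np.ones((3, 3, 3))) & liver):
                continue
            distract |= blob
            break

    hu = np.full(shape, cfg.background_hu)
    hu[liver] = cfg.liver_hu
    hu[tumor_total] = cfg.tumor_hu
    hu[distract] = cfg.liver_hu  # liver-like intensity, background label
    sd = np.full(shape, cfg.noise_sd)
    sd[liver & ~tumor_total] = cfg.liver_texture_sd
    hu = hu + rng.normal(0.0, 1.0, size=shape) * sd

    raw = (hu - cfg.calib_b) / cfg.calib_a
    return Phantom(
        raw=raw,
        calib_a=cfg.calib_a,
        calib_b=cfg.calib_b,
        labels=LabelVolume(labels=labels, spacing=cfg.spacing),
        distractor_mask=distract,
        tumor_count=placed,
    )


def random_case_config(template: PhantomConfig, rng: np.random.Generator) -> PhantomConfig:
    """Randomize the geometry of one cohort case within the template's ranges."""
    shape = np.asarray(template.shape)
    semi = np.asarray(template.liver_semiaxes) * rng.uniform(0.85, 1.1, size=3)
    semi = np.minimum(semi, (shape - 2) / 2.0)
    max_off = np.maximum(shape / 2.0 - semi - 1.0, 0.0)
    center = (shape - 1) / 2.0 + rng.uniform(-1, 1, size=3) * np.minimum(max_off, 3.0)
    return replace(
        template,
        liver_semiaxes=tuple(semi),
        liver_center=tuple(center),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_cases: int,
    template: PhantomConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[Phantom]:
    """Generate ``n_cases`` phantoms with randomized geometry.

    With ``out_dir`` set, writes NIfTI pairs ``case_XXX.nii`` (raw values with
    the calibration header) / ``case_XXX_label.nii`` plus a plain-text
    manifest of case id, seed and tumor count.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    phantoms = []
    manifest_rows = []
    for i in range(n_cases):
        cfg = random_case_config(template, rng)
        ph = generate_phantom(cfg)
        phantoms.append(ph)
        manifest_rows.append({"case": f"case_{i:03d}", "seed": cfg.rng_seed, "tumors": ph.tumor_count})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for row, ph in zip(manifest_rows, phantoms):
            write_raw_volume(
                ph.raw, ph.calib_a, ph.calib_b, template.spacing, out_dir / f"{row['case']}.nii"
            )
            write_volume(ph.labels, out_dir / f"{row['case']}_label.nii")
        with open(out_dir / "manifest.tsv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["case", "seed", "tumors"], delimiter="\t")
            writer.writeheader()
            writer.writerows(manifest_rows)
    return phantoms
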