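"""Segmentation evaluation metrics: Dice (per case and pooled), Hausdorff
distance, pixel recall, and lesion-level recall at an overlap threshold.

Conventions:

* Dice of two empty masks is 1 (affects tumor-free cases).
* Hausdorff distance is computed between **surface** voxels (foreground voxels
  with at least one 6-neighbor outside the mask) in physical units (mm) using
  the voxel spacing; it is undefined (error) when either mask is empty.
* Lesions are 26-connected 3D components of the tumor class; a ground-truth
  lesion counts as detected when some predicted component overlaps it with
  intersection-over-union at or above the threshold (0.5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def _as_mask(a) -> np.ndarray:
    return np.asarray(a).astype(bool)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); both-empty -> 1 by convention."""
    a, b = _as_mask(a), _as_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def dice_per_case(cases: list[tuple]) -> tuple[float, float]:
    """Unweighted mean and sample SD of per-case Dice; SD is 0 for one case."""
    if not cases:
        raise ValueError("no cases")
    values = [dice(p, t) for p, t in cases]
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def dice_global(cases: list[tuple]) -> float:
    """Dice with voxel counts pooled over all cases before the ratio."""
    if not cases:
        raise ValueError("no cases")
    inter = denom = 0
    for p, t in cases:
        p, t = _as_mask(p), _as_mask(t)
        if p.shape != t.shape:
            raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
        inter += int(np.logical_and(p, t).sum())
        denom += int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (n, 3) of foreground voxels with a 6-neighbor background
    (voxels on the array border count as surface)."""
    mask = _as_mask(mask)
    eroded = ndimage.binary_erosion(mask, structure=STRUCT_6, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between the surfaces of two masks, in mm."""
    a, b = _as_mask(a), _as_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("hausdorff distance is undefined for an empty mask")
    sp = np.asarray(spacing, dtype=np.float64)
    pa = surface_voxels(a) * sp
    pb = surface_voxels(b) * sp
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def pixel_recall(pred, truth) -> float:
    """Sensitivity |pred∩truth| / |truth|; undefined (error) for empty truth."""
    pred, truth = _as_mask(pred), _as_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    n_truth = int(truth.sum())
    if n_truth == 0:
        raise ValueError("pixel recall is undefined for empty truth")
    return int(np.logical_and(pred, truth).sum()) / n_truth


def lesion_recall_at_overlap(pred_tumor, truth_tumor, threshold: float = 0.5) -> float | None:
    """Fraction of ground-truth lesions detected at the given IoU threshold.

    Lesions are 26-connected components.  Returns ``None`` (undefined) when
    the truth contains no lesions.
    """
    pred, truth = _as_mask(pred_tumor), _as_mask(truth_tumor)
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    truth_cc, n_truth = ndimage.label(truth, structure=STRUCT_26)
    if n_truth == 0:
        return None
    pred_cc, n_pred = ndimage.label(pred, structure=STRUCT_26)
    detected = 0
    for lesion_id in range(1, n_truth + 1):
        lesion = truth_cc == lesion_id
        overlapping = np.unique(pred_cc[lesion])
        best = 0.0
        for pid in overlapping:
            if pid == 0:
                continue
            comp = pred_cc == pid
            inter = int(np.logical_and(lesion, comp).sum())
            union = int(np.logical_or(lesion, comp).sum())
            best = max(best, inter / union)
        if best >= threshold:
            detected += 1
    return detected / n_truth


def lesion_recall_intersection_over_truth(pred_tumor, truth_tumor, threshold: float = 0.5) -> float | None:
    """Alternative detection criterion: intersection over the lesion's own volume."""
    pred, truth = _as_mask(pred_tumor), _as_mask(truth_tumor)
    truth_cc, n_truth = ndimage.label(truth, structure=STRUCT_26)
    if n_truth == 0:
        return None
    pred_cc, _ = ndimage.label(pred, structure=STRUCT_26)
    detected = 0
    for lesion_id in range(1, n_truth + 1):
        lesion = truth_cc == lesion_id
        overlapping = [p for p in np.unique(pred_cc[lesion]) if p != 0]
        best = 0.0
        for pid in overlapping:
            inter = int(np.logical_and(lesion, pred_cc == pid).sum())
            best = max(best, inter / int(lesion.sum()))
        if best >= threshold:
            detected += 1
    return detected / n_truth


@dataclass
class MetricsReport:
    """Per-case and pooled evaluation results, exportable as a table."""

    per_case: pd.DataFrame
    summary: dict[str, float]

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = ["MetricsReport"]
        for key, val in self.summary.items():
            lines.append(f"  {key}: {val:.4f}" if val == val else f"  {key}: undefined")
        return "\n".join(lines)


def evaluate_cases(
    preds: dict[str, np.ndarray],
    truths: dict[str, np.ndarray],
    spacing: dict[str, tuple] | tuple = (1.0, 1.0, 1.0),
    overlap_threshold: float = 0.5,
) -> MetricsReport:
    """Assemble the full metric table over matched case ids.

    ``preds`` and ``truths`` map case id -> 3D label array over {0, 1, 2}.
    Hausdorff entries are NaN when either mask of the pair is empty, and pixel
    recall is NaN when the truth class is absent.
    """
    missing = sorted(set(truths) - set(preds))
    if missing:
        raise ValueError(f"prediction missing for case(s): {', '.join(missing)}")
    extra = sorted(set(preds) - set(truths))
    if extra:
        raise ValueError(f"no ground truth for case(s): {', '.join(extra)}")
    rows = []
    for cid in sorted(truths):
        p, t = np.asarray(preds[cid]), np.asarray(truths[cid])
        if p.shape != t.shape:
            raise ValueError(f"case {cid}: shape mismatch {p.shape} vs {t.shape}")
        sp = spacing[cid] if isinstance(spacing, dict) else spacing
        row = {"case": cid}
        for cls, name in ((1, "liver"), (2, "tumor")):
            pm, tm = p == cls, t == cls
            row[f"dice_{name}"] = dice(pm, tm)
            row[f"hausdorff_{name}"] = (
                hausdorff(pm, tm, sp) if (pm.any() and tm.any()) else float("nan")
            )
            row[f"recall_{name}"] = pixel_recall(pm, tm) if tm.any() else float("nan")
        lr = lesion_recall_at_overlap(p == 2, t == 2, overlap_threshold)
        row["lesion_recall"] = float("nan") if lr is None else lr
        rows.append(row)
    table = pd.DataFrame(rows)
    liver_cases = [(preds[c] == 1, truths[c] == 1) for c in sorted(truths)]
    tumor_cases = [(preds[c] == 2, truths[c] == 2) for c in sorted(truths)]
    liver_mean, liver_sd = dice_per_case(liver_cases)
    tumor_mean, tumor_sd = dice_per_case(tumor_cases)
    summary = {
        "dice_per_case_liver": liver_mean,
        "dice_per_case_liver_sd": liver_sd,
        "dice_per_case_tumor": tumor_mean,
        "dice_per_case_tumor_sd": tumor_sd,
        "dice_global_liver": dice_global(liver_cases),
        "dice_global_tumor": dice_global(tumor_cases),
        "hausdorff_liver_mean": float(np.nanmean(table["hausdorff_liver"].to_numpy()))
        if np.isfinite(table["hausdorff_liver"]).any()
        else float("nan"),
        "hausdorff_tumor_mean": float(np.nanmean(table["hausdorff_tumor"].to_numpy()))
        if np.isfinite(table["hausdorff_tumor"]).any()
        else float("nan"),
        f"recall_at_{int(overlap_threshold * 100)}_overlap": float(
            np.nanmean(table["lesion_recall"].to_numpy())
        )
        if np.isfinite(table["lesion_recall"]).any()
        else float("nan"),
    }
    return MetricsReport(per_case=table, summary=summary)
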