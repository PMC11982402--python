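"""Segmentation evaluation: Dice overlap, 95th-percentile Hausdorff distance,
precision/recall, and fold aggregation.

HD95 is the 95th percentile (linear interpolation between order statistics) of
the *pooled* set of directed nearest-boundary distances, x→y and y→x, in
millimetres through the voxel spacing; a ``directed_max`` flag gives the
max-of-directed-percentiles reading instead. Boundary voxels are mask voxels
with at least one face-adjacent background neighbour (voxels beyond the array
edge count as background). Empty-mask conventions: Dice of two empty masks is
1.0 (flagged); HD95 with any empty mask raises and is surfaced as missing in
summaries rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DegenerateInputError, ValidationError

__all__ = ["MetricsReport", "FoldSummary", "dice", "hd95", "precision_recall",
           "evaluate_case", "summarize_folds", "boundary_voxels"]


@dataclass
class MetricsReport:
    """Per-case metric values; ``hd95`` is None when undefined (empty mask)."""

    dsc: float
    hd95: float | None
    precision: float
    recall: float
    case_id: str = ""
    center: str = ""
    flags: tuple[str, ...] = ()


def _as_binary(a, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.dtype != bool:
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"{name} is not a binary mask (values {vals[:10]})")
        a = a.astype(bool)
    return a


def dice(x, y) -> float:
    """Dice similarity 2|x∩y| / (|x|+|y|); both-empty returns 1.0."""
    x = _as_binary(x, "x")
    y = _as_binary(y, "y")
    if x.shape != y.shape:
        raise ValidationError(f"mask shapes differ: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        return 1.0
    inter = int((x & y).sum())
    return 2.0 * inter / (nx + ny)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >=1 face-adjacent background neighbour (edges count
    as background)."""
    mask = _as_binary(mask, "mask")
    structure = ndimage.generate_binary_structure(mask.ndim, 1)  # faces only
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def hd95(x, y, spacing=None, directed_max: bool = False) -> float:
    """95th-percentile boundary distance between two non-empty masks, in mm."""
    x = _as_binary(x, "x")
    y = _as_binary(y, "y")
    if x.shape != y.shape:
        raise ValidationError(f"mask shapes differ: {x.shape} vs {y.shape}")
    if spacing is None:
        spacing = (1.0,) * x.ndim
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != x.ndim:
        raise ValidationError("spacing rank does not match masks")
    for name, m in (("x", x), ("y", y)):
        if not m.any():
            raise DegenerateInputError(f"hd95 undefined: mask {name!r} is empty")
    bx = boundary_voxels(x)
    by = boundary_voxels(y)
    # exact Euclidean distance (in mm) from every voxel to the nearest
    # boundary voxel of the other mask
    d_to_y = ndimage.distance_transform_edt(~by, sampling=spacing)
    d_to_x = ndimage.distance_transform_edt(~bx, sampling=spacing)
    dxy = d_to_y[bx]  # directed x -> y
    dyx = d_to_x[by]  # directed y -> x
    if directed_max:
        return float(max(np.percentile(dxy, 95), np.percentile(dyx, 95)))
    return float(np.percentile(np.concatenate([dxy, dyx]), 95))


def precision_recall(gt, pred) -> tuple[float, float]:
    """Voxel-count precision TP/(TP+FP) and recall TP/(TP+FN); 0/0 -> 0.0."""
    gt = _as_binary(gt, "gt")
    pred = _as_binary(pred, "pred")
    if gt.shape != pred.shape:
        raise ValidationError(f"mask shapes differ: {gt.shape} vs {pred.shape}")
    tp = int((gt & pred).sum())
    fp = int((~gt & pred).sum())
    fn = int((gt & ~pred).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def evaluate_case(gt, pred, spacing=None, case_id: str = "", center: str = "") -> MetricsReport:
    """All metrics for one case; HD95 set to None (flagged) when undefined."""
    d = dice(gt, pred)
    flags = []
    gt_b = _as_binary(gt, "gt")
    pred_b = _as_binary(pred, "pred")
    if not gt_b.any() and not pred_b.any():
        flags.append("both_empty_dice_1")
    try:
        h = hd95(gt, pred, spacing=spacing)
    except DegenerateInputError:
        h = None
        flags.append("hd95_undefined_empty_mask")
    p, r = precision_recall(gt, pred)
    if not pred_b.any() and gt_b.any():
        flags.append("precision_0_over_0")
    return MetricsReport(dsc=d, hd95=h, precision=p, recall=r,
                         case_id=case_id, center=center, flags=tuple(flags))


@dataclass
class FoldSummary:
    """Cross-fold aggregation: arithmetic fold average, median, and the
    maximum absolute deviation of any fold from the median."""

    folds: list[MetricsReport]
    mean: dict[str, float] = field(default_factory=dict)
    median: dict[str, float] = field(default_factory=dict)
    max_deviation: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": r.case_id or str(i), "dsc": r.dsc, "hd95": r.hd95,
                 "precision": r.precision, "recall": r.recall}
                for i, r in enumerate(self.folds)]
        return pd.DataFrame(rows)


_METRIC_FIELDS = ("dsc", "hd95", "precision", "recall")


def summarize_folds(fold_means: list[MetricsReport]) -> FoldSummary:
    """Aggregate per-fold mean reports into average / median / max deviation.

    Folds with an undefined HD95 are excluded from the HD95 aggregates
    (missing, not imputed).
    """
    if not fold_means:
        raise ValidationError("summarize_folds needs at least one fold")
    summary = FoldSummary(folds=list(fold_means))
    for f in _METRIC_FIELDS:
        vals = np.array([getattr(r, f) for r in fold_means
                         if getattr(r, f) is not None], dtype=float)
        if vals.size == 0:
            continue
        med = float(np.median(vals))
        summary.mean[f] = float(vals.mean())
        summary.median[f] = med
        summary.max_deviation[f] = float(np.abs(vals - med).max())
    return summary
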