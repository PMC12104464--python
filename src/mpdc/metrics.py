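"""Segmentation evaluation: Dice, Jaccard, 95th-percentile Hausdorff
distance (95HD) and Average Surface Distance (ASD).

Overlap metrics are reported in percent; surface metrics in voxel units
(optionally scaled by a physical spacing).  Surface distances are
computed between boundary voxels (a foreground voxel with at least one
background face-neighbour, the erosion-difference boundary) using
Euclidean distance transforms.  95HD is the 95th percentile of the
*pooled* directed boundary distances of both directions — one of the
conventions in use, fixed here for reproducibility — and ASD is their
mean, which makes both symmetric under swapping prediction and truth.

Scans are evaluated as re-stacked 3-D volumes with unit inter-slice
spacing unless spacing metadata is supplied.  An empty prediction (or
truth) with a nonempty counterpart has no boundary distances; such cases
are scored with the volume diagonal as a finite penalty and counted in
the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def dice_jaccard(pred_mask: np.ndarray, true_mask: np.ndarray) -> tuple[float, float]:
    """Overlap coefficients of two binary masks, in [0, 1].

    Both masks empty -> (1, 1); exactly one empty -> (0, 0).
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0
    inter = int((a & b).sum())
    union = na + nb - inter
    return 2.0 * inter / (na + nb), inter / union


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean boundary: foreground voxels with a background face-neighbour."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(mask.ndim, 1),
                                    border_value=0)
    return mask & ~eroded


def surface_distances(pred_mask: np.ndarray, true_mask: np.ndarray,
                      spacing=None, allow_empty: bool = False) -> tuple[float, float]:
    """(95HD, ASD) between the boundaries of two binary masks.

    Directed distances of both directions are pooled; 95HD is their 95th
    percentile, ASD their mean.  With ``allow_empty`` an empty mask scores
    the volume diagonal instead of raising.
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    spacing = np.ones(a.ndim) if spacing is None else np.asarray(spacing, dtype=float)
    if not a.any() and not b.any():
        return 0.0, 0.0
    if not a.any() or not b.any():
        if not allow_empty:
            raise ValueError("empty mask: surface distance undefined")
        diag = float(np.linalg.norm(np.array(a.shape) * spacing))
        return diag, diag
    ba, bb = boundary_voxels(a), boundary_voxels(b)
    # distance-to-boundary fields via EDT of the boundary complements
    dt_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    pooled = np.concatenate([dt_b[ba], dt_a[bb]])
    return float(np.percentile(pooled, 95)), float(pooled.mean())


@dataclass
class MetricReport:
    """Per-scan, per-class metric table plus aggregate means.

    ``per_scan[scan_id][class]`` maps to a dict with dice/jaccard in
    percent and hd95/asd in voxels.  ``empty_cases`` counts scan/class
    pairs where prediction or truth was empty (scored with the diagonal
    penalty for surface metrics, 0% overlap unless both were empty).
    """

    per_scan: dict = field(default_factory=dict)
    empty_cases: int = 0

    def aggregate(self) -> dict[str, float]:
        rows = [m for scan in self.per_scan.values() for m in scan.values()]
        if not rows:
            raise ValueError("empty report")
        return {k: float(np.mean([r[k] for r in rows]))
                for k in ("dice", "jaccard", "hd95", "asd")}


def evaluate_scan(pred_slices: np.ndarray, true_slices: np.ndarray,
                  class_list: list[int], spacing=None) -> tuple[dict, int]:
    """Metrics of one scan volume, per (non-background) class."""
    pred = np.asarray(pred_slices)
    true = np.asarray(true_slices)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth volume shape mismatch")
    out, empties = {}, 0
    for cls in class_list:
        p, t = pred == cls, true == cls
        d, j = dice_jaccard(p, t)
        if p.any() != t.any():
            empties += 1
        hd95, asd = surface_distances(p, t, spacing=spacing, allow_empty=True)
        out[cls] = {"dice": 100.0 * d, "jaccard": 100.0 * j, "hd95": hd95, "asd": asd}
    return out, empties


def evaluate_scans(pred_by_scan: dict[str, np.ndarray], true_by_scan: dict[str, np.ndarray],
                   n_classes: int, spacing=None) -> MetricReport:
    """Evaluate many scans; classes exclude background (class 0)."""
    if set(pred_by_scan) != set(true_by_scan):
        raise ValueError("prediction/truth scan sets differ")
    classes = list(range(1, n_classes))
    report = MetricReport()
    for scan_id in sorted(pred_by_scan):
        row, empties = evaluate_scan(pred_by_scan[scan_id], true_by_scan[scan_id],
                                     classes, spacing=spacing)
        report.per_scan[scan_id] = row
        report.empty_cases += empties
    return report


def stack_scan(slices: list[np.ndarray]) -> np.ndarray:
    """Stack ordered 2-D slices into a (n_slices, H, W) volume."""
    return np.stack(slices, axis=0)
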