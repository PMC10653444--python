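"""Segmentation quality metrics: four volume measures (Dice, sensitivity,
specificity, relative volume error) and two surface measures in millimetres
(95th-percentile Hausdorff distance and average symmetric surface distance).

Surface distances are computed on mask boundaries (foreground voxels with a
background 6-neighbour; outside the array counts as background) via exact
Euclidean distance transforms with anisotropic spacing support. HD95 uses
the max-of-directed-95th-percentiles convention with linear-interpolation
percentiles; pooled-percentile variants can differ slightly and are not
offered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "MetricsRecord", "confusion_counts", "dice", "sensitivity", "specificity",
    "rve", "surface_voxels", "hd95", "assd", "evaluate_case", "evaluate_set",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ["dice", "sensitivity", "specificity", "rve", "hd95_mm", "assd_mm"]


@dataclass(frozen=True)
class MetricsRecord:
    dice: float
    sensitivity: float
    specificity: float
    rve: float
    hd95_mm: float
    assd_mm: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be a binary (0/1) array")
    return a.astype(bool)


def confusion_counts(pred, gt) -> tuple[int, int, int, int]:
    """Hard voxel counts (TP, FP, FN, TN)."""
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return tp, fp, fn, tn


def dice(counts) -> float:
    tp, fp, fn, _ = counts
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


def sensitivity(counts) -> float:
    tp, _, fn, _ = counts
    return tp / (tp + fn) if tp + fn else np.nan


def specificity(counts) -> float:
    _, fp, _, tn = counts
    return tn / (tn + fp) if tn + fp else np.nan


def rve(counts) -> float:
    """Relative volume error |V_pred - V_gt| / V_gt (NaN on empty truth)."""
    tp, fp, fn, _ = counts
    v_pred, v_gt = tp + fp, tp + fn
    if v_gt == 0:
        warnings.warn("empty ground truth: RVE undefined", stacklevel=2)
        return np.nan
    return abs(v_pred - v_gt) / v_gt


def surface_voxels(mask, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Physical coordinates (mm) of boundary voxels.

    Boundary = foreground voxels with at least one background 6-neighbour,
    voxels on the array edge included (outside counts as background).
    """
    m = _as_binary(mask, "mask")
    if not m.any():
        raise ValueError("empty mask has no surface")
    interior = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    coords = np.argwhere(m & ~interior).astype(np.float64)
    return coords * np.asarray(spacing, dtype=np.float64)


def _surface_mask(mask: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    return mask & ~interior


def _directed_distances(a_surf: np.ndarray, b_surf: np.ndarray,
                        spacing) -> np.ndarray:
    """Distances from every surface voxel of A to the nearest of B, via the
    exact Euclidean distance transform of B's surface."""
    dist_to_b = ndimage.distance_transform_edt(~b_surf, sampling=spacing)
    return dist_to_b[a_surf]


def _surface_distance_sets(pred, gt, spacing):
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not p.any() or not g.any():
        raise ValueError("surface metrics need two non-empty masks")
    ps, gs = _surface_mask(p), _surface_mask(g)
    return (_directed_distances(ps, gs, spacing),
            _directed_distances(gs, ps, spacing))


def hd95(pred, gt, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile Hausdorff distance in mm."""
    d_pg, d_gp = _surface_distance_sets(pred, gt, spacing)
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)))


def assd(pred, gt, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm."""
    d_pg, d_gp = _surface_distance_sets(pred, gt, spacing)
    return float((d_pg.sum() + d_gp.sum()) / (d_pg.size + d_gp.size))


def evaluate_case(pred_mask, gt_mask, spacing=(1.0, 1.0, 1.0)) -> MetricsRecord:
    """All six metrics for one (prediction, ground truth) pair."""
    counts = confusion_counts(pred_mask, gt_mask)
    d_pg, d_gp = _surface_distance_sets(pred_mask, gt_mask, spacing)
    return MetricsRecord(
        dice=dice(counts),
        sensitivity=sensitivity(counts),
        specificity=specificity(counts),
        rve=rve(counts),
        hd95_mm=float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95))),
        assd_mm=float((d_pg.sum() + d_gp.sum()) / (d_pg.size + d_gp.size)),
    )


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Append mean and 95% CI half-width rows (Student t over cases)."""
    stats_rows = {}
    n = len(table)
    stats_rows["mean"] = table[METRIC_COLUMNS].mean()
    if n >= 2:
        half = table[METRIC_COLUMNS].sem() * stats.t.ppf(0.975, n - 1)
    else:
        half = pd.Series({c: np.nan for c in METRIC_COLUMNS})
    stats_rows["ci95_halfwidth"] = half
    agg = pd.DataFrame(stats_rows).T
    agg.insert(0, "case", agg.index)
    return agg


def evaluate_set(pairs, spacing=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Evaluate matched (name, pred_mask, gt_mask) triples.

    Returns per-case rows plus ``mean`` and ``ci95_halfwidth`` aggregate
    rows; with a single case the CI is reported as missing.
    """
    rows = []
    for name, pred, gt in pairs:
        rec = evaluate_case(pred, gt, spacing)
        rows.append({"case": name, **rec.as_dict()})
    if not rows:
        raise ValueError("no case pairs to evaluate")
    table = pd.DataFrame(rows)
    return pd.concat([table, aggregate(table)], ignore_index=True)
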