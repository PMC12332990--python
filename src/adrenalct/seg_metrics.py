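"""Segmentation evaluation: DSC, IOU, RVE and HD95.

DSC/IOU are voxel-overlap measures, RVE the relative volume error, HD95 the
95th percentile of the pooled symmetric surface-to-surface distances in
world millimetres.  ``evaluate_segmentation`` reports all four per region
(whole / left / right) and ``aggregate_reports`` assembles the cohort
mean +/- sd.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "SegMetricsReport",
    "overlap_metrics",
    "rve",
    "hd95",
    "boundary_voxels",
    "evaluate_segmentation",
    "aggregate_reports",
]

REGIONS = ("whole", "left", "right")
METRICS = ("dsc", "iou", "rve", "hd95")


@dataclasses.dataclass
class SegMetricsReport:
    """Per-region metrics for one case; percentages for dsc/iou/rve, mm for
    hd95; ``None`` marks an undefined metric (e.g. absent side)."""

    values: Dict[str, Dict[str, Optional[float]]]

    def as_row(self) -> Dict[str, Optional[float]]:
        return {
            f"{region}_{metric}": self.values.get(region, {}).get(metric)
            for region in REGIONS
            for metric in METRICS
        }


def _check_aligned(pred, truth):
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def overlap_metrics(pred, truth):
    """(dsc, iou) as fractions; (1, 1) when both masks are empty."""
    pred, truth = _check_aligned(pred, truth)
    n_pred = int(pred.sum())
    n_truth = int(truth.sum())
    if n_pred == 0 and n_truth == 0:
        logger.info("both masks empty: overlap metrics default to (1, 1)")
        return 1.0, 1.0
    inter = int((pred & truth).sum())
    dsc = 2.0 * inter / (n_pred + n_truth)
    iou = inter / (n_pred + n_truth - inter)
    return dsc, iou


def rve(pred, truth) -> float:
    """|V_pred - V_truth| / V_truth * 100 (voxel counts; spacing cancels)."""
    pred, truth = _check_aligned(pred, truth)
    n_truth = int(truth.sum())
    if n_truth == 0:
        raise ValueError("RVE undefined: truth mask is empty")
    return abs(int(pred.sum()) - n_truth) / n_truth * 100.0


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (k, 3) of foreground voxels with >= 1 face-adjacent background
    neighbor (volume border counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(mask & ~interior)


def hd95(pred, truth, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile (linear interpolation) of the pooled directed
    boundary distances pred->truth and truth->pred, in mm."""
    pred, truth = _check_aligned(pred, truth)
    if not pred.any() or not truth.any():
        raise ValueError("HD95 undefined: empty mask")
    sp = np.asarray(spacing, dtype=float)
    bp = boundary_voxels(pred) * sp
    bt = boundary_voxels(truth) * sp
    d_pt = cKDTree(bt).query(bp, k=1)[0]
    d_tp = cKDTree(bp).query(bt, k=1)[0]
    return float(np.percentile(np.concatenate([d_pt, d_tp]), 95))


def evaluate_segmentation(pred, truth, spacing=None) -> SegMetricsReport:
    """Left metrics on label 1, right on label 2, whole on the union.

    dsc/iou/rve reported in percent, hd95 in mm.  A side absent in the truth
    (or an empty boundary pairing for hd95) yields ``None`` entries.
    """
    pv = np.asarray(pred.voxels if hasattr(pred, "voxels") else pred)
    tv = np.asarray(truth.voxels if hasattr(truth, "voxels") else truth)
    if pv.shape != tv.shape:
        raise ValueError(f"shape mismatch: {pv.shape} vs {tv.shape}")
    if spacing is None:
        spacing = getattr(truth, "spacing", (1.0, 1.0, 1.0))
    values: Dict[str, Dict[str, Optional[float]]] = {}
    for region, selector in (
        ("whole", lambda a: a > 0),
        ("left", lambda a: a == 1),
        ("right", lambda a: a == 2),
    ):
        p, t = selector(pv), selector(tv)
        entry: Dict[str, Optional[float]] = dict.fromkeys(METRICS)
        if region != "whole" and not t.any():
            logger.warning("%s side absent in truth: metrics flagged missing", region)
            values[region] = entry
            continue
        dsc, iou = overlap_metrics(p, t)
        entry["dsc"] = dsc * 100.0
        entry["iou"] = iou * 100.0
        entry["rve"] = rve(p, t) if t.any() else None
        entry["hd95"] = hd95(p, t, spacing) if (p.any() and t.any()) else None
        values[region] = entry
    return SegMetricsReport(values)


def aggregate_reports(reports) -> pd.DataFrame:
    """Cohort mean +/- sd per region x metric (unweighted over patients;
    missing entries excluded)."""
    df = pd.DataFrame([r.as_row() for r in reports])
    rows = []
    for region in REGIONS:
        row = {"region": region}
        for metric in METRICS:
            col = df[f"{region}_{metric}"].dropna().astype(float)
            row[f"{metric}_mean"] = col.mean() if len(col) else np.nan
            row[f"{metric}_sd"] = col.std(ddof=1) if len(col) > 1 else np.nan
            row[f"{metric}_n"] = len(col)
        rows.append(row)
    return pd.DataFrame(rows)
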