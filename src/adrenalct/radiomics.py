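"""Per-gland quantitative feature extraction and staged feature selection.

Six feature families are computed from each segmented gland region of the
windowed image: first-order statistics, 3-D shape, gray-level co-occurrence
(GLCM), gray-level run-length (GLRLM), gray-level size-zone (GLSZM) and
neighborhood gray-tone difference (NGTDM).  Intensities are discretized with
a fixed bin width (default 0.04 on the [0,1] windowed scale, ~14 HU) so
texture levels are comparable across images.  Texture matrices are built in
3-D over the 13 unique direction offsets; GLCM/GLRLM features are averaged
over directions.

Selection is a staged reduction: near-zero-variance filter, pairwise
correlation filter, then an L1-penalized logistic ranking capped at a
configurable number of features per side.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.stats import kurtosis, skew
from skimage import measure
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "GlandRegion",
    "FeatureSelection",
    "extract_gland_regions",
    "extract_features",
    "build_feature_table",
    "select_features",
    "DEFAULT_BIN_WIDTH",
]

DEFAULT_BIN_WIDTH = 0.04

# 13 unique 3-D direction offsets (first nonzero component positive)
_DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclasses.dataclass
class GlandRegion:
    side: str  # "left" | "right"
    intensities: np.ndarray  # cropped box of windowed intensities
    mask: np.ndarray  # boolean support within the box
    spacing: Tuple[float, float, float]
    offset: Tuple[int, int, int]  # box corner in the source grid

    def __post_init__(self):
        if not self.mask.any():
            raise ValueError("gland region is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing))

    @property
    def values(self) -> np.ndarray:
        return self.intensities[self.mask].astype(np.float64)


@dataclasses.dataclass
class FeatureSelection:
    side: str
    selected: List[str]
    trace: Dict[str, int]  # surviving counts per stage


def extract_gland_regions(volume, mask) -> List[GlandRegion]:
    """One region per side present in the mask (1 = left, 2 = right); absent
    sides are omitted with a log message."""
    if hasattr(mask, "matches_grid") and not mask.matches_grid(volume):
        raise ValueError("mask is not aligned with the volume")
    voxels = np.asarray(mask.voxels if hasattr(mask, "voxels") else mask)
    image = np.asarray(volume.voxels if hasattr(volume, "voxels") else volume)
    spacing = tuple(getattr(volume, "spacing", (1.0, 1.0, 1.0)))
    regions = []
    for side, label in (("left", 1), ("right", 2)):
        support = voxels == label
        if not support.any():
            logger.warning("%s adrenal absent in mask; region omitted", side)
            continue
        slices = ndimage.find_objects(support.astype(np.int8))[0]
        regions.append(
            GlandRegion(
                side=side,
                intensities=np.ascontiguousarray(image[slices].astype(np.float32)),
                mask=np.ascontiguousarray(support[slices]),
                spacing=spacing,
                offset=tuple(s.start for s in slices),
            )
        )
    if not regions:
        logger.warning("empty mask: no gland regions extracted")
    return regions


# ---------------------------------------------------------------------------
# feature families
# ---------------------------------------------------------------------------

def _discretize(region: GlandRegion, bin_width: float):
    """Gray levels 1..Ng via fixed-width binning anchored at the region min."""
    vals = region.values
    levels = np.floor((vals - vals.min()) / bin_width).astype(int) + 1
    q = np.zeros(region.mask.shape, dtype=np.int32)
    q[region.mask] = levels
    return q, int(levels.max())


def _first_order(region: GlandRegion, q, ng) -> Dict[str, float]:
    v = region.values
    n = v.size
    counts = np.bincount(q[region.mask], minlength=ng + 1)[1:]
    p = counts / n
    p_nz = p[p > 0]
    f = {
        "firstorder_Energy": float((v**2).sum()),
        "firstorder_Entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "firstorder_Uniformity": float((p**2).sum()),
        "firstorder_Minimum": float(v.min()),
        "firstorder_Maximum": float(v.max()),
        "firstorder_Range": float(v.max() - v.min()),
        "firstorder_Mean": float(v.mean()),
        "firstorder_Median": float(np.median(v)),
        "firstorder_P10": float(np.percentile(v, 10)),
        "firstorder_P90": float(np.percentile(v, 90)),
        "firstorder_IQR": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "firstorder_MAD": float(np.abs(v - v.mean()).mean()),
        "firstorder_RMS": float(np.sqrt((v**2).mean())),
        "firstorder_StdDev": float(v.std()),
        "firstorder_Variance": float(v.var()),
        "firstorder_Skewness": float(skew(v)) if v.std() > 0 else 0.0,
        "firstorder_Kurtosis": float(kurtosis(v, fisher=False)) if v.std() > 0 else 0.0,
    }
    return f


def _shape(region: GlandRegion) -> Dict[str, float]:
    sp = np.asarray(region.spacing, dtype=float)
    vol = region.volume_mm3
    padded = np.pad(region.mask, 1).astype(np.float32)
    f: Dict[str, float] = {
        "shape_VoxelCount": float(region.voxel_count),
        "shape_VolumeMm3": float(vol),
    }
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=sp)
        area = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        area = np.nan
    f["shape_SurfaceAreaMm2"] = area
    f["shape_SurfaceToVolume"] = area / vol if np.isfinite(area) else np.nan
    f["shape_Sphericity"] = (
        float((36.0 * np.pi * vol**2) ** (1.0 / 3.0) / area)
        if np.isfinite(area) and area > 0
        else np.nan
    )
    coords = np.argwhere(region.mask) * sp
    # maximum 3-D diameter over hull vertices (all voxels when hull fails)
    try:
        pts = coords[ConvexHull(coords).vertices] if len(coords) > 10 else coords
    except Exception:
        pts = coords
    if len(pts) > 1:
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        f["shape_Max3DDiameter"] = float(np.sqrt(d2.max()))
    else:
        f["shape_Max3DDiameter"] = 0.0
    centered = coords - coords.mean(axis=0)
    if len(coords) > 3:
        eig = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
        f["shape_MajorAxisLength"] = float(4.0 * np.sqrt(eig[0]))
        f["shape_MinorAxisLength"] = float(4.0 * np.sqrt(eig[1]))
        f["shape_LeastAxisLength"] = float(4.0 * np.sqrt(eig[2]))
        f["shape_Elongation"] = (
            float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else np.nan
        )
        f["shape_Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else np.nan
    else:
        for k in ("MajorAxisLength", "MinorAxisLength", "LeastAxisLength",
                  "Elongation", "Flatness"):
            f[f"shape_{k}"] = np.nan
    return f


def _glcm_features(q, mask, ng) -> Dict[str, float]:
    i_idx, j_idx = np.meshgrid(
        np.arange(1, ng + 1), np.arange(1, ng + 1), indexing="ij"
    )
    per_dir: Dict[str, List[float]] = {}
    for d in _DIRECTIONS:
        a, b = _shifted_pairs(q, mask, d)
        if a.size == 0:
            continue
        counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
        mat = (counts + counts.T).astype(np.float64)  # symmetric
        P = mat / mat.sum()
        mu_i = (P * i_idx).sum()
        mu_j = (P * j_idx).sum()
        sd_i = np.sqrt((P * (i_idx - mu_i) ** 2).sum())
        sd_j = np.sqrt((P * (j_idx - mu_j) ** 2).sum())
        nz = P[P > 0]
        feats = {
            "glcm_Contrast": (P * (i_idx - j_idx) ** 2).sum(),
            "glcm_Dissimilarity": (P * np.abs(i_idx - j_idx)).sum(),
            "glcm_Idm": (P / (1.0 + (i_idx - j_idx) ** 2)).sum(),
            "glcm_JointEnergy": (P**2).sum(),
            "glcm_JointEntropy": -(nz * np.log2(nz)).sum(),
            "glcm_Autocorrelation": (P * i_idx * j_idx).sum(),
            "glcm_ClusterShade": (P * (i_idx + j_idx - mu_i - mu_j) ** 3).sum(),
            "glcm_Correlation": (
                ((P * (i_idx - mu_i) * (j_idx - mu_j)).sum() / (sd_i * sd_j))
                if sd_i > 0 and sd_j > 0
                else 1.0
            ),
        }
        for k, val in feats.items():
            per_dir.setdefault(k, []).append(float(val))
    if not per_dir:
        return {k: np.nan for k in (
            "glcm_Contrast", "glcm_Dissimilarity", "glcm_Idm", "glcm_JointEnergy",
            "glcm_JointEntropy", "glcm_Autocorrelation", "glcm_ClusterShade",
            "glcm_Correlation",
        )}
    return {k: float(np.mean(v)) for k, v in per_dir.items()}


def _shifted_pairs(q, mask, d):
    """Gray-level pairs (a, b) for voxels both inside the region, offset d."""
    sl_a, sl_b = [], []
    for dd, size in zip(d, q.shape):
        if dd >= 0:
            sl_a.append(slice(0, size - dd))
            sl_b.append(slice(dd, size))
        else:
            sl_a.append(slice(-dd, size))
            sl_b.append(slice(0, size + dd))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    return q[sl_a][valid], q[sl_b][valid]


def _glrlm_features(q, mask, ng) -> Dict[str, float]:
    names = ("glrlm_SRE", "glrlm_LRE", "glrlm_GLN", "glrlm_RLN", "glrlm_RP",
             "glrlm_LGLRE", "glrlm_HGLRE")
    coords = np.argwhere(mask)
    if coords.size == 0:
        return {k: np.nan for k in names}
    levels_flat = q[mask]
    n_vox = len(coords)
    per_dir: Dict[str, List[float]] = {}
    for d in _DIRECTIONS:
        dv = np.asarray(d)
        axis = int(np.nonzero(dv)[0][0])
        t = coords[:, axis] * dv[axis]
        key = coords - t[:, None] * dv[None, :]
        # encode line key compactly
        enc = (key + np.asarray(q.shape)).dot(
            np.array([1, 4 * q.shape[0], 16 * q.shape[0] * q.shape[1]])
        )
        order = np.lexsort((t, enc))
        te, ke, le = t[order], enc[order], levels_flat[order]
        new_run = np.ones(n_vox, dtype=bool)
        if n_vox > 1:
            cont = (ke[1:] == ke[:-1]) & (te[1:] == te[:-1] + 1) & (le[1:] == le[:-1])
            new_run[1:] = ~cont
        run_ids = np.cumsum(new_run) - 1
        run_len = np.bincount(run_ids)
        run_level = le[new_run]
        nr = float(len(run_len))
        max_len = int(run_len.max())
        R = np.zeros((ng, max_len), dtype=np.float64)
        np.add.at(R, (run_level - 1, run_len - 1), 1.0)
        j = np.arange(1, max_len + 1, dtype=np.float64)
        i = np.arange(1, ng + 1, dtype=np.float64)
        rj = R.sum(axis=0)
        ri = R.sum(axis=1)
        feats = {
            "glrlm_SRE": (rj / j**2).sum() / nr,
            "glrlm_LRE": (rj * j**2).sum() / nr,
            "glrlm_GLN": (ri**2).sum() / nr,
            "glrlm_RLN": (rj**2).sum() / nr,
            "glrlm_RP": nr / n_vox,
            "glrlm_LGLRE": (ri / i**2).sum() / nr,
            "glrlm_HGLRE": (ri * i**2).sum() / nr,
        }
        for k, val in feats.items():
            per_dir.setdefault(k, []).append(float(val))
    return {k: float(np.mean(v)) for k, v in per_dir.items()}


def _glszm_features(q, mask, ng) -> Dict[str, float]:
    names = ("glszm_SAE", "glszm_LAE", "glszm_GLN", "glszm_SZN", "glszm_ZP",
             "glszm_LGLZE", "glszm_HGLZE")
    zones: List[Tuple[int, int]] = []  # (level, size)
    for level in range(1, ng + 1):
        binary = (q == level) & mask
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary, structure=_STRUCT26)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    if not zones:
        return {k: np.nan for k in names}
    levels = np.array([z[0] for z in zones], dtype=np.float64)
    sizes = np.array([z[1] for z in zones], dtype=np.float64)
    nz = float(len(zones))
    n_vox = float(mask.sum())
    gl_counts = np.bincount(levels.astype(int))
    sz_counts = np.bincount(sizes.astype(int))
    return {
        "glszm_SAE": float((1.0 / sizes**2).sum() / nz),
        "glszm_LAE": float((sizes**2).sum() / nz),
        "glszm_GLN": float((gl_counts.astype(np.float64) ** 2).sum() / nz),
        "glszm_SZN": float((sz_counts.astype(np.float64) ** 2).sum() / nz),
        "glszm_ZP": float(nz / n_vox),
        "glszm_LGLZE": float((1.0 / levels**2).sum() / nz),
        "glszm_HGLZE": float((levels**2).sum() / nz),
    }


def _ngtdm_features(q, mask, ng) -> Dict[str, float]:
    names = ("ngtdm_Coarseness", "ngtdm_Contrast", "ngtdm_Busyness",
             "ngtdm_Complexity", "ngtdm_Strength")
    qf = q.astype(np.float64)
    inside = mask.astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neigh_sum = ndimage.convolve(qf * inside, kernel, mode="constant")
    neigh_cnt = ndimage.convolve(inside, kernel, mode="constant")
    valid = mask & (neigh_cnt > 0)
    if not valid.any():
        return {k: np.nan for k in names}
    abar = np.zeros_like(qf)
    abar[valid] = neigh_sum[valid] / neigh_cnt[valid]
    diff = np.abs(qf - abar)
    lv = q[valid]
    dv = diff[valid]
    n_total = float(valid.sum())
    s = np.zeros(ng + 1)
    n_i = np.zeros(ng + 1)
    np.add.at(s, lv, dv)
    np.add.at(n_i, lv, 1.0)
    p = n_i / n_total
    present = np.flatnonzero(n_i[1:] > 0) + 1
    ngp = float(len(present))
    i_lv = present.astype(np.float64)
    p_p, s_p = p[present], s[present]
    coarseness = 1.0 / (p_p * s_p).sum() if (p_p * s_p).sum() > 0 else 1e6
    if ngp > 1:
        pi = p_p[:, None]
        pj = p_p[None, :]
        ii = i_lv[:, None]
        jj = i_lv[None, :]
        contrast = (
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1.0))
        ) * (s_p.sum() / n_total)
        busy_den = np.abs(ii * pi - jj * pj).sum()
        busyness = (p_p * s_p).sum() / busy_den if busy_den > 0 else 0.0
        complexity = (
            np.abs(ii - jj) * (pi * s_p[:, None] + pj * s_p[None, :])
            / (pi + pj)
        ).sum() / n_total
        strength_num = ((pi + pj) * (ii - jj) ** 2).sum()
        strength = strength_num / s_p.sum() if s_p.sum() > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "ngtdm_Coarseness": float(coarseness),
        "ngtdm_Contrast": float(contrast),
        "ngtdm_Busyness": float(busyness),
        "ngtdm_Complexity": float(complexity),
        "ngtdm_Strength": float(strength),
    }


def extract_features(region: GlandRegion, bin_width: float = DEFAULT_BIN_WIDTH
                     ) -> Dict[str, float]:
    """Deterministic feature vector over the six families.

    Single-voxel regions get NaN for texture features (flagged missing);
    first-order and shape are always computed.
    """
    q, ng = _discretize(region, bin_width)
    features: Dict[str, float] = {}
    features.update(_first_order(region, q, ng))
    features.update(_shape(region))
    if region.voxel_count < 2:
        logger.warning("single-voxel region: texture features flagged missing")
        for fam in (_glcm_features, _glrlm_features, _glszm_features,
                    _ngtdm_features):
            features.update({k: np.nan for k in fam(q, region.mask, ng)})
        return features
    features.update(_glcm_features(q, region.mask, ng))
    features.update(_glrlm_features(q, region.mask, ng))
    features.update(_glszm_features(q, region.mask, ng))
    features.update(_ngtdm_features(q, region.mask, ng))
    return features


def build_feature_table(cases, bin_width: float = DEFAULT_BIN_WIDTH) -> pd.DataFrame:
    """Assemble the per-gland table.

    ``cases``: iterable of (patient_id, volume, mask, left_label,
    right_label).  One row per patient per present side, with ``side`` and
    binary ``label`` columns.
    """
    rows = []
    for pid, volume, mask, left_label, right_label in cases:
        for region in extract_gland_regions(volume, mask):
            row = {"patient_id": pid, "side": region.side,
                   "label": int(left_label if region.side == "left" else right_label)}
            row.update(extract_features(region, bin_width))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SelectionConfig:
    variance_threshold: float = 1e-10
    correlation_threshold: float = 0.95
    cap: int = 24
    l1_c: float = 1.0
    seed: int = 0


def select_features(table: pd.DataFrame, side: str,
                    config: Optional[SelectionConfig] = None) -> FeatureSelection:
    """Staged reduction: variance filter -> correlation filter -> L1-logistic
    ranking, capped.  Requires both classes present for the side."""
    config = config or SelectionConfig()
    sub = table[table["side"] == side] if "side" in table.columns else table
    y = sub["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"cannot select features: {side} labels are one-class")
    meta_cols = {"patient_id", "side", "label", "split"}
    feat_cols = [
        c for c in sub.columns
        if c not in meta_cols and np.issubdtype(sub[c].dtype, np.number)
    ]
    X = sub[feat_cols].to_numpy(dtype=float)
    # stage 0: drop columns with any missing value
    keep = ~np.isnan(X).any(axis=0)
    cols = [c for c, k in zip(feat_cols, keep) if k]
    X = X[:, keep]
    trace = {"initial": len(feat_cols)}

    variances = X.var(axis=0)
    keep = variances > config.variance_threshold
    cols = [c for c, k in zip(cols, keep) if k]
    X = X[:, keep]
    trace["variance_filter"] = len(cols)

    # stage 2: greedy correlation filter; on a tied pair keep the
    # higher-variance column (first by name when equal) - deterministic
    order = np.argsort([-X[:, i].var() for i in range(X.shape[1])], kind="stable")
    corr = np.corrcoef(X, rowvar=False) if X.shape[1] > 1 else np.ones((1, 1))
    kept_idx: List[int] = []
    for i in order:
        if all(abs(corr[i, j]) <= config.correlation_threshold for j in kept_idx):
            kept_idx.append(int(i))
    kept_idx.sort()
    cols = [cols[i] for i in kept_idx]
    X = X[:, kept_idx]
    trace["correlation_filter"] = len(cols)

    Xs = StandardScaler().fit_transform(X)
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=config.l1_c, max_iter=2000,
        random_state=config.seed,
    )
    clf.fit(Xs, y)
    weights = np.abs(clf.coef_[0])
    ranked = np.argsort(-weights, kind="stable")
    selected = [cols[i] for i in ranked if weights[i] > 0][: config.cap]
    if not selected:  # degenerate fit: fall back to top-|weight| columns
        selected = [cols[i] for i in ranked[: min(config.cap, len(cols))]]
    trace["l1_ranking"] = len(selected)
    return FeatureSelection(side=side, selected=selected, trace=trace)
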