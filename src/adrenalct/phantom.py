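"""Synthetic abdominal CT phantoms with paired adrenal masks and AI labels.

Each phantom is an HU volume holding an air shell, a soft-tissue body
ellipsoid, a bright spine block near the posterior midline and two small
bi-lobed paraspinal gland structures.  A gland can optionally carry a
spherical nodule; the side's incidentaloma label is 1 iff the nodule's
shortest diameter exceeds the 10 mm rule.  Phantoms are generated in the
"PLI" orientation (axis 0 -> posterior, axis 1 -> patient-left,
axis 2 -> inferior).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .io import CTVolume, LabelMask, save_volume, write_manifest, read_manifest

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_cohort",
    "split_cohort",
    "AI_DIAMETER_CUTOFF_MM",
    "HU_AIR",
    "HU_BODY",
    "HU_GLAND",
    "HU_SPINE",
]

AI_DIAMETER_CUTOFF_MM = 10.0  # shortest diameter > 1 cm defines a positive side

HU_AIR = -1000.0
HU_BODY = 40.0
HU_GLAND = 30.0
HU_SPINE = 300.0


@dataclasses.dataclass
class GlandGeometry:
    """Bi-lobed gland: union of two ellipsoids sharing an apex (inverted V)."""

    center_mm: Tuple[float, float, float]
    lobe_semiaxes_mm: Tuple[float, float, float] = (4.0, 10.0, 12.0)
    lobe_angle_deg: float = 30.0  # half-opening of the V in the axial plane


@dataclasses.dataclass
class PhantomSpec:
    dims: Tuple[int, int, int] = (96, 96, 48)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    body_hu: float = HU_BODY
    gland_hu: float = HU_GLAND
    gland_left: Optional[GlandGeometry] = None
    gland_right: Optional[GlandGeometry] = None
    nodule_left: Optional[Tuple[float, float]] = None  # (shortest diameter mm, contrast HU)
    nodule_right: Optional[Tuple[float, float]] = None
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for nod in (self.nodule_left, self.nodule_right):
            if nod is not None and nod[0] <= 0:
                raise ValueError(f"nodule shortest diameter must be > 0, got {nod[0]}")
        if self.gland_left is None:
            self.gland_left = _default_gland(self.dims, self.spacing, side="left")
        if self.gland_right is None:
            self.gland_right = _default_gland(self.dims, self.spacing, side="right")


def _default_gland(dims, spacing, side: str) -> GlandGeometry:
    extent = np.asarray(dims) * np.asarray(spacing)
    # paraspinal: posterior third, offset laterally from the midline; gland
    # size scales with the lateral extent so small phantoms keep a clear
    # inter-gland gap
    scale = extent[1] / 96.0
    cx = 0.62 * extent[0]
    offset = 0.24 * extent[1]
    cy = extent[1] / 2 + (offset if side == "left" else -offset)
    cz = 0.45 * extent[2]
    semi = tuple(float(s * scale) for s in (4.0, 10.0, 12.0))
    return GlandGeometry(center_mm=(cx, cy, cz), lobe_semiaxes_mm=semi)


def _world_grids(dims, spacing):
    axes = [np.arange(n) * s for n, s in zip(dims, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(grids, center, semiaxes, rotation=None) -> np.ndarray:
    """Boolean support of a (possibly rotated, axial-plane) ellipsoid."""
    dx = grids[0] - center[0]
    dy = grids[1] - center[1]
    dz = grids[2] - center[2]
    if rotation is not None:
        c, s = np.cos(rotation), np.sin(rotation)
        dx, dy = c * dx + s * dy, -s * dx + c * dy
    return (
        (dx / semiaxes[0]) ** 2 + (dy / semiaxes[1]) ** 2 + (dz / semiaxes[2]) ** 2
    ) <= 1.0


def _lobe_centers(geom: GlandGeometry):
    ang = np.deg2rad(geom.lobe_angle_deg)
    b = geom.lobe_semiaxes_mm[1]
    shift = 0.55 * b
    cx, cy, cz = geom.center_mm
    return (
        (cx + shift * np.sin(ang), cy + shift * np.cos(ang), cz),
        (cx + shift * np.sin(ang), cy - shift * np.cos(ang), cz),
    )


def _gland_support(grids, geom: GlandGeometry) -> np.ndarray:
    ang = np.deg2rad(geom.lobe_angle_deg)
    a, b, c = geom.lobe_semiaxes_mm
    # each lobe's long axis tilted +/- ang about the shared apex
    shift = 0.55 * b
    cx, cy, cz = geom.center_mm
    lobe1 = _ellipsoid(
        grids,
        (cx + shift * np.sin(ang), cy + shift * np.cos(ang), cz),
        (a, b, c),
        rotation=ang,
    )
    lobe2 = _ellipsoid(
        grids,
        (cx + shift * np.sin(ang), cy - shift * np.cos(ang), cz),
        (a, b, c),
        rotation=-ang,
    )
    return lobe1 | lobe2


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(volume, mask, left_label, right_label)``.  The mask labels the
    noiseless gland+nodule supports (1 = left, 2 = right); a side's label is
    1 iff its nodule's shortest diameter exceeds ``AI_DIAMETER_CUTOFF_MM``.
    """
    dims, spacing = tuple(spec.dims), tuple(spec.spacing)
    grids = _world_grids(dims, spacing)
    extent = np.asarray(dims) * np.asarray(spacing)

    hu = np.full(dims, HU_AIR, dtype=np.float32)
    body = _ellipsoid(
        grids,
        center=(extent[0] / 2, extent[1] / 2, extent[2] / 2),
        semiaxes=(0.46 * extent[0], 0.46 * extent[1], 0.60 * extent[2]),
    )
    hu[body] = spec.body_hu

    # bright spine block, posterior midline
    spine = (
        (grids[0] > 0.64 * extent[0])
        & (grids[0] < 0.84 * extent[0])
        & (np.abs(grids[1] - extent[1] / 2) < 0.07 * extent[1])
        & body
    )
    hu[spine] = HU_SPINE

    mask = np.zeros(dims, dtype=np.int16)
    labels = {}
    for side, label, geom, nodule in (
        ("left", 1, spec.gland_left, spec.nodule_left),
        ("right", 2, spec.gland_right, spec.nodule_right),
    ):
        support = _gland_support(grids, geom) & body
        hu[support] = spec.gland_hu
        side_label = 0
        if nodule is not None:
            diameter, contrast = nodule
            # anchored at the lobe farther from the mid-sagittal plane so the
            # nodule always touches its gland and stays lateral
            lobes = _lobe_centers(geom)
            mid = extent[1] / 2.0
            center = np.asarray(
                max(lobes, key=lambda c: abs(c[1] - mid)), dtype=float
            )
            # nodule grows from the gland apex; must stay near its gland
            nod = _ellipsoid(grids, center, (diameter / 2,) * 3) & body
            if not (nod & support).any():
                raise ValueError(
                    f"{side} nodule at {tuple(center)} does not touch its gland"
                )
            hu[nod] = spec.gland_hu + contrast
            support = support | nod
            side_label = int(diameter > AI_DIAMETER_CUTOFF_MM)
        mask[support] = label
        labels[side] = side_label

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=dims).astype(np.float32)

    volume = CTVolume(hu.astype(np.float32), spacing=spacing, orientation="PLI")
    label_mask = LabelMask(mask, spacing=spacing, orientation="PLI")
    return volume, label_mask, labels["left"], labels["right"]


def _random_spec(rng: np.random.Generator, dims, spacing, nodule_sides,
                 positive_range=(11.0, 18.0), contrast_range=(20.0, 60.0),
                 negative_nodule_prob=0.3, negative_range=(4.0, 9.0)) -> PhantomSpec:
    """Randomized geometry; nodule diameters straddle the 10 mm rule but are
    sampled away from exactly 10 to avoid label ambiguity."""
    extent = np.asarray(dims) * np.asarray(spacing)

    def jitter_gland(side):
        base = _default_gland(dims, spacing, side)
        jit = 0.03 * extent[1]
        c = np.asarray(base.center_mm) + rng.uniform(-jit, jit, size=3)
        sa = np.asarray(base.lobe_semiaxes_mm) * rng.uniform(0.85, 1.15, size=3)
        ang = float(rng.uniform(20, 40))
        return GlandGeometry(tuple(c), tuple(sa), ang)

    def draw_nodule(designated_positive: bool):
        if designated_positive:
            d = float(rng.uniform(*positive_range))
        else:
            if rng.random() >= negative_nodule_prob:
                return None
            d = float(rng.uniform(*negative_range))
        return (d, float(rng.uniform(*contrast_range)))

    return PhantomSpec(
        dims=tuple(dims),
        spacing=tuple(spacing),
        gland_left=jitter_gland("left"),
        gland_right=jitter_gland("right"),
        nodule_left=draw_nodule("left" in nodule_sides),
        nodule_right=draw_nodule("right" in nodule_sides),
        noise_sigma=float(rng.uniform(5, 12)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n: int,
    prevalence: float,
    laterality_weights: Sequence[float] = (0.65, 0.14, 0.21),
    seed: int = 0,
    out_dir="cohort",
    dims=(96, 96, 48),
    spacing=(1.0, 1.0, 3.0),
    contrast_range=(20.0, 60.0),
    noise_sigma: Optional[float] = None,
):
    """Generate ``n`` phantoms on disk plus a manifest.

    ``laterality_weights`` = (left-only, right-only, bilateral) mix among
    AI-positive records.  Per-record seeds derive from the master seed, so
    the cohort is reproducible record-by-record.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    w = np.asarray(laterality_weights, dtype=float)
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("laterality weights must be nonnegative and sum to 1")
    if 0 < prevalence and n * prevalence < 1:
        warnings.warn("n * prevalence < 1: cohort may contain no positive record")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    records = []
    for i, child in enumerate(master.spawn(n)):
        rng = np.random.default_rng(child)
        sides = ()
        if rng.random() < prevalence:
            sides = (("left",), ("right",), ("left", "right"))[
                int(rng.choice(3, p=w))
            ]
        spec = _random_spec(rng, dims, spacing, sides, contrast_range=contrast_range)
        if noise_sigma is not None:
            spec.noise_sigma = noise_sigma
        volume, mask, left, right = generate_phantom(spec)
        pid = f"P{i:04d}"
        img_path = out_dir / f"{pid}_image.nii"
        msk_path = out_dir / f"{pid}_mask.nii"
        save_volume(volume, img_path)
        save_volume(mask, msk_path)
        records.append(
            dict(
                patient_id=pid,
                image=str(img_path),
                mask=str(msk_path),
                left_label=left,
                right_label=right,
                split="train",
            )
        )
    manifest_path = out_dir / "manifest.tsv"
    write_manifest(records, manifest_path)
    return read_manifest(manifest_path)


def split_cohort(manifest, ratio=(0.7, 0.3), seed: int = 0, splits=("train", "valid")):
    """Stratified random split by AI presence on either side.

    Stratum proportions are preserved within one record; a stratum with
    fewer than 2 records goes wholly to the first split with a warning.
    Returns a copy of the manifest with the ``split`` column assigned.
    """
    ratio = np.asarray(ratio, dtype=float)
    if not np.isclose(ratio.sum(), 1.0):
        raise ValueError(f"split ratio must sum to 1, got {tuple(ratio)}")
    df = manifest.copy().reset_index(drop=True)
    any_ai = (df["left_label"].astype(int) | df["right_label"].astype(int)).to_numpy()
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(df), dtype=object)
    for stratum in (0, 1):
        idx = np.flatnonzero(any_ai == stratum)
        if len(idx) == 0:
            continue
        if len(idx) < 2:
            logger.warning(
                "stratum %d has %d record(s); assigned wholly to %s",
                stratum, len(idx), splits[0],
            )
            assignment[idx] = splits[0]
            continue
        perm = rng.permutation(idx)
        n_first = int(np.floor(ratio[0] * len(idx) + 0.5))
        assignment[perm[:n_first]] = splits[0]
        assignment[perm[n_first:]] = splits[1]
    df["split"] = assignment
    return df
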