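"""Cleanup of raw network output: component filtering, hole filling,
laterality assignment."""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .io import CTVolume, LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "Component",
    "ComponentSet",
    "find_components",
    "remove_noise_components",
    "fill_holes",
    "assign_laterality",
    "clean_mask",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass
class Component:
    label: int
    voxel_count: int
    centroid: Tuple[float, float, float]
    bounding_box: Tuple[Tuple[int, int], ...]  # (start, stop) per axis
    indices: object = None  # boolean support, kept for filtering


@dataclasses.dataclass
class ComponentSet:
    components: List[Component]
    connectivity: int


def _structure(connectivity: int):
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    return _STRUCTURES[connectivity]


def find_components(mask: LabelMask, connectivity: int = 26) -> ComponentSet:
    """Maximal connected components per foreground label."""
    struct = _structure(connectivity)
    comps = []
    for label in sorted(int(v) for v in np.unique(mask.voxels) if v > 0):
        binary = mask.voxels == label
        labeled, n = ndimage.label(binary, structure=struct)
        for i in range(1, n + 1):
            support = labeled == i
            count = int(support.sum())
            centroid = tuple(float(c) for c in ndimage.center_of_mass(support))
            objs = ndimage.find_objects((labeled == i).astype(np.int8))[0]
            bbox = tuple((s.start, s.stop) for s in objs)
            comps.append(Component(label, count, centroid, bbox, support))
    return ComponentSet(comps, connectivity)


def remove_noise_components(mask: LabelMask, policy: str = "keep-largest",
                            min_size: int = 0, connectivity: int = 26) -> LabelMask:
    """Drop spurious components per foreground label.

    ``policy='keep-largest'`` retains the single largest component per label
    (ties broken by lower centroid index order); ``policy='min-size'`` drops
    components below ``min_size`` voxels.
    """
    if policy not in ("keep-largest", "min-size"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "min-size" and min_size <= 0:
        raise ValueError("min_size must be positive for the min-size policy")
    comp_set = find_components(mask, connectivity)
    out = np.zeros_like(mask.voxels)
    for label in sorted({c.label for c in comp_set.components}):
        group = [c for c in comp_set.components if c.label == label]
        if policy == "keep-largest":
            keep = [max(group, key=lambda c: (c.voxel_count, tuple(-x for x in c.centroid)))]
        else:
            keep = [c for c in group if c.voxel_count >= min_size]
        if not keep:
            logger.warning("label %d entirely removed by noise filtering", label)
        for c in keep:
            out[c.indices] = label
    for label in (1, 2):
        if (mask.voxels == label).any() and not (out == label).any():
            logger.warning("no component retained for label %d (absent gland)", label)
    return mask.with_voxels(out)


def fill_holes(mask: LabelMask, connectivity: int = 6) -> LabelMask:
    """Fill background cavities not connected to the volume border, per
    foreground label.  Never removes a foreground voxel."""
    struct = _structure(connectivity)
    out = mask.voxels.copy()
    for label in sorted(int(v) for v in np.unique(mask.voxels) if v > 0):
        binary = mask.voxels == label
        filled = ndimage.binary_fill_holes(binary, structure=struct)
        out[filled & (out == 0)] = label
    return mask.with_voxels(out)


def _left_axis(orientation: str):
    """Return (axis, sign): moving along ``axis`` by +1 voxel moves ``sign``
    in the patient-left direction."""
    for axis, letter in enumerate(orientation):
        if letter == "L":
            return axis, 1.0
        if letter == "R":
            return axis, -1.0
    raise ValueError(f"orientation {orientation!r} has no L/R axis")


def assign_laterality(mask, volume: CTVolume, connectivity: int = 26) -> LabelMask:
    """Label components of a binary adrenal mask as left (1) / right (2).

    A component is assigned by its centroid's position along the patient
    left-right axis relative to the volume's mid-sagittal plane; when both
    components fall on one side the nearer-the-midline one is reassigned
    with a warning.
    """
    binary = np.asarray(mask.voxels if hasattr(mask, "voxels") else mask) > 0
    out = np.zeros(binary.shape, dtype=np.int16)
    result = LabelMask(
        out, spacing=volume.spacing, orientation=volume.orientation,
        origin=volume.origin,
    )
    if not binary.any():
        return result
    axis, sign = _left_axis(volume.orientation)
    mid = (binary.shape[axis] - 1) / 2.0
    struct = _structure(connectivity)
    labeled, n = ndimage.label(binary, structure=struct)
    centroids = ndimage.center_of_mass(binary, labeled, range(1, n + 1))
    # leftness: positive = patient-left of the mid-sagittal plane
    leftness = [sign * (c[axis] - mid) for c in centroids]
    assigned = [1 if ln > 0 else 2 for ln in leftness]
    if n == 2 and assigned[0] == assigned[1]:
        flip = int(np.argmin([abs(ln) for ln in leftness]))
        assigned[flip] = 1 if assigned[flip] == 2 else 2
        logger.warning(
            "both components on one side; reassigned the midline-nearest one"
        )
    for i, lab in enumerate(assigned):
        out[labeled == i + 1] = lab
    result.voxels = out
    return result


def clean_mask(mask: LabelMask, policy: str = "keep-largest", min_size: int = 0,
               noise_connectivity: int = 26, hole_connectivity: int = 6) -> LabelMask:
    """Default pipeline: remove noise components, then fill holes.

    Filling after removal avoids merging noise specks into the glands.
    """
    cleaned = remove_noise_components(
        mask, policy=policy, min_size=min_size, connectivity=noise_connectivity
    )
    return fill_holes(cleaned, connectivity=hole_connectivity)
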