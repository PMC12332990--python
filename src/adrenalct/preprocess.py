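"""Normalization chain: reorientation, resampling, windowing, patch sampling.

Defaults follow the segmentation recipe used throughout the cascade:
orientation "PLI", spacing (1, 1, 3) mm, abdominal window W=350 / L=40 HU
rescaled to [0, 1], training patches of 96^3 with foreground-biased random
cropping, Gaussian-noise and in-plane-rotation augmentation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

from .io import CTVolume, LabelMask, validate_orientation_code

__all__ = [
    "PreprocessConfig",
    "PatchPair",
    "reorient",
    "resample",
    "window_normalize",
    "preprocess_pair",
    "sample_patches",
    "augment",
]


@dataclasses.dataclass
class PreprocessConfig:
    target_orientation: str = "PLI"
    target_spacing: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    window_width: float = 350.0
    window_level: float = 40.0
    patch_size: Tuple[int, int, int] = (96, 96, 96)
    foreground_bias: float = 0.5
    noise_sigma_aug: float = 0.02
    rotation_range_deg: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.window_width <= 0:
            raise ValueError("window_width must be > 0")
        if any(p < 8 for p in self.patch_size):
            raise ValueError("patch_size components must be >= 8")
        if not 0.0 <= self.foreground_bias <= 1.0:
            raise ValueError("foreground_bias must be in [0, 1]")
        validate_orientation_code(self.target_orientation)


@dataclasses.dataclass
class PatchPair:
    image_patch: np.ndarray
    mask_patch: np.ndarray
    source_id: str = ""
    corner: Tuple[int, int, int] = (0, 0, 0)


def reorient(volume, target: str):
    """Permute/flip the grid so its orientation code equals ``target``.

    World positions of all voxels are unchanged (the affine is updated in
    step with the array).  Masks keep their integer labels.
    """
    target = validate_orientation_code(target)
    if volume.orientation == target:
        return volume
    src_ornt = nib.orientations.axcodes2ornt(tuple(volume.orientation))
    dst_ornt = nib.orientations.axcodes2ornt(tuple(target))
    transform = nib.orientations.ornt_transform(src_ornt, dst_ornt)
    data = nib.orientations.apply_orientation(volume.voxels, transform)
    new_affine = volume.affine @ nib.orientations.inv_ornt_aff(
        transform, volume.voxels.shape
    )
    from .io import metadata_from_affine

    spacing, code, origin = metadata_from_affine(new_affine)
    assert code == target
    return volume.with_voxels(
        np.ascontiguousarray(data), spacing=spacing, orientation=code, origin=origin
    )


def resample(volume, target_spacing):
    """Resample to ``target_spacing`` (mm).

    Output dims = round-half-away-from-zero(dims * spacing / target), min 1.
    Images use trilinear interpolation, masks nearest-neighbor (no new label
    values).  Grid corner (voxel 0,0,0) keeps its world position.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    in_dims = volume.voxels.shape
    in_sp = volume.spacing
    out_dims = tuple(
        max(1, int(np.floor(d * s / t + 0.5)))
        for d, s, t in zip(in_dims, in_sp, target_spacing)
    )
    if out_dims == in_dims and np.allclose(in_sp, target_spacing, atol=1e-9):
        return volume.with_voxels(volume.voxels.copy(), spacing=target_spacing)

    coords = np.meshgrid(
        *[
            np.arange(n_out) * (t / s)
            for n_out, t, s in zip(out_dims, target_spacing, in_sp)
        ],
        indexing="ij",
    )
    is_mask = isinstance(volume, LabelMask)
    order = 0 if is_mask else 1
    data = ndimage.map_coordinates(
        volume.voxels.astype(np.float32 if not is_mask else volume.voxels.dtype),
        np.stack(coords),
        order=order,
        mode="nearest",
    )
    return volume.with_voxels(data, spacing=target_spacing)


def window_normalize(volume: CTVolume, width: float = 350.0, level: float = 40.0):
    """Clamp HU to [level - width/2, level + width/2] and rescale to [0, 1]."""
    if width <= 0:
        raise ValueError("window width must be > 0")
    lo = level - width / 2.0
    out = np.clip((volume.voxels.astype(np.float32) - lo) / width, 0.0, 1.0)
    return volume.with_voxels(out)


def preprocess_pair(volume: CTVolume, mask, config: PreprocessConfig):
    """Full chain: reorient -> resample -> window.

    Idempotent: a volume whose values already lie in [0, 1] is treated as
    windowed and is not re-windowed.  ``mask`` may be None.
    """
    vol = reorient(volume, config.target_orientation)
    vol = resample(vol, config.target_spacing)
    already_windowed = vol.voxels.min() >= 0.0 and vol.voxels.max() <= 1.0
    if not already_windowed:
        vol = window_normalize(vol, config.window_width, config.window_level)
    if mask is None:
        return vol, None
    msk = reorient(mask, config.target_orientation)
    msk = resample(msk, config.target_spacing)
    return vol, msk


def _pad_to(arr: np.ndarray, target, value):
    pads = []
    for dim, tgt in zip(arr.shape, target):
        extra = max(0, tgt - dim)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, mode="constant", constant_values=value)
    return arr


def sample_patches(volume: CTVolume, mask: LabelMask, config: PreprocessConfig, n: int):
    """Draw ``n`` random patches; a ``foreground_bias`` fraction are forced to
    contain at least one gland voxel.  Volumes smaller than the patch are
    zero-padded symmetrically (background for masks)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ps = tuple(config.patch_size)
    img = _pad_to(volume.voxels.astype(np.float32), ps, 0.0)
    msk = _pad_to(mask.voxels, ps, 0)
    rng = np.random.default_rng(config.seed)
    fg_idx = np.argwhere(msk > 0)
    if len(fg_idx) == 0 and config.foreground_bias > 0:
        warnings.warn("empty mask: all patches will be background-only")

    pairs = []
    for k in range(n):
        force_fg = len(fg_idx) > 0 and rng.random() < config.foreground_bias
        if force_fg:
            vox = fg_idx[rng.integers(len(fg_idx))]
            corner = [
                int(np.clip(v - rng.integers(p), 0, dim - p))
                for v, p, dim in zip(vox, ps, img.shape)
            ]
        else:
            corner = [int(rng.integers(dim - p + 1)) for p, dim in zip(ps, img.shape)]
        sl = tuple(slice(c, c + p) for c, p in zip(corner, ps))
        pairs.append(
            PatchPair(
                image_patch=img[sl].copy(),
                mask_patch=msk[sl].copy(),
                source_id="",
                corner=tuple(corner),
            )
        )
    return pairs


def augment(pair: PatchPair, config: PreprocessConfig, seed: int) -> PatchPair:
    """Additive Gaussian noise (re-clamped to [0,1]) and a shared random
    in-plane rotation of image and mask.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    img = pair.image_patch.astype(np.float32)
    msk = pair.mask_patch
    if config.noise_sigma_aug > 0:
        img = np.clip(
            img + rng.normal(0, config.noise_sigma_aug, img.shape).astype(np.float32),
            0.0,
            1.0,
        )
    if config.rotation_range_deg > 0:
        angle = float(rng.uniform(-config.rotation_range_deg, config.rotation_range_deg))
        # rotate about the inferior-superior axis only: (1,1,3) mm anisotropy
        # makes out-of-plane rotation destructive
        img = ndimage.rotate(
            img, angle, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0
        )
        img = np.clip(img, 0.0, 1.0)
        msk = ndimage.rotate(
            msk, angle, axes=(0, 1), reshape=False, order=0, mode="constant", cval=0
        )
    return PatchPair(img, msk, source_id=pair.source_id, corner=pair.corner)
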