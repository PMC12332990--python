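"""NIfTI-backed volume and mask I/O.

The interchange layer for the whole cascade: CT volumes and label masks are
held as ``CTVolume`` / ``LabelMask`` objects carrying the voxel grid together
with spacing (mm), a three-letter orientation code and the world origin.
Orientation codes follow the nibabel convention: each letter names the
anatomical direction toward which the corresponding voxel axis *increases*
(e.g. ``"PLI"`` = axis 0 toward posterior, axis 1 toward patient-left,
axis 2 toward inferior).  World coordinates are RAS+.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CTVolume",
    "LabelMask",
    "VALID_LABELS",
    "load_volume",
    "save_volume",
    "read_manifest",
    "write_manifest",
]

VALID_LABELS = (0, 1, 2)  # background, left adrenal, right adrenal

_AXIS_DIRECTIONS = {
    "R": np.array([1.0, 0.0, 0.0]),
    "L": np.array([-1.0, 0.0, 0.0]),
    "A": np.array([0.0, 1.0, 0.0]),
    "P": np.array([0.0, -1.0, 0.0]),
    "S": np.array([0.0, 0.0, 1.0]),
    "I": np.array([0.0, 0.0, -1.0]),
}

_AXIS_GROUPS = ({"A", "P"}, {"L", "R"}, {"S", "I"})


def validate_orientation_code(code: str) -> str:
    """Check that ``code`` names one direction per anatomical axis."""
    if not isinstance(code, str) or len(code) != 3:
        raise ValueError(f"orientation code must be 3 letters, got {code!r}")
    code = code.upper()
    letters = set(code)
    for group in _AXIS_GROUPS:
        if len(letters & group) != 1:
            raise ValueError(
                f"orientation code {code!r} must contain exactly one of each "
                f"of {{A,P}}, {{L,R}}, {{S,I}}"
            )
    return code


def affine_from_metadata(spacing, orientation: str, origin) -> np.ndarray:
    """Build a RAS+ affine from spacing, orientation code and origin."""
    orientation = validate_orientation_code(orientation)
    affine = np.eye(4)
    for i, letter in enumerate(orientation):
        affine[:3, i] = _AXIS_DIRECTIONS[letter] * float(spacing[i])
    affine[:3, 3] = np.asarray(origin, dtype=float)
    return affine


def metadata_from_affine(affine: np.ndarray):
    """Recover (spacing, orientation code, origin) from a RAS+ affine."""
    codes = "".join(nib.orientations.aff2axcodes(affine))
    spacing = tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(float(x) for x in affine[:3, 3])
    return spacing, codes, origin


@dataclasses.dataclass
class CTVolume:
    """A 3-D scalar grid (HU or normalized [0,1]) with geometric metadata."""

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    orientation: str = "RAS"
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3-D grid, got shape {self.voxels.shape}")
        if min(self.voxels.shape) < 1:
            raise ValueError("grid dimensions must be >= 1 on every axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.orientation = validate_orientation_code(self.orientation)
        self.origin = tuple(float(x) for x in self.origin)

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        return affine_from_metadata(self.spacing, self.orientation, self.origin)

    def voxel_to_world(self, index) -> np.ndarray:
        """World (RAS+) coordinate of a voxel index (0-based)."""
        idx = np.asarray(index, dtype=float)
        return self.affine[:3, :3] @ idx + self.affine[:3, 3]

    def with_voxels(self, voxels: np.ndarray, **overrides) -> "CTVolume":
        kwargs = dict(
            spacing=self.spacing, orientation=self.orientation, origin=self.origin
        )
        kwargs.update(overrides)
        return type(self)(voxels, **kwargs)


@dataclasses.dataclass
class LabelMask(CTVolume):
    """Integer label grid aligned with a CTVolume.

    Labels: 0 background, 1 left adrenal, 2 right adrenal.
    """

    label_semantics = {0: "background", 1: "left adrenal", 2: "right adrenal"}

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.voxels.dtype, np.integer):
            rounded = np.rint(self.voxels)
            if not np.allclose(self.voxels, rounded, atol=1e-6):
                bad = np.unique(self.voxels[self.voxels != rounded])[:5]
                raise ValueError(f"mask contains non-integer values, e.g. {bad}")
            self.voxels = rounded.astype(np.int16)

    def check_labels(self, allowed=VALID_LABELS) -> "LabelMask":
        present = np.unique(self.voxels)
        bad = sorted(set(present.tolist()) - set(allowed))
        if bad:
            raise ValueError(f"mask contains unexpected label values {bad}")
        return self

    def matches_grid(self, volume: CTVolume) -> bool:
        return (
            self.voxels.shape == volume.voxels.shape
            and np.allclose(self.spacing, volume.spacing, atol=1e-6)
            and self.orientation == volume.orientation
        )


Volume = Union[CTVolume, LabelMask]


def load_volume(path, as_mask: bool = False, strict_labels: bool = True) -> Volume:
    """Load a NIfTI file as a CTVolume (or LabelMask when ``as_mask``).

    Spacing / orientation / origin are derived from the on-disk affine, never
    from free-text header fields.  With ``as_mask`` the values are cast to
    integers; ``strict_labels`` additionally enforces the {0,1,2} convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing, orientation, origin = metadata_from_affine(img.affine)
    if as_mask:
        mask = LabelMask(data, spacing=spacing, orientation=orientation, origin=origin)
        if strict_labels:
            mask.check_labels()
        return mask
    return CTVolume(
        data.astype(np.float32), spacing=spacing, orientation=orientation, origin=origin
    )


def save_volume(volume: Volume, path, create_parents: bool = True) -> Path:
    """Write a volume/mask to NIfTI; the affine encodes all metadata."""
    path = Path(path)
    if create_parents:
        path.parent.mkdir(parents=True, exist_ok=True)
    elif not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(volume, LabelMask):
        data = volume.voxels.astype(np.int16)
    else:
        data = volume.voxels.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    nib.save(img, str(path))
    return path


_MANIFEST_COLUMNS = ["patient_id", "image", "mask", "left_label", "right_label", "split"]


def write_manifest(records, path) -> Path:
    """Persist a cohort manifest (one row per patient) as tab-delimited text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(records, columns=_MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
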