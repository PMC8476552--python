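"""Volume containers and NIfTI-1 I/O.

Two grid types are shared by every stage of the pipeline:

* :class:`ImageVolume` — a 3D scalar field (the LGE signal intensity) with
  physical voxel spacing and origin in millimetres.
* :class:`LabelVolume` — a co-registered categorical grid using the fixed
  label scheme ``0 = background, 1 = blood pool, 2 = myocardium, 3 = scar``.
  Scar is a subset of the wall: for all geometric purposes the wall is
  ``labels ∈ {2, 3}``.

Conventions fixed here and relied on everywhere else:

* axis 2 of the array is the through-plane (long-axis) direction;
* voxel centres sit at ``origin + index * spacing`` (0-based indices);
* all physical quantities are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

__all__ = [
    "BACKGROUND",
    "BLOOD",
    "MYOCARDIUM",
    "SCAR",
    "VALID_LABELS",
    "ImageVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
]

BACKGROUND = 0
BLOOD = 1
MYOCARDIUM = 2
SCAR = 3
VALID_LABELS = (BACKGROUND, BLOOD, MYOCARDIUM, SCAR)

THROUGH_PLANE_AXIS = 2


def _check_geometry(data: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must have 3 components")
    if any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing must be strictly positive and finite, got {spacing}")
    if min(data.shape) < 2:
        raise ValueError(f"each axis needs >= 2 voxels, got shape {data.shape}")
    return spacing, origin


@dataclass
class ImageVolume:
    """3D scalar intensity grid with physical geometry (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing, self.origin = _check_geometry(self.data, self.spacing, self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values (NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


@dataclass
class LabelVolume:
    """Categorical anatomy grid: background / blood pool / myocardium / scar."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=1e-6):
                raise ValueError("label volume contains non-integer values")
            arr = rounded.astype(np.int16)
        self.labels = arr.astype(np.int16, copy=False)
        self.spacing, self.origin = _check_geometry(self.labels, self.spacing, self.origin)
        bad = np.setdiff1d(np.unique(self.labels), VALID_LABELS)
        if bad.size:
            raise ValueError(
                f"invalid label code(s) {bad.tolist()}; allowed codes are {list(VALID_LABELS)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    @property
    def wall_mask(self) -> np.ndarray:
        """Myocardium plus scar — scar counts as wall for geometry."""
        return (self.labels == MYOCARDIUM) | (self.labels == SCAR)

    @property
    def blood_mask(self) -> np.ndarray:
        return self.labels == BLOOD

    @property
    def scar_mask(self) -> np.ndarray:
        return self.labels == SCAR

    @property
    def background_mask(self) -> np.ndarray:
        return self.labels == BACKGROUND

    def with_labels(self, labels: np.ndarray) -> "LabelVolume":
        return replace(self, labels=labels)


Volume = Union[ImageVolume, LabelVolume]


def same_grid(a: Volume, b: Volume) -> bool:
    """True when two volumes share shape, spacing and origin (to float tolerance)."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing)
        and np.allclose(a.origin, b.origin)
    )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, kind: str = "image") -> Volume:
    """Read a NIfTI-1 volume as an :class:`ImageVolume` or :class:`LabelVolume`.

    Parameters
    ----------
    path:
        A ``.nii`` or ``.nii.gz`` file.
    kind:
        ``"image"`` for scalar intensities, ``"label"`` for the categorical
        anatomy (values must be integers in {0, 1, 2, 3}).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    if kind == "image":
        return ImageVolume(np.asarray(data, dtype=np.float64), zooms, origin)
    if kind == "label":
        return LabelVolume(data, zooms, origin)
    raise ValueError(f"kind must be 'image' or 'label', got {kind!r}")


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume to NIfTI-1. Labels are stored bit-exactly as int16."""
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int16)
    else:
        data = vol.data.astype(np.float64)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path
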