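"""Core spatial data types for thoracic CT and lesion masks.

All images live on a regular 3D grid with axes fixed as
(x = left-right, y = anterior-posterior, z = inferior-superior).
Voxel indexing is 0-based; bounding boxes are inclusive on both ends, so
the physical side length along axis ``a`` is ``(hi[a] - lo[a] + 1) * spacing[a]``.
Volumes are stored in Hounsfield units as floats; masks as non-negative
integers (0 = background).

NIfTI-1 is the on-disk format.  On load the image is reoriented to the
closest RAS orientation so the in-memory axis convention is stable
regardless of how the file was written.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np

__all__ = [
    "CtVolume",
    "BinaryMask",
    "InstanceMask",
    "BoundingBox3D",
    "GridMismatchError",
    "read_volume",
    "read_mask",
    "write_volume",
    "physical_extent",
    "check_congruent",
]

_SPACING_ATOL = 1e-6


class GridMismatchError(ValueError):
    """Raised when a (volume, mask) pair does not share shape/spacing/origin."""


@dataclasses.dataclass
class _Grid3D:
    """Shared grid bookkeeping for volumes and masks."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all extents must be >= 1, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "_Grid3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_SPACING_ATOL)
            and np.allclose(self.origin, other.origin, atol=_SPACING_ATOL)
        )

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff


@dataclasses.dataclass
class CtVolume(_Grid3D):
    """A 3D CT image in Hounsfield units on a regular anisotropic grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data, dtype=np.float32)


@dataclasses.dataclass
class BinaryMask(_Grid3D):
    """Foreground/background mask: 0 = normal tissue, 1 = lesion (or lung)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        data = np.asarray(self.data)
        vals = np.unique(data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary mask may contain only {0, 1}")
        self.data = data.astype(np.uint8)


@dataclasses.dataclass
class InstanceMask(_Grid3D):
    """Integer-labeled mask: 0 = background, k >= 1 = lesion instance k.

    Labels must be exactly ``{1..n_instances}`` with no gaps; instance
    connectivity (each label one 26-connected component) is the contract of
    the labeling stage and is not re-verified on every construction.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        data = np.asarray(self.data)
        if data.min() < 0:
            raise ValueError("instance labels must be non-negative")
        data = data.astype(np.uint16)
        labels = np.unique(data)
        labels = labels[labels > 0]
        n = len(labels)
        if n and (labels != np.arange(1, n + 1)).any():
            raise ValueError(f"labels must be 1..{n} with no gaps, got {labels.tolist()}")
        self.data = data
        self.n_instances = n

    def binarize(self) -> BinaryMask:
        return BinaryMask((self.data > 0).astype(np.uint8), self.spacing, self.origin)


AnyImage = Union[CtVolume, BinaryMask, InstanceMask]


@dataclasses.dataclass(frozen=True)
class BoundingBox3D:
    """Inclusive voxel-index box: lo <= hi componentwise."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if any(l > h for l, h in zip(lo, hi)):
            raise ValueError(f"lo must be <= hi componentwise, got lo={lo} hi={hi}")
        if any(l < 0 for l in lo):
            raise ValueError(f"box extends below index 0: lo={lo}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l + 1 for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def side_lengths_mm(self, spacing: Sequence[float]) -> tuple[float, float, float]:
        return tuple((h - l + 1) * s for l, h, s in zip(self.lo, self.hi, spacing))  # type: ignore[return-value]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def contains_within(self, shape: Sequence[int]) -> bool:
        return all(h < n for h, n in zip(self.hi, shape))


def check_congruent(a: _Grid3D, b: _Grid3D, what: str = "images") -> None:
    """Raise :class:`GridMismatchError` unless a and b share one grid."""
    if not a.same_grid(b):
        raise GridMismatchError(
            f"{what} are not grid-congruent: "
            f"shapes {a.shape} vs {b.shape}, spacings {a.spacing} vs {b.spacing}, "
            f"origins {a.origin} vs {b.origin}"
        )


def _load_canonical(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises its own hierarchy
        raise ValueError(f"not a readable NIfTI file: {path} ({exc})") from exc
    img = nib.as_closest_canonical(img)
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = img.slicer[..., 0]
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got shape {tuple(img.shape)} in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing {spacing} in header of {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    data = np.asanyarray(img.dataobj)
    return data, spacing, origin


def read_volume(path) -> CtVolume:
    """Read a 3D single-channel NIfTI CT volume (HU) from *path*."""
    data, spacing, origin = _load_canonical(path)
    return CtVolume(np.asarray(data, dtype=np.float32), spacing, origin)


def read_mask(path, instances: bool = True):
    """Read a NIfTI mask.

    With ``instances=True`` an :class:`InstanceMask` is returned; a mask
    stored as plain binary then simply has ``n_instances`` 0 or 1 per
    component re-derivation done downstream.  With ``instances=False`` any
    positive voxel maps to 1 and a :class:`BinaryMask` is returned.
    """
    data, spacing, origin = _load_canonical(path)
    data = np.rint(np.asarray(data)).astype(np.int64)
    if data.min() < 0:
        raise ValueError(f"mask at {path} has negative voxel values")
    if not instances:
        return BinaryMask((data > 0).astype(np.uint8), spacing, origin)
    # relabel to contiguous 1..n preserving label order
    labels = np.unique(data)
    labels = labels[labels > 0]
    lut = np.zeros(int(data.max()) + 1, dtype=np.uint16)
    lut[labels] = np.arange(1, len(labels) + 1, dtype=np.uint16)
    return InstanceMask(lut[data], spacing, origin)


def write_volume(v: AnyImage, path) -> None:
    """Write a volume or mask to *path* as NIfTI-1.

    Masks are stored with an unsigned integer voxel type, HU volumes as
    float32.  The affine is diagonal spacing plus origin translation.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(v, (BinaryMask, InstanceMask)):
        data = np.asarray(v.data, dtype=np.uint16)
    else:
        data = np.asarray(v.data, dtype=np.float32)
    img = nib.Nifti1Image(data, v.affine())
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


def physical_extent(v: _Grid3D, axis) -> float:
    """Physical extent of *v* along *axis* ('x'|'y'|'z' or 0|1|2), in mm."""
    a = _AXES[axis]
    return v.shape[a] * v.spacing[a]
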