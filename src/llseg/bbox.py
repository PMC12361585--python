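"""Stage 1: thoracic crop box from a lung mask, with minimum-size fallback.

The tightest box around the lung mask defines the crop.  Lung maskers can
fail on large or wall-attached masses, so each axis of the box is checked
against a minimum physical extent (defaults 210 x 150 x 120 mm, i.e. the
smallest plausible thorax): any axis shorter than its minimum is replaced
by the full image range on that axis.  An entirely empty lung mask maps to
the full-image box.  Comparisons are in physical mm because voxel spacing
varies several-fold across scanners.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, TypeVar

import numpy as np

from .volume import (
    AnyImage,
    BinaryMask,
    BoundingBox3D,
    CtVolume,
    InstanceMask,
)

__all__ = ["BboxConfig", "CropRecord", "lung_bbox", "apply_minimum_fallback", "crop_to_box"]


@dataclasses.dataclass(frozen=True)
class BboxConfig:
    """Per-axis minimum physical extents (mm) below which the fallback fires."""

    min_extent_mm: tuple[float, float, float] = (210.0, 150.0, 120.0)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.min_extent_mm):
            raise ValueError("min_extent_mm components must be strictly positive")


@dataclasses.dataclass(frozen=True)
class CropRecord:
    """Bookkeeping to pad a cropped mask back onto the original grid."""

    original_shape: tuple[int, int, int]
    lo: tuple[int, int, int]
    original_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def to_dict(self) -> dict:
        return {
            "original_shape": list(self.original_shape),
            "lo": list(self.lo),
            "original_origin": list(self.original_origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CropRecord":
        return cls(
            tuple(d["original_shape"]),
            tuple(d["lo"]),
            tuple(d.get("original_origin", (0.0, 0.0, 0.0))),
        )


def lung_bbox(mask: BinaryMask) -> Optional[BoundingBox3D]:
    """Tightest box containing all foreground voxels; ``None`` for an empty mask."""
    fg = np.asarray(mask.data) > 0
    if not fg.any():
        return None
    lo, hi = [], []
    for axis in range(3):
        proj = fg.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lo.append(int(idx[0]))
        hi.append(int(idx[-1]))
    return BoundingBox3D(tuple(lo), tuple(hi))


def apply_minimum_fallback(
    box: Optional[BoundingBox3D], grid: AnyImage, cfg: BboxConfig = BboxConfig()
) -> BoundingBox3D:
    """Replace sub-minimum axes of *box* with the full image range.

    Each axis is treated independently: if the box's physical side length is
    below ``cfg.min_extent_mm`` on that axis, the whole-image range is used
    for that axis; the other axes are untouched.  A ``None`` (empty-mask)
    box maps to the full-grid box.  The operation is idempotent.
    """
    shape = grid.shape
    if box is None:
        return BoundingBox3D((0, 0, 0), tuple(n - 1 for n in shape))
    if not box.contains_within(shape):
        raise ValueError(f"box {box} exceeds grid shape {shape}")
    sides = box.side_lengths_mm(grid.spacing)
    lo = list(box.lo)
    hi = list(box.hi)
    for a in range(3):
        if sides[a] < cfg.min_extent_mm[a]:
            lo[a] = 0
            hi[a] = shape[a] - 1
    return BoundingBox3D(tuple(lo), tuple(hi))


_Img = TypeVar("_Img", CtVolume, BinaryMask, InstanceMask)


def crop_to_box(v: _Img, box: BoundingBox3D) -> tuple[_Img, CropRecord]:
    """Crop *v* to *box* (inclusive corners) and return the crop record.

    The output origin is shifted so physical coordinates are preserved.
    Cropping an :class:`InstanceMask` can orphan labels; the cropped data is
    therefore returned as the same kind only when its label set remains
    contiguous, else it is recompacted preserving label order.
    """
    if not box.contains_within(v.shape):
        raise ValueError(f"box {box} out of bounds for shape {v.shape}")
    sub = np.asarray(v.data)[box.slices()].copy()
    new_origin = tuple(o + l * s for o, l, s in zip(v.origin, box.lo, v.spacing))
    record = CropRecord(v.shape, box.lo, v.origin)
    if isinstance(v, InstanceMask):
        labels = np.unique(sub)
        labels = labels[labels > 0]
        lut = np.zeros(int(sub.max()) + 1 if sub.size else 1, dtype=sub.dtype)
        lut[labels] = np.arange(1, len(labels) + 1, dtype=sub.dtype)
        return InstanceMask(lut[sub], v.spacing, new_origin), record
    out = type(v)(sub, v.spacing, new_origin)
    return out, record
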