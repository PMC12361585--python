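"""Stage 2: binary lesion segmentation, instance labeling, and padding.

The segmentation network proper is a pluggable backend behind
:class:`SegmentationBackend`; any model that maps a cropped CT to a
grid-congruent binary mask can be attached.  Two backends ship with the
package:

* :class:`ThresholdBackend` — an analytic oracle for phantoms: lesion
  tissue is the only material above a HU cutoff, so thresholding recovers
  the ground truth exactly on noise-free phantoms.  Used for end-to-end
  oracle tests.
* :class:`VoxelFeatureBackend` — a trainable voxelwise classifier
  (logistic regression on multiscale Gaussian intensity features in
  physical mm).  It is deliberately local: structures sharing the lesions'
  intensity signature (vessel-like tubes, fat-embedded nodules) are
  segmented too, which is what the downstream cascade false-positive
  reducer exists to clean up.

After binary segmentation, foreground is split into instances with the
conventional 3D connected-components algorithm under 26-connectivity, and
predicted masks are padded back to the original CT grid.
"""

from __future__ import annotations

import dataclasses
import pickle
from typing import Optional, Protocol, Sequence, Union, runtime_checkable

import numpy as np
from scipy import ndimage
from .bbox import CropRecord
from .volume import BinaryMask, BoundingBox3D, CtVolume, InstanceMask, check_congruent

__all__ = [
    "SegmentationBackend",
    "ThresholdBackend",
    "VoxelFeatureBackend",
    "VoxelFeatureConfig",
    "LesionCandidate",
    "segment_binary",
    "label_instances",
    "pad_to_original",
    "extract_candidates",
    "load_backend",
]

#: 26-connectivity stencil (face, edge and corner adjacency)
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract for a binary lesion-segmentation model."""

    def predict(self, ct_crop: CtVolume) -> BinaryMask: ...

    def fit(self, cases: Sequence[tuple[CtVolume, BinaryMask]]) -> "SegmentationBackend": ...

    def save(self, path) -> None: ...


class UntrainedBackendError(RuntimeError):
    pass


@dataclasses.dataclass
class ThresholdBackend:
    """Oracle backend for phantoms: foreground = voxels above *hu_cutoff*.

    On the phantom palette lesion-like tissue (+20 HU) is the only
    material above +10 HU, so this recovers the planted structures
    exactly when noise is absent.
    """

    hu_cutoff: float = 10.0

    def fit(self, cases) -> "ThresholdBackend":
        return self

    def predict(self, ct_crop: CtVolume) -> BinaryMask:
        fg = (ct_crop.data > self.hu_cutoff).astype(np.uint8)
        return BinaryMask(fg, ct_crop.spacing, ct_crop.origin)

    def save(self, path) -> None:
        _save_backend(self, path)


@dataclasses.dataclass(frozen=True)
class VoxelFeatureConfig:
    """Desk-scale defaults for the trainable voxelwise backend.

    ``sigmas_mm`` are the physical scales of the Gaussian intensity-context
    features; ``aeration_sigma_mm`` scales an additional "fraction of
    aerated tissue nearby" feature that separates intrapulmonary from
    chest-wall neighborhoods.  ``bg_samples_per_case`` bounds the plain
    background voxels drawn per case (all foreground and near-boundary
    voxels are kept), keeping a fit on a few dozen crops in the seconds
    range on one CPU.  The probability-map smoothing scale and decision
    threshold are calibrated on held-out training cases during ``fit``
    from ``smooth_grid_mm`` x ``threshold_grid``.
    """

    sigmas_mm: tuple[float, ...] = (1.0, 2.0, 4.0, 12.0)
    aeration_sigma_mm: float = 8.0
    bg_samples_per_case: int = 15_000
    max_iter: int = 200
    smooth_grid_mm: tuple[float, ...] = (2.0, 3.0)
    threshold_grid: tuple[float, ...] = (0.3, 0.4, 0.5)
    calibration_fraction: float = 0.2
    seed: int = 0


class VoxelFeatureBackend:
    """Trainable voxelwise lesion classifier on multiscale intensity features.

    A gradient-boosted classifier scores every voxel from its HU value,
    Gaussian-smoothed context at several physical scales, and a local
    aeration fraction; the probability map is then smoothed and
    thresholded.  The smoothing scale and threshold are chosen by Dice on
    a held-out calibration split of the training cases, so ``fit`` is a
    single self-contained call.
    """

    def __init__(self, config: VoxelFeatureConfig = VoxelFeatureConfig()):
        self.config = config
        self._model = None
        self.smooth_mm_: Optional[float] = None
        self.threshold_: Optional[float] = None

    # feature extraction ---------------------------------------------------
    def _features(self, ct: CtVolume) -> np.ndarray:
        data = np.asarray(ct.data, dtype=np.float32)
        cols = [data.ravel()]
        for sigma_mm in self.config.sigmas_mm:
            sigma_vox = [sigma_mm / s for s in ct.spacing]
            cols.append(ndimage.gaussian_filter(data, sigma_vox).ravel())
        aer = ndimage.gaussian_filter(
            (data < -400.0).astype(np.float32),
            [self.config.aeration_sigma_mm / s for s in ct.spacing],
        )
        cols.append(aer.ravel() * 1000.0)
        return np.stack(cols, axis=1) / 1000.0  # HU -> O(1) scale

    def _prob_map(self, ct: CtVolume) -> np.ndarray:
        prob = self._model.predict_proba(self._features(ct))[:, 1]
        return prob.reshape(ct.shape).astype(np.float32)

    def fit(self, cases: Sequence[tuple[CtVolume, BinaryMask]]) -> "VoxelFeatureBackend":
        from sklearn.ensemble import HistGradientBoostingClassifier

        rng = np.random.default_rng(self.config.seed)
        n_cal = max(1, int(round(self.config.calibration_fraction * len(cases))))
        if len(cases) <= n_cal:
            raise ValueError("too few cases to split off a calibration subset")
        fit_cases = list(cases[:-n_cal])
        cal_cases = list(cases[-n_cal:])
        xs, ys = [], []
        for ct, gt in fit_cases:
            check_congruent(ct, gt, "training (ct, mask) pair")
            feats = self._features(ct)
            fg_mask = np.asarray(gt.data) > 0
            near = ndimage.binary_dilation(fg_mask, np.ones((5, 5, 5), bool)) & ~fg_mask
            fg = np.flatnonzero(fg_mask.ravel())
            hard = np.flatnonzero(near.ravel())
            bg = np.flatnonzero(~(fg_mask | near).ravel())
            n_bg = min(len(bg), self.config.bg_samples_per_case)
            take = np.concatenate([fg, hard, rng.choice(bg, size=n_bg, replace=False)])
            xs.append(feats[take])
            ys.append(fg_mask.ravel()[take].astype(np.int8))
        X = np.concatenate(xs)
        y = np.concatenate(ys)
        if len(np.unique(y)) < 2:
            raise ValueError("training cases contain no lesion foreground")
        self._model = HistGradientBoostingClassifier(
            random_state=self.config.seed, max_iter=self.config.max_iter
        ).fit(X, y)
        # calibrate (smoothing, threshold) by mean Dice on held-out cases
        cal_probs = [self._prob_map(ct) for ct, _gt in cal_cases]
        best = (-1.0, None, None)
        for smooth_mm in self.config.smooth_grid_mm:
            for thr in self.config.threshold_grid:
                dices = []
                for (ct, gt), prob in zip(cal_cases, cal_probs):
                    sm = ndimage.gaussian_filter(prob, [smooth_mm / s for s in ct.spacing])
                    a = sm >= thr
                    b = np.asarray(gt.data) > 0
                    denom = int(a.sum()) + int(b.sum())
                    dices.append(2.0 * int((a & b).sum()) / denom if denom else 1.0)
                score = float(np.mean(dices))
                if score > best[0]:
                    best = (score, smooth_mm, thr)
        _, self.smooth_mm_, self.threshold_ = best
        return self

    def predict(self, ct_crop: CtVolume) -> BinaryMask:
        if self._model is None:
            raise UntrainedBackendError("backend must be fitted before predict()")
        prob = self._prob_map(ct_crop)
        prob = ndimage.gaussian_filter(prob, [self.smooth_mm_ / s for s in ct_crop.spacing])
        fg = (prob >= self.threshold_).astype(np.uint8)
        return BinaryMask(fg, ct_crop.spacing, ct_crop.origin)

    def save(self, path) -> None:
        _save_backend(self, path)


_BACKEND_FORMAT_VERSION = 1


def _save_backend(backend, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"version": _BACKEND_FORMAT_VERSION, "backend": backend}, fh)


def load_backend(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != _BACKEND_FORMAT_VERSION:
        raise ValueError(f"unsupported backend checkpoint version: {payload.get('version')}")
    return payload["backend"]


def segment_binary(backend: SegmentationBackend, ct_crop: CtVolume) -> BinaryMask:
    """Run *backend* on the cropped CT and validate the output contract."""
    mask = backend.predict(ct_crop)
    check_congruent(ct_crop, mask, "segmentation output and its input crop")
    return mask


def label_instances(mask: Union[BinaryMask, InstanceMask]) -> InstanceMask:
    """Split foreground into 26-connected components labeled 1..n.

    Labels follow the lexicographic scan order of each component's minimum
    voxel index, which makes the output deterministic; relabeling an
    already-instance-labeled mask preserves the partition.
    """
    fg = np.asarray(mask.data) > 0
    labeled, _ = ndimage.label(fg, structure=STRUCT_26)
    # scipy assigns labels in raster order of first-encountered voxel, which
    # is exactly the lexicographic minimum index of each component.
    return InstanceMask(labeled.astype(np.uint16), mask.spacing, mask.origin)


def pad_to_original(
    mask: Union[BinaryMask, InstanceMask], record: CropRecord
) -> Union[BinaryMask, InstanceMask]:
    """Place cropped mask content back at its offsets on the original grid."""
    data = np.asarray(mask.data)
    for axis in range(3):
        if record.lo[axis] + data.shape[axis] > record.original_shape[axis]:
            raise ValueError(
                f"crop record inconsistent with mask shape on axis {axis}: "
                f"lo={record.lo}, crop shape={data.shape}, original={record.original_shape}"
            )
    full = np.zeros(record.original_shape, dtype=data.dtype)
    sl = tuple(slice(l, l + n) for l, n in zip(record.lo, data.shape))
    full[sl] = data
    cls = InstanceMask if isinstance(mask, InstanceMask) else BinaryMask
    return cls(full, mask.spacing, record.original_origin)


@dataclasses.dataclass(frozen=True)
class LesionCandidate:
    """One predicted lesion instance and its summary geometry."""

    label: int
    voxel_count: int
    volume_mm3: float
    bbox: BoundingBox3D
    centroid_mm: tuple[float, float, float]
    axial_diameter_mm: float


def extract_candidates(pred: InstanceMask, ct: Optional[CtVolume] = None) -> list[LesionCandidate]:
    """Summarize each predicted instance as a :class:`LesionCandidate`."""
    from .metrics import axial_diameter  # local import to avoid cycle

    if ct is not None:
        check_congruent(pred, ct, "prediction and CT")
    data = np.asarray(pred.data)
    voxel_vol = float(np.prod(pred.spacing))
    out = []
    for label in range(1, pred.n_instances + 1):
        idx = np.argwhere(data == label)
        count = len(idx)
        lo = tuple(int(v) for v in idx.min(axis=0))
        hi = tuple(int(v) for v in idx.max(axis=0))
        centroid_vox = idx.mean(axis=0)
        centroid = tuple(
            float(o + c * s) for o, c, s in zip(pred.origin, centroid_vox, pred.spacing)
        )
        diam = axial_diameter(idx, pred.spacing)
        out.append(
            LesionCandidate(label, count, count * voxel_vol, BoundingBox3D(lo, hi), centroid, diam)
        )
    return out
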