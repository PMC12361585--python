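"""Stage 3: cascade false-positive reduction (CFPR).

Two classifiers filter predicted lesion candidates in sequence:

* **XPC** (extrapulmonary classifier) looks at the full coronal slice
  through the candidate's centroid — the plane that shows the pulmonary
  boundaries — as a (raw, candidate-mask) pair resampled to 1 x 1 mm and
  resized to 128 x 128.  Candidates judged fully extrapulmonary are
  dropped immediately.
* **LVC** (lesion validator classifier) sees a 96 mm cube centered on the
  candidate, resampled to 1 mm isotropic (96^3), and separates true
  lesions from intrapulmonary look-alikes.

Both classifiers output P(class 1 = true lesion).  The XPC's probability
of being extrapulmonary is ``p_e = 1 - P(lesion)``; a candidate is dropped
at stage XPC when ``p_e >= thr_e``, otherwise it is confirmed iff the LVC
probability strictly surpasses ``thr_i``.  Rejected candidates are erased
from the mask; survivors are relabeled 1..m preserving their relative
order, with their voxel sets untouched (the cascade only removes).

Thresholds outside [0, 1] act as pass-all / drop-all sentinels, which
makes the no-reduction pipeline an exact special case.
"""

from __future__ import annotations

import dataclasses
import pickle
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, CtVolume, InstanceMask, check_congruent

__all__ = [
    "CascadeConfig",
    "CandidatePatchPair",
    "Classifier",
    "Decision",
    "make_xpc_patch",
    "make_lvc_patch",
    "cascade_decide",
    "run_cfpr",
    "LungOverlapOracle",
    "GtOverlapOracle",
    "PooledPatchClassifier",
    "PASS_THROUGH",
    "load_classifier",
]


@dataclasses.dataclass(frozen=True)
class CascadeConfig:
    """Cascade thresholds and patch-geometry constants."""

    thr_e: float = 0.5
    thr_i: float = 0.5
    xpc_patch: tuple[int, int] = (128, 128)
    xpc_res_mm: float = 1.0
    lvc_patch: tuple[int, int, int] = (96, 96, 96)
    lvc_res_mm: float = 1.0


#: sentinel configuration under which every candidate is kept
PASS_THROUGH = CascadeConfig(thr_e=1.01, thr_i=-0.01)


@dataclasses.dataclass
class CandidatePatchPair:
    """(raw, mask) patch pair for one candidate; raw is 0-1 normalized and
    the mask channel contains only the candidate under evaluation."""

    raw: np.ndarray
    mask: np.ndarray
    geometry: str  # "2D-coronal" | "3D-crop"
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.raw.shape != self.mask.shape:
            raise ValueError("raw and mask patches must share a shape")
        if self.raw.size and (self.raw.min() < -1e-6 or self.raw.max() > 1 + 1e-6):
            raise ValueError("raw patch must be normalized to [0, 1]")


@runtime_checkable
class Classifier(Protocol):
    def predict_prob(self, pair: CandidatePatchPair) -> float: ...


def _minmax(arr: np.ndarray) -> np.ndarray:
    lo = float(arr.min())
    hi = float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr, dtype=np.float32)
    return ((arr - lo) / (hi - lo)).astype(np.float32)


def _resample_plane(arr: np.ndarray, spacing: tuple[float, float], out_shape: tuple[int, int],
                    order: int, cval: float) -> np.ndarray:
    """Map a 2D array with physical *spacing* onto *out_shape* pixels covering
    the same physical extent (resample-to-1mm + resize in one interpolation)."""
    ext = (arr.shape[0] * spacing[0], arr.shape[1] * spacing[1])
    coords = np.meshgrid(
        ((np.arange(out_shape[0]) + 0.5) * ext[0] / out_shape[0] - 0.5 * spacing[0]) / spacing[0],
        ((np.arange(out_shape[1]) + 0.5) * ext[1] / out_shape[1] - 0.5 * spacing[1]) / spacing[1],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        arr.astype(np.float32), np.stack(coords), order=order, mode="constant", cval=cval
    )


def _candidate_centroid_vox(pred: InstanceMask, label: int) -> np.ndarray:
    idx = np.argwhere(np.asarray(pred.data) == label)
    if idx.size == 0:
        raise KeyError(f"label {label} absent from prediction")
    return idx.mean(axis=0)


def make_xpc_patch(
    ct: CtVolume, pred: InstanceMask, label: int, cfg: CascadeConfig = CascadeConfig()
) -> CandidatePatchPair:
    """Central coronal (constant-y) slice pair for the XPC classifier.

    The full plane is used — not a crop — so the classifier sees the body
    outline and pulmonary boundaries around the candidate.
    """
    check_congruent(ct, pred, "ct and prediction")
    centroid = _candidate_centroid_vox(pred, label)
    iy = int(np.rint(centroid[1]))
    raw2d = np.asarray(ct.data)[:, iy, :]
    mask2d = (np.asarray(pred.data)[:, iy, :] == label).astype(np.float32)
    sp = (ct.spacing[0], ct.spacing[2])
    pad = float(raw2d.min())
    raw = _resample_plane(raw2d, sp, cfg.xpc_patch, order=1, cval=pad)
    mask = _resample_plane(mask2d, sp, cfg.xpc_patch, order=0, cval=0.0)
    return CandidatePatchPair(
        _minmax(raw), mask.astype(np.uint8), "2D-coronal",
        {"label": label, "slice_y": iy},
    )


def make_lvc_patch(
    ct: CtVolume, pred: InstanceMask, label: int, cfg: CascadeConfig = CascadeConfig()
) -> CandidatePatchPair:
    """1 mm-isotropic cube (default 96 mm) centered on the candidate.

    Regions outside the scanned volume are padded with the volume's
    minimum HU (air) before 0-1 normalization.
    """
    check_congruent(ct, pred, "ct and prediction")
    centroid_vox = _candidate_centroid_vox(pred, label)
    centroid_mm = centroid_vox * np.asarray(ct.spacing)
    n = np.asarray(cfg.lvc_patch)
    # physical sample positions of output voxel centers, then to index space
    offsets = [
        (np.arange(n[a]) - (n[a] - 1) / 2.0) * cfg.lvc_res_mm + centroid_mm[a]
        for a in range(3)
    ]
    grids = np.meshgrid(*offsets, indexing="ij")
    coords = np.stack([g / s for g, s in zip(grids, ct.spacing)])
    pad = float(np.asarray(ct.data).min())
    raw = ndimage.map_coordinates(
        np.asarray(ct.data, dtype=np.float32), coords, order=1, mode="constant", cval=pad
    )
    cand = (np.asarray(pred.data) == label).astype(np.float32)
    mask = ndimage.map_coordinates(cand, coords, order=0, mode="constant", cval=0.0)
    return CandidatePatchPair(
        _minmax(raw), mask.astype(np.uint8), "3D-crop", {"label": label}
    )


@dataclasses.dataclass(frozen=True)
class Decision:
    label: int
    keep: bool
    stage: Optional[str]  # "XPC" | "LVC" for drops, None for keeps
    p_xpc: Optional[float]
    p_lvc: Optional[float]


def cascade_decide(
    p_xpc_lesion: float, p_lvc_lesion: Optional[float], cfg: CascadeConfig
) -> tuple[bool, Optional[str]]:
    """Two-threshold cascade gate for one candidate.

    Returns ``(keep, stage)``; *stage* names the classifier that dropped
    the candidate (None when kept).  ``p_e = 1 - p_xpc_lesion`` is the
    extrapulmonary score: at ``p_e >= thr_e`` the candidate is dropped by
    XPC; below it, the candidate is kept iff the LVC probability strictly
    surpasses ``thr_i``.
    """
    p_e = 1.0 - p_xpc_lesion
    if p_e >= cfg.thr_e:
        return False, "XPC"
    if p_lvc_lesion is None:
        raise ValueError("candidate passed XPC but no LVC probability was provided")
    if p_lvc_lesion > cfg.thr_i:
        return True, None
    return False, "LVC"


def run_cfpr(
    ct: CtVolume,
    pred: InstanceMask,
    xpc: Optional[Classifier],
    lvc: Optional[Classifier],
    cfg: CascadeConfig = CascadeConfig(),
    use_xpc: bool = True,
    use_lvc: bool = True,
) -> tuple[InstanceMask, list[Decision]]:
    """Apply the cascade to every candidate of *pred*.

    Dropped candidates' voxels are set to 0; survivors are relabeled 1..m
    preserving relative order.  Disabling a stage (ablations) routes every
    candidate through the remaining one; with both disabled the input is
    returned unchanged apart from relabeling.
    """
    check_congruent(ct, pred, "ct and prediction")
    decisions: list[Decision] = []
    keep_labels: list[int] = []
    for label in range(1, pred.n_instances + 1):
        p_x: Optional[float] = None
        p_l: Optional[float] = None
        if use_xpc:
            if xpc is None:
                raise ValueError("use_xpc=True requires an XPC classifier")
            p_x = float(xpc.predict_prob(make_xpc_patch(ct, pred, label, cfg)))
            if 1.0 - p_x >= cfg.thr_e:
                decisions.append(Decision(label, False, "XPC", p_x, None))
                continue
        if use_lvc:
            if lvc is None:
                raise ValueError("use_lvc=True requires an LVC classifier")
            p_l = float(lvc.predict_prob(make_lvc_patch(ct, pred, label, cfg)))
            if not p_l > cfg.thr_i:
                decisions.append(Decision(label, False, "LVC", p_x, p_l))
                continue
        decisions.append(Decision(label, True, None, p_x, p_l))
        keep_labels.append(label)

    data = np.asarray(pred.data)
    lut = np.zeros(pred.n_instances + 1, dtype=data.dtype)
    for new, old in enumerate(keep_labels, start=1):
        lut[old] = new
    return InstanceMask(lut[data], pred.spacing, pred.origin), decisions


# ---------------------------------------------------------------------------
# oracle classifiers (ground-truth-aware; for tests and oracle pipelines)


class LungOverlapOracle:
    """XPC oracle: P(lesion) = 1 iff the candidate overlaps the lung mask.

    Holds the prediction and lung mask of the case under evaluation and
    resolves the candidate through the patch's label metadata.
    """

    def __init__(self, pred: InstanceMask, lung_mask: BinaryMask):
        check_congruent(pred, lung_mask, "prediction and lung mask")
        self._pred = np.asarray(pred.data)
        self._lung = np.asarray(lung_mask.data) > 0

    def predict_prob(self, pair: CandidatePatchPair) -> float:
        label = pair.meta["label"]
        return 1.0 if (self._lung & (self._pred == label)).any() else 0.0


class GtOverlapOracle:
    """LVC oracle: P(lesion) = 1 iff the candidate overlaps a gt lesion."""

    def __init__(self, pred: InstanceMask, gt: InstanceMask):
        check_congruent(pred, gt, "prediction and ground truth")
        self._pred = np.asarray(pred.data)
        self._gt = np.asarray(gt.data) > 0

    def predict_prob(self, pair: CandidatePatchPair) -> float:
        label = pair.meta["label"]
        return 1.0 if (self._gt & (self._pred == label)).any() else 0.0


class EnsembleClassifier:
    """Mean probability over member classifiers (fold-model ensembling)."""

    def __init__(self, members: Sequence[Classifier]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = list(members)

    def predict_prob(self, pair: CandidatePatchPair) -> float:
        return float(np.mean([m.predict_prob(pair) for m in self.members]))

    def save(self, path) -> None:
        _save_classifier(self, path)


class ConstantClassifier:
    """Outputs a fixed probability; the trainable-cascade fallback when a
    stage has no trainable signal (e.g. single-class training data)."""

    def __init__(self, prob: float = 1.0):
        self.prob = float(prob)

    def predict_prob(self, pair: CandidatePatchPair) -> float:
        return self.prob

    def fit(self, pairs, labels):
        return self

    def save(self, path) -> None:
        _save_classifier(self, path)


# ---------------------------------------------------------------------------
# trainable classifier backbone


class PooledPatchClassifier:
    """Small trainable classifier on block-pooled (raw, mask) patch features.

    The patch pair is block-averaged onto a coarse grid (16x16 for the 2D
    coronal view, 12^3 for the 3D crop), the two channels are concatenated
    and standardized, and a single-hidden-layer network is trained with
    Adam on binary cross-entropy.  The training loop (mini-batches of 32,
    L2 weight decay, early stopping on a validation fold with patience in
    epochs, best-loss weights restored) lives in :mod:`llseg.train`.
    """

    def __init__(self, geometry: str, pool: Optional[tuple[int, ...]] = None,
                 hidden: tuple[int, ...] = (64,), seed: int = 0):
        if geometry not in ("2D-coronal", "3D-crop"):
            raise ValueError(f"unknown geometry {geometry!r}")
        self.geometry = geometry
        self.pool = pool or ((4, 4) if geometry == "2D-coronal" else (4, 4, 4))
        self.hidden = hidden
        self.seed = seed
        self._net = None
        self._mu: Optional[np.ndarray] = None
        self._sd: Optional[np.ndarray] = None

    # -- features ----------------------------------------------------------
    def _pool_one(self, arr: np.ndarray) -> np.ndarray:
        fac = tuple(s // p for s, p in zip(arr.shape, self.pool))
        if any(f * p != s for f, p, s in zip(fac, self.pool, arr.shape)):
            raise ValueError(f"patch shape {arr.shape} not divisible by pool {self.pool}")
        view = arr.astype(np.float32)
        for axis, (p, f) in enumerate(zip(self.pool, fac)):
            view = view.reshape(view.shape[:axis] + (p, f) + view.shape[axis + 1:])
            view = view.mean(axis=axis + 1)
        return view.ravel()

    @staticmethod
    def _candidate_summaries(raw: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Candidate-focused statistics: the pooled channels describe the whole
        field of view, so a small candidate barely registers there; these
        summaries carry its intensity, its immediate surroundings (the shell
        that distinguishes e.g. pleural from fat-embedded neighborhoods) and
        its shape."""
        fg = mask > 0
        n = int(fg.sum())
        if n == 0:
            return np.zeros(10, dtype=np.float32)
        shell = ndimage.binary_dilation(fg, iterations=3) & ~fg
        ext = [(idx.max() - idx.min() + 1) / s for idx, s in
               zip(np.nonzero(fg), fg.shape)]
        ext += [0.0] * (3 - len(ext))
        elong = max(ext[:fg.ndim]) / max(min(ext[:fg.ndim]), 1e-6)
        # "aerated" pixels sit well below soft tissue after 0-1 normalization
        aer_in = float((raw[fg] < 0.5).mean())
        aer_shell = float((raw[shell] < 0.5).mean()) if shell.any() else 0.0
        return np.asarray(
            [
                float(raw[fg].mean()),
                float(raw[fg].std()),
                float(raw[shell].mean()) if shell.any() else 0.0,
                aer_in,
                aer_shell,
                n / raw.size,
                *ext,
                elong,
            ],
            dtype=np.float32,
        )

    def featurize(self, pairs: Sequence[CandidatePatchPair]) -> np.ndarray:
        rows = []
        cache_key = ("_features", self.geometry, self.pool)
        for pair in pairs:
            if pair.geometry != self.geometry:
                raise ValueError(f"expected {self.geometry} patch, got {pair.geometry}")
            cached = pair.meta.get(cache_key)
            if cached is None:
                cached = np.concatenate(
                    [
                        self._pool_one(pair.raw),
                        self._pool_one(pair.mask),
                        self._candidate_summaries(pair.raw, pair.mask),
                    ]
                )
                pair.meta[cache_key] = cached
            rows.append(cached)
        return np.asarray(rows, dtype=np.float32)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._mu is None:
            raise RuntimeError("classifier is not trained")
        return (X - self._mu) / self._sd

    def fit(
        self,
        pairs: Sequence[CandidatePatchPair],
        labels: Sequence[int],
        val_pairs: Optional[Sequence[CandidatePatchPair]] = None,
        val_labels: Optional[Sequence[int]] = None,
        **train_kwargs,
    ):
        from .train import fit_mlp  # deferred: train imports this module

        X = self.featurize(pairs)
        y = np.asarray(labels, dtype=int)
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd < 1e-8] = 1.0
        Xv = yv = None
        if val_pairs is not None and len(val_pairs):
            Xv = self.transform(self.featurize(val_pairs))
            yv = np.asarray(val_labels, dtype=int)
        self._net, self.curve_ = fit_mlp(
            self.transform(X), y, X_val=Xv, y_val=yv,
            hidden=self.hidden, seed=self.seed, **train_kwargs,
        )
        return self

    def predict_prob(self, pair: CandidatePatchPair) -> float:
        if self._net is None:
            raise RuntimeError("classifier is not trained")
        X = self.transform(self.featurize([pair]))
        return float(self._net.predict_proba(X)[0, 1])

    def predict_prob_many(self, pairs: Sequence[CandidatePatchPair]) -> np.ndarray:
        if self._net is None:
            raise RuntimeError("classifier is not trained")
        X = self.transform(self.featurize(pairs))
        return self._net.predict_proba(X)[:, 1]

    def save(self, path) -> None:
        _save_classifier(self, path)


_CLASSIFIER_FORMAT_VERSION = 1


def _save_classifier(clf, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"version": _CLASSIFIER_FORMAT_VERSION, "classifier": clf}, fh)


def load_classifier(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != _CLASSIFIER_FORMAT_VERSION:
        raise ValueError(f"unsupported classifier checkpoint version: {payload.get('version')}")
    return payload["classifier"]
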