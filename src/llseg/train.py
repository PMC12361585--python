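"""Candidate-dataset construction, classifier training, CV, and threshold tuning.

The false-positive-reduction classifiers are trained on *candidate
datasets* built by running the bounding-box + segmentation pipeline on
annotated cases: every predicted instance becomes one record, labeled 1
when it overlaps a ground-truth lesion (pairwise Dice > 0) and 0
otherwise, and tagged by its lung-mask overlap fraction as
extrapulmonary (no overlap), intrapulmonary (entirely inside) or partial.
The LVC trains on the full candidate set; the XPC subset keeps
extrapulmonary non-lesions plus all true lesions, mirroring its subtask.

Cases (never candidates) are split into 5 folds stratified by source tag
and binned z-spacing; candidate records inherit their case's fold.  The
training recipe is binary cross-entropy with Adam (lr 1e-3, L2 weight
decay 1e-4, batches of 32), random patch augmentations (translation,
flip, rotation, zoom, Gaussian noise) and early stopping after 30 epochs
without validation-loss improvement, restoring the best weights.

Classifier selection takes the highest validation AUROC across folds;
the cascade thresholds (thr_e, thr_i) are then tuned by exhaustive grid
search maximizing image-level mean Dice subject to pooled lesion
sensitivity staying within a tolerance of the best achievable value.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.neural_network import MLPClassifier

from .cascade import (
    CandidatePatchPair,
    CascadeConfig,
    ConstantClassifier,
    PASS_THROUGH,
    PooledPatchClassifier,
    make_lvc_patch,
    make_xpc_patch,
)
from .volume import BinaryMask, CtVolume, InstanceMask, check_congruent

__all__ = [
    "CandidateRecord",
    "TrainConfig",
    "FoldAssignment",
    "build_candidate_dataset",
    "subset_for_xpc",
    "assign_folds",
    "bin_z_spacing",
    "train_classifier",
    "select_best_and_tune_thresholds",
    "early_stopping_loop",
    "fit_mlp",
    "augment_pair",
    "TuningCandidate",
    "build_tuning_data",
]


# ---------------------------------------------------------------------------
# candidate dataset


@dataclasses.dataclass
class CandidateRecord:
    case_id: str
    label: int
    y: int  # 1 = lesion (max DSC vs gt > 0), 0 = non-lesion
    location: str  # extrapulmonary | partial | intrapulmonary
    max_dsc: float
    size: int = 0  # candidate voxel count
    patch_file: Optional[str] = None


def build_candidate_dataset(
    cases: Sequence[tuple[CtVolume, InstanceMask, InstanceMask, BinaryMask]],
    cfg: CascadeConfig = CascadeConfig(),
    case_ids: Optional[Sequence[str]] = None,
    patch_dir=None,
    with_patches: bool = True,
) -> tuple[list[CandidateRecord], dict]:
    """One record + (XPC, LVC) patch pair per predicted candidate.

    *cases* are (ct, gt instances, predicted instances, lung mask) tuples on
    one grid.  Returns the records and a ``{(case_id, label): (xpc_pair,
    lvc_pair)}`` patch map; with *patch_dir* the pairs are also materialized
    as ``.npz`` files referenced from the records.  ``with_patches=False``
    returns the records with an empty patch map (cheap labeling pass, e.g.
    before subsampling hard negatives).
    """
    ids = case_ids or [f"case{i:03d}" for i in range(len(cases))]
    records: list[CandidateRecord] = []
    patches: dict[tuple[str, int], tuple[CandidatePatchPair, CandidatePatchPair]] = {}
    for cid, (ct, gt, pred, lung) in zip(ids, cases):
        for m, name in ((gt, "gt"), (pred, "pred"), (lung, "lung mask")):
            check_congruent(ct, m, f"ct and {name}")
        gdata = np.asarray(gt.data)
        pdata = np.asarray(pred.data)
        lungfg = np.asarray(lung.data) > 0
        gt_sizes = {int(g): int((gdata == g).sum()) for g in range(1, gt.n_instances + 1)}
        for label in range(1, pred.n_instances + 1):
            cand = pdata == label
            size = int(cand.sum())
            best = 0.0
            for g, gsize in gt_sizes.items():
                inter = int((cand & (gdata == g)).sum())
                if inter:
                    best = max(best, 2.0 * inter / (size + gsize))
            frac = float((cand & lungfg).sum()) / size
            loc = "extrapulmonary" if frac == 0 else ("intrapulmonary" if frac == 1 else "partial")
            rec = CandidateRecord(cid, label, int(best > 0), loc, best, size)
            if not with_patches:
                records.append(rec)
                continue
            pair = (make_xpc_patch(ct, pred, label, cfg), make_lvc_patch(ct, pred, label, cfg))
            patches[(cid, label)] = pair
            if patch_dir is not None:
                patch_dir = Path(patch_dir)
                patch_dir.mkdir(parents=True, exist_ok=True)
                f = patch_dir / f"{cid}_cand{label:03d}.npz"
                np.savez_compressed(
                    f,
                    xpc_raw=pair[0].raw, xpc_mask=pair[0].mask,
                    lvc_raw=pair[1].raw, lvc_mask=pair[1].mask,
                )
                rec.patch_file = str(f)
            records.append(rec)
    return records, patches


def subset_for_xpc(records: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """XPC training subset: extrapulmonary non-lesions + all true lesions."""
    return [r for r in records if (r.y == 0 and r.location == "extrapulmonary") or r.y == 1]


# ---------------------------------------------------------------------------
# stratified folds


def bin_z_spacing(sz_mm: float) -> str:
    """Bin slice spacing into thin (<=1 mm), standard (1-3 mm), thick (>3 mm)."""
    if sz_mm <= 1.0:
        return "z<=1"
    if sz_mm <= 3.0:
        return "1<z<=3"
    return "z>3"


@dataclasses.dataclass
class FoldAssignment:
    case_to_fold: dict[str, int]
    n_folds: int = 5

    def fold_of(self, case_id: str) -> int:
        return self.case_to_fold[case_id]

    def cases_in(self, fold: int) -> list[str]:
        return [c for c, f in self.case_to_fold.items() if f == fold]


def assign_folds(
    case_ids: Sequence[str],
    strata: dict[str, tuple],
    seed: int = 0,
    n_folds: int = 5,
) -> FoldAssignment:
    """Deterministic stratified k-fold case partition (per-stratum counts ±1)."""
    if len(case_ids) < n_folds:
        raise ValueError(f"need at least {n_folds} cases, got {len(case_ids)}")
    rng = np.random.default_rng(seed)
    by_stratum: dict[tuple, list[str]] = {}
    for cid in case_ids:
        by_stratum.setdefault(strata[cid], []).append(cid)
    assignment: dict[str, int] = {}
    offset = 0
    for key in sorted(by_stratum):
        members = sorted(by_stratum[key])
        rng.shuffle(members)
        for i, cid in enumerate(members):
            assignment[cid] = (offset + i) % n_folds
        offset += len(members)
    return FoldAssignment(assignment, n_folds)


# ---------------------------------------------------------------------------
# training recipe


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Classifier training recipe (BCE + Adam + augmentations + early stop)."""

    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    patience: int = 30
    max_epochs: int = 200
    n_augment: int = 2
    translation_frac: float = 0.1
    rotation_deg: float = 15.0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def early_stopping_loop(
    step_fn: Callable[[int], float],
    patience: int,
    max_epochs: int,
    on_improve: Optional[Callable[[int], None]] = None,
) -> list[float]:
    """Run ``step_fn(epoch)`` (returning a monitored loss) with early stopping.

    Stops after *patience* consecutive epochs without strict improvement;
    ``on_improve(epoch)`` fires whenever a new best loss is seen.  Returns
    the per-epoch loss curve (1-based epochs).
    """
    best = np.inf
    since_best = 0
    losses: list[float] = []
    for epoch in range(1, max_epochs + 1):
        loss = float(step_fn(epoch))
        losses.append(loss)
        if loss < best:
            best = loss
            since_best = 0
            if on_improve is not None:
                on_improve(epoch)
        else:
            since_best += 1
        if since_best >= patience:
            break
    return losses


def fit_mlp(
    X: np.ndarray,
    y: np.ndarray,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    hidden: tuple[int, ...] = (64,),
    lr: float = 1e-3,
    weight_decay: float = 1e-4,
    batch_size: int = 32,
    patience: int = 30,
    max_epochs: int = 200,
    seed: int = 0,
) -> tuple[MLPClassifier, list[float]]:
    """Mini-batch Adam training of a small MLP on binary cross-entropy.

    One epoch = one shuffled pass in batches of *batch_size* via
    ``partial_fit`` (which keeps Adam's moment state across epochs).  The
    monitored loss is validation log-loss when a validation set is given,
    else training log-loss; the best-loss weights are restored at the end.
    """
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    net = MLPClassifier(
        hidden_layer_sizes=hidden,
        solver="adam",
        learning_rate_init=lr,
        alpha=weight_decay,
        batch_size=min(batch_size, len(y)),
        random_state=seed,
        max_iter=1,
    )
    rng = np.random.default_rng(seed)
    bs = min(batch_size, len(y))
    Xm, ym = (X_val, y_val) if X_val is not None else (X, y)
    best_state: dict = {}

    def _snapshot(_epoch: int) -> None:
        best_state["coefs"] = [c.copy() for c in net.coefs_]
        best_state["intercepts"] = [b.copy() for b in net.intercepts_]

    def _epoch(_e: int) -> float:
        order = rng.permutation(len(y))
        for start in range(0, len(y), bs):
            idx = order[start:start + bs]
            net.batch_size = len(idx)  # one Adam update per mini-batch
            net.partial_fit(X[idx], y[idx], classes=classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return log_loss(ym, net.predict_proba(Xm)[:, 1], labels=classes)

    curve = early_stopping_loop(_epoch, patience, max_epochs, on_improve=_snapshot)
    if best_state:
        net.coefs_ = best_state["coefs"]
        net.intercepts_ = best_state["intercepts"]
    return net, curve


def _affine_pair(raw, mask, matrix, offset, order_raw=1):
    out_raw = ndimage.affine_transform(raw, matrix, offset=offset, order=order_raw, cval=0.0)
    out_mask = ndimage.affine_transform(
        mask.astype(np.float32), matrix, offset=offset, order=0, cval=0.0
    )
    return out_raw, out_mask


def augment_pair(
    pair: CandidatePatchPair, rng: np.random.Generator, cfg: TrainConfig = TrainConfig()
) -> CandidatePatchPair:
    """Random translation / flip / rotation / zoom / Gaussian noise on a patch pair."""
    raw = pair.raw.astype(np.float32)
    mask = pair.mask.astype(np.uint8)
    ndim = raw.ndim
    # translation (always)
    shift = rng.uniform(-cfg.translation_frac, cfg.translation_frac, size=ndim) * raw.shape
    raw = ndimage.shift(raw, shift, order=1, cval=0.0)
    mask = ndimage.shift(mask.astype(np.float32), shift, order=0, cval=0.0)
    # flips
    for axis in range(ndim):
        if rng.random() < 0.5:
            raw = np.flip(raw, axis)
            mask = np.flip(mask, axis)
    # in-plane rotation (first two axes), applied with probability 1/2
    if cfg.rotation_deg > 0 and rng.random() < 0.5:
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        raw = ndimage.rotate(raw, angle, axes=(0, 1), reshape=False, order=1, cval=0.0)
        mask = ndimage.rotate(
            mask.astype(np.float32), angle, axes=(0, 1), reshape=False, order=0, cval=0.0
        )
    # zoom about the center, applied with probability 1/2
    if rng.random() < 0.5:
        z = rng.uniform(*cfg.zoom_range)
        matrix = np.eye(ndim) / z
        center = (np.asarray(raw.shape) - 1) / 2.0
        offset = center - matrix.diagonal() * center
        raw, mask = _affine_pair(raw, mask, matrix, offset)
    if cfg.noise_sd > 0:
        raw = raw + rng.normal(0, cfg.noise_sd, raw.shape).astype(np.float32)
    raw = np.clip(raw, 0.0, 1.0)
    return CandidatePatchPair(raw, (mask > 0.5).astype(np.uint8), pair.geometry, dict(pair.meta))


def train_classifier(
    records: Sequence[CandidateRecord],
    patches: dict,
    cfg: TrainConfig,
    fold: FoldAssignment,
    fold_idx: int,
    geometry: str = "3D-crop",
    augmented: Optional[Sequence[tuple[str, CandidatePatchPair, int]]] = None,
) -> tuple[PooledPatchClassifier, list[float]]:
    """Train one classifier with fold *fold_idx* held out for early stopping.

    *geometry* selects which element of the (XPC, LVC) patch pair feeds the
    classifier: "2D-coronal" -> XPC view, "3D-crop" -> LVC view.  When a
    pre-built *augmented* pool of (case_id, pair, label) entries is given it
    is used (filtered to training-fold cases) instead of augmenting inline,
    so several folds can share one augmentation pass.
    """
    which = 0 if geometry == "2D-coronal" else 1
    train_recs = [r for r in records if fold.fold_of(r.case_id) != fold_idx]
    val_recs = [r for r in records if fold.fold_of(r.case_id) == fold_idx]
    if len({r.y for r in train_recs}) < 2:
        raise ValueError("training folds contain a single class; cannot train")
    rng = np.random.default_rng(cfg.seed)
    pairs = [patches[(r.case_id, r.label)][which] for r in train_recs]
    labels = [r.y for r in train_recs]
    aug_pairs = list(pairs)
    aug_labels = list(labels)
    if augmented is not None:
        for cid, p, lab in augmented:
            if fold.fold_of(cid) != fold_idx:
                aug_pairs.append(p)
                aug_labels.append(lab)
    else:
        for _ in range(cfg.n_augment):
            for p, lab in zip(pairs, labels):
                aug_pairs.append(augment_pair(p, rng, cfg))
                aug_labels.append(lab)
    val_pairs = [patches[(r.case_id, r.label)][which] for r in val_recs]
    val_labels = [r.y for r in val_recs]
    clf = PooledPatchClassifier(geometry, seed=cfg.seed)
    clf.fit(
        aug_pairs, aug_labels, val_pairs=val_pairs, val_labels=val_labels,
        lr=cfg.lr, weight_decay=cfg.weight_decay, batch_size=cfg.batch_size,
        patience=cfg.patience, max_epochs=cfg.max_epochs,
    )
    return clf, clf.curve_


# ---------------------------------------------------------------------------
# threshold tuning


@dataclasses.dataclass
class TuningCandidate:
    """Per-candidate quantities needed to replay the cascade at any thresholds."""

    case_index: int
    label: int
    size: int
    gt_intersection: int
    overlapping_gt: tuple[int, ...]  # global gt-lesion indices
    p_xpc: float
    p_lvc: float


@dataclasses.dataclass
class TuningData:
    candidates: list[TuningCandidate]
    gt_totals: np.ndarray  # per-case gt foreground voxel counts
    n_gt_lesions: int

    def evaluate(self, thr_e: float, thr_i: float) -> tuple[float, float]:
        """(mean image DSC, pooled lesion sensitivity) at the given thresholds."""
        n_cases = len(self.gt_totals)
        num = np.zeros(n_cases)
        den = self.gt_totals.astype(float).copy()
        detected = np.zeros(self.n_gt_lesions, dtype=bool)
        for c in self.candidates:
            keep = not (1.0 - c.p_xpc >= thr_e) and (c.p_lvc > thr_i)
            if keep:
                num[c.case_index] += 2.0 * c.gt_intersection
                den[c.case_index] += c.size
                for g in c.overlapping_gt:
                    detected[g] = True
        dscs = np.where(den > 0, num / np.maximum(den, 1e-12), 1.0)
        sens = detected.mean() if self.n_gt_lesions else float("nan")
        return float(dscs.mean()), float(sens)


def build_tuning_data(
    gt_masks: Sequence[InstanceMask],
    pred_masks: Sequence[InstanceMask],
    probs: dict[tuple[int, int], tuple[float, float]],
) -> TuningData:
    """Assemble cascade-replay data; *probs* maps (case_index, label) to
    out-of-fold (p_xpc, p_lvc) probabilities.  Candidates absent from
    *probs* (e.g. hard negatives not selected for training) are left out
    of the replay."""
    cands: list[TuningCandidate] = []
    gt_totals = []
    gt_offset = 0
    for ci, (gt, pred) in enumerate(zip(gt_masks, pred_masks)):
        gdata = np.asarray(gt.data)
        pdata = np.asarray(pred.data)
        gt_totals.append(int((gdata > 0).sum()))
        for label in range(1, pred.n_instances + 1):
            if (ci, label) not in probs:
                continue
            cand = pdata == label
            inter_labels = np.unique(gdata[cand])
            inter_labels = inter_labels[inter_labels > 0]
            p_x, p_l = probs[(ci, label)]
            cands.append(
                TuningCandidate(
                    ci, label, int(cand.sum()), int(((gdata > 0) & cand).sum()),
                    tuple(int(g) - 1 + gt_offset for g in inter_labels), p_x, p_l,
                )
            )
        gt_offset += gt.n_instances
    return TuningData(cands, np.asarray(gt_totals), gt_offset)


def select_best_and_tune_thresholds(
    fold_classifiers: dict[int, tuple],
    fold_aurocs: dict[int, tuple[float, float]],
    tuning: TuningData,
    grid_step: float = 0.01,
    sensitivity_tol: float = 0.01,
) -> tuple:
    """Pick the per-type best-AUROC classifiers and grid-tune (thr_e, thr_i).

    ``fold_aurocs[f] = (auroc_xpc, auroc_lvc)`` on fold *f*'s held-out
    candidates.  The exhaustive grid is {0, step, ..., 1}²; the objective is
    mean image-level Dice after the cascade subject to pooled lesion
    sensitivity >= (best achievable − *sensitivity_tol*); ties break toward
    higher sensitivity, then lower thr_i, then higher thr_e (the more
    conservative extrapulmonary gate).  When no grid
    point is feasible, pass-through sentinels are returned with a warning.
    """
    if not 0 < grid_step <= 1:
        raise ValueError("grid_step must lie in (0, 1]")
    def _key(v: float) -> float:  # undefined AUROC never wins
        return -1.0 if np.isnan(v) else v

    best_x = max(fold_aurocs, key=lambda f: (_key(fold_aurocs[f][0]), -f))
    best_l = max(fold_aurocs, key=lambda f: (_key(fold_aurocs[f][1]), -f))
    xpc = fold_classifiers[best_x][0]
    lvc = fold_classifiers[best_l][1]

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    results = []
    for thr_e in grid:
        for thr_i in grid:
            d, s = tuning.evaluate(float(thr_e), float(thr_i))
            results.append((float(thr_e), float(thr_i), d, s))
    best_sens = max(s for *_th, s in results)
    feasible = [r for r in results if r[3] >= best_sens - sensitivity_tol]
    if not feasible:
        warnings.warn("no feasible threshold grid point; returning pass-through sentinels")
        return xpc, lvc, PASS_THROUGH.thr_e, PASS_THROUGH.thr_i
    thr_e, thr_i, _d, _s = max(feasible, key=lambda r: (r[2], r[3], -r[1], r[0]))
    return xpc, lvc, thr_e, thr_i


def fold_validation_aurocs(
    records: Sequence[CandidateRecord],
    patches: dict,
    fold: FoldAssignment,
    classifiers: dict[int, tuple],
) -> dict[int, tuple[float, float]]:
    """Held-fold AUROCs (XPC on its subset, LVC on all candidates) per fold."""
    out = {}
    for f, (xpc, lvc) in classifiers.items():
        val = [r for r in records if fold.fold_of(r.case_id) == f]
        xval = subset_for_xpc(val)
        def _auc(clf, recs, which):
            ys = [r.y for r in recs]
            if len(set(ys)) < 2 or clf is None:
                return float("nan")
            ps = [clf.predict_prob(patches[(r.case_id, r.label)][which]) for r in recs]
            return float(roc_auc_score(ys, ps))
        out[f] = (_auc(xpc, xval, 0), _auc(lvc, val, 1))
    return out
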