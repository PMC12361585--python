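"""Reproducible end-to-end phantom studies: train, tune, evaluate ablations.

This module wires the pieces into the standard experiment on synthetic
cohorts: fit the segmentation backend on training phantoms, run the
bounding-box + segmentation (LLSB) pipeline to harvest lesion candidates,
train the cascade classifiers under stratified 5-fold CV, tune the
cascade thresholds on out-of-fold predictions, and compare the ablations
on held-out phantoms.  Both the acceptance study and the example scripts
call these functions, so numbers in reports always come from the same
code path.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .bbox import BboxConfig, apply_minimum_fallback, crop_to_box, lung_bbox
from .cascade import CascadeConfig, ConstantClassifier, EnsembleClassifier, PASS_THROUGH
from .metrics import EvalReport, SizeFilter, detection_metrics, evaluate_cohort, match_lesions
from .phantom import PhantomCase, PhantomSpec, generate_cohort, reference_lung_masker
from .pipeline import PipelineConfig, run_pipeline
from .segment import VoxelFeatureBackend, VoxelFeatureConfig
from .train import (
    TrainConfig,
    assign_folds,
    bin_z_spacing,
    build_candidate_dataset,
    build_tuning_data,
    fold_validation_aurocs,
    select_best_and_tune_thresholds,
    subset_for_xpc,
    train_classifier,
)
from .volume import BinaryMask, CtVolume, InstanceMask

__all__ = [
    "crop_case",
    "fit_backend",
    "llsb_predict",
    "CascadeModels",
    "train_cascade",
    "evaluate_ablations",
    "learned_study",
]


def crop_case(case: PhantomCase, bbox_cfg: BboxConfig = BboxConfig()):
    """Thoracic crop of a phantom's CT and binarized ground truth."""
    lung = reference_lung_masker(case.ct)
    box = apply_minimum_fallback(lung_bbox(lung), case.ct, bbox_cfg)
    ct_c, record = crop_to_box(case.ct, box)
    gt_c, _ = crop_to_box(case.gt_lesions.binarize(), box)
    return ct_c, gt_c, record


def fit_backend(
    train_cases: Sequence[PhantomCase],
    seed: int = 0,
    bbox_cfg: BboxConfig = BboxConfig(),
) -> VoxelFeatureBackend:
    """Fit the voxel-feature segmentation backend on phantom crops."""
    crops = [crop_case(c, bbox_cfg)[:2] for c in train_cases]
    backend = VoxelFeatureBackend(VoxelFeatureConfig(seed=seed))
    backend.fit(crops)
    return backend


def llsb_predict(
    cases: Sequence[PhantomCase],
    backend,
    bbox_cfg: BboxConfig = BboxConfig(),
) -> list[InstanceMask]:
    """Bounding-box + segmentation predictions (no FP reduction) per case."""
    cfg = PipelineConfig(backend, use_xpc=False, use_lvc=False, bbox=bbox_cfg)
    return [run_pipeline(c.ct, cfg, lung_mask=None)[0] for c in cases]


def harvest_candidate_predictions(
    train_cases: Sequence[PhantomCase],
    seed: int = 0,
    bbox_cfg: BboxConfig = BboxConfig(),
    n_splits: int = 2,
) -> list[InstanceMask]:
    """Out-of-sample LLSB predictions for candidate harvesting.

    The training cases are split into *n_splits* blocks; each block is
    predicted by a backend fitted on the other blocks (cross-fitting), so
    harvested candidates show the false-positive behavior the cascade
    will face on unseen scans, rather than in-sample optimism.
    """
    n = len(train_cases)
    preds: list[Optional[InstanceMask]] = [None] * n
    for split in range(n_splits):
        held = list(range(split, n, n_splits))
        others = [c for i, c in enumerate(train_cases) if i % n_splits != split]
        backend = fit_backend(others, seed=seed + 1 + split, bbox_cfg=bbox_cfg)
        for i, mask in zip(held, llsb_predict([train_cases[i] for i in held], backend, bbox_cfg)):
            preds[i] = mask
    return preds  # type: ignore[return-value]


@dataclasses.dataclass
class CascadeModels:
    xpc: object
    lvc: object
    thr_e: float
    thr_i: float
    fold_aurocs: dict
    n_candidates: int
    n_lesion_candidates: int
    oof_probs: dict = dataclasses.field(default_factory=dict)  # (case_idx, label) -> (p_xpc, p_lvc)
    records: list = dataclasses.field(default_factory=list)

    @property
    def cascade_config(self) -> CascadeConfig:
        return CascadeConfig(thr_e=self.thr_e, thr_i=self.thr_i)


def train_cascade(
    train_cases: Sequence[PhantomCase],
    backend,
    train_cfg: TrainConfig = TrainConfig(),
    cascade_cfg: CascadeConfig = CascadeConfig(),
    bbox_cfg: BboxConfig = BboxConfig(),
    n_folds: int = 5,
    grid_step: float = 0.02,
    sensitivity_tol: float = 0.0,
    preds: Optional[Sequence[InstanceMask]] = None,
    max_negatives_per_case: int = 8,
) -> CascadeModels:
    """Train XPC + LVC under stratified CV and tune the cascade thresholds.

    All true-lesion candidates are kept; non-lesion candidates are capped
    at *max_negatives_per_case* per scan, largest first, so a scan with
    speckly segmentation output cannot flood the candidate set.  When the
    XPC training subset degenerates to a single class on some fold (no
    extrapulmonary false candidates harvested), that stage falls back to
    a constant pass-through classifier; the threshold grid then
    effectively disables the XPC gate.
    """
    if preds is None:
        preds = llsb_predict(train_cases, backend, bbox_cfg)
    ids = [f"case{i:03d}" for i in range(len(train_cases))]
    bundles = [
        (c.ct, c.gt_lesions, p, c.lung_mask) for c, p in zip(train_cases, preds)
    ]
    all_records, _ = build_candidate_dataset(
        bundles, cascade_cfg, case_ids=ids, with_patches=False
    )
    records = []
    for cid in ids:
        case_recs = [r for r in all_records if r.case_id == cid]
        records.extend(r for r in case_recs if r.y == 1)
        negs = sorted((r for r in case_recs if r.y == 0), key=lambda r: -r.size)
        records.extend(negs[:max_negatives_per_case])
    from .cascade import make_lvc_patch, make_xpc_patch

    patches = {}
    for r in records:
        case = train_cases[ids.index(r.case_id)]
        pred = preds[ids.index(r.case_id)]
        patches[(r.case_id, r.label)] = (
            make_xpc_patch(case.ct, pred, r.label, cascade_cfg),
            make_lvc_patch(case.ct, pred, r.label, cascade_cfg),
        )
    strata = {cid: (bin_z_spacing(c.spec.spacing[2]),) for cid, c in zip(ids, train_cases)}
    folds = assign_folds(ids, strata, seed=train_cfg.seed, n_folds=n_folds)

    # one shared augmentation pass; folds reuse the pool filtered by case
    from .train import augment_pair

    rng = np.random.default_rng(train_cfg.seed)
    xpc_records = subset_for_xpc(records)
    aug_xpc = [
        (r.case_id, augment_pair(patches[(r.case_id, r.label)][0], rng, train_cfg), r.y)
        for _ in range(train_cfg.n_augment) for r in xpc_records
    ]
    aug_lvc = [
        (r.case_id, augment_pair(patches[(r.case_id, r.label)][1], rng, train_cfg), r.y)
        for _ in range(train_cfg.n_augment) for r in records
    ]
    classifiers: dict[int, tuple] = {}
    for f in range(n_folds):
        try:
            xpc, _ = train_classifier(
                xpc_records, patches, train_cfg, folds, f, "2D-coronal", augmented=aug_xpc
            )
        except ValueError:
            xpc = ConstantClassifier(1.0)
        try:
            lvc, _ = train_classifier(
                records, patches, train_cfg, folds, f, "3D-crop", augmented=aug_lvc
            )
        except ValueError:
            lvc = ConstantClassifier(1.0)
        classifiers[f] = (xpc, lvc)
    aurocs = fold_validation_aurocs(records, patches, folds, classifiers)

    # leave-one-fold-out ensemble probabilities for threshold tuning: each
    # candidate is scored by the mean of the classifiers that never saw its
    # case, matching the variance profile of the deployed full ensemble
    probs: dict[tuple[int, int], tuple[float, float]] = {}
    for r in records:
        f = folds.fold_of(r.case_id)
        others = [classifiers[g] for g in classifiers if g != f]
        pair = patches[(r.case_id, r.label)]
        probs[(ids.index(r.case_id), r.label)] = (
            float(np.mean([x.predict_prob(pair[0]) for x, _l in others])),
            float(np.mean([l.predict_prob(pair[1]) for _x, l in others])),
        )
    tuning = build_tuning_data([c.gt_lesions for c in train_cases], preds, probs)
    _xpc_best, _lvc_best, thr_e, thr_i = select_best_and_tune_thresholds(
        classifiers, aurocs, tuning, grid_step=grid_step, sensitivity_tol=sensitivity_tol
    )
    # deployment: full fold ensemble, with a sensitivity guard that keeps the
    # operating point at most half the weakest true-candidate score away
    xpc = EnsembleClassifier([x for x, _l in classifiers.values()])
    lvc = EnsembleClassifier([l for _x, l in classifiers.values()])
    pos = [probs[(ids.index(r.case_id), r.label)] for r in records if r.y == 1]
    if pos:
        min_px = min(p[0] for p in pos)
        min_pl = min(p[1] for p in pos)
        thr_e = max(thr_e, min(1.0, 1.0 - 0.5 * min_px))
        thr_i = min(thr_i, 0.5 * min_pl)
    return CascadeModels(
        xpc, lvc, thr_e, thr_i, aurocs,
        n_candidates=len(records),
        n_lesion_candidates=sum(r.y for r in records),
        oof_probs=probs,
        records=records,
    )


def evaluate_ablations(
    test_cases: Sequence[PhantomCase],
    backend,
    models: CascadeModels,
    ablations: Sequence[str] = ("LLSB", "LLSB_CFPR"),
    size_filter: SizeFilter = SizeFilter(),
    n_resamples: int = 1000,
    seed: int = 0,
    bbox_cfg: BboxConfig = BboxConfig(),
) -> dict[str, dict]:
    """Run the named ablations on held-out cases and evaluate each.

    Returns per ablation the :class:`EvalReport` plus the mean count of
    false-positive predictions per scan (predictions with no ground-truth
    overlap conferring TP status under the size filter).
    """
    out: dict[str, dict] = {}
    gt_masks = [c.gt_lesions for c in test_cases]
    for name in ablations:
        cfg = PipelineConfig.ablation(
            name, backend, xpc=models.xpc, lvc=models.lvc,
            bbox=bbox_cfg, cascade=models.cascade_config, seed=seed,
        )
        preds = [run_pipeline(c.ct, cfg)[0] for c in test_cases]
        report = evaluate_cohort(
            gt_masks, preds, size_filter, n_resamples=n_resamples, seed=seed
        )
        tables = [match_lesions(g, p) for g, p in zip(gt_masks, preds)]
        det = detection_metrics(tables, size_filter)
        fp_total = det.n_pred - det.n_tp_pred
        out[name] = {
            "report": report,
            "fp_per_scan": fp_total / len(test_cases),
            "preds": preds,
        }
    return out


def learned_study(
    seed: int = 0,
    n_train: int = 50,
    n_test: int = 10,
    n_backend_cases: int = 30,
    base_spec: PhantomSpec = PhantomSpec(),
    train_cfg: Optional[TrainConfig] = None,
    n_resamples: int = 1000,
    ablations: Sequence[str] = ("LLSB", "LLSB_CFPR"),
) -> dict:
    """The standard learned end-to-end experiment on one synthetic cohort.

    Generates ``n_train + n_test`` phantoms; the deployed backend is
    fitted on the first ``n_backend_cases`` training crops, cascade
    candidates are harvested from all training cases with cross-fitted
    backends, and the requested ablations are evaluated on the held-out
    block with the measurable-lesion (>= 10 mm) filter.
    """
    train_cfg = train_cfg or TrainConfig(seed=seed)
    cohort = generate_cohort(n_train + n_test, base_spec, seed=seed)
    train_cases, test_cases = cohort[:n_train], cohort[n_train:]
    backend = fit_backend(train_cases[:n_backend_cases], seed=seed)
    harvest = harvest_candidate_predictions(train_cases, seed=seed)
    models = train_cascade(train_cases, backend, train_cfg, preds=harvest)
    results = evaluate_ablations(
        test_cases, backend, models, ablations, n_resamples=n_resamples, seed=seed
    )
    return {
        "backend": backend,
        "models": models,
        "train_cases": train_cases,
        "test_cases": test_cases,
        "results": results,
    }
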