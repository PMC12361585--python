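"""Candidate datasets, stratified folds, training recipe, threshold tuning."""

import numpy as np
import pytest

from llseg.cascade import CandidatePatchPair, PooledPatchClassifier
from llseg.train import (
    CandidateRecord,
    TrainConfig,
    TuningCandidate,
    TuningData,
    assign_folds,
    augment_pair,
    bin_z_spacing,
    build_candidate_dataset,
    build_tuning_data,
    early_stopping_loop,
    fit_mlp,
    select_best_and_tune_thresholds,
    subset_for_xpc,
    train_classifier,
)
from llseg.volume import BinaryMask, CtVolume, InstanceMask

from conftest import as_binary, as_instance, as_volume


# ---------------------------------------------------------------------------
# candidate labeling


def _toy_case():
    """One scan: gt lesion inside the lung, pred with one TP and two FPs."""
    shape = (24, 24, 24)
    ct = as_volume(np.full(shape, -1000.0))
    lung = np.zeros(shape, dtype=np.uint8)
    lung[4:20, 4:20, 4:20] = 1
    gt = np.zeros(shape, dtype=np.uint16)
    gt[8:12, 8:12, 8:12] = 1
    pred = np.zeros(shape, dtype=np.uint16)
    pred[8:12, 8:12, 8:12] = 1     # matches gt, fully inside lung
    pred[14:16, 14:16, 14:16] = 2  # FP inside lung
    pred[0:2, 0:2, 0:2] = 3        # FP fully outside lung
    return ct, as_instance(gt), as_instance(pred), as_binary(lung)


class TestBuildCandidateDataset:
    def test_labels_and_location_tags(self):
        records, patches = build_candidate_dataset([_toy_case()])
        by_label = {r.label: r for r in records}
        assert by_label[1].y == 1 and by_label[1].location == "intrapulmonary"
        assert by_label[2].y == 0 and by_label[2].location == "intrapulmonary"
        assert by_label[3].y == 0 and by_label[3].location == "extrapulmonary"
        assert by_label[1].max_dsc == pytest.approx(1.0)
        assert len(patches) == 3

    def test_idempotent_labeling(self):
        a, _ = build_candidate_dataset([_toy_case()], with_patches=False)
        b, _ = build_candidate_dataset([_toy_case()], with_patches=False)
        assert [(r.label, r.y, r.location) for r in a] == [(r.label, r.y, r.location) for r in b]

    def test_partial_tag_for_wall_straddling_candidate(self):
        ct, gt, pred, lung = _toy_case()
        data = np.asarray(pred.data).copy()
        data[data == 3] = 0
        data[18:22, 8:10, 8:10] = 3  # straddles the lung boundary at x=20
        records, _ = build_candidate_dataset(
            [(ct, gt, InstanceMask(data, pred.spacing), lung)], with_patches=False
        )
        assert {r.label: r.location for r in records}[3] == "partial"

    def test_patches_materialized_to_disk(self, tmp_path):
        records, _ = build_candidate_dataset([_toy_case()], patch_dir=tmp_path)
        assert all(r.patch_file and (tmp_path / r.patch_file.split("/")[-1]).exists()
                   for r in records)


class TestSubsetForXpc:
    def test_rule_enumeration(self):
        recs = [
            CandidateRecord("c", 1, 0, "intrapulmonary", 0.0),
            CandidateRecord("c", 2, 0, "extrapulmonary", 0.0),
            CandidateRecord("c", 3, 0, "partial", 0.0),
            CandidateRecord("c", 4, 1, "partial", 0.5),
            CandidateRecord("c", 5, 1, "intrapulmonary", 0.9),
        ]
        kept = {r.label for r in subset_for_xpc(recs)}
        assert kept == {2, 4, 5}  # extrapulmonary non-lesions + all lesions


class TestAssignFolds:
    def test_single_stratum_balanced(self):
        ids = [f"c{i}" for i in range(10)]
        folds = assign_folds(ids, {i: ("a",) for i in ids}, seed=1)
        sizes = [len(folds.cases_in(f)) for f in range(5)]
        assert sizes == [2, 2, 2, 2, 2]

    def test_two_strata_of_five(self):
        ids = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        strata = {i: (i[0],) for i in ids}
        folds = assign_folds(ids, strata, seed=2)
        for f in range(5):
            members = folds.cases_in(f)
            assert len(members) == 2
            assert {m[0] for m in members} == {"a", "b"}

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(13)]
        strata = {i: (bin_z_spacing(0.5 + int(i[1:]) % 4),) for i in ids}
        assert assign_folds(ids, strata, seed=9).case_to_fold == \
            assign_folds(ids, strata, seed=9).case_to_fold

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            assign_folds(["a", "b"], {"a": (1,), "b": (1,)}, seed=0)

    def test_candidates_inherit_case_fold(self):
        records, _ = build_candidate_dataset([_toy_case()], case_ids=["k"],
                                             with_patches=False)
        ids = ["k"] + [f"c{i}" for i in range(6)]
        folds = assign_folds(ids, {i: ("s",) for i in ids}, seed=0)
        fold_of_case = folds.fold_of("k")
        assert all(folds.fold_of(r.case_id) == fold_of_case for r in records)

    def test_z_spacing_bins(self):
        assert bin_z_spacing(0.8) == "z<=1"
        assert bin_z_spacing(2.5) == "1<z<=3"
        assert bin_z_spacing(4.0) == "z>3"


class TestEarlyStopping:
    def test_monotonically_worsening_stops_after_patience(self):
        losses = early_stopping_loop(lambda e: float(e), patience=30, max_epochs=500)
        assert len(losses) == 31  # epoch 1 is best; 30 worsening epochs then stop

    def test_improving_runs_to_max(self):
        losses = early_stopping_loop(lambda e: -float(e), patience=30, max_epochs=40)
        assert len(losses) == 40

    def test_on_improve_reports_best_epochs(self):
        seen = []
        curve = {1: 5.0, 2: 3.0, 3: 4.0, 4: 2.0, 5: 2.5, 6: 2.6}
        early_stopping_loop(lambda e: curve[e], patience=2, max_epochs=6,
                            on_improve=seen.append)
        assert seen == [1, 2, 4]


class TestFitMlp:
    def _separable(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(-1.0, 0.4, (n // 2, 6))
        X1 = rng.normal(1.0, 0.4, (n // 2, 6))
        X = np.vstack([X0, X1]).astype(np.float32)
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_loss_decreases_over_first_epochs(self):
        X, y = self._separable()
        _net, curve = fit_mlp(X, y, max_epochs=5, patience=30, seed=1)
        assert curve[-1] < curve[0]

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_mlp(X, np.zeros(10, dtype=int))


def _synthetic_pairs(n_cases=10, per_case=6, seed=0):
    """Separable-by-construction 2D patch pairs: lesion blob vs empty raw."""
    rng = np.random.default_rng(seed)
    records, patches = [], {}
    for ci in range(n_cases):
        cid = f"case{ci}"
        for k in range(per_case):
            y = k % 2
            raw = rng.uniform(0, 0.1, (128, 128)).astype(np.float32)
            mask = np.zeros((128, 128), dtype=np.uint8)
            mask[40:60, 40:60] = 1
            if y:
                raw[40:60, 40:60] += 0.8
            raw = np.clip(raw, 0, 1)
            pair = CandidatePatchPair(raw, mask, "2D-coronal", {"label": k + 1})
            records.append(CandidateRecord(cid, k + 1, y, "partial", float(y), 400))
            patches[(cid, k + 1)] = (pair, pair)
    return records, patches


class TestTrainClassifier:
    def test_separable_patches_reach_high_auroc(self):
        from sklearn.metrics import roc_auc_score

        records, patches = _synthetic_pairs()
        ids = sorted({r.case_id for r in records})
        folds = assign_folds(ids, {i: ("s",) for i in ids}, seed=0)
        cfg = TrainConfig(seed=0, max_epochs=60, n_augment=1)
        clf, curve = train_classifier(records, patches, cfg, folds, 0, "2D-coronal")
        val = [r for r in records if folds.fold_of(r.case_id) == 0]
        probs = [clf.predict_prob(patches[(r.case_id, r.label)][0]) for r in val]
        assert roc_auc_score([r.y for r in val], probs) >= 0.95
        assert len(curve) >= 1

    def test_single_class_training_folds_rejected(self):
        records, patches = _synthetic_pairs(n_cases=6)
        for r in records:
            r.y = 1
        ids = sorted({r.case_id for r in records})
        folds = assign_folds(ids, {i: ("s",) for i in ids}, seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(records, patches, TrainConfig(seed=0), folds, 0, "2D-coronal")


class TestAugmentPair:
    def test_shapes_and_ranges_preserved(self, rng):
        raw = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        mask = (rng.random((64, 64)) < 0.1).astype(np.uint8)
        pair = CandidatePatchPair(raw, mask, "2D-coronal")
        out = augment_pair(pair, rng, TrainConfig())
        assert out.raw.shape == raw.shape and out.mask.shape == mask.shape
        assert 0.0 <= out.raw.min() and out.raw.max() <= 1.0
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_3d_pair_supported(self, rng):
        raw = rng.uniform(0, 1, (32, 32, 32)).astype(np.float32)
        mask = np.zeros((32, 32, 32), dtype=np.uint8)
        mask[10:16, 10:16, 10:16] = 1
        out = augment_pair(CandidatePatchPair(raw, mask, "3D-crop"), rng, TrainConfig())
        assert out.raw.shape == (32, 32, 32)


class TestSelectAndTune:
    def _tuning(self, probs_by_y):
        """Two cases, two candidates each: one TP (y=1) and one FP (y=0)."""
        cands = []
        gt_totals = np.array([100, 100])
        for ci in range(2):
            for label, y in ((1, 1), (2, 0)):
                p_x, p_l = probs_by_y[y]
                cands.append(TuningCandidate(
                    ci, label, 100, 100 if y else 0,
                    (ci,) if y else (), p_x, p_l,
                ))
        return TuningData(cands, gt_totals, 2)

    def test_oracle_probabilities_remove_fps_keep_tps(self):
        tuning = self._tuning({1: (1.0, 1.0), 0: (0.0, 0.0)})
        fold_clfs = {0: ("xpc0", "lvc0"), 1: ("xpc1", "lvc1")}
        aurocs = {0: (0.9, 0.8), 1: (0.95, 0.99)}
        xpc, lvc, thr_e, thr_i = select_best_and_tune_thresholds(
            fold_clfs, aurocs, tuning, grid_step=0.1
        )
        assert (xpc, lvc) == ("xpc1", "lvc1")  # highest AUROC per type
        d, s = tuning.evaluate(thr_e, thr_i)
        assert s == 1.0 and d == 1.0  # all TPs kept, all FPs dropped

    def test_vacuous_constraint_returns_unconstrained_optimum(self):
        tuning = self._tuning({1: (1.0, 0.9), 0: (1.0, 0.4)})
        _x, _l, thr_e, thr_i = select_best_and_tune_thresholds(
            {0: (None, None)}, {0: (0.5, 0.5)}, tuning,
            grid_step=0.1, sensitivity_tol=1.0,
        )
        d_at_choice, _ = tuning.evaluate(thr_e, thr_i)
        best_d = max(
            tuning.evaluate(te / 10, ti / 10)[0]
            for te in range(11) for ti in range(11)
        )
        assert d_at_choice == pytest.approx(best_d)

    def test_coarse_grid_stays_on_grid(self):
        tuning = self._tuning({1: (1.0, 1.0), 0: (0.0, 0.0)})
        _x, _l, thr_e, thr_i = select_best_and_tune_thresholds(
            {0: (None, None)}, {0: (0.5, 0.5)}, tuning, grid_step=0.5
        )
        assert thr_e in (0.0, 0.5, 1.0) and thr_i in (0.0, 0.5, 1.0)

    def test_tuned_thresholds_satisfy_sensitivity_constraint(self):
        tuning = self._tuning({1: (0.9, 0.6), 0: (0.7, 0.3)})
        _x, _l, thr_e, thr_i = select_best_and_tune_thresholds(
            {0: (None, None)}, {0: (0.5, 0.5)}, tuning, grid_step=0.05,
        )
        best_sens = max(
            tuning.evaluate(te * 0.05, ti * 0.05)[1]
            for te in range(21) for ti in range(21)
        )
        _d, s = tuning.evaluate(thr_e, thr_i)
        assert s >= best_sens - 0.01

    def test_bad_grid_step_rejected(self):
        with pytest.raises(ValueError):
            select_best_and_tune_thresholds(
                {0: (None, None)}, {0: (0.5, 0.5)},
                self._tuning({1: (1, 1), 0: (0, 0)}), grid_step=0.0,
            )


class TestBuildTuningData:
    def test_replay_matches_mask_arithmetic(self):
        gt = np.zeros((12, 12, 12), dtype=np.uint16)
        gt[2:6, 2:6, 2:6] = 1
        pred = np.zeros_like(gt)
        pred[2:6, 2:6, 2:6] = 1
        pred[8:10, 8:10, 8:10] = 2
        probs = {(0, 1): (1.0, 1.0), (0, 2): (1.0, 0.0)}
        tuning = build_tuning_data([as_instance(gt)], [as_instance(pred)], probs)
        dsc_all, sens_all = tuning.evaluate(1.01, -0.01)  # keep everything
        n_gt, n_tp, n_fp = 64, 64, 8
        assert dsc_all == pytest.approx(2 * n_tp / (n_gt + n_tp + n_fp))
        assert sens_all == 1.0
        dsc_cut, sens_cut = tuning.evaluate(1.01, 0.5)  # drop the FP candidate
        assert dsc_cut == pytest.approx(1.0)
        assert sens_cut == 1.0
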