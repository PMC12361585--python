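"""Evaluation protocol: Dice, Hd-95, diameters, matching, pooling, bootstrap."""

import numpy as np
import pytest

from llseg.metrics import (
    SizeFilter,
    axial_diameter,
    bootstrap_ci,
    detection_metrics,
    dsc,
    froc,
    hd95,
    match_lesions,
    segmentation_metrics,
    volume_agreement,
)
from llseg.volume import InstanceMask

from conftest import as_instance


# ---------------------------------------------------------------------------
# independent oracles


def dsc_set_oracle(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(p) for p in np.argwhere(a)}
    sb = {tuple(p) for p in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def surface_points_oracle(mask: np.ndarray, spacing) -> np.ndarray:
    """Face-neighbor surface definition re-implemented with explicit loops."""
    pts = []
    for p in np.argwhere(mask):
        on_surface = False
        for axis in range(3):
            for d in (-1, 1):
                q = p.copy()
                q[axis] += d
                if not (0 <= q[axis] < mask.shape[axis]) or not mask[tuple(q)]:
                    on_surface = True
        if on_surface:
            pts.append(p * np.asarray(spacing))
    return np.asarray(pts)


def hd95_pairwise_oracle(a, b, spacing) -> float:
    pa = surface_points_oracle(a, spacing)
    pb = surface_points_oracle(b, spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


def random_blob(rng, shape=(14, 14, 14), density=0.08):
    m = rng.random(shape) < density
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


class TestDsc:
    def test_identical_sets(self, rng):
        a = random_blob(rng)
        assert dsc(a, a) == 1.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = a[0, 0, 1] = True
        b[0, 0, 1] = b[0, 0, 2] = True
        assert dsc(a, b) == pytest.approx(0.5)

    def test_random_pairs_match_set_oracle(self, rng):
        for _ in range(30):
            a, b = random_blob(rng), random_blob(rng)
            assert dsc(a, b) == pytest.approx(dsc_set_oracle(a, b))

    def test_symmetric(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        assert dsc(a, b) == dsc(b, a)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))


class TestHd95:
    def test_identical_sets_zero(self, rng):
        a = random_blob(rng)
        assert hd95(a, a, (1.0, 1.5, 2.0)) == 0.0

    def test_two_voxels_one_axis(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        b[0, 0, 3] = True
        assert hd95(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_random_sets_match_pairwise_oracle(self, rng):
        spacing = (1.0, 1.3, 2.1)
        for _ in range(20):
            a, b = random_blob(rng), random_blob(rng)
            assert hd95(a, b, spacing) == pytest.approx(
                hd95_pairwise_oracle(a, b, spacing), abs=1e-9
            )

    def test_symmetric(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        sp = (1.0, 1.0, 2.0)
        assert hd95(a, b, sp) == pytest.approx(hd95(b, a, sp))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            hd95(np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool), (1, 1, 1))


class TestAxialDiameter:
    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert axial_diameter(m, (1, 1, 1)) == 0.0

    def test_in_plane_line(self):
        m = np.zeros((15, 3, 3), bool)
        m[0:11, 0, 0] = True
        assert axial_diameter(m, (1.0, 1.0, 5.0)) == pytest.approx(10.0)

    def test_digitized_sphere(self):
        xs = np.arange(24) - 11.5
        d2 = xs[:, None, None] ** 2 + xs[None, :, None] ** 2 + xs[None, None, :] ** 2
        sphere = d2 <= 10.0**2  # 20 mm sphere at 1 mm iso
        assert 18.0 <= axial_diameter(sphere, (1, 1, 1)) <= 21.0

    def test_brute_force_on_random_blob(self, rng):
        m = random_blob(rng, (8, 8, 4), 0.3)
        sx, sy = 1.2, 0.9
        best = 0.0
        for z in range(m.shape[2]):
            pts = np.argwhere(m[:, :, z]).astype(float) * (sx, sy)
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    best = max(best, float(np.linalg.norm(pts[i] - pts[j])))
        assert axial_diameter(m, (sx, sy, 3.0)) == pytest.approx(best)


class TestMatchLesions:
    def test_disjoint_masks(self):
        gt = np.zeros((8, 8, 8), dtype=np.uint16)
        pred = np.zeros_like(gt)
        gt[0:2, 0:2, 0:2] = 1
        pred[5:7, 5:7, 5:7] = 1
        table = match_lesions(as_instance(gt), as_instance(pred))
        assert table.pairs == {}
        assert table.tp_pred_labels(SizeFilter(0)) == set()

    def test_identical_masks_match_one_to_one(self):
        gt = np.zeros((10, 10, 10), dtype=np.uint16)
        gt[0:3, 0:3, 0:3] = 1
        gt[6:9, 6:9, 6:9] = 2
        table = match_lesions(as_instance(gt), as_instance(gt))
        assert set(table.pairs) == {(1, 1), (2, 2)}
        assert all(st.dsc == 1.0 and st.hd95 == 0.0 for st in table.pairs.values())

    def test_one_pred_spanning_two_gt(self):
        gt = np.zeros((9, 3, 3), dtype=np.uint16)
        gt[0:3, 0, 0] = 1
        gt[6:9, 0, 0] = 2
        pred = np.zeros_like(gt)
        pred[0:9, 0, 0] = 1
        table = match_lesions(as_instance(gt), as_instance(pred))
        assert set(table.pairs) == {(1, 1), (2, 1)}
        det = detection_metrics([table], SizeFilter(0))
        assert det.n_tp_pred == 1  # the spanning prediction counts once
        assert det.recall == 1.0   # both gt lesions detected


class TestDetectionMetrics:
    def test_perfect(self):
        gt = np.zeros((8, 8, 8), dtype=np.uint16)
        gt[0:3, 0:3, 0:3] = 1
        t = match_lesions(as_instance(gt), as_instance(gt))
        det = detection_metrics([t], SizeFilter(0))
        assert det.precision == det.recall == det.f1 == 1.0

    def test_pooled_arithmetic(self):
        """3 gt, 2 detected; 4 pred of which 2 overlap: R=2/3, P=1/2."""
        gt = np.zeros((30, 6, 6), dtype=np.uint16)
        pred = np.zeros_like(gt)
        for i, lab in enumerate((1, 2, 3)):
            gt[i * 10:i * 10 + 3, 0:3, 0:3] = lab
        pred[0:3, 0:3, 0:3] = 1          # hits gt 1
        pred[10:13, 0:3, 0:3] = 2        # hits gt 2
        pred[0:2, 4:6, 4:6] = 3          # miss
        pred[25:27, 4:6, 4:6] = 4        # miss
        det = detection_metrics(
            [match_lesions(as_instance(gt), as_instance(pred))], SizeFilter(0)
        )
        assert det.recall == pytest.approx(2 / 3)
        assert det.precision == pytest.approx(1 / 2)
        assert det.f1 == pytest.approx(2 * 0.5 * (2 / 3) / (0.5 + 2 / 3))

    def test_random_cohorts_match_counting_oracle(self, rng):
        from llseg.segment import label_instances
        from llseg.volume import BinaryMask

        def random_instances(n_blobs):
            data = np.zeros((14, 14, 14), dtype=np.uint8)
            for _ in range(n_blobs):
                p = rng.integers(0, 11, 3)
                data[p[0]:p[0] + 3, p[1]:p[1] + 3, p[2]:p[2] + 3] = 1
            return label_instances(BinaryMask(data, (1.0, 1.0, 1.0)))

        for _ in range(8):
            tables = []
            n_gt = n_det = n_pred = n_tp = 0
            for _case in range(3):
                gt = random_instances(int(rng.integers(0, 3)))
                pred = random_instances(int(rng.integers(0, 4)))
                tables.append(match_lesions(gt, pred))
                gdata = np.asarray(gt.data)
                pdata = np.asarray(pred.data)
                n_gt += gt.n_instances
                n_pred += pred.n_instances
                for g in range(1, gt.n_instances + 1):
                    if (pdata[gdata == g] > 0).any():
                        n_det += 1
                for p in range(1, pred.n_instances + 1):
                    if (gdata[pdata == p] > 0).any():
                        n_tp += 1
            det = detection_metrics(tables, SizeFilter(0))
            if n_gt:
                assert det.recall == pytest.approx(n_det / n_gt)
            if n_pred:
                assert det.precision == pytest.approx(n_tp / n_pred)

    def test_size_filter_excludes_small_gt(self):
        gt = np.zeros((30, 8, 8), dtype=np.uint16)
        gt[0:12, 0:4, 0:4] = 1    # ~11 mm at 1 mm spacing: measurable
        gt[20, 6, 6] = 2          # single voxel: below 10 mm
        pred = np.zeros_like(gt)
        pred[20, 6, 6] = 1        # hits only the small lesion
        t = match_lesions(as_instance(gt), as_instance(pred))
        det = detection_metrics([t], SizeFilter(10.0))
        assert det.n_gt == 1          # small lesion out of the denominator
        assert det.recall == 0.0
        assert det.precision == 0.0   # small gt does not confer TP status
        det_all = detection_metrics([t], SizeFilter(0.0))
        assert det_all.n_gt == 2 and det_all.recall == pytest.approx(0.5)


class TestSegmentationMetrics:
    def test_perfect_prediction(self):
        gt = np.zeros((10, 10, 10), dtype=np.uint16)
        gt[0:4, 0:4, 0:4] = 1
        t = match_lesions(as_instance(gt), as_instance(gt))
        seg = segmentation_metrics([t], SizeFilter(0))
        assert (seg.dsc_image, seg.dsc_lesion, seg.hd95_lesion) == (1.0, 1.0, 0.0)

    def test_best_dsc_selected_per_lesion(self):
        gt = np.zeros((20, 10, 4), dtype=np.uint16)
        gt[0:10, 0:4, 0:2] = 1
        pred = np.zeros_like(gt)
        pred[0:10, 0:3, 0:2] = 1   # strong match
        pred[0:2, 3:4, 0:2] = 2    # weak second match
        t = match_lesions(as_instance(gt), as_instance(pred))
        seg = segmentation_metrics([t], SizeFilter(0))
        assert seg.dsc_lesion == pytest.approx(max(st.dsc for st in t.pairs.values()))

    def test_three_case_toy_cohort_hand_computed(self):
        tables = []
        # case 1: exact match of one 3-voxel lesion
        gt = np.zeros((9, 3, 3), dtype=np.uint16)
        gt[0:3, 0, 0] = 1
        tables.append(match_lesions(as_instance(gt), as_instance(gt)))
        # case 2: half-overlap: gt 4 voxels, pred 4 voxels, intersection 2
        gt2 = np.zeros((9, 3, 3), dtype=np.uint16)
        pred2 = np.zeros_like(gt2)
        gt2[0:4, 0, 0] = 1
        pred2[2:6, 0, 0] = 1
        tables.append(match_lesions(as_instance(gt2), as_instance(pred2)))
        # case 3: one missed lesion, no predictions
        gt3 = np.zeros((9, 3, 3), dtype=np.uint16)
        gt3[0:3, 0, 0] = 1
        pred3 = np.zeros_like(gt3)
        tables.append(match_lesions(as_instance(gt3), as_instance(pred3)))
        seg = segmentation_metrics(tables, SizeFilter(0))
        assert seg.dsc_image == pytest.approx((1.0 + 0.5 + 0.0) / 3)
        assert seg.dsc_lesion == pytest.approx((1.0 + 0.5 + 0.0) / 3)
        assert seg.n_unmatched_gt == 1

    def test_lesion_free_case_with_empty_prediction_flagged(self):
        empty = as_instance(np.zeros((5, 5, 5), dtype=np.uint16))
        t = match_lesions(empty, empty)
        seg = segmentation_metrics([t], SizeFilter(0))
        assert seg.dsc_image == 1.0
        assert seg.n_empty_image_pairs == 1

    def test_invariant_to_instance_relabeling(self, rng):
        gt = np.zeros((14, 14, 14), dtype=np.uint16)
        gt[0:3, 0:3, 0:3] = 1
        gt[6:9, 6:9, 6:9] = 2
        gt[11:13, 0:2, 0:2] = 3
        pred = np.roll(gt, 1, axis=0)
        swapped = np.zeros_like(gt)
        for old, new in ((1, 3), (2, 1), (3, 2)):
            swapped[gt == old] = new
        t1 = match_lesions(as_instance(gt), as_instance(pred))
        t2 = match_lesions(as_instance(swapped), as_instance(pred))
        for f in (SizeFilter(0), SizeFilter(2.5)):
            a, b = detection_metrics([t1], f), detection_metrics([t2], f)
            assert (a.f1, a.precision, a.recall) == (b.f1, b.precision, b.recall)
            sa, sb = segmentation_metrics([t1], f), segmentation_metrics([t2], f)
            assert sa.dsc_image == pytest.approx(sb.dsc_image)
            assert sa.dsc_lesion == pytest.approx(sb.dsc_lesion)


class TestFroc:
    def _cohort(self):
        gt = np.zeros((20, 6, 6), dtype=np.uint16)
        gt[0:4, 0:4, 0:4] = 1
        pred = np.zeros_like(gt)
        pred[0:4, 0:4, 0:4] = 1    # TP candidate
        pred[10:12, 0:2, 0:2] = 2  # FP candidate
        table = match_lesions(as_instance(gt), as_instance(pred))
        return [table], [{1: 0.9, 2: 0.2}]

    def test_extreme_points(self):
        tables, scores = self._cohort()
        points = froc(tables, scores, SizeFilter(0))
        assert points[-1] == (1.0, 1.0)   # keep everything
        assert (0.0, 0.0) in points       # threshold above all scores

    def test_separable_scores_reach_full_sensitivity_at_zero_fp(self):
        tables, scores = self._cohort()
        points = froc(tables, scores, SizeFilter(0))
        assert (0.0, 1.0) in points

    def test_requires_scores(self):
        tables, _ = self._cohort()
        with pytest.raises(ValueError):
            froc(tables, [{}], SizeFilter(0))


class TestVolumeAgreement:
    def test_identity(self):
        pairs = [(0.1, 0.1), (0.2, 0.2), (0.4, 0.4)]
        va = volume_agreement(pairs)
        assert va.r2 == pytest.approx(1.0)
        assert va.bias == pytest.approx(0.0)
        assert (va.loa_low, va.loa_high) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_constant_offset(self):
        pairs = [(g + 0.05, g) for g in (0.1, 0.2, 0.4, 0.8)]
        va = volume_agreement(pairs)
        assert va.r2 == pytest.approx(1.0)
        assert va.bias == pytest.approx(0.05)
        assert va.loa_high - va.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_random_pairs_match_formula_oracle(self, rng):
        gt = rng.uniform(0.05, 1.0, 12)
        pred = gt + rng.normal(0, 0.08, 12)
        va = volume_agreement(list(zip(pred, gt)))
        slope, intercept = np.polyfit(gt, pred, 1)
        fitted = slope * gt + intercept
        ss_res = ((pred - fitted) ** 2).sum()
        ss_tot = ((pred - pred.mean()) ** 2).sum()
        assert va.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)
        diff = pred - gt
        assert va.bias == pytest.approx(diff.mean(), abs=1e-12)
        assert va.loa_low == pytest.approx(diff.mean() - 1.96 * diff.std(), abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            volume_agreement([(0.1, 0.1), (0.2, 0.2)])

    def test_zero_gt_variance(self):
        with pytest.raises(ValueError):
            volume_agreement([(0.1, 0.2), (0.15, 0.2), (0.3, 0.2)])


class TestBootstrap:
    def test_constant_metric_collapses(self):
        mean, (lo, hi) = bootstrap_ci(lambda cs: 0.7, list(range(10)), 200, seed=1)
        assert mean == lo == hi == 0.7

    def test_seed_determinism(self):
        cases = list(np.random.default_rng(3).normal(0, 1, 20))
        a = bootstrap_ci(np.mean, cases, 300, seed=5)
        b = bootstrap_ci(np.mean, cases, 300, seed=5)
        assert a == b

    def test_interval_orders_and_brackets(self):
        cases = list(np.random.default_rng(4).normal(2.0, 0.5, 40))
        mean, (lo, hi) = bootstrap_ci(np.mean, cases, 500, seed=2)
        assert lo <= mean <= hi
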