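"""Multi-lesion detection and segmentation evaluation.

Detection follows an overlap rule: a predicted lesion is a true positive
iff it overlaps some ground-truth lesion (pairwise Dice > 0); a ground
truth lesion is detected iff some prediction overlaps it; false positives
and false negatives are the overlap-free remainders.  Detection metrics
are pooled over all lesions across scans (micro-average); image-level
Dice is a per-scan macro-average.

A RECIST-style size filter restricts the analysis to measurable ground
truth lesions (axial diameter >= ``min_diameter_mm``, default 10 mm).
Lesions below the cutoff leave recall's denominator and do not confer
true-positive status on predictions; predictions themselves are never
size-filtered.

Lesion-level Dice takes, per ground-truth lesion, the highest pairwise
Dice among its matches (0 when unmatched); lesion-level Hd-95 the lowest
pairwise Hd-95 among matches, averaged over matched lesions only — the two
optima may come from different predictions.

Uncertainty is estimated by bootstrapping scans with replacement.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .volume import InstanceMask, check_congruent

__all__ = [
    "SizeFilter",
    "PairStats",
    "MatchTable",
    "DetectionMetrics",
    "SegmentationMetrics",
    "VolumeAgreement",
    "EvalReport",
    "dsc",
    "hd95",
    "axial_diameter",
    "match_lesions",
    "detection_metrics",
    "segmentation_metrics",
    "froc",
    "volume_agreement",
    "bootstrap_ci",
    "evaluate_cohort",
]


# ---------------------------------------------------------------------------
# primitive metrics


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two boolean grids.

    Both-empty pairs score 1.0 by convention (callers flag this case).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface_points_mm(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Physical coordinates of surface voxels (foreground with a face-adjacent
    background neighbor, or on the array border)."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surf = mask & ~eroded
    return np.argwhere(surf) * np.asarray(spacing, dtype=float)


def hd95(a: np.ndarray, b: np.ndarray, spacing: Sequence[float]) -> float:
    """95th-percentile symmetric surface distance (mm) between two masks.

    Pools the directed surface distances in both directions and takes the
    95th percentile; anisotropic spacing is honored.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("hd95 undefined for an empty mask")
    pa = _surface_points_mm(a, spacing)
    pb = _surface_points_mm(b, spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def axial_diameter(lesion, spacing: Sequence[float]) -> float:
    """Maximum in-plane (axial, constant-z) Feret diameter in mm.

    *lesion* is a boolean 3D array or an (N, 3) array of voxel indices.
    Distances are between voxel centers, so a single voxel has diameter 0.
    """
    idx = np.argwhere(lesion) if np.asarray(lesion).ndim == 3 else np.asarray(lesion)
    if idx.size == 0:
        raise ValueError("axial_diameter undefined for an empty lesion")
    sx, sy = float(spacing[0]), float(spacing[1])
    best = 0.0
    for z in np.unique(idx[:, 2]):
        pts = idx[idx[:, 2] == z, :2].astype(float) * (sx, sy)
        if len(pts) < 2:
            continue
        if len(pts) > 800:  # Feret diameter is attained on the convex hull
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        best = max(best, float(pdist(pts).max()))
    return best


# ---------------------------------------------------------------------------
# lesion matching


@dataclasses.dataclass(frozen=True)
class PairStats:
    intersection: int
    dsc: float
    hd95: float


@dataclasses.dataclass
class MatchTable:
    """Overlap graph between ground-truth and predicted lesions of one scan.

    Stores per-lesion sizes and diameters plus per-overlapping-pair stats,
    which is sufficient to evaluate any size filter without the masks.
    """

    case_id: str
    spacing: tuple[float, float, float]
    gt_sizes: dict[int, int]
    pred_sizes: dict[int, int]
    gt_diameter_mm: dict[int, float]
    pairs: dict[tuple[int, int], PairStats]

    def gt_labels(self, size_filter: "SizeFilter") -> list[int]:
        return [g for g in self.gt_sizes if self.gt_diameter_mm[g] >= size_filter.min_diameter_mm]

    def matches_of_gt(self, g: int) -> list[tuple[int, PairStats]]:
        return [(p, st) for (gg, p), st in self.pairs.items() if gg == g]

    def tp_pred_labels(self, size_filter: "SizeFilter") -> set[int]:
        keep_gt = set(self.gt_labels(size_filter))
        return {p for (g, p) in self.pairs if g in keep_gt}


@dataclasses.dataclass(frozen=True)
class SizeFilter:
    """Measurable-lesion filter on ground truth (RECIST-style, default 10 mm)."""

    min_diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.min_diameter_mm < 0:
            raise ValueError("min_diameter_mm must be >= 0")


def match_lesions(gt: InstanceMask, pred: InstanceMask, case_id: str = "") -> MatchTable:
    """Match every ground-truth lesion with all overlapping predictions."""
    check_congruent(gt, pred, "gt and pred masks")
    gdata = np.asarray(gt.data)
    pdata = np.asarray(pred.data)
    gt_sizes = {int(l): int(c) for l, c in zip(*np.unique(gdata[gdata > 0], return_counts=True))}
    pred_sizes = {int(l): int(c) for l, c in zip(*np.unique(pdata[pdata > 0], return_counts=True))}
    gt_diam = {
        g: axial_diameter(gdata == g, gt.spacing) for g in gt_sizes
    }
    pairs: dict[tuple[int, int], PairStats] = {}
    both = (gdata > 0) & (pdata > 0)
    if both.any():
        g_over = gdata[both].astype(np.int64)
        p_over = pdata[both].astype(np.int64)
        combos, counts = np.unique(np.stack([g_over, p_over]), axis=1, return_counts=True)
        for (g, p), inter in zip(combos.T, counts):
            g, p = int(g), int(p)
            a = gdata == g
            b = pdata == p
            pair_dsc = 2.0 * int(inter) / (gt_sizes[g] + pred_sizes[p])
            pairs[(g, p)] = PairStats(int(inter), pair_dsc, hd95(a, b, gt.spacing))
    return MatchTable(case_id, gt.spacing, gt_sizes, pred_sizes, gt_diam, pairs)


# ---------------------------------------------------------------------------
# pooled metrics


@dataclasses.dataclass(frozen=True)
class DetectionMetrics:
    f1: float
    precision: float
    recall: float
    n_gt: int
    n_pred: int
    n_tp_pred: int


def detection_metrics(
    tables: Sequence[MatchTable], size_filter: SizeFilter = SizeFilter()
) -> DetectionMetrics:
    """Pooled F1/precision/recall over all scans under the size filter."""
    n_gt = n_detected = n_pred = n_tp = 0
    for t in tables:
        keep = t.gt_labels(size_filter)
        n_gt += len(keep)
        n_detected += sum(1 for g in keep if t.matches_of_gt(g))
        n_pred += len(t.pred_sizes)
        n_tp += len(t.tp_pred_labels(size_filter))
    recall = n_detected / n_gt if n_gt else float("nan")
    precision = n_tp / n_pred if n_pred else float("nan")
    if np.isnan(recall) or np.isnan(precision) or (precision + recall) == 0:
        f1 = 0.0 if (precision == 0 or recall == 0) else float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return DetectionMetrics(f1, precision, recall, n_gt, n_pred, n_tp)


@dataclasses.dataclass(frozen=True)
class SegmentationMetrics:
    dsc_image: float
    dsc_lesion: float
    hd95_lesion: float
    n_unmatched_gt: int
    n_empty_image_pairs: int  # scans where both filtered gt and pred were empty


def segmentation_metrics(
    tables: Sequence[MatchTable], size_filter: SizeFilter = SizeFilter()
) -> SegmentationMetrics:
    """Image-level Dice (per-scan macro-average) and lesion-level Dice/Hd-95."""
    image_dscs = []
    n_empty = 0
    lesion_dscs = []
    lesion_hd95s = []
    n_unmatched = 0
    for t in tables:
        keep = t.gt_labels(size_filter)
        gt_total = sum(t.gt_sizes[g] for g in keep)
        pred_total = sum(t.pred_sizes.values())
        inter_total = sum(st.intersection for (g, _p), st in t.pairs.items() if g in keep)
        if gt_total + pred_total == 0:
            image_dscs.append(1.0)  # degenerate: lesion-free scan, empty prediction
            n_empty += 1
        else:
            image_dscs.append(2.0 * inter_total / (gt_total + pred_total))
        for g in keep:
            matches = t.matches_of_gt(g)
            if matches:
                lesion_dscs.append(max(st.dsc for _p, st in matches))
                lesion_hd95s.append(min(st.hd95 for _p, st in matches))
            else:
                lesion_dscs.append(0.0)
                n_unmatched += 1
    return SegmentationMetrics(
        float(np.mean(image_dscs)) if image_dscs else float("nan"),
        float(np.mean(lesion_dscs)) if lesion_dscs else float("nan"),
        float(np.mean(lesion_hd95s)) if lesion_hd95s else float("nan"),
        n_unmatched,
        n_empty,
    )


def froc(
    tables: Sequence[MatchTable],
    scores: Sequence[dict[int, float]],
    size_filter: SizeFilter = SizeFilter(),
) -> list[tuple[float, float]]:
    """Free-response operating points: (mean FP per scan, pooled sensitivity).

    *scores* gives, per scan, a keep-score for every predicted label (e.g.
    the cascade's lesion-validity probability).  A keep-threshold is swept
    over all observed scores; at each point predictions scoring >= the
    threshold are kept and FP/scan and sensitivity are recomputed.  Points
    are sorted by FP/scan.
    """
    if len(tables) != len(scores):
        raise ValueError("need one score dict per match table")
    all_scores = sorted({s for d in scores for s in d.values()})
    if not all_scores:
        raise ValueError("no candidate scores provided")
    thresholds = all_scores + [np.inf]
    n_gt = sum(len(t.gt_labels(size_filter)) for t in tables)
    points = []
    for thr in thresholds:
        fp = 0
        detected = 0
        for t, sc in zip(tables, scores):
            kept = {p for p, s in sc.items() if s >= thr}
            keep_gt = t.gt_labels(size_filter)
            tp_preds = t.tp_pred_labels(size_filter)
            fp += len(kept - tp_preds)
            detected += sum(
                1 for g in keep_gt if any(p in kept for p, _ in t.matches_of_gt(g))
            )
        points.append((fp / len(tables), detected / n_gt if n_gt else float("nan")))
    return sorted(set(points))


@dataclasses.dataclass(frozen=True)
class VolumeAgreement:
    r2: float
    bias: float
    loa_low: float
    loa_high: float


def volume_agreement(pairs: Sequence[tuple[float, float]]) -> VolumeAgreement:
    """Least-squares R² plus Bland–Altman bias and limits of agreement.

    *pairs* are per-scan (predicted, ground-truth) total lesion volumes in
    liters.  Bias = mean(pred - gt); LoA = bias ± 1.96·SD(pred - gt).
    """
    if len(pairs) < 3:
        raise ValueError("volume agreement needs >= 3 (pred, gt) pairs")
    pred = np.asarray([p for p, _ in pairs], dtype=float)
    gt = np.asarray([g for _, g in pairs], dtype=float)
    if np.ptp(gt) == 0:
        raise ValueError("ground-truth volumes have zero variance; R² undefined")
    fit = stats.linregress(gt, pred)
    diff = pred - gt
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    return VolumeAgreement(float(fit.rvalue**2), bias, bias - 1.96 * sd, bias + 1.96 * sd)


def bootstrap_ci(
    metric_fn: Callable[[Sequence], float],
    cases: Sequence,
    n_resamples: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Case-level bootstrap: resample scans with replacement, recompute the
    metric, report the resample mean and percentile CI.  Resamples on which
    the metric is undefined (NaN or error) are skipped and counted."""
    if len(cases) < 1:
        raise ValueError("bootstrap needs >= 1 case")
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n_resamples):
        take = rng.integers(0, len(cases), size=len(cases))
        try:
            v = float(metric_fn([cases[i] for i in take]))
        except (ValueError, ZeroDivisionError):
            skipped += 1
            continue
        if np.isnan(v):
            skipped += 1
            continue
        vals.append(v)
    if skipped > 0.01 * n_resamples:
        warnings.warn(f"bootstrap skipped {skipped}/{n_resamples} undefined resamples")
    if not vals:
        return float("nan"), (float("nan"), float("nan"))
    arr = np.asarray(vals)
    alpha = (1 - ci) / 2 * 100
    return float(arr.mean()), (float(np.percentile(arr, alpha)), float(np.percentile(arr, 100 - alpha)))


# ---------------------------------------------------------------------------
# cohort report


@dataclasses.dataclass
class EvalReport:
    detection: DetectionMetrics
    segmentation: SegmentationMetrics
    froc_points: Optional[list[tuple[float, float]]]
    volume: Optional[VolumeAgreement]
    bootstrap: dict[str, dict[str, float]]
    size_filter: SizeFilter
    n_cases: int

    def to_dict(self) -> dict:
        d = {
            "n_cases": self.n_cases,
            "min_diameter_mm": self.size_filter.min_diameter_mm,
            "detection": dataclasses.asdict(self.detection),
            "segmentation": dataclasses.asdict(self.segmentation),
            "bootstrap": self.bootstrap,
        }
        if self.froc_points is not None:
            d["froc"] = [list(p) for p in self.froc_points]
        if self.volume is not None:
            d["volume"] = dataclasses.asdict(self.volume)
        return d


_BOOT_METRICS: dict[str, Callable[[Sequence[MatchTable], SizeFilter], float]] = {
    "dsc_image": lambda ts, f: segmentation_metrics(ts, f).dsc_image,
    "dsc_lesion": lambda ts, f: segmentation_metrics(ts, f).dsc_lesion,
    "hd95_lesion": lambda ts, f: segmentation_metrics(ts, f).hd95_lesion,
    "f1": lambda ts, f: detection_metrics(ts, f).f1,
    "precision": lambda ts, f: detection_metrics(ts, f).precision,
    "recall": lambda ts, f: detection_metrics(ts, f).recall,
}


def evaluate_cohort(
    gt_masks: Sequence[InstanceMask],
    pred_masks: Sequence[InstanceMask],
    size_filter: SizeFilter = SizeFilter(),
    scores: Optional[Sequence[dict[int, float]]] = None,
    n_resamples: int = 1000,
    seed: int = 0,
    case_ids: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Run the full evaluation protocol on a cohort of (gt, pred) scans."""
    if len(gt_masks) != len(pred_masks):
        raise ValueError("need one prediction per ground-truth mask")
    ids = case_ids or [f"case{i:03d}" for i in range(len(gt_masks))]
    tables = [match_lesions(g, p, i) for g, p, i in zip(gt_masks, pred_masks, ids)]
    det = detection_metrics(tables, size_filter)
    seg = segmentation_metrics(tables, size_filter)
    boot = {}
    for name, fn in _BOOT_METRICS.items():
        mean, (lo, hi) = bootstrap_ci(
            lambda ts, fn=fn: fn(ts, size_filter), tables, n_resamples, seed
        )
        boot[name] = {"mean": mean, "lo": lo, "hi": hi}
    froc_points = froc(tables, scores, size_filter) if scores is not None else None
    vols = []
    for g, p in zip(gt_masks, pred_masks):
        voxel_l = float(np.prod(g.spacing)) * 1e-6
        vols.append((float((p.data > 0).sum()) * voxel_l, float((g.data > 0).sum()) * voxel_l))
    try:
        vol = volume_agreement(vols)
    except ValueError:
        vol = None
    return EvalReport(det, seg, froc_points, vol, boot, size_filter, len(gt_masks))


# ---------------------------------------------------------------------------
# plotting hooks (lazy matplotlib import)


def plot_froc(points: Sequence[tuple[float, float]], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fp, sens = zip(*points)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(fp, sens, marker="o")
    ax.set_xlabel("mean FP per scan")
    ax.set_ylabel("lesion sensitivity")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bland_altman(pairs: Sequence[tuple[float, float]], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred = np.asarray([p for p, _ in pairs])
    gt = np.asarray([g for _, g in pairs])
    mean = (pred + gt) / 2
    diff = pred - gt
    bias = diff.mean()
    sd = diff.std(ddof=0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=12)
    for y, style in ((bias, "-"), (bias + 1.96 * sd, "--"), (bias - 1.96 * sd, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of predicted and manual volume (L)")
    ax.set_ylabel("difference (L)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
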