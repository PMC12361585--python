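# llseg — multi-instance lung lesion segmentation on thoracic CT

`llseg` implements a three-stage pipeline for detecting and segmenting
*all* lung cancer lesions in a thoracic CT scan — not just the primary
tumor — together with the multi-lesion evaluation protocol needed to
judge such a system, and a synthetic phantom generator that makes every
experiment reproducible on a laptop with no patient data.

The pipeline (`LLSB_CFPR`):

1. **Thoracic bounding box.** A lung mask (pluggable; a threshold-based
   reference masker ships with the package) defines a tight crop box.
   Because density-based lung maskers exclude large wall-attached
   masses, any box axis whose physical extent falls below a minimum
   (210 × 150 × 120 mm, the smallest plausible thorax) is replaced by
   the full image range on that axis.
2. **Multi-instance segmentation.** A pluggable backend maps the crop to
   a binary lesion mask; foreground is split into instances with 3D
   connected components under 26-connectivity and padded back to the
   original grid. The shipped trainable backend is a voxelwise
   gradient-boosted classifier on multiscale intensity features; any
   model honoring the `SegmentationBackend` contract (e.g. a full 3D
   U-Net) can be attached instead.
3. **Cascade false-positive reduction (CFPR).** Every candidate is
   screened by two classifiers: the **XPC** sees the full coronal slice
   through the candidate centroid (128×128 at 1×1 mm) and rejects fully
   extrapulmonary detections when its extrapulmonary score
   `p_e = 1 − P(lesion)` reaches `thr_e`; survivors are confirmed by the
   **LVC**, a 3D view (96³ at 1 mm isotropic) centered on the candidate,
   iff `P(lesion) > thr_i`. Rejected candidates are erased from the
   mask; the cascade never adds voxels.

Evaluation follows the multi-lesion protocol: a predicted lesion is a
true positive iff it overlaps a ground-truth lesion (pairwise Dice > 0);
recall/precision/F1 are pooled over lesions; segmentation quality is
image-level Dice (per-scan average) plus lesion-level Dice and
95th-percentile Hausdorff distance (best match per ground-truth lesion);
a RECIST-style filter restricts analysis to measurable lesions (≥ 10 mm
axial diameter); volume agreement is reported as R² and Bland–Altman
bias/limits; uncertainty comes from a 1,000-resample case-level
bootstrap. FROC curves (sensitivity vs. mean FP per scan) are available
for score sweeps.

## Worked example

`examples/03_oracle_pipeline.py` runs the pipeline on a synthetic
phantom with every learned slot replaced by an analytic oracle:

```text
candidates before false-positive reduction: 4 (ground truth has 2 lesions)
  candidate 1: kept
  candidate 2: dropped by XPC
  candidate 3: kept
  candidate 4: dropped by LVC
after cascade: 2 candidates, recall=1.00, precision=1.00, lesion Dice=1.00
```

The segmentation stage finds four candidates — the two true lesions plus
two planted distractors. The cascade removes the extrapulmonary
distractor at stage XPC and the intrapulmonary vessel-like distractor at
stage LVC; recall and precision of 1.00 mean exactly the true lesions
survived.

The other examples cover phantom generation (`01`), the bounding-box
fallback on a wall-attached mass (`02`), the evaluation protocol on toy
masks (`04`), and a miniature learned end-to-end study (`05`). A thin
CLI mirrors the library (`llseg phantom | bbox | segment |
build-candidates | train-xpc | train-lvc | tune-thresholds | cfpr |
evaluate | run`).

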