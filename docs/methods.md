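# Methods

This note records the models, conventions and design choices behind
`llseg`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, what the synthetic phantoms do and do not emulate,
and where the design was genuinely open.

## Spatial conventions

Volumes are 3D scalar grids in Hounsfield units with per-axis spacing in
mm; axes are fixed as (x = left–right, y = anterior–posterior,
z = inferior–superior) and every NIfTI file is reoriented to the closest
RAS orientation on load. Voxel indexing is 0-based; bounding boxes are
inclusive on both ends, so the physical side length along an axis is
`(hi − lo + 1) · spacing`. Instance masks carry labels `1..n` with no
gaps, each label one 26-connected component. All cross-image operations
require grid congruence (same shape, spacing, origin) and raise
otherwise.

## Stage 1 — thoracic bounding box

The crop box is the tightest box around the lung-mask foreground. The
fallback rule compares each axis's *physical* side length against a
per-axis minimum — 210, 150, 120 mm by default, the smallest plausible
adult thorax — and substitutes the whole-image range for any axis below
its minimum; an empty lung mask maps to the whole image. Physical mm
(not voxels) is the right comparison unit because slice spacing varies
several-fold across scanners. No margin is added around the box.

One subtlety: the rule is *not* monotone in the input mask. When a
growing lung box crosses a minimum, the output flips from the
whole-image range to the (smaller) box itself. This is inherent to the
rule; the tested invariants are idempotence, containment of the input
box, and monotonicity within threshold regimes.

The reference lung masker thresholds at −400 HU, discards components
touching the x/y image border (ambient air) or smaller than 10 cm³, and
closes the result morphologically. Like any density-based masker it
excludes dense wall-attached lesions — exactly the failure mode the
fallback protects against. Any masker can be substituted through the
pipeline's `lung_masker` hook.

## Stage 2 — segmentation and instance labeling

The segmentation network proper sits behind the `SegmentationBackend`
protocol (`fit` on (crop, binary-mask) pairs, `predict` to a
grid-congruent binary mask, serializable). Two backends ship:

* **ThresholdBackend** — an analytic oracle for phantoms (foreground =
  HU > +10; on the phantom palette only lesion-like tissue is above
  that). Used in oracle tests and wherever a perfect segmentation stage
  is needed to isolate other components.
* **VoxelFeatureBackend** — the trainable reference backend: a
  gradient-boosted classifier scoring each voxel from its HU value,
  Gaussian-smoothed context at 1/2/4/12 mm physical scales, and a local
  aeration fraction (8 mm-scale mean of the −400 HU indicator, which
  separates intrapulmonary from chest-wall neighborhoods). Training
  samples every foreground and near-boundary voxel plus 15,000
  background voxels per case; the probability map is Gaussian-smoothed
  and thresholded, with the smoothing scale and threshold chosen by mean
  Dice on a held-out fifth of the training crops inside `fit`. This is a
  deliberately small, CPU-trainable stand-in for a deep segmentation
  network; it is local by construction, so structures sharing the
  lesions' intensity signature are segmented too — the downstream
  cascade exists to remove them. A 3D U-Net or similar can be attached
  through the same interface without touching the rest of the pipeline.

Binary output is split into instances by 3D connected components under
26-connectivity (face, edge and corner adjacency). Labels follow the
lexicographic scan order of each component's minimum voxel index, making
the labeling deterministic. Predicted masks are padded back to the
original grid using the stored crop record. No size filtering happens at
this stage: false positives are removed by the cascade, and the
measurable-lesion filter lives in evaluation only.

## Stage 3 — cascade false-positive reduction

Both classifiers output `P(class 1 = true lesion)`; the XPC's
extrapulmonary score is defined as `p_e = 1 − P(lesion)`, keeping one
output convention across the cascade. The gate semantics are: drop at
stage XPC when `p_e ≥ thr_e`; otherwise confirm iff the LVC probability
strictly surpasses `thr_i`. Sentinels outside [0, 1]
(`thr_e = 1.01, thr_i = −0.01`) make the cascade an exact no-op, so the
no-reduction pipeline is a special case rather than a separate code
path.

Patch conventions: the XPC sees the **full** coronal plane through the
candidate centroid (rounded to the nearest slice), resampled to 1×1 mm
and resized to 128×128 — the full plane, not a crop, because judging
"fully extrapulmonary" requires the body outline and pulmonary
boundaries as context. The LVC sees a 96 mm cube centered on the
centroid at 1 mm isotropic (96³). The mask channel carries only the
candidate under evaluation; sibling candidates are excluded. Out-of-view
regions are padded with the volume's minimum HU (air) before per-patch
min–max normalization to [0, 1]; constant patches map to zero. No HU
windowing precedes normalization.

The shipped classifier backbone (`PooledPatchClassifier`) block-averages
the (raw, mask) pair onto a coarse grid (4×4 for the coronal view, 4³
for the cube), appends ten candidate-focused summaries (mean/SD of raw
under the mask, mean of a 3-pixel shell around it, aerated fractions
inside and in the shell, size fraction, per-axis extents, elongation),
standardizes, and feeds a single-hidden-layer (64-unit) network. The
summaries carry the physics — a candidate's own intensity, what
surrounds it (lung air, chest wall, fat), and its shape (vessel-like
tubes are elongated; true lesions compact) — while the pooled channels
keep coarse anatomical layout. Earlier variants with finer pooled grids
(16², 12³) overfitted at the few-hundred-candidate scale and produced
occasional saturated-wrong probabilities on borderline true lesions; the
small grid plus summaries removed that failure mode.

Erasing a dropped candidate zeroes its voxels; survivors are relabeled
`1..m` preserving relative order with voxel sets untouched. Removal-only
and candidate-order invariance are tested properties.

## Training the cascade

Candidate datasets are built from pipeline predictions on annotated
cases: one record per predicted instance, labeled 1 iff its pairwise
Dice with any ground-truth lesion exceeds 0, and tagged by lung-overlap
fraction (0 → extrapulmonary, 1 → intrapulmonary, else partial). The LVC
trains on all candidates; the XPC subset keeps extrapulmonary
non-lesions plus all true lesions, mirroring its subtask of rejecting
fully extrapulmonary detections (true lesions are assumed at least
partially intrapulmonary).

Harvesting uses 2-fold *cross-fitted* backends (each training case
predicted by a backend that never saw it) so the harvested candidates
show the false-positive behavior the cascade will face on unseen scans;
in-sample predictions are far too clean. Hard negatives are capped at 8
per case (largest first) so a speckly segmentation of one scan cannot
flood the set.

Cases — never candidates — are split into 5 folds stratified by source
tag and binned z-spacing (≤ 1 mm, 1–3 mm, > 3 mm; round-robin within
strata, balanced to ±1). The recipe per fold: binary cross-entropy,
Adam (lr 1e-3), L2 weight decay 1e-4, mini-batches of 32, random patch
augmentations (translation ±10%, axis flips, in-plane rotation ±15°,
zoom 0.9–1.1, Gaussian noise, two augmented copies per training patch),
early stopping after 30 epochs without validation-fold loss improvement
with best-loss weights restored. The early-stopping monitor is the
held-fold loss (the natural choice when folds exist).

Threshold tuning is an exhaustive grid over `(thr_e, thr_i)` (step 0.02
in the standard study; the op's default is 0.01), maximizing image-level
mean Dice subject to pooled lesion sensitivity within a tolerance of the
best achievable value (δ = 0.01 by default; the standard study uses
δ = 0, i.e. strict preservation); ties break toward higher sensitivity,
then lower `thr_i`, then the more conservative (higher) `thr_e`.

Two deployment choices deserve emphasis. `select_best_and_tune_thresholds`
selects per-type fold classifiers by highest held-fold AUROC, and that
op is what tunes the thresholds; the *deployed* cascade, however, uses
the mean-probability **ensemble** of the five fold models, with
leave-one-fold-out ensemble probabilities feeding the tuning so tuned
thresholds match the deployed variance profile. Single selected models
occasionally emitted confidently-wrong scores (≈ 0.005) on borderline
true lesions — tail variance that no threshold tied to validation
statistics can absorb — and ensembling removes most of it. Second, a
**sensitivity guard** clamps the operating point to at most half the
weakest true-candidate score observed out-of-fold (`thr_i ≤ min p_lvc/2`
and symmetrically for `thr_e`), buying margin against distribution shift
at a small false-positive cost. Sensitivity is the clinically expensive
side of this trade.

## Evaluation protocol

* Detection: overlap rule (pair Dice > 0); a prediction overlapping ≥ 1
  ground-truth lesion is one TP; one prediction covering two lesions
  yields two detected lesions and one non-FP prediction. Metrics are
  pooled over lesions across scans (micro-average).
* Measurable-lesion filter: applies to ground truth only (predictions
  are filtered by the cascade, not by size). Lesions under the cutoff
  (10 mm axial Feret diameter, computed per constant-z slice between
  voxel centers) leave recall's denominator and do not confer TP status.
  Setting the cutoff to 0 reproduces the all-lesion analysis as a
  configuration.
* Segmentation: image-level Dice is the per-scan whole-mask Dice
  averaged over scans (a lesion-free scan with an empty prediction
  scores 1 and is flagged); lesion-level Dice takes each ground-truth
  lesion's best pairwise Dice (0 if unmatched); lesion-level Hd-95 takes
  the lowest pairwise Hd-95 among matches, averaged over matched lesions
  only — the Dice-best and Hd-95-best match may be different
  predictions. Hd-95 pools directed surface distances in both
  directions (surface = foreground voxel with a face-adjacent background
  neighbor or on the array border) and takes the 95th percentile, in mm
  under anisotropic spacing.
* Volume agreement is computed on per-scan total lesion volume in liters
  (so false positives and misses count as burden error): least-squares
  R², Bland–Altman bias and bias ± 1.96 SD limits.
* Bootstrap: scans (not lesions) are the resampling unit — lesions
  within a scan are not independent — with 1,000 resamples and
  percentile 95% intervals; undefined resamples are skipped and counted,
  with a warning past 1%.
* FROC: a keep-threshold swept over per-candidate scores, reporting
  (mean FP/scan, pooled sensitivity) per operating point.

## The phantom generator

Phantoms are piecewise-constant HU on simple shapes — air −1000, body
ellipsoid 0, two lung ellipsoids −800, lesions +20 — plus Gaussian noise
(10 HU SD default). Lesions are ellipsoids (30% lobulated unions of 2–4
overlapping lobes, exercising non-convex labeling) with the largest
in-plane semi-axis set by the drawn diameter, placed intrapulmonary or
straddling the pleural boundary (wall-attached, 20% by default).
Fully-extrapulmonary ground truth is generatable (`p_extrapulmonary`)
but defaults to 0: lung lesions are pulmonary, and the XPC gate by
design rejects candidates with no lung overlap, so extrapulmonary truth
would guarantee recall loss. Distractors provide false-positive
material with the lesions' own HU: vessel-like intrapulmonary tubes
(2–3.2 mm radius capsules, preferentially z-oriented) and extrapulmonary
nodule-in-fat pockets (+20 HU core in a −100 HU fat ellipsoid). Cohorts
jitter spacing per case (in-plane 2.0–3.0 mm, z 1.2–5.0 mm) and draw
lesion counts from a distribution with median 2 per scan, mimicking
multicenter heterogeneity in slice thickness, field of view and burden.

Defaults: 80×80×56 voxels at (2.8, 2.0, 2.3) mm → 224×160×129 mm field
of view, just above the bbox minima. The grid is chosen so the smallest
measurable lesions (10 mm) span tens of voxels even for the half that a
wall-attached lesion presents to the lung; at coarser desk-scale grids
such lesions rasterize to one or two voxels, which no candidate
classifier can tell from noise. Everything is bit-deterministic under
the spec seed; cohort generation redraws a case's seed (deterministically)
if a placement is infeasible after bounded retries.

What the phantoms do *not* emulate: realistic CT texture and noise
correlation, contrast enhancement, respiratory motion, airway/vessel
trees, lesion HU heterogeneity, or anatomy beyond two ellipsoidal lungs
in an ellipsoidal body. Passing tests on phantoms therefore demonstrate
the pipeline's *mechanics* — stage contracts, geometry, training and
tuning plumbing, metric definitions — not clinical performance; numbers
from phantom studies are not comparable to numbers on patient data.

## Standard study sizes

The standard learned study (acceptance script; the test suite runs the
same at fewer bootstrap resamples) uses 50 training + 10 held-out
phantoms, the backend fitted on the first 30 training crops, candidates
harvested from all 50 (≈ 250–380 candidates), and 1,000 bootstrap
resamples — sizes at which the full experiment completes in a few
minutes on one CPU while keeping ≥ 200 candidates for classifier
training. Typical results (seed 1): FP/scan 2.8 → 0.7 with the cascade,
sensitivity 1.00 → 1.00, precision 0.39 → 0.72, image Dice
0.80 → 0.82. The directional pattern — precision rises sharply, recall
essentially preserved — is the pipeline's design goal; exact values move
with the seed.

## Known limitations

* The voxel-feature backend is intensity-local; it cannot learn shape
  priors and under-segments the chest-wall side of wall-attached
  lesions. On real CT a 3D U-Net-class backend should be attached.
* The XPC/LVC backbone is a small MLP on pooled features; it is adequate
  for phantom-scale separability, not a claim about real-CT capacity.
  Deeper backbones (ResNet-class, transformers, pretrained weights) plug
  into the same `Classifier` protocol.
* DICOM ingestion, inter-grid resampling and registration are out of
  scope; inputs are NIfTI volumes on a common grid per case.
* The evaluation treats annotation as exact; inter-reader variability is
  not modeled.
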