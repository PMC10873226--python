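# Methods

This note documents the models, parameter choices and numerical conventions
behind `twistcad`, and what the synthetic experiments do and do not show.

## Problem setting

Ultrafast (TWIST) breast DCE-MRI produces one pre-contrast volume and a
train of post-contrast volumes — 14 here — spanning roughly 102 seconds of
contrast inflow. In a screening population the large majority of breasts is
lesion-free, so detection systems must be evaluated (and are best trained)
under that prevalence. The package implements a two-stage detector: a
single-timepoint candidate detector on the final subtraction MIP, followed
by a temporal classifier that scores each candidate's enhancement dynamics
across all 14 subtraction MIPs and rejects non-lesion enhancers.

## Synthetic phantom

The phantom generator replaces a clinical cohort; its defaults encode the
cohort composition the pipeline targets:

| parameter | default | rationale |
|---|---|---|
| lesion prevalence | 0.17 | fraction of breasts with ≥ 1 lesion in the reference screening cohort |
| multi-lesion fraction | 0.57 | fraction of involved breasts with > 1 lesion |
| malignant fraction | 0.283 | fraction of lesions malignant |
| benign / malignant median diameter | 9 / 22 mm | reported cohort medians; diameters drawn log-normally (σ = 0.45), clipped to [5 mm, 36 mm] and to what the breast mask can contain |
| post-contrast volumes | 14, equally spaced over 102 s | the inter-volume timing of the sequence is not published; equal spacing is an assumption |
| volume geometry | 32 × 96 × 96 voxels per breast, 2 mm isotropic | desk-scale speed; one breast ≈ 0.3 Mvoxel |
| baseline / noise | 100 / σ = 6 intensity units | tissue baseline with mild Gaussian acquisition noise, int16 |
| confounders | Poisson(2) vessels per breast, one nipple, diffuse parenchymal enhancement in 35 % of breasts | the documented false-positive sources of MIP-based detection |

Contrast kinetics are **piecewise linear**: zero until a time-to-enhancement
(TTE), linear wash-in to a peak over a rise duration, then linear washout
floored at zero. This is deliberately not a pharmacokinetic model: it is the
simplest form that realises the fast-versus-slow distinction and admits
closed-form test oracles. Class defaults (seconds, intensity units,
intensity/s; each lesion jitters them ±15 %):

| class | TTE | rise | peak | washout |
|---|---|---|---|---|
| malignant | 10 | 25 | 300 | 0.5 |
| benign | 35 | 50 | 220 | 0.0 |
| vessel | 3 | 12 | 300 | 1.8 |
| nipple | 5 | 20 | 180 | 0.6 |
| parenchyma | 40 | 60 | 45 | 0.0 |

Malignant lesions enhance earlier than benign ones; vessels and nipples
enhance fastest but wash out strongly, so they are still bright at the last
timepoint (stage 1 must see them, producing realistic false positives) while
remaining temporally separable (stage 2 can reject them). Geometry — lesion
spheres or lobulated sphere unions, vessel tubes, the nipple blob, the
breast-mask ellipsoid — is fixed at *planning* time; rendering an exam only
evaluates kinetics and adds seeded noise, so ground-truth boxes (tight boxes
of each lesion's projected footprint) never depend on rendering order.
Everything is a deterministic function of the cohort seed.

**What the phantom does not emulate:** MR physics (coil profiles, k-space
view sharing, compressed sensing), motion, bias fields, anatomical texture,
lymph nodes, and the continuum of borderline kinetic behaviour seen in real
parenchyma. Its confounders are *fully* separable from lesions by their
wash-out — which is why the temporal stage removes essentially all phantom
false positives, a much stronger reduction than is achievable clinically.
Passing phantom tests therefore demonstrates correct mechanics of the
pipeline, not clinical performance.

## Preprocessing conventions

* Subtraction clamps negative differences at zero — enhancement is the
  signal of interest and projecting signed noise would inflate the MIP
  background.
* The projection axis is fixed to the slice axis (axis 0 of `(z, y, x)`).
* Pixel coordinates are 0-based and half-open everywhere; LabelMe float
  vertices are rounded to the nearest integer on read.
* 8-bit normalisation clips at the image's 99.9th percentile (robust to
  single hot voxels) and rounds half away from zero.
* The auto left/right split takes the centre of the near-minimal plateau of
  column sums within the central third of the image — the flat inter-breast
  valley makes a bare argmin land on an arbitrary noise column.
* Breast masks must already share the TWIST voxel grid; resampling a mask
  from another field of view is the caller's responsibility.

## Stage 1: detector backends

The production counterpart of this stage is a large fine-tuned object
detector; re-training one is out of scope, so the stage is a contract with
two bundled backends.

**BlobDetector** (analytic reference): a multi-scale difference-of-Gaussians
stack (σ from 1.5 to 8 px, 6 scales, geometric spacing). Local maxima of the
scale-normalised response above the 98th percentile of responses over
nonzero pixels become candidates; the box side is 2√2·σ of the detecting
scale; `det_score` is the peak response divided by the image's maximum
response, so scores lie in (0, 1] but are only comparable *within* one image
— per-image normalisation means the top candidate of an empty breast also
scores 1.0. That is a deliberate property of the reference backend: it
guarantees stage-1 false positives at screening prevalence, which is the
regime the temporal stage is there to fix. Greedy NMS at IoU 0.45 with ties
broken by box position; at most 50 candidates per image.

**HeatmapDetector** (trainable): pixel-wise logistic regression on feature
maps — an intensity pyramid, DoG bands, scale-normalised Laplacians,
Hessian blobness (separates compact blobs from elongated vessels) and
distance to the breast boundary (separates interior lesions from nipples,
which sit on the skin line). Positive pixels are ground-truth box cores
(boxes shrunk by a quarter per side); negatives are subsampled 5:1.
Candidates are local maxima of the smoothed probability map; the box is the
connected component above half the peak probability; `det_score` is the peak
probability (comparable across images). Training takes seconds on one CPU
and is deterministic under its seed.

A known limitation at the phantom's 2 mm voxel pitch: a 5 mm lesion (the
minimum the generator produces) projects to a ~2-pixel dot with no shape
information, and no single-timepoint detector can rank such dots above the
phantom's deliberately enhancing confounders. The trainable backend's
high-sensitivity guarantee (≥ 0.85 at 2 FP/breast on held-out phantoms) is
therefore asserted for lesions ≥ 10 mm, which the grid resolves; small
lesions are still detected as candidates and recovered by the full
two-stage system at its operating point.

## Stage 2: temporal clip classifier

Each candidate above `th0` yields a **clip**: the box expanded by 20 % per
side, clipped to the image, cut from each of the 14 MIPs, bilinearly
resampled to 32 × 32, and scaled by the clip's global maximum (an all-zero
clip stays zero). The classifier is a compact gated recurrent network:

* per-frame embedding: 4 × 4 average pooling → 16 features (no learned
  parameters; the clip normalisation already standardises scale);
* one GRU layer with 24 hidden units, implemented directly on numpy arrays;
  the analytic backward pass is verified against numerical differentiation
  in the test suite;
* sigmoid head **initialised at zero**, so the untrained model is a constant
  0.5 predictor and any score ordering is learned from the labels (this also
  makes label-permutation nulls behave: chance-level held-out AUC);
* training: class-weighted binary cross-entropy, full-batch Adam
  (lr 0.02, ℓ2 10⁻⁴), at most 400 epochs with early stopping (patience 40)
  on a held-out fifth of the training clips; all randomness seeded.

Training labels per fold: positives are clips at annotated ground-truth
boxes **plus** clips at detector candidates that match ground truth — the
model scores detector-shaped boxes at test time, and training only on
ground-truth-tight geometry left a scale/offset shift that rejected true
lesions. Negatives are clips at detector candidates on the same fold's
training breasts that match no ground truth (hard-negative mining; no
breasts outside the fold's training split are ever touched).

The merge rule is fixed: accept iff `det_score ≥ th0` and `seq_score ≥ th1`
(defaults 0.5 / 0.5), `final_score = det_score · seq_score` so that a
free-response sweep ranks by both stages. The product rule is this package's
choice; the original system's merge rule is not published. Rejected
candidates are retained with `accepted=False` for audit.

## Evaluation

* **Hit criterion** (not published by the reference system; fixed here):
  candidate centre inside the ground-truth box OR IoU ≥ 0.3. Centre-hit is
  the standard convention in breast-CAD free-response analysis; the IoU
  clause adds robustness for large lesions. Assignment is greedy in
  descending score, one-to-one, each candidate taking its highest-IoU hit.
* **FROC**: thresholds sweep the distinct candidate scores; sensitivity =
  matched lesions / all lesions, false positives per breast = unmatched
  accepted candidates / all evaluated breasts (uninvolved ones included).
  Sensitivity at an operating point p is the maximum sensitivity among cuts
  with fppb ≤ p — a conservative step convention without interpolation.
* **Per-fold metrics**: sensitivity = TP/lesions, PPV = TP/predictions,
  FP-reduction fraction = (stage-1 false positives rejected by stage 2) /
  (stage-1 false positives). Printed values are rounded to two decimals,
  half away from zero. Fold summaries report the unweighted mean and the
  min–max range; both pooled and mean-of-folds PPV are computed, since the
  two conventions differ. `removed_fp` counts rejected stage-1 *false
  positives* only; a rejected true positive lowers sensitivity instead, so
  `baseline FP − removed FP` need not equal the integrated FP count when
  stage 2 also removes true positives.

## Cross-validation

Breasts are the grouping unit; all exams of one breast stay in one fold, and
left/right breasts of one woman are independent groups. Folds are stratified
by the involved flag (involved counts per fold differ by ≤ 1; total fold
sizes by ≤ 1). Within a fold, the detector training set is balanced — all
involved training breasts plus an equal, seeded subsample of uninvolved
ones — and the remaining uninvolved training breasts (the isolated negative
set) are merged into that fold's test data, restoring screening prevalence
at evaluation time. Detector and sequence model are trained on the same
split; train/test disjointness is asserted at run time and any violation is
a hard failure. With the analytic backend, per-breast detections are cached
across folds (they depend only on the image).

Each breast is evaluated on its first exam's MIP stack; repeat exams
exercise the group binding but are not double-counted in the FP-per-breast
denominator.

## Problem sizes and runtime

Default experiment sizes were chosen so the full suite runs comfortably on a
single CPU: the end-to-end cross-validation uses a 200-breast cohort
(~2 minutes), the clip benchmark 400 clips (~10 s), oracle-equivalence
suites 1000 randomised trials each (< 1 min). One master seed fans out to
per-module seeds via a hash of the seed and the module name, so modules are
reproducible in isolation and full runs are byte-identical under one seed.

## Known limitations

* The phantom's temporal separability is idealised; the ~99.9 % phantom
  false-positive reduction says nothing about the clinically achievable
  fraction (~15 % for the reference system).
* The reference blob backend's per-image score normalisation makes its raw
  FROC at screening prevalence poor by construction; it exists to exercise
  the pipeline, not to compete with a trained detector.
* No registration or motion correction between timepoints; no bias-field
  correction; masks are analytic ellipsoids, not segmentations.
* The recurrent classifier's architecture is this package's choice; the
  reference system's sequence-model details are not published.
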