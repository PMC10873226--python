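"""Group-bound, prevalence-aware cross-validation of the two-stage system.

Breasts are the grouping unit: all exams of one breast stay in one fold
(left and right breasts of one woman are independent groups). Folds are
stratified by the involved flag so every fold carries an almost equal
number of lesion breasts. Within each fold the detector training set is
balanced (all involved training breasts plus an equal number of uninvolved
ones); the leftover uninvolved training breasts — the *isolated negative
set* — are merged into the fold's test data so that evaluation happens at
screening prevalence. The detector backend and the sequence classifier are
trained on the same split, then integrated, so no information crosses the
train/test boundary anywhere in the pipeline (asserted at run time).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .detect import (
    BlobDetector,
    Candidate,
    DetectorBackend,
    HeatmapDetector,
    TrainingAssembly,
    assemble_training_set,
)
from .evaluate import (
    FoldReport,
    FrocCurve,
    MatchResult,
    aggregate_folds,
    froc_curve,
    match_detections,
    reports_to_frame,
)
from .fpreduce import GRUSequenceClassifier, ThresholdConfig, extract_clip, merge_scores
from .phantom import Cohort
from .preprocess import BBox, normalize_image

logger = logging.getLogger(__name__)

__all__ = [
    "SplitManifest",
    "FoldRunResult",
    "CrossvalResult",
    "group_shuffle_split",
    "run_fold",
    "run_crossval",
    "make_backend",
]


@dataclass
class SplitManifest:
    """Breast-level fold assignment (group-bound, stratified by involvement)."""

    assignment: dict[str, int]  # breast_id -> test fold index
    k: int
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return sorted(b for b, f in self.assignment.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(b for b, f in self.assignment.items() if f != fold)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"k": self.k, "seed": self.seed, "assignment": self.assignment},
                       indent=1, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SplitManifest":
        d = json.loads(Path(path).read_text())
        return cls(assignment=d["assignment"], k=d["k"], seed=d["seed"])


def group_shuffle_split(
    records: Sequence[Mapping], k: int = 5, seed: int = 0
) -> SplitManifest:
    """Stratified k-fold assignment of breasts.

    Involved and uninvolved breasts are shuffled separately and dealt
    round-robin, the uninvolved stream starting where the involved one
    stopped so overall fold sizes differ by at most one breast. Every exam
    of a breast inherits the breast's fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    involved = [r["breast_id"] for r in records if r["involved"]]
    uninvolved = [r["breast_id"] for r in records if not r["involved"]]
    if len(involved) < k:
        raise ValueError(
            f"need at least {k} involved breasts for {k}-fold stratification, "
            f"got {len(involved)}"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(involved)
    rng.shuffle(uninvolved)
    assignment: dict[str, int] = {}
    for i, bid in enumerate(involved):
        assignment[bid] = i % k
    offset = len(involved) % k
    for i, bid in enumerate(uninvolved):
        assignment[bid] = (offset + i) % k
    return SplitManifest(assignment=assignment, k=k, seed=seed)


def make_backend(name: str, params: dict | None = None, seed: int = 0) -> DetectorBackend:
    params = dict(params or {})
    if name == "blob":
        return BlobDetector(**params)
    if name == "heatmap":
        params.setdefault("seed", seed)
        return HeatmapDetector(**params)
    raise ValueError(f"unknown detector backend {name!r}")


# ---------------------------------------------------------------------------
# per-fold execution
# ---------------------------------------------------------------------------


@dataclass
class FoldRunResult:
    fold: int
    stage1: FoldReport
    integrated: FoldReport
    froc_stage1: FrocCurve
    froc_integrated: FrocCurve
    assembly: TrainingAssembly
    candidates: dict[str, list[Candidate]] = field(default_factory=dict, repr=False)


def _detect_on_breast(
    cohort: Cohort,
    backend: DetectorBackend,
    breast_id: str,
    cache: dict[str, list[Candidate]] | None,
) -> list[Candidate]:
    if cache is not None and breast_id in cache:
        return cache[breast_id]
    stack = cohort.mip_stack(breast_id)
    image = normalize_image(stack.last)
    cands = backend.predict(image)
    for c in cands:
        c.breast_id = breast_id
        c.exam_id = stack.exam_id
    if cache is not None:
        cache[breast_id] = cands
    return cands


def run_fold(
    cohort: Cohort,
    split: SplitManifest,
    fold: int,
    thresholds: ThresholdConfig | None = None,
    backend: DetectorBackend | None = None,
    clip_margin_fraction: float = 0.2,
    clip_patch_size: int = 32,
    seed: int = 0,
    detection_cache: dict[str, list[Candidate]] | None = None,
) -> FoldRunResult:
    """Train both stages on one fold and evaluate at screening prevalence.

    Returns stage-1-only and integrated fold reports plus both FROC curves,
    so the false-positive reduction of the temporal stage is measurable.
    """
    th = thresholds or ThresholdConfig()
    records = cohort.records()
    train_ids = split.train_ids(fold)
    test_ids = split.test_ids(fold)
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise RuntimeError(f"leakage: breasts {sorted(overlap)} in both train and test")

    rng = np.random.default_rng(seed)
    assembly = assemble_training_set(records, train_ids, rng)

    if backend is None:
        backend = BlobDetector()
    trainable = getattr(backend, "trainable", False)
    if trainable:
        images, boxes = [], []
        for bid in assembly.balanced_ids:
            images.append(normalize_image(cohort.mip_stack(bid).last))
            boxes.append(cohort.ground_truth(bid).bboxes)
        backend.fit(images, boxes)
        fold_cache: dict[str, list[Candidate]] | None = {}
    else:
        backend.fit([], [])
        fold_cache = detection_cache if detection_cache is not None else {}

    # --- stage-2 training data: GT clips vs hard-negative candidate clips --
    pos_clips, neg_clips = [], []
    for bid in assembly.balanced_ids:
        stack = cohort.mip_stack(bid)
        gt_boxes = cohort.ground_truth(bid).bboxes
        for b in gt_boxes:
            pos_clips.append(
                extract_clip(stack, b, clip_margin_fraction, clip_patch_size)
            )
        cands = _detect_on_breast(cohort, backend, bid, fold_cache)
        stage1 = [c for c in cands if c.det_score >= th.th0]
        matched = match_detections(stage1, gt_boxes, score_attr="det_score")
        for i, c in enumerate(stage1):
            clip = extract_clip(stack, c.box, clip_margin_fraction, clip_patch_size)
            if i in matched.matched_candidates:
                # lesion hit at the detector's own box geometry: a hard
                # positive matching what the model will see at test time
                pos_clips.append(clip)
            else:
                neg_clips.append(clip)
    if not pos_clips or not neg_clips:
        raise ValueError("sequence model needs both lesion and non-lesion training clips")
    seq_model = GRUSequenceClassifier()
    labels = [1] * len(pos_clips) + [0] * len(neg_clips)
    seq_model.fit(pos_clips + neg_clips, labels, seed=seed)

    # --- evaluation: fold test breasts plus the isolated negative set ------
    eval_ids = list(test_ids) + list(assembly.isolated_negative_ids)
    leak = set(eval_ids[: len(test_ids)]) & set(train_ids)
    if leak:
        raise RuntimeError(f"leakage: test breasts {sorted(leak)} seen in training")

    per_breast_cands: dict[str, list[Candidate]] = {}
    per_breast_gt: dict[str, list[BBox]] = {}
    tp1 = fp1 = tp2 = fp2 = removed_fp = 0
    n_lesions = 0
    n_involved = 0
    for bid in eval_ids:
        stack = cohort.mip_stack(bid)
        gt_boxes = cohort.ground_truth(bid).bboxes
        per_breast_gt[bid] = gt_boxes
        n_lesions += len(gt_boxes)
        n_involved += bool(gt_boxes)
        cands = _detect_on_breast(cohort, backend, bid, fold_cache)
        stage1 = [c for c in cands if c.det_score >= th.th0]
        for c in stage1:
            clip = extract_clip(stack, c.box, clip_margin_fraction, clip_patch_size)
            merge_scores(c, seq_model.score(clip), th)
        per_breast_cands[bid] = stage1

        res1 = match_detections(stage1, gt_boxes, score_attr="det_score")
        tp1 += res1.tp
        fp1 += res1.fp
        accepted = [c for c in stage1 if c.accepted]
        res2 = match_detections(accepted, gt_boxes, score_attr="final_score")
        tp2 += res2.tp
        fp2 += res2.fp
        # stage-1 FPs that the sequence stage rejected
        fp_idx = set(range(len(stage1))) - res1.matched_candidates
        removed_fp += sum(1 for i in fp_idx if not stage1[i].accepted)

    stage1_report = FoldReport(
        fold=fold,
        n_breasts=len(eval_ids),
        n_breasts_with_lesion=n_involved,
        n_lesions=n_lesions,
        tp=tp1,
        total_predictions=tp1 + fp1,
    )
    integrated_report = FoldReport(
        fold=fold,
        n_breasts=len(eval_ids),
        n_breasts_with_lesion=n_involved,
        n_lesions=n_lesions,
        tp=tp2,
        total_predictions=tp2 + fp2,
        removed_fp=removed_fp,
        baseline_fp=fp1,
    )
    froc1 = froc_curve(per_breast_cands, per_breast_gt, score_attr="det_score")
    accepted_cands = {
        b: [c for c in cl if c.accepted] for b, cl in per_breast_cands.items()
    }
    froc2 = froc_curve(accepted_cands, per_breast_gt, score_attr="final_score")
    return FoldRunResult(
        fold=fold,
        stage1=stage1_report,
        integrated=integrated_report,
        froc_stage1=froc1,
        froc_integrated=froc2,
        assembly=assembly,
        candidates=per_breast_cands,
    )


# ---------------------------------------------------------------------------
# full cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CrossvalResult:
    folds: list[FoldRunResult]
    split: SplitManifest

    def summary(self) -> dict:
        s1_sens = [f.stage1.sensitivity for f in self.folds]
        s2_sens = [f.integrated.sensitivity for f in self.folds]
        s1_ppv = [f.stage1.ppv for f in self.folds]
        s2_ppv = [f.integrated.ppv for f in self.folds]
        reductions = [f.integrated.fp_reduction_fraction for f in self.folds]
        pooled_removed = sum(f.integrated.removed_fp for f in self.folds)
        pooled_baseline = sum(f.integrated.baseline_fp or 0 for f in self.folds)
        return {
            "stage1_sensitivity": aggregate_folds(s1_sens),
            "integrated_sensitivity": aggregate_folds(s2_sens),
            "stage1_ppv": aggregate_folds(s1_ppv),
            "integrated_ppv": aggregate_folds(s2_ppv),
            "fp_reduction_fraction": aggregate_folds(reductions),
            "pooled_fp_reduction": (
                pooled_removed / pooled_baseline if pooled_baseline else 0.0
            ),
        }

    def to_frame(self):
        import pandas as pd

        rows = []
        for f in self.folds:
            s1, s2 = f.stage1, f.integrated
            rows.append(
                {
                    "fold": f.fold,
                    "n_breasts": s1.n_breasts,
                    "n_breasts_with_lesion": s1.n_breasts_with_lesion,
                    "n_lesions": s1.n_lesions,
                    "stage1_sensitivity": s1.sensitivity,
                    "stage1_ppv": s1.ppv,
                    "stage1_tp": s1.tp,
                    "stage1_predictions": s1.total_predictions,
                    "integrated_sensitivity": s2.sensitivity,
                    "integrated_ppv": s2.ppv,
                    "integrated_tp": s2.tp,
                    "integrated_predictions": s2.total_predictions,
                    "removed_fp": s2.removed_fp,
                    "fp_reduction_fraction": s2.fp_reduction_fraction,
                }
            )
        return pd.DataFrame(rows)


def run_crossval(
    cohort: Cohort,
    k: int = 5,
    seed: int = 0,
    thresholds: ThresholdConfig | None = None,
    backend_name: str = "blob",
    backend_params: dict | None = None,
    clip_margin_fraction: float = 0.2,
    clip_patch_size: int = 32,
) -> CrossvalResult:
    """Run all folds; the detection cache is shared across folds only for
    the analytic (training-free) backend, whose predictions do not depend on
    the fold."""
    records = cohort.records()
    split = group_shuffle_split(records, k=k, seed=seed)
    backend = make_backend(backend_name, backend_params, seed=seed)
    shared_cache: dict[str, list[Candidate]] | None = (
        {} if not getattr(backend, "trainable", False) else None
    )
    folds = []
    for fold in range(k):
        fold_backend = (
            backend
            if not getattr(backend, "trainable", False)
            else make_backend(backend_name, backend_params, seed=seed + fold)
        )
        folds.append(
            run_fold(
                cohort,
                split,
                fold,
                thresholds=thresholds,
                backend=fold_backend,
                clip_margin_fraction=clip_margin_fraction,
                clip_patch_size=clip_patch_size,
                seed=seed + 1000 * fold,
                detection_cache=shared_cache,
            )
        )
    return CrossvalResult(folds=folds, split=split)
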