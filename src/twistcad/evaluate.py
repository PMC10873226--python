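"""Detection matching, FROC analysis and per-fold screening metrics.

Localisation correctness: a candidate *hits* a ground-truth box if the
candidate's centre lies inside the box OR their IoU is at least 0.3
(centre-hit is the standard criterion in breast CAD free-response analysis;
the IoU clause adds robustness for large lesions). Candidates are assigned
greedily in descending score, one-to-one; unmatched candidates are false
positives, unmatched ground-truth boxes false negatives.

FROC curves sweep the distinct candidate scores as thresholds; at each cut
sensitivity is matched lesions over total lesions and the false-positive
rate is total unmatched accepted candidates over the total breast count
(uninvolved breasts included). Sensitivity at an operating point ``p`` (in
false positives per breast) is the maximum sensitivity among cuts with
``fppb <= p`` — a step convention without interpolation.

Printed metrics are rounded to two decimals, half away from zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import Candidate, iou
from .preprocess import BBox

__all__ = [
    "MatchResult",
    "FrocCurve",
    "FoldReport",
    "DEFAULT_OPERATING_POINTS",
    "match_detections",
    "froc_curve",
    "fold_metrics",
    "aggregate_folds",
    "round_half_away",
    "hits",
    "froc_fixture",
    "plot_froc",
]

DEFAULT_OPERATING_POINTS: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0)

IOU_HIT_THRESHOLD = 0.3


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round half away from zero (so 0.005 -> 0.01, -0.005 -> -0.01)."""
    factor = 10**decimals
    return float(np.sign(value) * np.floor(abs(value) * factor + 0.5) / factor)


def hits(candidate_box: BBox, gt_box: BBox) -> bool:
    """Hit criterion: candidate centre inside the box OR IoU >= 0.3."""
    cx, cy = candidate_box.center
    inside = gt_box.x <= cx < gt_box.x2 and gt_box.y <= cy < gt_box.y2
    return inside or iou(candidate_box, gt_box) >= IOU_HIT_THRESHOLD


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (cand idx, gt idx)

    @property
    def matched_candidates(self) -> set[int]:
        return {c for c, _ in self.pairs}

    @property
    def matched_gt(self) -> set[int]:
        return {g for _, g in self.pairs}


def _score_of(cand: Candidate, score_attr: str) -> float:
    v = getattr(cand, score_attr)
    return cand.det_score if v is None else float(v)


def match_detections(
    candidates: Sequence[Candidate],
    gt_boxes: Sequence[BBox],
    score_attr: str = "final_score",
) -> MatchResult:
    """Greedy one-to-one assignment of candidates to ground-truth boxes.

    Candidates are visited in descending score (ties broken by box x, then
    y); each is matched to the unmatched ground-truth box it hits with the
    highest IoU (ties broken by lower ground-truth index).
    """
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-_score_of(candidates[i], score_attr),
                       candidates[i].box.x, candidates[i].box.y),
    )
    taken: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for ci in order:
        cbox = candidates[ci].box
        best_gi, best_iou = -1, -1.0
        for gi, gbox in enumerate(gt_boxes):
            if gi in taken or not hits(cbox, gbox):
                continue
            overlap = iou(cbox, gbox)
            if overlap > best_iou:
                best_gi, best_iou = gi, overlap
        if best_gi >= 0:
            taken.add(best_gi)
            pairs.append((ci, best_gi))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(candidates) - tp, fn=len(gt_boxes) - tp, pairs=pairs)


# ---------------------------------------------------------------------------
# FROC
# ---------------------------------------------------------------------------


@dataclass
class FrocCurve:
    thresholds: np.ndarray  # descending score cuts
    sensitivity: np.ndarray
    fppb: np.ndarray
    n_lesions: int
    n_breasts: int
    operating_points: tuple[float, ...] = DEFAULT_OPERATING_POINTS

    def sensitivity_at(self, fp_per_breast: float) -> float:
        """Max sensitivity among cuts with fppb <= the operating point."""
        ok = self.fppb <= fp_per_breast + 1e-12
        return float(self.sensitivity[ok].max()) if ok.any() else 0.0

    def summary(self) -> dict[str, float]:
        return {f"sens@{p:g}": self.sensitivity_at(p) for p in self.operating_points}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fppb": self.fppb, "sensitivity": self.sensitivity}
        )


def froc_curve(
    per_breast_candidates: Mapping[str, Sequence[Candidate]],
    per_breast_gt: Mapping[str, Sequence[BBox]],
    score_attr: str = "final_score",
    operating_points: Sequence[float] = DEFAULT_OPERATING_POINTS,
) -> FrocCurve:
    """Free-response curve over all breasts (uninvolved ones included).

    Every key of ``per_breast_gt`` names an evaluated breast; breasts
    without candidates contribute to the false-positive denominator.
    """
    breast_ids = list(per_breast_gt.keys())
    n_breasts = len(breast_ids)
    n_lesions = sum(len(per_breast_gt[b]) for b in breast_ids)
    if n_lesions == 0:
        raise ValueError("FROC undefined: no ground-truth lesions in the evaluation set")

    all_scores = sorted(
        {
            _score_of(c, score_attr)
            for b in breast_ids
            for c in per_breast_candidates.get(b, [])
        },
        reverse=True,
    )
    if not all_scores:
        all_scores = [1.0]

    sens, fppb = [], []
    for thr in all_scores:
        total_tp = 0
        total_fp = 0
        for b in breast_ids:
            cands = [
                c
                for c in per_breast_candidates.get(b, [])
                if _score_of(c, score_attr) >= thr
            ]
            res = match_detections(cands, per_breast_gt[b], score_attr=score_attr)
            total_tp += res.tp
            total_fp += res.fp
        sens.append(total_tp / n_lesions)
        fppb.append(total_fp / n_breasts)
    return FrocCurve(
        thresholds=np.asarray(all_scores),
        sensitivity=np.asarray(sens),
        fppb=np.asarray(fppb),
        n_lesions=n_lesions,
        n_breasts=n_breasts,
        operating_points=tuple(operating_points),
    )


# ---------------------------------------------------------------------------
# fold-level metrics
# ---------------------------------------------------------------------------


@dataclass
class FoldReport:
    """Counts and derived metrics for one cross-validation fold."""

    fold: int
    n_breasts: int
    n_breasts_with_lesion: int
    n_lesions: int
    tp: int
    total_predictions: int
    removed_fp: int = 0
    baseline_fp: int | None = None  # stage-1 FP count (for reduction fraction)

    def __post_init__(self) -> None:
        for name in ("n_breasts", "n_lesions", "tp", "total_predictions", "removed_fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tp > self.n_lesions:
            raise ValueError("tp cannot exceed the number of lesions")
        if self.tp > self.total_predictions:
            raise ValueError("tp cannot exceed the number of predictions")

    @property
    def sensitivity(self) -> float:
        if self.n_lesions == 0:
            raise ZeroDivisionError("sensitivity undefined with zero lesions")
        return round_half_away(self.tp / self.n_lesions)

    @property
    def ppv(self) -> float:
        if self.total_predictions == 0:
            raise ZeroDivisionError("PPV undefined with zero predictions")
        return round_half_away(self.tp / self.total_predictions)

    @property
    def fp_reduction_fraction(self) -> float:
        if not self.baseline_fp:
            raise ZeroDivisionError("FP reduction undefined without a stage-1 baseline")
        return round_half_away(self.removed_fp / self.baseline_fp)

    def to_dict(self) -> dict:
        d = {
            "fold": self.fold,
            "n_breasts": self.n_breasts,
            "n_breasts_with_lesion": self.n_breasts_with_lesion,
            "n_lesions": self.n_lesions,
            "tp": self.tp,
            "total_predictions": self.total_predictions,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "removed_fp": self.removed_fp,
        }
        if self.baseline_fp:
            d["baseline_fp"] = self.baseline_fp
            d["fp_reduction_fraction"] = self.fp_reduction_fraction
        return d


def fold_metrics(
    n_lesions: int,
    tp: int,
    total_predictions: int,
    removed_fp: int = 0,
    baseline_fp: int | None = None,
) -> tuple[float, float, float | None]:
    """(sensitivity, PPV, FP-reduction fraction) from raw fold counts.

    ``baseline_fp`` is the stage-1 false-positive count
    (stage-1 predictions minus stage-1 true positives); the reduction
    fraction is ``removed_fp / baseline_fp``. All three values are rounded
    to two decimals, half away from zero.
    """
    if n_lesions <= 0:
        raise ZeroDivisionError("sensitivity undefined with zero lesions")
    if total_predictions <= 0:
        raise ZeroDivisionError("PPV undefined with zero predictions")
    sensitivity = round_half_away(tp / n_lesions)
    ppv = round_half_away(tp / total_predictions)
    reduction = None
    if baseline_fp is not None:
        if baseline_fp <= 0:
            raise ZeroDivisionError("FP reduction undefined with zero baseline FPs")
        reduction = round_half_away(removed_fp / baseline_fp)
    return sensitivity, ppv, reduction


def aggregate_folds(values: Sequence[float]) -> dict[str, float]:
    """Unweighted mean (rounded to 2 decimals) and (min, max) range."""
    if len(values) == 0:
        raise ValueError("cannot aggregate zero folds")
    arr = np.asarray(values, dtype=np.float64)
    return {
        "mean": round_half_away(float(arr.mean())),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def pooled_and_mean_ppv(
    tps: Sequence[int], predictions: Sequence[int]
) -> tuple[float, float]:
    """Both PPV conventions: pooled (sum/sum) and mean of per-fold values."""
    pooled = round_half_away(sum(tps) / sum(predictions))
    mean = aggregate_folds(
        [round_half_away(t / p) for t, p in zip(tps, predictions)]
    )["mean"]
    return pooled, mean


# ---------------------------------------------------------------------------
# fixture + plotting
# ---------------------------------------------------------------------------


def froc_fixture() -> tuple[dict[str, list[Candidate]], dict[str, list[BBox]], dict]:
    """Hand-enumerated 4-breast / 5-candidate free-response fixture.

    Two lesions on breasts b0 and b1; candidates in descending score:
    TP 0.9 (b0), FP 0.8 (b2), FP 0.7 (b3), TP 0.6 (b1), FP 0.5 (b2).
    Sweeping the five cuts by hand gives (sensitivity, fppb):
    (0.5, 0), (0.5, 0.25), (0.5, 0.5), (1.0, 0.5), (1.0, 0.75) — hence
    sensitivity 0.5 at 0.25 FP/breast and 1.0 at 1 FP/breast.
    """
    gt = {
        "b0": [BBox(10, 10, 10, 10)],
        "b1": [BBox(40, 40, 10, 10)],
        "b2": [],
        "b3": [],
    }

    def cand(bid, box, score):
        c = Candidate(box=box, det_score=score, breast_id=bid)
        c.final_score = score
        return c

    cands = {
        "b0": [cand("b0", BBox(11, 11, 8, 8), 0.9)],
        "b1": [cand("b1", BBox(41, 39, 9, 9), 0.6)],
        "b2": [cand("b2", BBox(70, 70, 8, 8), 0.8), cand("b2", BBox(5, 70, 8, 8), 0.5)],
        "b3": [cand("b3", BBox(20, 60, 8, 8), 0.7)],
    }
    expected = {
        "points": [(0.9, 0.0, 0.5), (0.8, 0.25, 0.5), (0.7, 0.5, 0.5),
                   (0.6, 0.5, 1.0), (0.5, 0.75, 1.0)],  # (threshold, fppb, sens)
        "sens@0.25": 0.5,
        "sens@0.5": 1.0,
        "sens@1": 1.0,
    }
    return cands, gt, expected


def plot_froc(curves: Mapping[str, FrocCurve], path: str | Path) -> None:
    """Plot one or more FROC curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        order = np.argsort(curve.fppb)
        ax.step(curve.fppb[order], curve.sensitivity[order], where="post", label=name)
    ax.set_xlabel("false positives per breast")
    ax.set_ylabel("sensitivity")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reports_to_frame(reports: Sequence[FoldReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])


def write_reports(
    reports: Sequence[FoldReport], csv_path: str | Path, json_path: str | Path | None = None
) -> None:
    df = reports_to_frame(reports)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps([r.to_dict() for r in reports], indent=1))
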