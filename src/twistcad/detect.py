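"""Stage-1 candidate detection on the final subtraction MIP.

The production system this mirrors fine-tunes a large one-stage object
detector on the last-timepoint subtraction MIPs (the last timepoint is used
so that slowly enhancing benign lesions are visible). Re-training such a
detector is out of scope here; instead the stage is a *contract*
(:class:`DetectorBackend`) with two bundled backends:

* :class:`BlobDetector` — an analytic multi-scale difference-of-Gaussians
  detector, deterministic and training-free;
* :class:`HeatmapDetector` — a small trainable pixel-wise logistic
  objectness model over Gaussian/DoG feature maps, fit in seconds on CPU.

External detectors interoperate through YOLO-text prediction files with a
confidence column (see :mod:`twistcad.preprocess`).

Training-set assembly follows the screening-imbalance recipe: every involved
breast enters the training set, an equal number of uninvolved breasts is
subsampled, and the remaining negatives form the *isolated negative set*
that is merged back at test time to restore screening prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage

from .preprocess import BBox

logger = logging.getLogger(__name__)

__all__ = [
    "Candidate",
    "DetectorBackend",
    "BlobDetector",
    "HeatmapDetector",
    "TrainingAssembly",
    "blob_detect",
    "nms",
    "iou",
    "assemble_training_set",
]


@dataclass
class Candidate:
    """A scored detector box, later augmented by the sequence stage."""

    box: BBox
    det_score: float
    breast_id: str = ""
    exam_id: str = ""
    timepoint_source: int = 14
    seq_score: float | None = None
    final_score: float | None = None
    accepted: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.det_score <= 1.0:
            raise ValueError(f"det_score {self.det_score} outside [0, 1]")


class DetectorBackend(Protocol):
    """Contract every stage-1 backend satisfies.

    ``predict`` must be deterministic given the trained state and input;
    ``fit`` may be a no-op for analytic backends.
    """

    def fit(self, images: Sequence[np.ndarray], boxes: Sequence[Sequence[BBox]]) -> None: ...

    def predict(self, image: np.ndarray) -> list[Candidate]: ...


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ix = max(0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def nms(candidates: Sequence[Candidate], iou_threshold: float = 0.45) -> list[Candidate]:
    """Greedy non-maximum suppression.

    Candidates are visited in descending ``det_score`` (ties broken by
    smaller x, then smaller y); one is suppressed if its IoU with any
    already-kept candidate reaches the threshold.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = sorted(candidates, key=lambda c: (-c.det_score, c.box.x, c.box.y))
    kept: list[Candidate] = []
    for cand in order:
        if all(iou(cand.box, k.box) < iou_threshold for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# reference backend: multi-scale difference of Gaussians
# ---------------------------------------------------------------------------


def blob_detect(
    image: np.ndarray,
    min_sigma: float = 1.5,
    max_sigma: float = 8.0,
    n_scales: int = 6,
    peak_percentile: float = 98.0,
    iou_threshold: float = 0.45,
    max_candidates: int = 50,
) -> list[Candidate]:
    """Detect bright blobs on an 8-bit MIP with a DoG scale stack.

    Local maxima of the scale-normalised difference-of-Gaussians response
    that exceed the ``peak_percentile`` of the response over nonzero image
    pixels become candidates. The box side is ``2*sqrt(2)*sigma`` of the
    detecting scale and ``det_score`` is the peak response divided by the
    image's maximum response, so scores lie in (0, 1].
    """
    if min_sigma >= max_sigma:
        raise ValueError("min_sigma must be < max_sigma")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    nonzero = image > 0
    if not nonzero.any():
        return []

    sigmas = np.geomspace(min_sigma, max_sigma, n_scales + 1)
    smoothed = [ndimage.gaussian_filter(image, s) for s in sigmas]
    # scale-normalised DoG responses
    stack = np.stack(
        [
            (smoothed[i] - smoothed[i + 1]) * (sigmas[i] / (sigmas[i + 1] - sigmas[i]))
            for i in range(n_scales)
        ]
    )
    threshold = np.percentile(stack[:, nonzero], peak_percentile)
    max_resp = float(stack.max())
    if max_resp <= 0:
        return []

    local_max = stack == ndimage.maximum_filter(stack, size=3, mode="constant", cval=-np.inf)
    peaks = np.argwhere(local_max & (stack > max(threshold, 0.0)))
    height, width = image.shape
    cands: list[Candidate] = []
    for si, py, px in peaks:
        sigma = sigmas[si]
        side = max(2, int(round(2.0 * np.sqrt(2.0) * sigma)))
        x = int(px - side // 2)
        y = int(py - side // 2)
        try:
            box = BBox(x, y, side, side, label="candidate").clipped(height, width)
        except ValueError:
            continue
        score = float(stack[si, py, px] / max_resp)
        cands.append(Candidate(box=box, det_score=min(1.0, max(0.0, score))))
    kept = nms(cands, iou_threshold)
    return kept[:max_candidates]


@dataclass
class BlobDetector:
    """Analytic reference backend wrapping :func:`blob_detect` (no training)."""

    min_sigma: float = 1.5
    max_sigma: float = 8.0
    n_scales: int = 6
    peak_percentile: float = 98.0
    iou_threshold: float = 0.45
    max_candidates: int = 50

    trainable: bool = False

    def fit(self, images: Sequence[np.ndarray], boxes: Sequence[Sequence[BBox]]) -> None:
        return None

    def predict(self, image: np.ndarray) -> list[Candidate]:
        return blob_detect(
            image,
            min_sigma=self.min_sigma,
            max_sigma=self.max_sigma,
            n_scales=self.n_scales,
            peak_percentile=self.peak_percentile,
            iou_threshold=self.iou_threshold,
            max_candidates=self.max_candidates,
        )


# ---------------------------------------------------------------------------
# trainable backend: pixel-wise logistic objectness heatmap
# ---------------------------------------------------------------------------


def _pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature maps for the objectness model.

    Intensity pyramid and DoG bands capture brightness and scale; the
    scale-normalised Laplacian and Hessian blobness separate compact blobs
    (lesions) from elongated structures (vessels); distance to the breast
    boundary separates interior lesions from nipples, which sit on the skin
    line.
    """
    img = np.asarray(image, dtype=np.float64) / 255.0
    feats = [img]
    sig = [0.8, 1.5, 3.0, 6.0]
    smoothed = [ndimage.gaussian_filter(img, s) for s in sig]
    feats.extend(smoothed)
    for i in range(len(sig) - 1):
        feats.append(smoothed[i] - smoothed[i + 1])
    for s in (1.0, 2.5):
        feats.append(-(s**2) * ndimage.gaussian_laplace(img, s))
        sm = ndimage.gaussian_filter(img, s)
        hxx = ndimage.sobel(ndimage.sobel(sm, 1), 1)
        hyy = ndimage.sobel(ndimage.sobel(sm, 0), 0)
        hxy = ndimage.sobel(ndimage.sobel(sm, 0), 1)
        trace = hxx + hyy
        determinant = hxx * hyy - hxy**2
        disc = np.sqrt(np.maximum(trace**2 / 4 - determinant, 0.0))
        l1, l2 = trace / 2 - disc, trace / 2 + disc
        blobness = np.where(
            (l1 < 0) & (l2 < 0), np.abs(l1) / (np.abs(l2) + 1e-9), 0.0
        )
        feats.append(blobness)
    support = ndimage.binary_fill_holes(ndimage.gaussian_filter(img, 2.0) > 0.02)
    dist = ndimage.distance_transform_edt(support)
    feats.append(np.minimum(dist, 20.0) / 20.0)
    return np.stack(feats, axis=-1)  # (H, W, F)


@dataclass
class HeatmapDetector:
    """Trainable objectness-heatmap backend (logistic regression per pixel).

    Positive pixels lie inside ground-truth boxes (shrunk toward the
    centre); negatives are subsampled from the remainder. At predict time
    the probability heatmap is smoothed, local maxima become candidates and
    the box is the tight component above half the peak probability around
    each maximum. ``det_score`` is the peak probability, hence comparable
    across images.
    """

    seed: int = 0
    peak_probability: float = 0.02
    iou_threshold: float = 0.45
    max_candidates: int = 50
    negative_ratio: float = 5.0

    trainable: bool = True
    _model: object | None = field(default=None, repr=False)

    def fit(self, images: Sequence[np.ndarray], boxes: Sequence[Sequence[BBox]]) -> None:
        from sklearn.linear_model import LogisticRegression

        if len(images) == 0:
            raise ValueError("cannot fit the heatmap detector on an empty set")
        rng = np.random.default_rng(self.seed)
        X_parts, y_parts = [], []
        for image, box_list in zip(images, boxes):
            feats = _pixel_features(image)
            h, w, nf = feats.shape
            pos = np.zeros((h, w), dtype=bool)
            for b in box_list:
                # shrink the box by a quarter per side: label core lesion pixels
                dx, dy = b.w // 4, b.h // 4
                pos[b.y + dy : b.y2 - dy, b.x + dx : b.x2 - dx] = True
            pos_idx = np.argwhere(pos)
            neg_idx = np.argwhere(~pos)
            n_neg = int(max(200, self.negative_ratio * max(len(pos_idx), 1)))
            sel = rng.choice(len(neg_idx), size=min(n_neg, len(neg_idx)), replace=False)
            neg_idx = neg_idx[sel]
            for idx, label in ((pos_idx, 1), (neg_idx, 0)):
                if len(idx) == 0:
                    continue
                X_parts.append(feats[idx[:, 0], idx[:, 1]])
                y_parts.append(np.full(len(idx), label))
        X = np.concatenate(X_parts)
        y = np.concatenate(y_parts)
        if len(np.unique(y)) < 2:
            raise ValueError("heatmap detector training needs both classes")
        model = LogisticRegression(max_iter=500, C=10.0)
        model.fit(X, y)
        self._model = model

    def predict(self, image: np.ndarray) -> list[Candidate]:
        if self._model is None:
            raise RuntimeError("HeatmapDetector.predict called before fit")
        feats = _pixel_features(image)
        h, w, nf = feats.shape
        prob = self._model.predict_proba(feats.reshape(-1, nf))[:, 1].reshape(h, w)
        prob = ndimage.gaussian_filter(prob, 0.5)
        local_max = prob == ndimage.maximum_filter(prob, size=5, mode="constant")
        peaks = np.argwhere(local_max & (prob >= self.peak_probability))
        cands: list[Candidate] = []
        for py, px in peaks:
            peak_p = prob[py, px]
            # component above half the peak around the maximum fixes the box
            above = prob >= 0.5 * peak_p
            lab, _ = ndimage.label(above)
            comp = lab == lab[py, px]
            rows = np.flatnonzero(comp.any(axis=1))
            cols = np.flatnonzero(comp.any(axis=0))
            box = BBox(
                int(cols[0]), int(rows[0]),
                int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1),
                label="candidate",
            )
            cands.append(Candidate(box=box, det_score=float(peak_p)))
        kept = nms(cands, self.iou_threshold)
        return kept[: self.max_candidates]


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------


@dataclass
class TrainingAssembly:
    """Balanced detector training set plus the isolated negative set."""

    positive_ids: list[str]
    negative_ids: list[str]
    isolated_negative_ids: list[str]

    @property
    def balanced_ids(self) -> list[str]:
        return self.positive_ids + self.negative_ids


def assemble_training_set(
    records: Sequence[dict],
    fold_train_ids: Sequence[str],
    rng: np.random.Generator,
) -> TrainingAssembly:
    """Balance a fold's training breasts for detector training.

    All involved breasts are kept; uninvolved breasts are subsampled
    without replacement to the same count. The remaining uninvolved
    breasts become the isolated negative set, merged back into the fold's
    test data at evaluation time to restore screening prevalence.
    """
    train_ids = set(fold_train_ids)
    by_id = {r["breast_id"]: r for r in records}
    positives = [bid for bid in fold_train_ids if by_id[bid]["involved"]]
    negatives = [bid for bid in fold_train_ids if not by_id[bid]["involved"]]
    if len(positives) == 0:
        logger.error("assemble_training_set: no involved breasts in the training fold")
        return TrainingAssembly([], [], sorted(negatives))
    if len(positives) > len(negatives):
        raise ValueError(
            f"cannot balance: {len(positives)} positives but only "
            f"{len(negatives)} negatives available"
        )
    chosen = rng.choice(len(negatives), size=len(positives), replace=False)
    chosen_set = {negatives[i] for i in chosen}
    balanced_negatives = [bid for bid in negatives if bid in chosen_set]
    isolated = [bid for bid in negatives if bid not in chosen_set]
    return TrainingAssembly(
        positive_ids=list(positives),
        negative_ids=balanced_negatives,
        isolated_negative_ids=isolated,
    )
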