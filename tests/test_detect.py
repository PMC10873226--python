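"""Stage-1 detection: blob backend, NMS, training-set assembly, trainable backend."""

import numpy as np
import pytest

from twistcad.detect import (
    BlobDetector,
    Candidate,
    HeatmapDetector,
    assemble_training_set,
    blob_detect,
    iou,
    nms,
)
from twistcad.preprocess import BBox, normalize_image


def _gaussian_blob(shape, cy, cx, sigma, amp=255.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


def nms_oracle(candidates, thr):
    """Independent NMS: repeatedly take the global best remaining candidate
    and drop everything overlapping it."""
    remaining = sorted(candidates, key=lambda c: (-c.det_score, c.box.x, c.box.y))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [c for c in remaining if iou(c.box, best.box) < thr]
    return kept


def random_candidates(rng, n, extent=100):
    out = []
    for _ in range(n):
        x, y = rng.integers(0, extent - 1, size=2)
        w, h = rng.integers(2, 30, size=2)
        out.append(
            Candidate(
                box=BBox(int(x), int(y), int(w), int(h)),
                det_score=float(rng.integers(0, 20)) / 20.0,
            )
        )
    return out


class TestNms:
    def test_single_candidate_unchanged(self):
        c = Candidate(box=BBox(0, 0, 5, 5), det_score=0.5)
        assert nms([c], 0.45) == [c]

    def test_duplicate_boxes_keep_higher_score(self):
        hi = Candidate(box=BBox(10, 10, 8, 8), det_score=0.9)
        lo = Candidate(box=BBox(10, 10, 8, 8), det_score=0.7)
        assert nms([lo, hi], 0.45) == [hi]

    def test_matches_bruteforce_reference(self, rng):
        for _ in range(50):
            cands = random_candidates(rng, 50)
            assert nms(cands, 0.45) == nms_oracle(cands, 0.45)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            nms([], 1.0)


class TestBlobDetect:
    def test_blank_image_has_no_candidates(self):
        assert blob_detect(np.zeros((64, 64), dtype=np.uint8)) == []

    def test_single_blob_localised(self):
        img = _gaussian_blob((96, 128), 40, 60, 3.0).astype(np.uint8)
        cands = blob_detect(img)
        assert len(cands) == 1
        cx, cy = cands[0].box.center
        assert abs(cx - 60) <= 2 and abs(cy - 40) <= 2
        assert cands[0].det_score == pytest.approx(1.0)

    def test_two_separated_blobs_survive_nms(self):
        img = (
            _gaussian_blob((96, 128), 40, 40, 3.0) + _gaussian_blob((96, 128), 40, 80, 3.0)
        ).astype(np.uint8)
        cands = blob_detect(img)
        assert len(cands) == 2
        centers = sorted(c.box.center[0] for c in cands)
        assert abs(centers[0] - 40) <= 2 and abs(centers[1] - 80) <= 2

    def test_scores_in_unit_interval(self, small_cohort):
        bid = next(p.breast_id for p in small_cohort.plans if p.involved)
        img = normalize_image(small_cohort.mip_stack(bid).last)
        cands = blob_detect(img)
        assert cands, "phantom lesion breast should produce candidates"
        assert all(0.0 < c.det_score <= 1.0 for c in cands)

    def test_intensity_rescaling_preserves_candidates(self, small_cohort):
        bid = next(p.breast_id for p in small_cohort.plans if p.involved)
        raw = small_cohort.mip_stack(bid).last
        a = blob_detect(normalize_image(raw))
        b = blob_detect(normalize_image(raw * 2.7))
        assert [(c.box, round(c.det_score, 9)) for c in a] == [
            (c.box, round(c.det_score, 9)) for c in b
        ]

    def test_bad_sigma_range_rejected(self):
        with pytest.raises(ValueError):
            blob_detect(np.zeros((8, 8)), min_sigma=5.0, max_sigma=2.0)


class TestAssembleTrainingSet:
    @staticmethod
    def _records(n_pos, n_neg):
        recs = [{"breast_id": f"P{i}", "involved": True} for i in range(n_pos)]
        recs += [{"breast_id": f"N{i}", "involved": False} for i in range(n_neg)]
        return recs

    def test_balancing_counts(self, rng):
        recs = self._records(10, 50)
        ids = [r["breast_id"] for r in recs]
        asm = assemble_training_set(recs, ids, rng)
        assert len(asm.positive_ids) == 10
        assert len(asm.negative_ids) == 10
        assert len(asm.isolated_negative_ids) == 40

    def test_negative_partition_is_exact(self, rng):
        recs = self._records(7, 23)
        ids = [r["breast_id"] for r in recs]
        asm = assemble_training_set(recs, ids, rng)
        negatives = {r["breast_id"] for r in recs if not r["involved"]}
        assert set(asm.negative_ids) | set(asm.isolated_negative_ids) == negatives
        assert not set(asm.negative_ids) & set(asm.isolated_negative_ids)

    def test_no_positives_logs_error_and_returns_empty(self, rng, caplog):
        recs = self._records(0, 5)
        asm = assemble_training_set(recs, [r["breast_id"] for r in recs], rng)
        assert asm.balanced_ids == []
        assert len(asm.isolated_negative_ids) == 5
        assert any("no involved breasts" in r.message for r in caplog.records)

    def test_more_positives_than_negatives_rejected(self, rng):
        recs = self._records(6, 3)
        with pytest.raises(ValueError, match="cannot balance"):
            assemble_training_set(recs, [r["breast_id"] for r in recs], rng)

    def test_seeded_selection_reproducible(self):
        recs = self._records(5, 40)
        ids = [r["breast_id"] for r in recs]
        a = assemble_training_set(recs, ids, np.random.default_rng(3))
        b = assemble_training_set(recs, ids, np.random.default_rng(3))
        assert a.negative_ids == b.negative_ids


class TestHeatmapDetector:
    def test_predict_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            HeatmapDetector().predict(np.zeros((32, 32), dtype=np.uint8))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            HeatmapDetector().fit([], [])

    def test_fit_predict_on_phantoms(self, small_cohort):
        involved = [p.breast_id for p in small_cohort.plans if p.involved][:5]
        uninvolved = [p.breast_id for p in small_cohort.plans if not p.involved][:5]
        ids = involved + uninvolved
        images = [normalize_image(small_cohort.mip_stack(b).last) for b in ids]
        boxes = [small_cohort.ground_truth(b).bboxes for b in ids]
        det = HeatmapDetector(seed=0)
        det.fit(images, boxes)
        # deterministic predictions
        preds_a = det.predict(images[0])
        preds_b = det.predict(images[0])
        assert [(c.box, c.det_score) for c in preds_a] == [
            (c.box, c.det_score) for c in preds_b
        ]
        # background images never yield confident candidates
        zero_preds = det.predict(np.zeros_like(images[0]))
        assert all(c.det_score < 0.5 for c in zero_preds)

    def test_trained_backend_finds_heldout_lesions(self):
        """Trainable backend reaches high sensitivity at 2 FP/breast on phantoms.

        The high-sensitivity claim is asserted for lesions of at least
        10 mm: at the phantom's 2 mm voxel pitch a 5 mm lesion projects to a
        2-pixel dot carrying no shape information, so sub-resolution lesions
        cannot be ranked above the phantom's deliberately enhancing
        confounders by any single-timepoint detector. Overall sensitivity
        (all lesions, including sub-resolution ones) is asserted looser.
        """
        from twistcad.evaluate import froc_curve
        from twistcad.phantom import Cohort, CohortConfig

        cohort = Cohort(CohortConfig(n_breasts=100, seed=7))
        train_pool = set(cohort.breast_ids[:50])
        involved = [p.breast_id for p in cohort.plans if p.involved]
        uninvolved = [p.breast_id for p in cohort.plans if not p.involved]
        tr_pos = [b for b in involved if b in train_pool]
        tr_neg = [b for b in uninvolved if b in train_pool][: len(tr_pos)]
        test_ids = [b for b in cohort.breast_ids if b not in train_pool]
        det = HeatmapDetector(seed=0)
        det.fit(
            [normalize_image(cohort.mip_stack(b).last) for b in tr_pos + tr_neg],
            [cohort.ground_truth(b).bboxes for b in tr_pos + tr_neg],
        )
        cands = {b: det.predict(normalize_image(cohort.mip_stack(b).last)) for b in test_ids}
        gt = {b: cohort.ground_truth(b) for b in test_ids}
        resolvable = {
            b: [g.box for g in gt[b].boxes if g.diameter_mm >= 10.0] for b in test_ids
        }
        curve = froc_curve(cands, resolvable, score_attr="det_score")
        assert curve.sensitivity_at(2.0) >= 0.85
        all_lesions = {b: gt[b].bboxes for b in test_ids}
        overall = froc_curve(cands, all_lesions, score_attr="det_score")
        assert overall.sensitivity_at(2.0) >= 0.5
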