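"""Temporal clips, the gated recurrent classifier, and score merging."""

import numpy as np
import pytest

from twistcad.detect import Candidate
from twistcad.fpreduce import (
    Clip,
    GRUSequenceClassifier,
    ThresholdConfig,
    _backward,
    _forward,
    _init_params,
    extract_clip,
    fit_sequence_model,
    frame_features,
    merge_scores,
)
from twistcad.phantom import synthetic_clip_task
from twistcad.preprocess import BBox, MipStack


def _stack(arrays):
    return MipStack(mips=[a.astype(np.float32) for a in arrays], pixel_size=2.0)


class TestExtractClip:
    def test_shape_contract(self, rng):
        stack = _stack([rng.random((40, 50)) for _ in range(14)])
        clip = extract_clip(stack, BBox(10, 5, 8, 12), patch_size=32)
        assert clip.frames.shape == (14, 32, 32)
        assert 0.0 <= clip.frames.min() and clip.frames.max() <= 1.0

    def test_full_image_box_equals_resized_mips(self, rng):
        from skimage.transform import resize

        mips = [rng.random((40, 40)) for _ in range(3)]
        stack = _stack(mips)
        clip = extract_clip(stack, BBox(0, 0, 40, 40), margin_fraction=0.0, patch_size=16)
        ref = np.stack(
            [
                resize(m, (16, 16), order=1, mode="edge", anti_aliasing=False,
                       preserve_range=True)
                for m in mips
            ]
        )
        ref /= ref.max()
        assert np.allclose(clip.frames, ref, atol=1e-6)

    def test_all_zero_clip_stays_zero(self):
        stack = _stack([np.zeros((20, 20)) for _ in range(5)])
        clip = extract_clip(stack, BBox(2, 2, 6, 6))
        assert np.all(clip.frames == 0)

    def test_phantom_lesion_mean_rises_during_wash_in(self, small_cohort):
        cfg = small_cohort.config
        plan = next(p for p in small_cohort.plans if p.involved)
        stack = small_cohort.mip_stack(plan.breast_id)
        gt = small_cohort.ground_truth(plan.breast_id)
        for lesion, g in zip(plan.lesions, gt.boxes):
            clip = extract_clip(stack, g.box)
            means = clip.frames.mean(axis=(1, 2))
            times = cfg.times[1:]  # sub1..sub14 acquisition times
            k = lesion.kinetics
            on_rise = (times >= k.time_to_enhancement) & (
                times <= k.time_to_enhancement + k.rise_duration
            )
            rise_means = means[on_rise]
            if len(rise_means) >= 2:
                assert np.all(np.diff(rise_means) >= -0.01)

    def test_negative_margin_rejected(self, rng):
        stack = _stack([rng.random((20, 20))])
        with pytest.raises(ValueError):
            extract_clip(stack, BBox(0, 0, 5, 5), margin_fraction=-0.1)


class TestFrameFeatures:
    def test_pooling_geometry(self):
        frames = np.zeros((2, 32, 32), dtype=np.float32)
        frames[0, :8, :8] = 1.0  # exactly the first 8x8 pooling block
        feats = frame_features(frames, grid=4)
        assert feats.shape == (2, 16)
        assert feats[0, 0] == pytest.approx(1.0)
        assert feats[0, 1:].sum() == 0.0


class TestGruInternals:
    def test_analytic_gradients_match_numerical(self):
        rng = np.random.default_rng(0)
        N, T, D, H = 3, 5, 4, 4
        X = rng.normal(size=(N, T, D))
        y = np.array([1.0, 0.0, 1.0])
        params = _init_params(D, H, rng)
        params["wo"] = rng.normal(0, 0.5, size=(H, 1))

        def loss(p):
            probs, _, _ = _forward(p, X)
            probs = np.clip(probs, 1e-12, 1 - 1e-12)
            return -np.mean(y * np.log(probs) + (1 - y) * np.log(1 - probs))

        probs, h, cache = _forward(params, X)
        grads = _backward(params, cache, h, (probs - y) / N)
        eps = 1e-6
        for key, arr in params.items():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in range(min(arr.size, 5)):
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss(params)
                arr[idx] = orig - eps
                lm = loss(params)
                arr[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8), key
                next(it, None)


class TestSequenceClassifier:
    def test_training_is_deterministic_under_seed(self):
        clips, labels = synthetic_clip_task(n=60, seed=2)
        a = fit_sequence_model(clips, labels, seed=4).score_many(clips)
        b = fit_sequence_model(clips, labels, seed=4).score_many(clips)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        clips, labels = synthetic_clip_task(n=20, seed=2)
        with pytest.raises(ValueError):
            fit_sequence_model(clips, np.ones_like(labels), seed=0)

    def test_scores_lie_in_unit_interval(self):
        clips, labels = synthetic_clip_task(n=60, seed=2)
        model = fit_sequence_model(clips, labels, seed=0)
        scores = model.score_many(clips)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_separates_fast_from_slow_clips(self):
        clips, labels = synthetic_clip_task(n=120, seed=3)
        test = (np.arange(120) // 2) % 4 == 0
        model = fit_sequence_model(clips[~test], labels[~test], seed=0)
        scores = model.score_many(clips[test])
        pos = scores[labels[test] == 1]
        neg = scores[labels[test] == 0]
        assert pos.mean() > neg.mean() + 0.3

    def test_save_load_round_trip(self, tmp_path):
        clips, labels = synthetic_clip_task(n=40, seed=5)
        model = fit_sequence_model(clips, labels, seed=1)
        path = tmp_path / "seq.npz"
        model.save(path)
        loaded = GRUSequenceClassifier.load(path)
        assert np.allclose(model.score_many(clips), loaded.score_many(clips))

    def test_architecture_bounds_enforced(self):
        with pytest.raises(ValueError):
            GRUSequenceClassifier(hidden_units=64)
        with pytest.raises(ValueError):
            GRUSequenceClassifier(pool_grid=5)

    def test_clip_tiff_export(self, tmp_path):
        import tifffile

        clips, _ = synthetic_clip_task(n=2, seed=0)
        from twistcad.fpreduce import export_clip_tiff

        clip = Clip(frames=clips[0])
        export_clip_tiff(clip, tmp_path / "clip.tiff")
        back = tifffile.imread(tmp_path / "clip.tiff")
        assert np.allclose(back, clips[0])


class TestMergeScores:
    TH = ThresholdConfig(0.5, 0.5)

    def test_low_sequence_score_rejected(self):
        c = Candidate(box=BBox(0, 0, 4, 4), det_score=0.8)
        accepted, final = merge_scores(c, 0.3, self.TH)
        assert not accepted
        assert final == pytest.approx(0.24)
        assert c.accepted is False  # retained for audit

    def test_perfect_scores_accepted(self):
        c = Candidate(box=BBox(0, 0, 4, 4), det_score=1.0)
        accepted, final = merge_scores(c, 1.0, self.TH)
        assert accepted and final == 1.0

    def test_detector_gate_precedes_sequence_stage(self):
        c = Candidate(box=BBox(0, 0, 4, 4), det_score=0.4)
        accepted, _ = merge_scores(c, 1.0, self.TH)
        assert not accepted

    def test_raising_th1_never_accepts_more(self, rng):
        cands = [
            Candidate(box=BBox(int(x), 0, 4, 4), det_score=float(s))
            for x, s in zip(rng.integers(0, 50, 30), rng.random(30))
        ]
        seqs = rng.random(30)
        counts = []
        for th1 in np.linspace(0, 1, 11):
            th = ThresholdConfig(0.5, float(th1))
            counts.append(
                sum(merge_scores(c, float(s), th)[0] for c, s in zip(cands, seqs))
            )
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_out_of_range_seq_score_rejected(self):
        c = Candidate(box=BBox(0, 0, 4, 4), det_score=0.8)
        with pytest.raises(ValueError):
            merge_scores(c, 1.2, self.TH)
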