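"""Phantom generator: kinetics, geometry, cohort structure, determinism."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from twistcad.phantom import (
    Cohort,
    CohortConfig,
    DEFAULT_KINETICS,
    GroundTruth,
    KineticParams,
    LesionSpec,
    enhancement_curve,
    generate_cohort,
    generate_exam,
    plan_cohort,
)
from twistcad.preprocess import load_series_nifti, mip_stack_from_series, read_labelme


class TestEnhancementCurve:
    def test_zero_amplitude_gives_zeros(self):
        k = KineticParams(10.0, 20.0, 0.0)
        assert np.all(enhancement_curve(k, [0, 5, 50, 100]) == 0)

    def test_pre_enhancement_is_zero(self):
        k = KineticParams(60.0, 30.0, 100.0)
        assert np.all(enhancement_curve(k, [0, 30, 59]) == 0)

    def test_linear_rise_midpoint(self):
        k = KineticParams(20.0, 40.0, 100.0, 0.0)
        assert enhancement_curve(k, [40.0])[0] == pytest.approx(50.0)

    def test_washout_declines_and_floors_at_zero(self):
        k = KineticParams(0.0, 10.0, 100.0, 2.0)
        vals = enhancement_curve(k, [10.0, 30.0, 200.0])
        assert vals[0] == pytest.approx(100.0)
        assert vals[1] == pytest.approx(60.0)
        assert vals[2] == 0.0

    def test_non_increasing_times_rejected(self):
        k = KineticParams(0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            enhancement_curve(k, [0.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            enhancement_curve(k, [-1.0, 5.0])

    @given(
        tte=st.floats(0, 60),
        rise=st.floats(1, 60),
        peak=st.floats(0, 500),
        washout=st.floats(0, 3),
    )
    def test_nonnegative_and_monotone_on_rise(self, tte, rise, peak, washout):
        k = KineticParams(tte, rise, peak, washout)
        times = np.linspace(0.0, 150.0, 61)
        vals = enhancement_curve(k, times)
        assert np.all(vals >= 0)
        on_rise = (times >= tte) & (times <= tte + rise)
        assert np.all(np.diff(vals[on_rise]) >= -1e-9)

    def test_default_table_orders_malignant_before_benign(self):
        assert (
            DEFAULT_KINETICS["malignant"].time_to_enhancement
            < DEFAULT_KINETICS["benign"].time_to_enhancement
        )


class TestGenerateExam:
    CFG = CohortConfig(n_breasts=2, seed=0)

    def test_sphere_footprint_box_matches_diameter(self):
        lesion = LesionSpec(
            center=(16.0, 48.0, 48.0),
            diameter_mm=22.0,
            kinetics=DEFAULT_KINETICS["malignant"],
            malignant=True,
        )
        _, _, gt = generate_exam(self.CFG, {"left": [lesion]}, np.random.default_rng(4))
        assert len(gt["left"].boxes) == 1
        box = gt["left"].boxes[0].box
        # projected footprint width in mm within +-2 voxels of the diameter
        assert abs(box.w * self.CFG.spacing[2] - 22.0) <= 2 * self.CFG.spacing[2]
        assert abs(box.h * self.CFG.spacing[1] - 22.0) <= 2 * self.CFG.spacing[1]

    def test_no_lesions_gives_empty_ground_truth(self):
        left, right, gt = generate_exam(self.CFG, {}, np.random.default_rng(1))
        assert gt["left"].boxes == [] and gt["right"].boxes == []
        assert left.n_post == self.CFG.n_post

    def test_seeded_determinism_bit_identical(self):
        lesion = LesionSpec(
            center=(16.0, 48.0, 48.0),
            diameter_mm=10.0,
            kinetics=DEFAULT_KINETICS["benign"],
            malignant=False,
        )
        runs = []
        for _ in range(2):
            left, _, _ = generate_exam(
                self.CFG, {"left": [lesion]}, np.random.default_rng(9)
            )
            runs.append([left.t0] + left.posts)
        assert all(np.array_equal(a, b) for a, b in zip(*runs))

    def test_lesion_outside_mask_raises(self):
        lesion = LesionSpec(
            center=(0.0, 0.0, 0.0),
            diameter_mm=8.0,
            kinetics=DEFAULT_KINETICS["benign"],
            malignant=False,
        )
        with pytest.raises(ValueError, match="outside"):
            generate_exam(self.CFG, {"left": [lesion]}, np.random.default_rng(0))


class TestCohortStructure:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_breasts=0)

    def test_prevalence_extremes(self):
        all_inv = plan_cohort(CohortConfig(n_breasts=20, lesion_prevalence=1.0, seed=2))
        assert all(p.involved and p.lesions for p in all_inv)
        none_inv = plan_cohort(CohortConfig(n_breasts=20, lesion_prevalence=0.0, seed=2))
        assert not any(p.involved for p in none_inv)

    def test_seeded_plan_reproducible(self):
        a = plan_cohort(CohortConfig(n_breasts=100, lesion_prevalence=0.17, seed=7))
        b = plan_cohort(CohortConfig(n_breasts=100, lesion_prevalence=0.17, seed=7))
        assert sum(p.involved for p in a) == sum(p.involved for p in b)
        assert [p.exam_seeds for p in a] == [p.exam_seeds for p in b]

    def test_default_size_medians_match_cohort_description(self):
        cfg = CohortConfig()
        assert cfg.benign_size_median == 9.0
        assert cfg.malignant_size_median == 22.0
        # realized diameters concentrate around the medians
        plans = plan_cohort(CohortConfig(n_breasts=400, lesion_prevalence=1.0, seed=3))
        benign = [l.diameter_mm for p in plans for l in p.lesions if not l.malignant]
        malignant = [l.diameter_mm for p in plans for l in p.lesions if l.malignant]
        assert abs(np.median(benign) - 9.0) < 2.0
        assert abs(np.median(malignant) - 22.0) < 5.0

    def test_involved_breasts_have_boxes_uninvolved_none(self, small_cohort):
        for plan in small_cohort.plans[:20]:
            gt = small_cohort.ground_truth(plan.breast_id)
            if plan.involved:
                assert len(gt.boxes) >= 1
            else:
                assert gt.boxes == []

    def test_boxes_inside_image_bounds(self, small_cohort):
        h, w = small_cohort.config.volume_shape[1:]
        for plan in small_cohort.plans:
            for g in small_cohort.ground_truth(plan.breast_id).boxes:
                assert 0 <= g.box.x and g.box.x2 <= w
                assert 0 <= g.box.y and g.box.y2 <= h


class TestRenderedCohort:
    def test_kinetic_separation_malignant_reaches_half_peak_earlier(self, small_cohort):
        half_times = {"malignant": [], "benign": []}
        for plan in small_cohort.plans:
            if not plan.involved:
                continue
            stack = small_cohort.mip_stack(plan.breast_id)
            arr = stack.as_array()
            for lesion, g in zip(plan.lesions, small_cohort.ground_truth(plan.breast_id).boxes):
                b = g.box
                series = arr[:, b.y : b.y2, b.x : b.x2].mean(axis=(1, 2))
                half = 0.5 * series.max()
                t_half = np.argmax(series >= half)
                half_times["malignant" if g.malignant else "benign"].append(t_half)
        assert half_times["malignant"] and half_times["benign"], "seeded cohort lacks a class"
        assert np.mean(half_times["malignant"]) < np.mean(half_times["benign"])

    def test_lesions_enhance_above_surroundings(self, small_cohort):
        for plan in small_cohort.plans:
            if not plan.involved:
                continue
            last = small_cohort.mip_stack(plan.breast_id).last
            h, w = last.shape
            for g in small_cohort.ground_truth(plan.breast_id).boxes:
                b = g.box
                inner = last[b.y : b.y2, b.x : b.x2].mean()
                pad = 4
                y1, y2 = max(0, b.y - pad), min(h, b.y2 + pad)
                x1, x2 = max(0, b.x - pad), min(w, b.x2 + pad)
                annulus = last[y1:y2, x1:x2].sum() - last[b.y : b.y2, b.x : b.x2].sum()
                n_annulus = (y2 - y1) * (x2 - x1) - b.area
                assert inner > annulus / n_annulus

    def test_mip_rendering_deterministic(self, small_cohort):
        bid = small_cohort.breast_ids[0]
        fresh = Cohort(small_cohort.config)
        a = small_cohort.mip_stack(bid).as_array()
        b = fresh.mip_stack(bid).as_array()
        assert np.array_equal(a, b)


class TestCohortPersistence:
    def test_save_round_trips_volumes_and_annotations(self, tmp_path):
        cfg = CohortConfig(n_breasts=3, seed=5, volume_shape=(16, 48, 48))
        cohort = generate_cohort(cfg, out_dir=tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert len(manifest["breasts"]) == 3
        for rec in manifest["breasts"]:
            series = load_series_nifti(
                tmp_path / rec["exams"][0]["path"], breast_id=rec["breast_id"]
            )
            assert series.n_post == cfg.n_post
            on_disk = mip_stack_from_series(series)
            in_memory = cohort.mip_stack(rec["breast_id"])
            assert all(
                np.array_equal(a, b) for a, b in zip(on_disk.mips, in_memory.mips)
            )
            boxes = read_labelme(tmp_path / rec["ground_truth"])
            assert len(boxes) == len(cohort.ground_truth(rec["breast_id"]).boxes)

    def test_manifest_byte_identical_under_seed(self, tmp_path):
        cfg = CohortConfig(n_breasts=4, seed=11, volume_shape=(8, 24, 24))
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        assert (tmp_path / "a/manifest.json").read_bytes() == (
            tmp_path / "b/manifest.json"
        ).read_bytes()
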