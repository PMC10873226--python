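"""Synthetic ultrafast DCE-MRI phantom cohorts.

Real ultrafast (TWIST) screening exams acquire one pre-contrast volume and a
rapid train of post-contrast volumes (14 here) inside roughly 102 seconds of
contrast-agent inflow. Lesions reveal themselves by enhancement; malignant
lesions typically enhance earlier (shorter time-to-enhancement, faster
wash-in) than benign ones, and normal enhancing structures — vessels,
nipples, background parenchyma — are the dominant sources of detector false
positives.

This module renders desk-scale breast phantoms with exactly those
properties so the whole detection pipeline is testable without patient data:

* each breast is a half-axes ellipsoid mask in a small voxel grid
  (default 32 x 96 x 96 at 2 mm isotropic);
* lesions are spheres or lobulated sphere unions with class-specific
  piecewise-linear contrast kinetics (delay, linear wash-in to a peak,
  linear washout floored at zero);
* confounders: thin bright vessel tubes with fast wash-in and pronounced
  washout, a small anterior nipple blob, and optional diffuse parenchymal
  enhancement — all enhancing structures a detector will flag;
* Gaussian acquisition noise, int16 intensities, full determinism under the
  cohort seed.

Cohort structure (lesion prevalence, multi-lesion fraction, malignant
fraction, median lesion sizes) defaults to the composition of a published
screening cohort: 17% of breasts involved, 57% of involved breasts with
multiple lesions, 28.3% of lesions malignant, median diameters 9 mm
(benign) and 22 mm (malignant).

Geometry (lesion placement, ground-truth boxes) is fixed at *planning* time;
rendering only evaluates kinetics and adds noise, so ground truth never
depends on whether or when a volume is rendered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .preprocess import (
    BBox,
    MipStack,
    TwistSeries,
    mip_stack_from_series,
    save_series_nifti,
    write_labelme,
)

__all__ = [
    "KineticParams",
    "LesionSpec",
    "CohortConfig",
    "GroundTruth",
    "GroundTruthBox",
    "Cohort",
    "BreastPlan",
    "DEFAULT_KINETICS",
    "enhancement_curve",
    "generate_exam",
    "generate_cohort",
    "plan_cohort",
    "breast_mask",
    "synthetic_clip_task",
]

TOTAL_WINDOW_S = 102.0  # contrast-inflow window spanned by the post-contrast train

KINETIC_CLASSES = ("malignant", "benign", "vessel", "nipple", "parenchyma")


@dataclass(frozen=True)
class KineticParams:
    """Piecewise-linear contrast-enhancement kinetics.

    The enhancement is 0 before ``time_to_enhancement`` (TTE), rises
    linearly to ``peak_amplitude`` over ``rise_duration``, then declines at
    ``washout_slope`` (intensity/second), floored at zero. This is the
    simplest kinetic form that realises the fast (malignant-like) versus
    slow (benign-like) wash-in distinction with closed-form values.
    """

    time_to_enhancement: float
    rise_duration: float
    peak_amplitude: float
    washout_slope: float = 0.0
    class_label: str = "malignant"

    def __post_init__(self) -> None:
        if self.time_to_enhancement < 0:
            raise ValueError("time_to_enhancement must be >= 0")
        if self.rise_duration <= 0:
            raise ValueError("rise_duration must be > 0")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if self.washout_slope < 0:
            raise ValueError("washout_slope must be >= 0")
        if self.class_label not in KINETIC_CLASSES:
            raise ValueError(f"unknown kinetic class {self.class_label!r}")


#: Default kinetic parameter table. Malignant lesions enhance earlier than
#: benign ones (TTE 10 s vs 35 s); vessels and nipples enhance fast but wash
#: out strongly, which is what the temporal false-positive stage exploits;
#: parenchyma enhances late and weakly.
DEFAULT_KINETICS: dict[str, KineticParams] = {
    "malignant": KineticParams(10.0, 25.0, 300.0, 0.5, "malignant"),
    "benign": KineticParams(35.0, 50.0, 220.0, 0.0, "benign"),
    "vessel": KineticParams(3.0, 12.0, 300.0, 1.8, "vessel"),
    "nipple": KineticParams(5.0, 20.0, 180.0, 0.6, "nipple"),
    "parenchyma": KineticParams(40.0, 60.0, 45.0, 0.0, "parenchyma"),
}
assert (
    DEFAULT_KINETICS["malignant"].time_to_enhancement
    < DEFAULT_KINETICS["benign"].time_to_enhancement
)


def enhancement_curve(kinetics: KineticParams, times: Sequence[float]) -> np.ndarray:
    """Evaluate the piecewise-linear enhancement at the given times.

    ``times`` must be non-negative and strictly increasing.
    """
    t = np.asarray(times, dtype=np.float64)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1D sequence")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    tte = kinetics.time_to_enhancement
    rise = kinetics.rise_duration
    peak = kinetics.peak_amplitude
    out = np.zeros_like(t)
    rising = (t >= tte) & (t < tte + rise)
    out[rising] = peak * (t[rising] - tte) / rise
    after = t >= tte + rise
    out[after] = np.maximum(0.0, peak - kinetics.washout_slope * (t[after] - tte - rise))
    return out


# ---------------------------------------------------------------------------
# geometry specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionSpec:
    """One lesion: placement, size, shape and kinetics."""

    center: tuple[float, float, float]  # (z, y, x) voxel coordinates
    diameter_mm: float
    kinetics: KineticParams
    malignant: bool
    shape: str = "sphere"  # "sphere" or "lobulated"
    n_lobes: int = 3

    def __post_init__(self) -> None:
        if self.diameter_mm < 5.0:
            raise ValueError("lesion diameter must be >= 5 mm")
        if self.shape not in ("sphere", "lobulated"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")


@dataclass(frozen=True)
class VesselSpec:
    start: tuple[float, float, float]
    direction: tuple[float, float, float]  # unit vector
    length_vox: float
    radius_vox: float
    kinetics: KineticParams


@dataclass(frozen=True)
class NippleSpec:
    center: tuple[float, float, float]
    radius_vox: float
    kinetics: KineticParams


@dataclass(frozen=True)
class GroundTruthBox:
    box: BBox
    malignant: bool
    diameter_mm: float


@dataclass
class GroundTruth:
    """Per-breast annotation: tight boxes of each lesion's MIP footprint."""

    breast_id: str
    exam_id: str
    boxes: list[GroundTruthBox] = field(default_factory=list)

    @property
    def bboxes(self) -> list[BBox]:
        return [g.box for g in self.boxes]


@dataclass
class CohortConfig:
    """Parameters of a synthetic screening cohort.

    Defaults mirror the published screening cohort composition the pipeline
    targets; ``seed`` fully determines every volume and annotation.
    """

    n_breasts: int = 200
    lesion_prevalence: float = 0.17
    multi_lesion_fraction: float = 0.57
    malignant_fraction: float = 0.283
    benign_size_median: float = 9.0
    malignant_size_median: float = 22.0
    size_sigma: float = 0.45  # log-space spread of lesion diameters
    max_diameter_mm: float = 36.0
    confounders_per_breast: float = 2.0  # mean vessel count (Poisson); nipple always
    parenchyma_fraction: float = 0.35
    second_exam_fraction: float = 0.10
    timepoint_interval: float = TOTAL_WINDOW_S / 14
    n_post: int = 14
    volume_shape: tuple[int, int, int] = (32, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    baseline_intensity: float = 100.0
    noise_sigma: float = 6.0
    kinetics: dict[str, KineticParams] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS)
    )
    kinetic_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lesion_prevalence",
            "multi_lesion_fraction",
            "malignant_fraction",
            "parenchyma_fraction",
            "second_exam_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.n_breasts <= 0:
            raise ValueError("n_breasts must be >= 1")
        if self.n_post < 1:
            raise ValueError("n_post must be >= 1")

    @property
    def times(self) -> np.ndarray:
        """Acquisition times (s) of t0..tN; t0 at 0, equal spacing."""
        return np.arange(self.n_post + 1) * self.timepoint_interval


@dataclass
class BreastPlan:
    """Frozen geometry and identity of one phantom breast."""

    breast_id: str
    laterality: str
    involved: bool
    lesions: list[LesionSpec]
    vessels: list[VesselSpec]
    nipple: NippleSpec
    parenchyma: bool
    exam_ids: list[str]
    exam_seeds: list[int]
    field_strength_tag: str


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def breast_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Binary ellipsoid breast mask with margins on every side."""
    nz, ny, nx = shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    az, ay, ax = 0.42 * nz, 0.42 * ny, 0.42 * nx
    norm = ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2
    return (norm <= 1.0).astype(np.uint8)


def _ellipsoid_params(shape: tuple[int, int, int]):
    nz, ny, nx = shape
    center = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    semi = np.array([0.42 * nz, 0.42 * ny, 0.42 * nx])
    return center, semi


def _local_grid(shape, center, extent):
    """Integer bounding box [lo, hi) around center with the given extent."""
    lo = np.maximum(np.floor(np.asarray(center) - extent).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(center) + extent).astype(int) + 1, shape)
    return lo, hi


def _add_sphere(weight: np.ndarray, center, radius: float, soft: float = 1.0) -> None:
    """Accumulate (max) a soft-edged sphere: weight 1 inside radius-soft,
    linear falloff to 0 at radius+soft."""
    lo, hi = _local_grid(weight.shape, center, radius + soft + 1)
    z, y, x = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    dist = np.sqrt(
        (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    )
    w = np.clip((radius + soft - dist) / (2.0 * soft), 0.0, 1.0)
    region = weight[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(region, w, out=region)


def lesion_weight(spec: LesionSpec, shape, spacing) -> np.ndarray:
    """Soft-edged footprint (max 1) of a lesion in voxel space."""
    w = np.zeros(shape, dtype=np.float32)
    radius_vox = spec.diameter_mm / (2.0 * spacing[1])
    if spec.shape == "sphere":
        _add_sphere(w, spec.center, radius_vox)
    else:
        # lobulated: union of n_lobes spheres offset around the main one
        main_r = radius_vox * 0.8
        _add_sphere(w, spec.center, main_r)
        # lobe layout derives from the lesion's own placement, so footprints
        # (and hence ground-truth boxes) are reproducible without extra state
        seed = int(
            np.abs(np.asarray(spec.center, dtype=np.float64).view(np.int64)).sum()
            % (2**31)
        )
        rng = np.random.default_rng(seed)
        for _ in range(spec.n_lobes):
            offset = rng.normal(0.0, 0.35 * radius_vox, size=3)
            offset *= radius_vox * 0.45 / max(np.linalg.norm(offset), 1e-9)
            _add_sphere(w, np.asarray(spec.center) + offset, main_r * 0.75)
    return w


def _vessel_weight(spec: VesselSpec, shape) -> np.ndarray:
    """Soft tube footprint around a line segment."""
    w = np.zeros(shape, dtype=np.float32)
    p0 = np.asarray(spec.start, dtype=float)
    d = np.asarray(spec.direction, dtype=float)
    p1 = p0 + d * spec.length_vox
    lo_c = np.minimum(p0, p1)
    hi_c = np.maximum(p0, p1)
    pad = spec.radius_vox + 2
    lo = np.maximum(np.floor(lo_c - pad).astype(int), 0)
    hi = np.minimum(np.ceil(hi_c + pad).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return w
    z, y, x = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = np.stack([z, y, x], axis=-1).astype(float)
    rel = pts - p0
    t = np.clip(rel @ d, 0.0, spec.length_vox)
    nearest = p0 + t[..., None] * d
    dist = np.linalg.norm(pts - nearest, axis=-1)
    soft = 0.8
    tube = np.clip((spec.radius_vox + soft - dist) / (2 * soft), 0.0, 1.0)
    region = w[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(region, tube.astype(np.float32), out=region)
    return w


def _parenchyma_weight(shape) -> np.ndarray:
    center, semi = _ellipsoid_params(shape)
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    norm = np.sqrt(
        ((z - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((x - center[2]) / semi[2]) ** 2
    )
    return np.clip(1.0 - norm / 0.5, 0.0, 1.0).astype(np.float32)


def _jitter_kinetics(k: KineticParams, rng: np.random.Generator, amount: float) -> KineticParams:
    def j(v: float) -> float:
        return float(v * rng.uniform(1.0 - amount, 1.0 + amount))

    return KineticParams(
        time_to_enhancement=j(k.time_to_enhancement),
        rise_duration=max(1.0, j(k.rise_duration)),
        peak_amplitude=j(k.peak_amplitude),
        washout_slope=j(k.washout_slope),
        class_label=k.class_label,
    )


# ---------------------------------------------------------------------------
# cohort planning
# ---------------------------------------------------------------------------


def _sample_lesion(
    config: CohortConfig, malignant: bool, rng: np.random.Generator
) -> LesionSpec:
    median = config.malignant_size_median if malignant else config.benign_size_median
    center, semi = _ellipsoid_params(config.volume_shape)
    # the volume geometry caps how large a lesion can fit inside the mask
    fit_cap = 2.0 * config.spacing[1] * max(0.8 * semi.min() - 1.0, 1.25)
    cap = min(config.max_diameter_mm, fit_cap)
    diameter = float(
        np.clip(rng.lognormal(math.log(median), config.size_sigma), 5.0, max(5.0, cap))
    )
    radius_vox = diameter / (2.0 * config.spacing[1])
    # rejection-sample a center that keeps the whole lesion inside the mask;
    # the ellipsoid centre always qualifies, so fall back to it
    margin = (radius_vox + 1.0) / semi.min()
    limit = max(0.0, 0.95 - margin)
    c = center.copy()
    for _ in range(500):
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) > 1.0:
            continue
        if np.linalg.norm(u) <= limit:
            c = center + u * semi
            break
    klass = "malignant" if malignant else "benign"
    kin = _jitter_kinetics(config.kinetics[klass], rng, config.kinetic_jitter)
    shape = "lobulated" if rng.random() < 0.3 else "sphere"
    return LesionSpec(
        center=tuple(float(v) for v in c),
        diameter_mm=diameter,
        kinetics=kin,
        malignant=malignant,
        shape=shape,
    )


def _sample_vessel(config: CohortConfig, rng: np.random.Generator) -> VesselSpec:
    center, semi = _ellipsoid_params(config.volume_shape)
    u = rng.uniform(-0.6, 0.6, size=3)
    start = center + u * semi
    d = rng.normal(0.0, 1.0, size=3)
    d[0] *= 0.3  # vessels run mostly in-plane
    d /= np.linalg.norm(d)
    length = float(rng.uniform(12.0, 28.0))
    kin = _jitter_kinetics(config.kinetics["vessel"], rng, config.kinetic_jitter)
    return VesselSpec(
        start=tuple(float(v) for v in start),
        direction=tuple(float(v) for v in d),
        length_vox=length,
        radius_vox=float(rng.uniform(0.8, 1.3)),
        kinetics=kin,
    )


def _plan_breast(config: CohortConfig, index: int, rng: np.random.Generator) -> BreastPlan:
    breast_id = f"B{index:04d}"
    laterality = "left" if index % 2 == 0 else "right"
    involved = bool(rng.random() < config.lesion_prevalence)
    lesions: list[LesionSpec] = []
    if involved:
        n_lesions = 1
        if rng.random() < config.multi_lesion_fraction:
            n_lesions = 2 + int(rng.poisson(0.1))
        for _ in range(n_lesions):
            malignant = bool(rng.random() < config.malignant_fraction)
            lesions.append(_sample_lesion(config, malignant, rng))
    n_vessels = int(rng.poisson(config.confounders_per_breast))
    vessels = [_sample_vessel(config, rng) for _ in range(n_vessels)]
    center, semi = _ellipsoid_params(config.volume_shape)
    nipple = NippleSpec(
        center=(float(center[0]), float(center[1] + 0.93 * semi[1]), float(center[2])),
        radius_vox=1.6,
        kinetics=_jitter_kinetics(config.kinetics["nipple"], rng, config.kinetic_jitter),
    )
    parenchyma = bool(rng.random() < config.parenchyma_fraction)
    n_exams = 2 if rng.random() < config.second_exam_fraction else 1
    exam_ids = [f"{breast_id}-e{i}" for i in range(n_exams)]
    exam_seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(n_exams)]
    field_tag = "3T" if rng.random() < 0.6 else "1.5T"
    return BreastPlan(
        breast_id=breast_id,
        laterality=laterality,
        involved=involved,
        lesions=lesions,
        vessels=vessels,
        nipple=nipple,
        parenchyma=parenchyma,
        exam_ids=exam_ids,
        exam_seeds=exam_seeds,
        field_strength_tag=field_tag,
    )


def plan_cohort(config: CohortConfig) -> list[BreastPlan]:
    """Draw the full cohort structure (no images rendered)."""
    rng = np.random.default_rng(config.seed)
    return [_plan_breast(config, i, rng) for i in range(config.n_breasts)]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_series(
    config: CohortConfig, plan: BreastPlan, exam_index: int
) -> TwistSeries:
    """Render t0..tN volumes of one breast exam (seeded, deterministic)."""
    shape = config.volume_shape
    mask = breast_mask(shape)
    baseline = config.baseline_intensity * mask.astype(np.float32)

    objects: list[tuple[np.ndarray, KineticParams]] = []
    for lesion in plan.lesions:
        objects.append((lesion_weight(lesion, shape, config.spacing), lesion.kinetics))
    for vessel in plan.vessels:
        objects.append((_vessel_weight(vessel, shape), vessel.kinetics))
    npl = np.zeros(shape, dtype=np.float32)
    _add_sphere(npl, plan.nipple.center, plan.nipple.radius_vox)
    objects.append((npl, plan.nipple.kinetics))
    if plan.parenchyma:
        objects.append((_parenchyma_weight(shape), config.kinetics["parenchyma"]))

    mask_f = mask.astype(np.float32)
    times = config.times
    curves = [enhancement_curve(k, times) for _, k in objects]

    rng = np.random.default_rng(plan.exam_seeds[exam_index])
    volumes: list[np.ndarray] = []
    for ti in range(config.n_post + 1):
        vol = baseline.copy()
        for (w, _), curve in zip(objects, curves):
            if curve[ti] > 0:
                vol += w * mask_f * float(curve[ti])
        vol += rng.normal(0.0, config.noise_sigma, size=shape)
        np.clip(vol, 0.0, 30000.0, out=vol)
        volumes.append(np.round(vol).astype(np.int16))

    return TwistSeries(
        t0=volumes[0],
        posts=volumes[1:],
        mask=mask,
        spacing=config.spacing,
        breast_id=plan.breast_id,
        exam_id=plan.exam_ids[exam_index],
        laterality=plan.laterality,
        field_strength_tag=plan.field_strength_tag,
    )


def _ground_truth_boxes(config: CohortConfig, plan: BreastPlan) -> GroundTruth:
    """Tight MIP-plane boxes of each lesion's projected footprint."""
    gt = GroundTruth(breast_id=plan.breast_id, exam_id=plan.exam_ids[0])
    for lesion in plan.lesions:
        w = lesion_weight(lesion, config.volume_shape, config.spacing)
        proj = w.max(axis=0) > 0.5
        if not proj.any():  # pragma: no cover - lesions are always >= 5 mm
            continue
        rows = np.flatnonzero(proj.any(axis=1))
        cols = np.flatnonzero(proj.any(axis=0))
        box = BBox(
            x=int(cols[0]),
            y=int(rows[0]),
            w=int(cols[-1] - cols[0] + 1),
            h=int(rows[-1] - rows[0] + 1),
            label="malignant-lesion" if lesion.malignant else "lesion",
        )
        gt.boxes.append(GroundTruthBox(box=box, malignant=lesion.malignant,
                                       diameter_mm=lesion.diameter_mm))
    return gt


def _check_lesions_inside(config: CohortConfig, lesions: Iterable[LesionSpec]) -> None:
    mask = breast_mask(config.volume_shape)
    for i, lesion in enumerate(lesions):
        c = tuple(int(round(v)) for v in lesion.center)
        if not (
            0 <= c[0] < mask.shape[0]
            and 0 <= c[1] < mask.shape[1]
            and 0 <= c[2] < mask.shape[2]
            and mask[c]
        ):
            raise ValueError(f"lesion {i} at center {lesion.center} lies outside the breast mask")


def generate_exam(
    config: CohortConfig,
    lesion_specs: dict[str, list[LesionSpec]],
    rng: np.random.Generator,
    exam_index: int = 0,
    breast_ids: tuple[str, str] = ("L", "R"),
) -> tuple[TwistSeries, TwistSeries, dict[str, GroundTruth]]:
    """Render one bilateral exam with explicitly supplied lesions.

    ``lesion_specs`` maps "left"/"right" to lesion lists; confounders are
    drawn from ``rng``. Returns the two series plus per-side ground truth.
    """
    out_series = []
    out_gt: dict[str, GroundTruth] = {}
    for side, bid in zip(("left", "right"), breast_ids):
        lesions = list(lesion_specs.get(side, []))
        _check_lesions_inside(config, lesions)
        n_vessels = int(rng.poisson(config.confounders_per_breast))
        vessels = [_sample_vessel(config, rng) for _ in range(n_vessels)]
        center, semi = _ellipsoid_params(config.volume_shape)
        plan = BreastPlan(
            breast_id=bid,
            laterality=side,
            involved=bool(lesions),
            lesions=lesions,
            vessels=vessels,
            nipple=NippleSpec(
                center=(float(center[0]), float(center[1] + 0.93 * semi[1]), float(center[2])),
                radius_vox=1.6,
                kinetics=config.kinetics["nipple"],
            ),
            parenchyma=False,
            exam_ids=[f"{bid}-e{exam_index}"],
            exam_seeds=[int(rng.integers(0, 2**31 - 1))],
            field_strength_tag="3T",
        )
        out_series.append(_render_series(config, plan, 0))
        out_gt[side] = _ground_truth_boxes(config, plan)
    return out_series[0], out_series[1], out_gt


# ---------------------------------------------------------------------------
# cohort object
# ---------------------------------------------------------------------------


class Cohort:
    """A planned synthetic cohort with lazy, cached per-exam rendering."""

    def __init__(self, config: CohortConfig, plans: list[BreastPlan] | None = None):
        self.config = config
        self.plans = plans if plans is not None else plan_cohort(config)
        self._by_id = {p.breast_id: p for p in self.plans}
        self._mip_cache: dict[tuple[str, int], MipStack] = {}

    # -- structure ---------------------------------------------------------

    @property
    def breast_ids(self) -> list[str]:
        return [p.breast_id for p in self.plans]

    def plan(self, breast_id: str) -> BreastPlan:
        return self._by_id[breast_id]

    def records(self) -> list[dict]:
        """Manifest records (one per breast)."""
        recs = []
        for p in self.plans:
            recs.append(
                {
                    "breast_id": p.breast_id,
                    "laterality": p.laterality,
                    "exam_ids": list(p.exam_ids),
                    "involved": p.involved,
                    "n_lesions": len(p.lesions),
                    "malignant_flags": [l.malignant for l in p.lesions],
                    "field_strength_tag": p.field_strength_tag,
                }
            )
        return recs

    def ground_truth(self, breast_id: str) -> GroundTruth:
        return _ground_truth_boxes(self.config, self._by_id[breast_id])

    # -- rendering ---------------------------------------------------------

    def series(self, breast_id: str, exam_index: int = 0) -> TwistSeries:
        return _render_series(self.config, self._by_id[breast_id], exam_index)

    def mip_stack(self, breast_id: str, exam_index: int = 0) -> MipStack:
        key = (breast_id, exam_index)
        if key not in self._mip_cache:
            self._mip_cache[key] = mip_stack_from_series(self.series(breast_id, exam_index))
        return self._mip_cache[key]

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """Write NIfTI volumes, LabelMe ground truth and manifest.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest: dict = {
            "config": _config_to_jsonable(self.config),
            "breasts": [],
        }
        for plan in self.plans:
            rec = {
                "breast_id": plan.breast_id,
                "laterality": plan.laterality,
                "involved": plan.involved,
                "malignant_flags": [l.malignant for l in plan.lesions],
                "field_strength_tag": plan.field_strength_tag,
                "exams": [],
            }
            gt = _ground_truth_boxes(self.config, plan)
            for ei, exam_id in enumerate(plan.exam_ids):
                series = _render_series(self.config, plan, ei)
                exam_dir = directory / plan.breast_id / exam_id
                save_series_nifti(series, exam_dir)
                rec["exams"].append(
                    {"exam_id": exam_id, "path": str(exam_dir.relative_to(directory))}
                )
            h, w = self.config.volume_shape[1], self.config.volume_shape[2]
            gt_path = directory / plan.breast_id / "ground_truth.json"
            gt_path.parent.mkdir(parents=True, exist_ok=True)
            write_labelme(gt.bboxes, gt_path, image_shape=(h, w))
            rec["ground_truth"] = str(gt_path.relative_to(directory))
            manifest["breasts"].append(rec)
        manifest_path = directory / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest_path


def _config_to_jsonable(config: CohortConfig) -> dict:
    d = {}
    for k, v in vars(config).items():
        if k == "kinetics":
            d[k] = {name: vars(kp) for name, kp in v.items()}
        elif isinstance(v, tuple):
            d[k] = list(v)
        else:
            d[k] = v
    return d


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> Cohort:
    """Plan (and optionally persist) a synthetic cohort.

    With ``out_dir`` the full NIfTI/LabelMe/manifest tree is written; without
    it the returned :class:`Cohort` renders exams lazily in memory.
    """
    cohort = Cohort(config)
    if out_dir is not None:
        cohort.save(out_dir)
    return cohort


# ---------------------------------------------------------------------------
# synthetic clip benchmark for the sequence classifier
# ---------------------------------------------------------------------------


def synthetic_clip_task(
    n: int = 400,
    seed: int = 0,
    patch_size: int = 32,
    n_frames: int = 14,
    noise_sigma: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded fast- versus slow/flat-kinetic clip classification task.

    Positives (label 1) are blobs with fast wash-in (short TTE); negatives
    are either slow late-enhancing blobs or flat noise-only clips. Clips are
    globally max-normalised like the production clip extractor. Returns
    ``(clips, labels)`` with clips of shape (n, n_frames, patch, patch).
    """
    rng = np.random.default_rng(seed)
    times = (np.arange(1, n_frames + 1)) * (TOTAL_WINDOW_S / n_frames)
    yy, xx = np.mgrid[:patch_size, :patch_size]
    clips = np.zeros((n, n_frames, patch_size, patch_size), dtype=np.float32)
    labels = np.zeros(n, dtype=np.int64)
    for i in range(n):
        positive = i % 2 == 0
        labels[i] = int(positive)
        cy = patch_size / 2 + rng.uniform(-3, 3)
        cx = patch_size / 2 + rng.uniform(-3, 3)
        sigma = rng.uniform(3.0, 7.0)
        profile = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        if positive:
            kin = KineticParams(
                time_to_enhancement=rng.uniform(5.0, 18.0),
                rise_duration=rng.uniform(15.0, 30.0),
                peak_amplitude=1.0,
                washout_slope=rng.uniform(0.0, 0.002),
            )
            curve = enhancement_curve(kin, times)
        elif rng.random() < 0.5:
            kin = KineticParams(
                time_to_enhancement=rng.uniform(40.0, 60.0),
                rise_duration=rng.uniform(45.0, 70.0),
                peak_amplitude=1.0,
                washout_slope=0.0,
            )
            curve = enhancement_curve(kin, times)
        else:
            curve = np.zeros_like(times)  # flat: noise only
        clip = curve[:, None, None] * profile[None, :, :]
        clip = clip + rng.normal(0.0, noise_sigma, size=clip.shape)
        np.clip(clip, 0.0, None, out=clip)
        peak = clip.max()
        if peak > 0:
            clip /= peak
        clips[i] = clip.astype(np.float32)
    return clips, labels
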