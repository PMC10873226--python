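"""Subtraction / MIP preprocessing for ultrafast DCE-MRI series.

The preprocessing turns one breast's 4D TWIST acquisition (a pre-contrast
volume ``t0`` plus 14 post-contrast volumes ``t1..t14``) into a stack of 14
two-dimensional subtraction maximum-intensity projections (MIPs), which is
the representation every downstream stage (candidate detection, temporal
false-positive reduction, evaluation) operates on.

Steps, in order:

1. voxelwise subtraction ``sub_i = max(0, t_i - t0)`` — enhancing tissue is
   the signal of interest, so negative differences are clamped to zero;
2. multiplication with a binary breast mask to remove chest-wall and
   background signal;
3. maximum-intensity projection along the slice axis (axis 0 of ``(z,y,x)``);
4. optional left/right breast splitting of bilateral images;
5. 8-bit normalisation for detector backends.

Annotation I/O (LabelMe rectangles, YOLO text labels) also lives here so
that external detectors can exchange boxes with the pipeline.

Masks are assumed to already share the TWIST voxel grid; resampling a mask
from a different field of view onto the TWIST grid is the caller's duty.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TwistSeries",
    "MipStack",
    "BBox",
    "subtract_series",
    "project_mip",
    "mip_stack_from_series",
    "split_left_right",
    "normalize_image",
    "read_labelme",
    "write_labelme",
    "write_yolo_txt",
    "read_yolo_txt",
    "save_series_nifti",
    "load_series_nifti",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in 0-based, half-open pixel coordinates.

    The box covers columns ``[x, x+w)`` and rows ``[y, y+h)``.
    """

    x: int
    y: int
    w: int
    h: int
    label: str = "lesion"

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w}, h={self.h}")

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) in pixel coordinates."""
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> int:
        return self.w * self.h

    def clipped(self, height: int, width: int) -> "BBox":
        """Clip the box to an image of the given shape."""
        x1 = max(0, min(self.x, width))
        y1 = max(0, min(self.y, height))
        x2 = max(0, min(self.x + self.w, width))
        y2 = max(0, min(self.y + self.h, height))
        if x2 <= x1 or y2 <= y1:
            raise ValueError("box does not intersect the image")
        return BBox(x1, y1, x2 - x1, y2 - y1, self.label)


@dataclass
class TwistSeries:
    """One breast's ultrafast acquisition: t0 plus n post-contrast volumes.

    All volumes and the binary breast mask share one ``(z, y, x)`` grid.
    """

    t0: np.ndarray
    posts: list[np.ndarray]
    mask: np.ndarray
    spacing: tuple[float, float, float]
    breast_id: str = ""
    exam_id: str = ""
    laterality: str = "left"
    field_strength_tag: str | None = None

    def __post_init__(self) -> None:
        if self.t0.ndim != 3:
            raise ValueError(f"t0 must be 3D, got shape {self.t0.shape}")
        shape = self.t0.shape
        for i, vol in enumerate(self.posts, start=1):
            if vol.shape != shape:
                raise ValueError(
                    f"post-contrast volume t{i} shape {vol.shape} != t0 shape {shape}"
                )
        if self.mask.shape != shape:
            raise ValueError(f"mask shape {self.mask.shape} != volume shape {shape}")
        mask_vals = np.unique(self.mask)
        if not np.all(np.isin(mask_vals, (0, 1))):
            raise ValueError("mask must be binary (values 0/1)")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be left/right, got {self.laterality!r}")

    @property
    def n_post(self) -> int:
        return len(self.posts)


@dataclass
class MipStack:
    """Ordered subtraction MIPs (sub1..subN) for one breast and exam."""

    mips: list[np.ndarray]
    pixel_size: float
    breast_id: str = ""
    exam_id: str = ""
    laterality: str = "left"

    def __post_init__(self) -> None:
        shape = self.mips[0].shape
        for i, m in enumerate(self.mips):
            if m.ndim != 2:
                raise ValueError(f"MIP {i} is not 2D")
            if m.shape != shape:
                raise ValueError("all MIPs in a stack must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mips[0].shape

    @property
    def last(self) -> np.ndarray:
        """The final subtraction MIP (sub14 by default) — the detector input."""
        return self.mips[-1]

    def as_array(self) -> np.ndarray:
        """Stack as a (T, H, W) array."""
        return np.stack(self.mips, axis=0)


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------


def subtract_series(series: TwistSeries) -> list[np.ndarray]:
    """Masked subtraction volumes ``sub_i = mask * max(0, t_i - t0)``.

    Returns the volumes in acquisition order (t1..tN). Negative differences
    are clamped at zero: only enhancement carries signal and projecting
    signed noise would inflate the MIP background.
    """
    t0 = series.t0.astype(np.float32)
    mask = series.mask.astype(np.float32)
    subs = []
    for post in series.posts:
        sub = post.astype(np.float32) - t0
        np.maximum(sub, 0.0, out=sub)
        sub *= mask
        subs.append(sub)
    return subs


def project_mip(volume: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along the slice axis (axis 0)."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    return volume.max(axis=0)


def mip_stack_from_series(series: TwistSeries) -> MipStack:
    """Full per-breast preprocessing: subtraction, masking, MIP."""
    dy, dx = series.spacing[1], series.spacing[2]
    if not np.isclose(dy, dx):
        raise ValueError("in-plane spacing must be isotropic for MIP pixel size")
    mips = [project_mip(sub) for sub in subtract_series(series)]
    return MipStack(
        mips=mips,
        pixel_size=float(dy),
        breast_id=series.breast_id,
        exam_id=series.exam_id,
        laterality=series.laterality,
    )


def split_left_right(
    image: np.ndarray, midline: int | str = "auto"
) -> tuple[np.ndarray, np.ndarray]:
    """Split a bilateral image into (left, right) halves at a column.

    ``midline="auto"`` places the cut at the minimum of the column sums
    restricted to the central third of the image — the dark valley between
    the two breasts. On an all-zero image the auto mode falls back to the
    middle column and logs a warning.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[1] < 2:
        raise ValueError("expected a 2D image with width >= 2")
    width = image.shape[1]
    if midline == "auto":
        if not np.any(image):
            logger.warning("split_left_right: all-zero image, falling back to midline W/2")
            m = width // 2
        else:
            lo = width // 3
            hi = width - width // 3
            col_sums = image[:, lo:hi].sum(axis=0)
            # centre of the near-minimal plateau: the inter-breast valley is
            # flat, so a bare argmin would land on an arbitrary noise column
            floor = col_sums.min() + 0.05 * (col_sums.max() - col_sums.min())
            low = col_sums <= floor
            runs = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
            starts, ends = runs[::2], runs[1::2]
            widest = int(np.argmax(ends - starts))
            m = lo + int((starts[widest] + ends[widest]) // 2)
    else:
        m = int(midline)
        if not 0 < m < width:
            raise ValueError(f"midline {m} outside (0, {width})")
    return image[:, :m], image[:, m:]


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Map a non-negative image to 8-bit.

    Intensities are clipped at the image's 99.9th percentile (robust to
    single hot voxels) and scaled linearly to [0, 255] with round-half-away-
    from-zero. An all-zero image maps to all zeros.
    """
    image = np.asarray(image, dtype=np.float64)
    if np.any(image < 0):
        raise ValueError("normalize_image expects non-negative intensities")
    ceiling = float(np.percentile(image, 99.9))
    if ceiling <= 0:
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = np.clip(image, 0.0, ceiling) * (255.0 / ceiling)
    return np.floor(scaled + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def write_labelme(
    boxes: Sequence[BBox],
    path: str | Path,
    image_shape: tuple[int, int] | None = None,
    image_path: str = "",
) -> None:
    """Write boxes as a LabelMe-compatible JSON of rectangle shapes."""
    shapes = []
    for b in boxes:
        shapes.append(
            {
                "label": b.label,
                "points": [[float(b.x), float(b.y)], [float(b.x2), float(b.y2)]],
                "group_id": None,
                "shape_type": "rectangle",
                "flags": {},
            }
        )
    doc = {
        "version": "5.0.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": int(image_shape[0]) if image_shape else None,
        "imageWidth": int(image_shape[1]) if image_shape else None,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_labelme(path: str | Path) -> list[BBox]:
    """Read rectangle shapes from a LabelMe JSON into 0-based half-open boxes.

    Float vertices are rounded to the nearest integer; the two points may
    come in any corner order.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed LabelMe JSON ({exc})") from exc
    boxes: list[BBox] = []
    for i, shape in enumerate(doc.get("shapes", [])):
        if shape.get("shape_type") != "rectangle":
            continue
        pts = shape.get("points")
        if not pts or len(pts) != 2:
            raise ValueError(f"{path}: rectangle shape {i} lacks two corner points")
        (xa, ya), (xb, yb) = pts
        x1, x2 = sorted((int(round(xa)), int(round(xb))))
        y1, y2 = sorted((int(round(ya)), int(round(yb))))
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"{path}: rectangle shape {i} has zero area")
        boxes.append(BBox(x1, y1, x2 - x1, y2 - y1, shape.get("label", "lesion")))
    return boxes


def write_yolo_txt(
    boxes: Sequence[BBox],
    image_shape: tuple[int, int],
    path: str | Path,
    class_ids: Sequence[int] | None = None,
    confidences: Sequence[float] | None = None,
) -> None:
    """Write YOLO label lines ``class cx cy w h [conf]``, normalised to (0, 1]."""
    height, width = image_shape
    lines = []
    for i, b in enumerate(boxes):
        cid = class_ids[i] if class_ids is not None else 0
        cx = (b.x + b.w / 2.0) / width
        cy = (b.y + b.h / 2.0) / height
        nw = b.w / width
        nh = b.h / height
        parts = [str(cid)] + [f"{v:.6g}" for v in (cx, cy, nw, nh)]
        if confidences is not None:
            parts.append(f"{confidences[i]:.6g}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(
    path: str | Path, image_shape: tuple[int, int]
) -> list[tuple[BBox, int, float | None]]:
    """Read YOLO label lines; returns (box, class_id, confidence-or-None) tuples."""
    height, width = image_shape
    out: list[tuple[BBox, int, float | None]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        cid = int(parts[0])
        cx, cy, nw, nh = (float(p) for p in parts[1:5])
        for name, v in (("cx", cx), ("cy", cy), ("w", nw), ("h", nh)):
            if not 0.0 < v <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: normalised {name}={v} outside (0, 1]"
                )
        conf = float(parts[5]) if len(parts) == 6 else None
        w = max(1, int(round(nw * width)))
        h = max(1, int(round(nh * height)))
        x = int(round(cx * width - w / 2.0))
        y = int(round(cy * height - h / 2.0))
        box = BBox(x, y, w, h).clipped(height, width)
        out.append((box, cid, conf))
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O (nibabel)
# ---------------------------------------------------------------------------


def save_series_nifti(series: TwistSeries, directory: str | Path) -> list[Path]:
    """Write t0, t1..tN and the mask as int16 .nii.gz files; returns the paths."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(series.spacing) + [1.0])
    paths = []

    def _write(vol: np.ndarray, name: str) -> None:
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.int16), affine)
        p = directory / name
        nib.save(img, str(p))
        paths.append(p)

    _write(series.t0, "t00.nii.gz")
    for i, vol in enumerate(series.posts, start=1):
        _write(vol, f"t{i:02d}.nii.gz")
    _write(series.mask.astype(np.int16), "mask.nii.gz")
    return paths


def load_series_nifti(
    directory: str | Path,
    breast_id: str = "",
    exam_id: str = "",
    laterality: str = "left",
) -> TwistSeries:
    """Load a series written by :func:`save_series_nifti`."""
    import nibabel as nib

    directory = Path(directory)
    t_paths = sorted(directory.glob("t[0-9][0-9].nii.gz"))
    if not t_paths:
        raise FileNotFoundError(f"no timepoint volumes under {directory}")
    vols = []
    spacing = None
    for p in t_paths:
        img = nib.load(str(p))
        vols.append(np.asarray(img.dataobj, dtype=np.int16))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = np.asarray(nib.load(str(directory / "mask.nii.gz")).dataobj).astype(np.uint8)
    return TwistSeries(
        t0=vols[0],
        posts=vols[1:],
        mask=mask,
        spacing=spacing,  # type: ignore[arg-type]
        breast_id=breast_id,
        exam_id=exam_id,
        laterality=laterality,
    )
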