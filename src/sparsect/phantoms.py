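"""Synthetic chest phantoms in Hounsfield units.

Phantoms are additive compositions of ellipses on a -1000 HU (air)
background.  They provide HU-correct tissue classes — lung parenchyma with
small vessel-like inclusions, soft tissue, a bony spine, an optional tumor —
arranged so that every non-air pixel lies inside the inscribed circle of the
square grid, which is the region an equiangular fan beam with a finite
detector arc can cover exactly.

A cohort groups slices under synthetic "patients".  Slices of one patient
share body and lung outlines up to small jitter, so that patient-level
train/test splitting is the meaningful unit of data leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "EllipseSpec",
    "PhantomImage",
    "Rect",
    "ROILayout",
    "Patient",
    "Cohort",
    "make_shepp_logan",
    "sample_chest_phantom",
    "generate_cohort",
    "ROI_SIZES_512",
]

# HU levels of the tissue classes (air background is the -1000 HU baseline).
HU_AIR = -1000.0
HU_LUNG = -800.0
HU_SOFT = 40.0
HU_BONE = 700.0
HU_VESSEL = -250.0
HU_TUMOR = 40.0

#: ROI edge sizes (height == width) at the reference 512-px grid:
#: lung 40, soft 40, bone 15, air 50.
ROI_SIZES_512 = {"lung": 40, "soft": 40, "bone": 15, "air": 50}

_TISSUE_LABELS = ("air", "lung", "soft", "bone", "tumor")


@dataclass(frozen=True)
class EllipseSpec:
    """One additive ellipse: HU contribution inside, nothing outside."""

    center_xy: tuple[float, float]  # (x=col, y=row) in pixels
    semi_axes: tuple[float, float]  # (a along x before rotation, b) in pixels
    rotation: float = 0.0  # degrees, counter-clockwise
    value: float = 0.0  # additive HU contribution
    tissue_label: str = "soft"

    def __post_init__(self) -> None:
        if not (self.semi_axes[0] > 0 and self.semi_axes[1] > 0):
            raise ValueError("semi_axes must be positive")
        if not math.isfinite(self.value):
            raise ValueError("ellipse value must be finite")
        if self.tissue_label not in _TISSUE_LABELS:
            raise ValueError(f"unknown tissue_label {self.tissue_label!r}")

    def contains(self, x, y):
        """Boolean mask of points inside the ellipse (vectorized)."""
        phi = math.radians(self.rotation)
        dx = np.asarray(x, dtype=float) - self.center_xy[0]
        dy = np.asarray(y, dtype=float) - self.center_xy[1]
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomImage:
    """A square 2D HU image with its physical pixel spacing (mm/pixel)."""

    pixels: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("phantom pixels must be a square 2D grid")
        if not np.all(np.isfinite(px)):
            raise ValueError("phantom pixels must be finite")
        object.__setattr__(self, "pixels", px.astype(np.float32, copy=False))

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle: top-left corner plus height x width (pixels)."""

    top: int
    left: int
    height: int
    width: int

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.top + self.height),
                slice(self.left, self.left + self.width))

    def inside(self, size: int) -> bool:
        return (self.top >= 0 and self.left >= 0
                and self.top + self.height <= size
                and self.left + self.width <= size)


@dataclass(frozen=True)
class ROILayout:
    """One measurement rectangle per tissue region (lung/soft/bone/air)."""

    lung: Rect
    soft: Rect
    bone: Rect
    air: Rect

    def items(self):
        return (("lung", self.lung), ("soft", self.soft),
                ("bone", self.bone), ("air", self.air))

    def validate(self, size: int) -> None:
        for name, rect in self.items():
            if not rect.inside(size):
                raise ValueError(f"{name} ROI {rect} outside {size}x{size} image")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    slices: tuple[tuple[PhantomImage, ROILayout], ...]


@dataclass(frozen=True)
class Cohort:
    patients: tuple[Patient, ...]
    master_seed: int
    size: int = field(default=0)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        sizes = {img.size for p in self.patients for img, _ in p.slices}
        if len(sizes) > 1:
            raise ValueError("all slices in a cohort must share one size")
        if self.size == 0 and sizes:
            object.__setattr__(self, "size", sizes.pop())

    @property
    def n_slices(self) -> int:
        return sum(len(p.slices) for p in self.patients)

    def iter_slices(self):
        for patient in self.patients:
            for image, roi in patient.slices:
                yield patient.patient_id, image, roi


def _pixel_spacing(size: int) -> float:
    # 45 cm field of view regardless of grid size.
    return 450.0 / size


def rasterize(specs, size: int, background: float = HU_AIR) -> PhantomImage:
    """Sum ellipse contributions over a ``size`` x ``size`` grid."""
    cols, rows = np.meshgrid(np.arange(size, dtype=float),
                             np.arange(size, dtype=float))
    img = np.full((size, size), background, dtype=float)
    for spec in specs:
        img[spec.contains(cols, rows)] += spec.value
    return PhantomImage(np.clip(img, -1100.0, 2000.0), _pixel_spacing(size))


# ---------------------------------------------------------------------------
# Shepp–Logan head phantom

# Columns: intensity, a, b, x0, y0, rotation (deg); unit-square coordinates.
_SHEPP_LOGAN_ELLIPSES = (
    (2.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.98, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.02, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.02, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.01, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.01, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.01, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.01, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def shepp_logan_ellipses(size: int) -> tuple[EllipseSpec, ...]:
    """The ten standard ellipses scaled to pixel coordinates.

    Intensities are mapped affinely to HU: summed intensity 0 (outside the
    skull) -> -1000 HU and the peak summed intensity 2 -> +1000 HU, i.e.
    ``HU = -1000 + 1000 * intensity``, so each ellipse contributes
    ``1000 * intensity`` additively.
    """
    c = (size - 1) / 2.0
    r = (size - 1) / 2.0
    specs = []
    for inten, a, b, x0, y0, rot in _SHEPP_LOGAN_ELLIPSES:
        specs.append(EllipseSpec(
            center_xy=(c + x0 * r, c - y0 * r),  # row axis points down
            semi_axes=(a * r, b * r),
            rotation=-rot,
            value=1000.0 * inten,
            tissue_label="soft",
        ))
    return tuple(specs)


def make_shepp_logan(size: int) -> PhantomImage:
    """Standard 10-ellipse head phantom mapped to [-1000, 1000] HU."""
    if size < 32:
        raise ValueError("size must be at least 32")
    return rasterize(shepp_logan_ellipses(size), size)


# ---------------------------------------------------------------------------
# Chest phantom


def _chest_params(rng: np.random.Generator, size: int) -> list[EllipseSpec]:
    """Draw the ellipse composition of one synthetic patient."""
    c = (size - 1) / 2.0
    specs: list[EllipseSpec] = []

    body_a = 0.42 * size * rng.uniform(0.97, 1.03)
    body_b = 0.30 * size * rng.uniform(0.97, 1.03)
    body_cx = c + rng.uniform(-0.004, 0.004) * size
    body_cy = c + 0.02 * size + rng.uniform(-0.004, 0.004) * size
    specs.append(EllipseSpec((body_cx, body_cy), (body_a, body_b),
                             rng.uniform(-2.0, 2.0), HU_SOFT - HU_AIR, "soft"))

    lung_centers = []
    for side in (-1.0, 1.0):
        a = 0.145 * size * rng.uniform(0.92, 1.08)
        b = 0.195 * size * rng.uniform(0.92, 1.08)
        cx = body_cx + side * 0.195 * size * rng.uniform(0.96, 1.04)
        cy = body_cy - 0.02 * size + rng.uniform(-0.008, 0.008) * size
        rot = side * rng.uniform(2.0, 10.0)
        specs.append(EllipseSpec((cx, cy), (a, b), rot,
                                 HU_LUNG - HU_SOFT, "lung"))
        lung_centers.append((cx, cy, a, b, rot))

    # Spine: circular bone structure on the posterior midline, inside the body.
    spine_r = 0.062 * size * rng.uniform(0.95, 1.05)
    spine_cy = body_cy + 0.205 * size
    specs.append(EllipseSpec((body_cx, spine_cy), (spine_r, spine_r),
                             0.0, HU_BONE - HU_SOFT, "bone"))

    # Vessel-like high-contrast inclusions inside each lung.  Semi-axes are
    # 1-4 px on the 512 grid and shrink proportionally below it (they are
    # the fine structure that vanishes under aggressive correction).  They
    # avoid the innermost part of the lung so a homogeneous ROI exists.
    vscale = max(size / 512.0, 0.3)
    for cx, cy, a, b, rot in lung_centers:
        phi = math.radians(rot)
        for _ in range(int(rng.integers(5, 11))):
            rr = math.sqrt(rng.uniform(0.14, 1.0))
            th = rng.uniform(0.0, 2.0 * math.pi)
            u = rr * math.cos(th) * max(a - 0.05 * size, 2.0)
            v = rr * math.sin(th) * max(b - 0.05 * size, 2.0)
            vx = cx + u * math.cos(phi) - v * math.sin(phi)
            vy = cy + u * math.sin(phi) + v * math.cos(phi)
            axes = (rng.uniform(1.0, 4.0) * vscale,
                    rng.uniform(1.0, 4.0) * vscale)
            specs.append(EllipseSpec((vx, vy), axes, rng.uniform(0.0, 180.0),
                                     HU_VESSEL - HU_LUNG, "lung"))

    # Optional tumor: a soft-tissue-density nodule in one lung.
    if rng.uniform() < 0.5:
        cx, cy, a, b, rot = lung_centers[int(rng.integers(0, 2))]
        tr = rng.uniform(0.02, 0.04) * size
        phi = math.radians(rot)
        u = rng.uniform(-0.3, 0.3) * a
        v = rng.uniform(-0.3, 0.3) * b
        tx = cx + u * math.cos(phi) - v * math.sin(phi)
        ty = cy + u * math.sin(phi) + v * math.cos(phi)
        specs.append(EllipseSpec((tx, ty), (tr, tr * rng.uniform(0.8, 1.2)),
                                 rng.uniform(0.0, 180.0),
                                 HU_TUMOR - HU_LUNG, "tumor"))
    return specs


def _jitter_params(specs, rng: np.random.Generator) -> list[EllipseSpec]:
    """Small slice-to-slice perturbation (<=3% axes, <=2 px centers)."""
    out = []
    for s in specs:
        f = rng.uniform(0.97, 1.03, size=2)
        dc = rng.uniform(-2.0, 2.0, size=2)
        out.append(replace(
            s,
            center_xy=(s.center_xy[0] + dc[0], s.center_xy[1] + dc[1]),
            semi_axes=(s.semi_axes[0] * f[0], s.semi_axes[1] * f[1]),
            rotation=s.rotation + rng.uniform(-1.0, 1.0),
        ))
    return out


def roi_sizes(size: int) -> dict[str, int]:
    """Reference ROI edge lengths at 512 px, proportionally scaled below 512."""
    if size >= 512:
        return dict(ROI_SIZES_512)
    return {k: max(3, round(v * size / 512)) for k, v in ROI_SIZES_512.items()}


def _find_roi(mask: np.ndarray, h: int, w: int) -> Rect:
    """Deepest-interior placement of an h x w rectangle fully inside mask."""
    size = mask.shape[0]
    ok = np.ones((size - h + 1, size - w + 1), dtype=bool) if h <= size and w <= size else None
    if ok is None:
        raise ValueError("ROI larger than image")
    # Window purity via an integral image: position valid iff window sum == h*w.
    csum = np.pad(np.cumsum(np.cumsum(mask, axis=0), axis=1), ((1, 0), (1, 0)))
    win = (csum[h:, w:] - csum[:-h, w:] - csum[h:, :-w] + csum[:-h, :-w])
    valid = win == h * w
    if not valid.any():
        raise ValueError("no homogeneous placement found for ROI")
    # Prefer the placement whose center sits deepest inside the region.
    dist = ndimage.distance_transform_edt(mask)
    centers = dist[h // 2:h // 2 + valid.shape[0], w // 2:w // 2 + valid.shape[1]]
    score = np.where(valid, centers, -1.0)
    top, left = np.unravel_index(int(np.argmax(score)), score.shape)
    return Rect(int(top), int(left), h, w)


def _layout_for(image: PhantomImage) -> ROILayout:
    """Algorithmic ROI placement inside homogeneous parts of each tissue."""
    px = image.pixels.astype(float)
    size = image.size
    sz = roi_sizes(size)
    cols, rows = np.meshgrid(np.arange(size, dtype=float),
                             np.arange(size, dtype=float))
    c = (size - 1) / 2.0
    in_circle = (cols - c) ** 2 + (rows - c) ** 2 <= c ** 2
    masks = {
        "lung": np.abs(px - HU_LUNG) < 1.0,
        "soft": np.abs(px - HU_SOFT) < 1.0,
        "bone": np.abs(px - HU_BONE) < 1.0,
        "air": (np.abs(px - HU_AIR) < 1.0) & in_circle,
    }
    rects = {name: _find_roi(masks[name], sz[name], sz[name]) for name in masks}
    layout = ROILayout(**rects)
    layout.validate(size)
    return layout


def sample_chest_phantom(seed: int, size: int) -> tuple[PhantomImage, ROILayout]:
    """One seeded chest slice plus its measurement-ROI layout.

    Deterministic in ``(seed, size)``.  At 512 px the ROIs are exactly
    40x40 (lung), 40x40 (soft tissue), 15x15 (bone) and 50x50 (air).
    """
    if size < 64:
        raise ValueError("size must be at least 64")
    rng = np.random.default_rng(seed)
    image = rasterize(_chest_params(rng, size), size)
    return image, _layout_for(image)


def generate_cohort(n_patients: int, slices_per_patient: int, size: int,
                    seed: int) -> Cohort:
    """Seeded cohort of synthetic patients with correlated slices.

    Per-patient sub-seeds are spawned deterministically from the master
    seed; each slice is the patient's base anatomy under small jitter, so
    slices within a patient are highly correlated (as adjacent thin CT
    slices are) while patients differ.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients for a patient-level split")
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")
    if size < 64:
        raise ValueError("size must be at least 64")
    master = np.random.SeedSequence(seed)
    patients = []
    width = max(3, len(str(n_patients - 1)))
    for pid, child in enumerate(master.spawn(n_patients)):
        rng = np.random.default_rng(child)
        base = _chest_params(rng, size)
        slices = []
        for _ in range(slices_per_patient):
            specs = _jitter_params(base, rng)
            image = rasterize(specs, size)
            slices.append((image, _layout_for(image)))
        patients.append(Patient(f"patient_{pid:0{width}d}", tuple(slices)))
    return Cohort(tuple(patients), master_seed=seed, size=size)
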