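"""Dataset assembly, normalization, patient-level splitting and training.

The functions here are thin wrappers over the estimator classes in
:mod:`sparsect.restorers`; they exist so a study can be described in terms
of cohorts and view intervals rather than raw arrays.  Splitting is always
by patient — with 3 mm slices, adjacent slices of one patient are nearly
identical, so a slice-level split would leak training anatomy into the
evaluation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fanbeam import build_geometry, project
from .fbp import reconstruct
from .phantoms import Cohort, PhantomImage, ROILayout
from .restorers import AERestorer, CGANRestorer, UNetRestorer

__all__ = [
    "ScaleRecord", "normalize_minmax", "denormalize", "split_by_patient",
    "PairedDataset", "TrainConfig", "TrainedModel", "train",
    "apply_correction", "make_paired_dataset", "MODEL_KINDS",
]

MODEL_KINDS = ("ae", "unet", "cgan")


@dataclass(frozen=True)
class ScaleRecord:
    """(min, max) HU of an image; inverts the unit-range normalization."""

    hu_min: float
    hu_max: float


def normalize_minmax(image) -> tuple[np.ndarray, ScaleRecord]:
    """Map an HU image to (0, 1) between its own min and max."""
    px = image.pixels if isinstance(image, PhantomImage) else np.asarray(image)
    px = px.astype(np.float64)
    lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        raise ValueError("constant image: min-max normalization undefined")
    return (px - lo) / (hi - lo), ScaleRecord(lo, hi)


def denormalize(unit: np.ndarray, record: ScaleRecord) -> np.ndarray:
    """Invert :func:`normalize_minmax` back to HU."""
    return np.asarray(unit, dtype=np.float64) \
        * (record.hu_max - record.hu_min) + record.hu_min


def split_by_patient(cohort: Cohort, train_fraction: float = 0.9,
                     seed: int = 0) -> tuple[Cohort, Cohort]:
    """Random patient-level partition into training and evaluation cohorts.

    ``round(train_fraction * n)`` patients (at least 1, at most n-1) go to
    training; no patient contributes slices to both sides.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(cohort.patients)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    n_train = int(round(train_fraction * n))
    n_train = max(1, min(n - 1, n_train))
    order = np.random.default_rng(seed).permutation(n)
    train_idx = set(order[:n_train].tolist())
    train = tuple(p for i, p in enumerate(cohort.patients) if i in train_idx)
    test = tuple(p for i, p in enumerate(cohort.patients) if i not in train_idx)
    return (Cohort(train, cohort.master_seed, cohort.size),
            Cohort(test, cohort.master_seed, cohort.size))


@dataclass(frozen=True)
class PairedDataset:
    """Aligned (artifact, original) image stacks for one view interval."""

    artifacts: np.ndarray  # (n, size, size) HU
    originals: np.ndarray  # (n, size, size) HU
    patient_ids: tuple[str, ...]
    view_interval: float
    roi_layouts: tuple[ROILayout, ...] = ()

    def __post_init__(self) -> None:
        if self.artifacts.shape != self.originals.shape:
            raise ValueError("artifact and original stacks must share shape")
        if len(self.patient_ids) != self.artifacts.shape[0]:
            raise ValueError("one patient id per image pair required")

    def __len__(self) -> int:
        return self.artifacts.shape[0]


def make_paired_dataset(cohort: Cohort, view_interval: float,
                        source_to_center: float = 400.0,
                        detector_arc_spacing: float = 0.25) -> PairedDataset:
    """Simulate sparse acquisition for every slice of a cohort.

    Each slice is forward-projected at the given rotational interval and
    reconstructed by filtered backprojection, yielding the streaked
    artifact image paired with its original.
    """
    geom = build_geometry(cohort.size, view_interval, source_to_center,
                          detector_arc_spacing)
    artifacts, originals, pids, rois = [], [], [], []
    for pid, image, roi in cohort.iter_slices():
        artifacts.append(reconstruct(project(image, geom)).pixels)
        originals.append(image.pixels)
        pids.append(pid)
        rois.append(roi)
    return PairedDataset(np.stack(artifacts), np.stack(originals),
                         tuple(pids), float(view_interval), tuple(rois))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the per-model training recipe
    (CGAN: Adam 0.0002, batch 1; AE/U-Net: Adam 0.001, batch 4; 200 epochs,
    scalable down)."""

    learning_rate: float
    batch_size: int
    epochs: int = 200
    seed: int = 0
    base_filters: int | None = None
    depth: int = 4
    lambda_l1: float = 100.0
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def for_model(cls, kind: str, **overrides) -> "TrainConfig":
        kind = kind.lower()
        if kind == "cgan":
            base = dict(learning_rate=2e-4, batch_size=1)
        elif kind in ("ae", "unet"):
            base = dict(learning_rate=1e-3, batch_size=4)
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainedModel:
    """A fitted restorer plus its configuration and loss history."""

    kind: str
    estimator: object
    config: TrainConfig
    history: list = field(default_factory=list)

    def predict(self, X):
        return self.estimator.predict(X)


def _make_estimator(kind: str, config: TrainConfig):
    common = dict(depth=config.depth, epochs=config.epochs,
                  learning_rate=config.learning_rate,
                  batch_size=config.batch_size, seed=config.seed)
    if kind == "ae":
        return AERestorer(base_filters=config.base_filters or 8, **common)
    if kind == "unet":
        return UNetRestorer(base_filters=config.base_filters or 64, **common)
    if kind == "cgan":
        return CGANRestorer(base_filters=config.base_filters or 64,
                            lambda_l1=config.lambda_l1,
                            dropout=config.dropout, **common)
    raise ValueError(f"unknown model kind {kind!r}")


def train(kind: str, dataset: PairedDataset,
          config: TrainConfig | None = None) -> TrainedModel:
    """Fit one restoration model on a paired dataset."""
    kind = kind.lower()
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    config = config or TrainConfig.for_model(kind)
    est = _make_estimator(kind, config)
    est.fit(dataset.artifacts, dataset.originals)
    return TrainedModel(kind, est, config, list(est.loss_history_))


def apply_correction(model, artifact) -> PhantomImage:
    """Run a trained model on one artifact image, returning an HU image.

    ``model`` is anything with a ``predict`` accepting an (n, H, W) stack
    (a :class:`TrainedModel` or a fitted restorer).
    """
    if isinstance(artifact, PhantomImage):
        px, spacing = artifact.pixels, artifact.pixel_spacing
    else:
        px = np.asarray(artifact, dtype=np.float32)
        spacing = 450.0 / px.shape[0]
    out = np.asarray(model.predict(px[None]))[0]
    return PhantomImage(out.astype(np.float32), spacing)
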