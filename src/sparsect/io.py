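"""Serialization: cohorts and sinograms to HDF5, slices to 16-bit TIFF.

TIFF slices store ``HU + 1024`` as unsigned 16-bit with the offset recorded
in the image description, the usual trick for carrying negative HU in
unsigned rasters.  ``load_raster`` ingests arbitrary user-supplied
grayscale images through imageio and applies the same offset convention.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .fanbeam import FanBeamGeometry, Sinogram
from .phantoms import Cohort, Patient, PhantomImage, Rect, ROILayout

__all__ = [
    "save_cohort", "load_cohort", "save_sinogram", "load_sinogram",
    "save_tiff", "load_tiff", "load_raster", "HU_OFFSET",
]

HU_OFFSET = 1024


def _roi_to_array(layout: ROILayout) -> np.ndarray:
    return np.array([[r.top, r.left, r.height, r.width]
                     for _, r in layout.items()], dtype=np.int32)


def _roi_from_array(arr: np.ndarray) -> ROILayout:
    rects = [Rect(*map(int, row)) for row in arr]
    return ROILayout(lung=rects[0], soft=rects[1], bone=rects[2],
                     air=rects[3])


def save_cohort(path, cohort: Cohort) -> None:
    """Write a cohort as /patient_<id>/slice_<k>/{pixels,roi}."""
    with h5py.File(path, "w") as f:
        f.attrs["master_seed"] = cohort.master_seed
        f.attrs["size"] = cohort.size
        for patient in cohort.patients:
            grp = f.create_group(patient.patient_id)
            for k, (image, roi) in enumerate(patient.slices):
                sl = grp.create_group(f"slice_{k}")
                ds = sl.create_dataset("pixels", data=image.pixels,
                                       compression="gzip")
                ds.attrs["pixel_spacing_mm"] = image.pixel_spacing
                sl.create_dataset("roi", data=_roi_to_array(roi))


def load_cohort(path) -> Cohort:
    with h5py.File(path, "r") as f:
        patients = []
        for pid in sorted(f.keys()):
            grp = f[pid]
            slices = []
            for k in sorted(grp.keys(), key=lambda s: int(s.split("_")[1])):
                sl = grp[k]
                image = PhantomImage(sl["pixels"][...],
                                     float(sl["pixels"].attrs["pixel_spacing_mm"]))
                slices.append((image, _roi_from_array(sl["roi"][...])))
            patients.append(Patient(pid, tuple(slices)))
        return Cohort(tuple(patients), int(f.attrs["master_seed"]),
                      int(f.attrs["size"]))


def save_sinogram(path, sinogram: Sinogram) -> None:
    """HDF5 with /values and the geometry as attributes (or .npy values)."""
    path = str(path)
    if path.endswith(".npy"):
        np.save(path, sinogram.values)
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=sinogram.values, compression="gzip")
        g = sinogram.geometry
        f.attrs["geometry"] = json.dumps({
            "image_size": g.image_size,
            "view_interval": g.view_interval,
            "source_to_center": g.source_to_center,
            "detector_arc_spacing": g.detector_arc_spacing,
            "n_detectors": g.n_detectors,
        })


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        geom = FanBeamGeometry(**json.loads(f.attrs["geometry"]))
        return Sinogram(f["values"][...], geom)


def save_tiff(path, image: PhantomImage) -> None:
    """16-bit TIFF with stored_value = HU + 1024."""
    import tifffile

    stored = np.clip(np.round(image.pixels.astype(np.float64)) + HU_OFFSET,
                     0, 65535).astype(np.uint16)
    tifffile.imwrite(path, stored, description=json.dumps(
        {"hu_offset": HU_OFFSET, "pixel_spacing_mm": image.pixel_spacing}))


def load_tiff(path) -> PhantomImage:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        stored = page.asarray()
        meta = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (ValueError, TypeError):
                meta = {}
    offset = meta.get("hu_offset", HU_OFFSET)
    spacing = meta.get("pixel_spacing_mm", 450.0 / stored.shape[0])
    return PhantomImage(stored.astype(np.float32) - offset, spacing)


def load_raster(path, hu_offset: float = HU_OFFSET) -> PhantomImage:
    """Read a user-supplied grayscale raster slice as an HU image."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float32)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.shape[0] != arr.shape[1]:
        side = min(arr.shape)
        arr = arr[:side, :side]
    return PhantomImage(arr - hu_offset, 450.0 / arr.shape[0])
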