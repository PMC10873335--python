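"""Filtered backprojection for equiangular fan-beam sinograms.

The reconstruction is the textbook direct fan-beam FBP: detector samples
are pre-weighted by D*cos(gamma), each view is convolved with a discrete
Shepp-Logan (sinc-windowed ramp) kernel carrying the equiangular
0.5*(gamma/sin gamma)^2 correction, and the filtered views are backprojected
with inverse-square source-to-pixel distance weighting and the angular step
between views as integration measure.  The chain project -> reconstruct is
linear, so HU images in give HU images out; with sparse view sets the
output is the streaked "simulated artifact image".

Pixels outside the inscribed circle of the grid (which the fan never covers
fully) are set to -1000 HU (air).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .fanbeam import Sinogram
from .phantoms import PhantomImage

__all__ = ["FilterKernel", "shepp_logan_kernel", "reconstruct"]

OUTSIDE_HU = -1000.0


@dataclass(frozen=True)
class FilterKernel:
    """Symmetric convolution kernel; ``taps[half_width]`` is the center tap."""

    taps: np.ndarray
    spacing: float  # detector sample spacing (radians) it was built for

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=np.float64)
        if taps.ndim != 1 or taps.size % 2 != 1:
            raise ValueError("taps must be 1D with odd length")
        if not np.allclose(taps, taps[::-1]):
            raise ValueError("kernel must be symmetric")
        object.__setattr__(self, "taps", taps)

    @property
    def half_width(self) -> int:
        return (self.taps.size - 1) // 2


def shepp_logan_kernel(half_width: int, spacing: float) -> FilterKernel:
    """Discrete Shepp-Logan ramp: h[n] = -2 / (pi^2 spacing^2 (4n^2 - 1)).

    The center tap is positive (2 / (pi spacing)^2), the taps are even in n,
    and their sum telescopes to zero as the half-width grows (zero DC gain).
    """
    if half_width < 8:
        raise ValueError("half_width must be at least 8")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n = np.arange(-half_width, half_width + 1, dtype=np.float64)
    taps = -2.0 / (math.pi ** 2 * spacing ** 2 * (4.0 * n ** 2 - 1.0))
    return FilterKernel(taps, spacing)


def _equiangular_taps(kernel: FilterKernel) -> np.ndarray:
    """Fold the fan-beam 0.5*(gamma/sin gamma)^2 factor into the taps."""
    k = kernel.half_width
    n = np.arange(-k, k + 1, dtype=np.float64)
    gamma = n * kernel.spacing
    ratio = np.ones_like(gamma)
    nz = n != 0
    ratio[nz] = (gamma[nz] / np.sin(gamma[nz])) ** 2
    return 0.5 * ratio * kernel.taps


def reconstruct(sinogram: Sinogram, out_size: int | None = None,
                kernel: FilterKernel | None = None) -> PhantomImage:
    """Fan-beam FBP of a (possibly sparse) sinogram back to an HU image.

    ``out_size`` must equal the geometry's ``image_size`` (it defaults to
    it); the reconstruction grid is the acquisition grid.  A custom
    ``kernel`` may replace the default full-support Shepp-Logan kernel.
    """
    geom = sinogram.geometry
    if out_size is None:
        out_size = geom.image_size
    if out_size != geom.image_size:
        raise ValueError("out_size must equal the geometry image_size")
    values = sinogram.values
    if values.size == 0:
        raise ValueError("empty sinogram")

    size = geom.image_size
    dist = geom.source_to_center
    dgamma = math.radians(geom.detector_arc_spacing)
    dbeta = math.radians(geom.view_interval)
    gamma = geom.fan_angles
    half = (geom.n_detectors - 1) // 2

    if kernel is None:
        kernel = shepp_logan_kernel(geom.n_detectors, dgamma)
    taps = _equiangular_taps(kernel)

    # (i) cosine + distance pre-weight, (ii) filter each view.
    weighted = values * (dist * np.cos(gamma))[None, :]
    filtered = fftconvolve(weighted, taps[None, :], mode="same", axes=1)
    filtered *= dgamma

    # (iii) backprojection with 1/L^2 weighting.
    c = (size - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(size, dtype=np.float64),
                             np.arange(size, dtype=np.float64))
    accum = np.zeros((size, size), dtype=np.float64)
    det_index = np.arange(geom.n_detectors, dtype=np.float64)
    for view, angle in enumerate(geom.view_angles):
        beta = math.radians(angle)
        sx = c + dist * math.cos(beta)
        sy = c + dist * math.sin(beta)
        ux, uy = -math.cos(beta), -math.sin(beta)
        vx = cols - sx
        vy = rows - sy
        l2 = vx * vx + vy * vy
        # Fan angle of each pixel, signed consistently with the projector.
        gpix = np.arctan2(ux * vy - uy * vx, ux * vx + uy * vy)
        idx = gpix / dgamma + half
        accum += np.interp(idx.ravel(), det_index,
                           filtered[view]).reshape(size, size) / l2
    accum *= dbeta

    mask = (cols - c) ** 2 + (rows - c) ** 2 <= c ** 2
    out = np.where(mask, accum, OUTSIDE_HU)
    return PhantomImage(np.clip(out, -32768, 32767), 450.0 / size)
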