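"""Forward projection: geometry contracts, oracles, symmetries."""

import math

import numpy as np
import pytest

from sparsect.fanbeam import (FanBeamGeometry, GeometryError, Sinogram,
                              build_geometry, project)
from sparsect.phantoms import PhantomImage

from conftest import make_smooth_disc


def oracle_ray_integral(pixels, sx, sy, dirx, diry, radius, cx, cy,
                        step=0.05):
    """Independent dense-sampling line integral with explicit bilinear
    interpolation (no shared code with the projector)."""
    # intersection of the ray with the circle |p - c| <= radius
    ox, oy = sx - cx, sy - cy
    b = ox * dirx + oy * diry
    disc = b * b - (ox * ox + oy * oy - radius * radius)
    if disc <= 0:
        return 0.0
    t0, t1 = -b - math.sqrt(disc), -b + math.sqrt(disc)
    n = int(math.ceil((t1 - t0) / step))
    total = 0.0
    size = pixels.shape[0]
    for i in range(n):
        t = t0 + (i + 0.5) * (t1 - t0) / n
        x = sx + t * dirx
        y = sy + t * diry
        x0, y0 = int(math.floor(x)), int(math.floor(y))
        fx, fy = x - x0, y - y0
        acc = 0.0
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy_, wy in ((0, 1 - fy), (1, fy)):
                xi, yi = x0 + dx, y0 + dy_
                val = pixels[yi, xi] if 0 <= xi < size and 0 <= yi < size \
                    else -1000.0
                acc += wx * wy * val
        total += acc * (t1 - t0) / n
    return total


class TestGeometry:
    @pytest.mark.parametrize("interval,n_views", [(1.0, 360), (2.0, 180),
                                                  (5.0, 72), (10.0, 36)])
    def test_view_counts(self, interval, n_views):
        geom = build_geometry(64, interval)
        assert geom.n_views == n_views
        assert len(geom.view_angles) == n_views
        assert geom.view_angles[1] - geom.view_angles[0] == interval

    def test_detector_count_formula(self):
        geom = build_geometry(256, 1.0, source_to_center=400.0,
                              detector_arc_spacing=0.25)
        # 2 * ceil(asin(128/400) / 0.25deg) + 1
        assert geom.n_detectors == 151

    def test_detector_arc_covers_object(self):
        for size in (64, 128, 256):
            geom = build_geometry(size, 1.0)
            half_span = (geom.n_detectors - 1) / 2 \
                * math.radians(geom.detector_arc_spacing)
            assert half_span >= math.asin((size / 2) / geom.source_to_center)

    def test_source_inside_object_rejected(self):
        with pytest.raises(GeometryError):
            build_geometry(256, 1.0, source_to_center=100.0)

    def test_non_divisor_interval_rejected(self):
        with pytest.raises(ValueError):
            build_geometry(64, 7.0)

    def test_even_detector_count_rejected(self):
        with pytest.raises(ValueError):
            FanBeamGeometry(64, 1.0, n_detectors=10)


class TestProjection:
    def test_zero_image_gives_zero_sinogram(self):
        img = PhantomImage(np.zeros((64, 64)), 1.0)
        sino = project(img, build_geometry(64, 10.0))
        assert np.allclose(sino.values, 0.0, atol=1e-9)

    def test_rotational_symmetry_of_smooth_disc(self):
        # rows of a rotationally symmetric object agree up to grid
        # discretization error
        img = make_smooth_disc(128)
        sino = project(img, build_geometry(128, 10.0))
        dev = np.abs(sino.values - sino.values[0]).max()
        assert dev / np.abs(sino.values).max() < 1e-3

    def test_single_pixel_against_dense_oracle(self):
        size = 64
        px = np.zeros((size, size))
        px[32, 32] = 1000.0
        img = PhantomImage(px, 1.0)
        geom = build_geometry(size, 30.0)
        sino = project(img, geom, step=0.25)
        c = (size - 1) / 2.0
        for view in range(geom.n_views):
            beta = math.radians(geom.view_angles[view])
            sx = c + geom.source_to_center * math.cos(beta)
            sy = c + geom.source_to_center * math.sin(beta)
            ux, uy = -math.cos(beta), -math.sin(beta)
            d = int(np.argmax(sino.values[view]))
            # maximum is at/next to the central detector (pixel is 0.5 px
            # off the rotation center)
            half = (geom.n_detectors - 1) // 2
            assert abs(d - half) <= 2
            gam = geom.fan_angles[d]
            dirx = ux * math.cos(gam) - uy * math.sin(gam)
            diry = ux * math.sin(gam) + uy * math.cos(gam)
            expected = oracle_ray_integral(px, sx, sy, dirx, diry,
                                           (size - 1) / 2.0, c, c)
            assert sino.values[view, d] == pytest.approx(expected, rel=0.02)

    def test_chest_phantom_views_match_oracle(self, chest64):
        image, _ = chest64
        geom = build_geometry(64, 90.0)
        sino = project(image, geom, step=0.1)
        px = image.pixels.astype(float)
        c = (64 - 1) / 2.0
        for view in range(geom.n_views):
            beta = math.radians(geom.view_angles[view])
            sx = c + geom.source_to_center * math.cos(beta)
            sy = c + geom.source_to_center * math.sin(beta)
            ux, uy = -math.cos(beta), -math.sin(beta)
            for d in (10, (geom.n_detectors - 1) // 2, geom.n_detectors - 11):
                gam = geom.fan_angles[d]
                dirx = ux * math.cos(gam) - uy * math.sin(gam)
                diry = ux * math.sin(gam) + uy * math.cos(gam)
                expected = oracle_ray_integral(px, sx, sy, dirx, diry,
                                               c, c, c, step=0.02)
                assert sino.values[view, d] == pytest.approx(
                    expected, rel=0.02, abs=2.0)

    def test_linearity(self, chest64, rng):
        image, _ = chest64
        geom = build_geometry(64, 30.0)
        other = PhantomImage(rng.normal(0, 100, (64, 64)), 1.0)
        pa = project(image, geom).values
        pb = project(other, geom).values
        combo = PhantomImage(2.0 * image.pixels.astype(float)
                             - 0.5 * other.pixels.astype(float), 1.0)
        pc = project(combo, geom).values
        # images are stored as float32, so exactness is at single precision
        assert np.allclose(pc, 2.0 * pa - 0.5 * pb, rtol=1e-5, atol=1e-2)

    def test_view_subset_consistency_bit_identical(self, chest64):
        image, _ = chest64
        s1 = project(image, build_geometry(64, 1.0))
        s10 = project(image, build_geometry(64, 10.0))
        assert np.array_equal(s1.values[::10], s10.values)

    def test_central_ray_symmetry(self):
        # phantom symmetric about the horizontal axis: column d at view v
        # equals column -d at view -v
        img = make_smooth_disc(64)
        sino = project(img, build_geometry(64, 30.0)).values
        n_views = sino.shape[0]
        for v in range(n_views):
            mirrored = sino[(n_views - v) % n_views, ::-1]
            assert np.allclose(sino[v], mirrored, rtol=1e-6, atol=1e-6)

    def test_step_refinement_converges(self, chest64):
        image, _ = chest64
        geom = build_geometry(64, 30.0)
        coarse = project(image, geom, step=0.5).values
        fine = project(image, geom, step=0.25).values
        rel = np.abs(coarse - fine).max() / np.abs(fine).max()
        assert rel < 0.005

    def test_shape_mismatch_rejected(self, chest64):
        image, _ = chest64
        with pytest.raises(ValueError):
            project(image, build_geometry(128, 10.0))

    def test_sinogram_shape_contract(self):
        geom = build_geometry(64, 10.0)
        with pytest.raises(ValueError):
            Sinogram(np.zeros((5, geom.n_detectors)), geom)
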