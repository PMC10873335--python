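"""Metric definitions against independent scalar-loop oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsect.metrics import (SSIMParams, build_report, line_profile,
                              mean_abs_error, mean_error, psnr, ssim_global,
                              two_tailed_t_test)
from sparsect.phantoms import Rect

from conftest import make_disc


# --- independent scalar-loop oracles ---------------------------------------

def oracle_me(x, y):
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            total += x[i, j] - y[i, j]
    return total / (x.shape[0] * x.shape[1])


def oracle_mae(x, y):
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            total += abs(x[i, j] - y[i, j])
    return total / (x.shape[0] * x.shape[1])


def oracle_ssim(x, y, c1=400.0, c2=3600.0):
    n = x.shape[0] * x.shape[1]
    mx = sum(x[i, j] for i in range(x.shape[0])
             for j in range(x.shape[1])) / n
    my = sum(y[i, j] for i in range(y.shape[0])
             for j in range(y.shape[1])) / n
    vx = vy = cov = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            vx += (x[i, j] - mx) ** 2
            vy += (y[i, j] - my) ** 2
            cov += (x[i, j] - mx) * (y[i, j] - my)
    vx, vy, cov = vx / n, vy / n, cov / n
    return ((2 * mx * my + c1) * (2 * cov + c2)) \
        / ((mx * mx + my * my + c1) * (vx + vy + c2))


def oracle_psnr(x, y):
    n = x.shape[0] * x.shape[1]
    mse = sum((x[i, j] - y[i, j]) ** 2 for i in range(x.shape[0])
              for j in range(x.shape[1])) / n
    peak = max(x[i, j] for i in range(x.shape[0]) for j in range(x.shape[1]))
    return 10.0 * math.log10(peak ** 2 / mse)


def oracle_t_test(a, b):
    """Textbook Welch two-sample t statistic and p value."""
    from scipy.stats import t as tdist
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    tstat = (ma - mb) / math.sqrt(se2)
    dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(tstat), dof)
    return tstat, p


# --- ME / MAE ---------------------------------------------------------------

class TestMeanErrors:
    def test_identity_is_zero(self, rng):
        x = rng.normal(0, 100, (8, 8))
        assert mean_error(x, x) == 0.0
        assert mean_abs_error(x, x) == 0.0

    def test_constant_offset(self, rng):
        y = rng.normal(0, 100, (8, 8))
        assert mean_error(y + 5.0, y) == pytest.approx(5.0)
        assert mean_abs_error(y + 5.0, y) == pytest.approx(5.0)

    def test_hand_arithmetic_2x2(self):
        y = np.zeros((2, 2))
        x = np.array([[1.0, -1.0], [3.0, 1.0]])
        assert mean_error(x, y) == pytest.approx(1.0)
        assert mean_abs_error(x, y) == pytest.approx(1.5)

    def test_roi_restriction(self, rng):
        y = np.zeros((10, 10))
        x = np.zeros((10, 10))
        x[2:4, 3:5] = 8.0
        roi = Rect(2, 3, 2, 2)
        assert mean_error(x, y, roi) == pytest.approx(8.0)
        assert mean_error(x, y) == pytest.approx(8.0 * 4 / 100)

    def test_roi_out_of_bounds_rejected(self):
        x = np.zeros((8, 8))
        with pytest.raises(ValueError):
            mean_error(x, x, Rect(5, 5, 4, 4))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_mae_dominates_absolute_me(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(0, 50, (6, 6))
        y = r.normal(0, 50, (6, 6))
        assert mean_abs_error(x, y) >= abs(mean_error(x, y)) - 1e-12


# --- SSIM -------------------------------------------------------------------

class TestSSIM:
    def test_constants(self):
        p = SSIMParams()
        assert p.c1 == pytest.approx(400.0)
        assert p.c2 == pytest.approx(3600.0)

    def test_identity_is_one(self, rng):
        x = rng.normal(0, 100, (16, 16))
        assert ssim_global(x, x) == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        a, b = 30.0, 70.0
        x = np.full((8, 8), a)
        y = np.full((8, 8), b)
        expected = (2 * a * b + 400.0) / (a * a + b * b + 400.0)
        assert ssim_global(x, y) == pytest.approx(expected)

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(0, 300, (16, 16))
            y = rng.normal(0, 300, (16, 16))
            assert ssim_global(x, y) == pytest.approx(
                oracle_ssim(x, y), rel=1e-9)

    def test_bounded_above_by_one(self, rng):
        for _ in range(20):
            x = rng.normal(0, 500, (12, 12))
            y = rng.normal(0, 500, (12, 12))
            assert ssim_global(x, y) <= 1.0 + 1e-12


# --- PSNR -------------------------------------------------------------------

class TestPSNR:
    def test_forty_db_example(self):
        # max(X) = 100, MSE = 1 -> 40 dB
        x = np.full((4, 4), 99.0)
        x[0, 0] = 100.0
        y = x - 1.0
        assert psnr(x, y) == pytest.approx(
            10 * math.log10(100.0 ** 2 / 1.0), rel=1e-9)

    def test_halving_mse_adds_three_db(self, rng):
        y = rng.normal(50, 10, (16, 16))
        y[0, 0] = 1000.0  # fixes max(X) across both comparisons
        noise = rng.normal(0, 1, (16, 16))
        noise[0, 0] = 0.0
        a = psnr(y + noise, y)
        b = psnr(y + noise / math.sqrt(2), y)
        assert b - a == pytest.approx(10 * math.log10(2), abs=1e-9)

    def test_identical_images_rejected(self):
        x = np.ones((4, 4))
        with pytest.raises(ValueError):
            psnr(x, x)

    def test_matches_scalar_loop_oracle(self, rng):
        x = rng.normal(100, 30, (16, 16))
        y = rng.normal(100, 30, (16, 16))
        assert psnr(x, y) == pytest.approx(oracle_psnr(x, y), rel=1e-9)


# --- line profile -----------------------------------------------------------

class TestLineProfile:
    def test_length_and_constant_series(self):
        img = np.full((32, 48), 7.0)
        prof = line_profile(img, "horizontal", 5)
        assert len(prof) == 48
        assert (prof["hu"] == 7.0).all()
        assert len(line_profile(img, "vertical", 10)) == 32

    def test_disc_profile_plateaus_in_order(self):
        disc = make_disc(64, 0.0)
        prof = line_profile(disc.pixels, "horizontal", 31)["hu"].to_numpy()
        # air -> disc -> air
        assert prof[0] == -1000.0 and prof[-1] == -1000.0
        assert prof[31] == 0.0
        transitions = np.flatnonzero(np.diff(prof) != 0)
        assert len(transitions) == 2

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            line_profile(np.zeros((8, 8)), "horizontal", 8)


# --- t-test -----------------------------------------------------------------

class TestTTest:
    def test_identical_samples(self):
        t, p = two_tailed_t_test([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a = [10.0, 11.0, 12.0, 13.0]
        b = [20.0, 21.0, 22.0, 23.0]
        t, p = two_tailed_t_test(a, b)
        t_exp, p_exp = oracle_t_test(a, b)
        assert t == pytest.approx(t_exp, rel=1e-9)
        assert p == pytest.approx(p_exp, rel=1e-9)
        assert p < 0.005  # clearly separated samples are significant

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            two_tailed_t_test([1.0], [1.0, 2.0])


# --- report building --------------------------------------------------------

def _rows(model, interval, metric, values, region="whole"):
    return [{"model": model, "view_interval": interval, "region": region,
             "metric": metric, "value": v} for v in values]


class TestBuildReport:
    def test_aggregation_mean_and_sample_sd(self):
        df = pd.DataFrame(_rows("with_artifacts", 10.0, "ssim", [0.8, 0.9]))
        rep = build_report(df)
        assert len(rep) == 1
        assert rep.loc[0, "mean"] == pytest.approx(0.85)
        assert rep.loc[0, "sd"] == pytest.approx(0.0707, abs=1e-4)

    def test_single_image_sd_zero(self):
        df = pd.DataFrame(_rows("with_artifacts", 10.0, "ssim", [0.8]))
        assert build_report(df).loc[0, "sd"] == 0.0

    def test_t_test_against_artifact_condition(self):
        df = pd.DataFrame(
            _rows("with_artifacts", 10.0, "ssim", [0.1, 0.11, 0.12])
            + _rows("cgan", 10.0, "ssim", [0.8, 0.81, 0.82]))
        rep = build_report(df).set_index("model")
        assert math.isnan(rep.loc["with_artifacts", "p_vs_artifacts"])
        assert rep.loc["cgan", "p_vs_artifacts"] < 0.005
        assert bool(rep.loc["cgan", "significant"])

    def test_full_grid_shape(self):
        frames = []
        for model in ("with_artifacts", "ae", "unet", "cgan"):
            for interval in (1.0, 2.0, 5.0, 10.0):
                frames += _rows(model, interval, "ssim", [0.5, 0.6])
        rep = build_report(pd.DataFrame(frames))
        # 4 conditions x 4 intervals, one (region, metric) cell each
        assert len(rep) == 16
        assert set(rep["model"]) == {"with_artifacts", "ae", "unet", "cgan"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            build_report(pd.DataFrame([{"model": "x", "value": 1.0}]))
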