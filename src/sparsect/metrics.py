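"""Image-quality metrics and report building.

ME and MAE are signed and absolute mean HU differences inside a rectangular
ROI.  SSIM is computed globally — one window covering the whole image —
with stabilizing constants derived from a 2000 HU dynamic range
(C1 = (0.01*2000)^2 = 400, C2 = (0.03*2000)^2 = 3600).  PSNR uses the
maximum of the evaluated image as the peak.  Reports aggregate per-image
metrics to mean +- sample standard deviation per (model, view interval,
region, metric) cell, with two-tailed t-tests against the uncorrected
("with_artifacts") condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantoms import Rect

__all__ = [
    "SSIMParams",
    "mean_error",
    "mean_abs_error",
    "ssim_global",
    "ssim_windowed",
    "psnr",
    "line_profile",
    "two_tailed_t_test",
    "build_report",
    "P_SIGNIFICANT",
]

#: significance threshold used when flagging report p-values
P_SIGNIFICANT = 0.005

ARTIFACT_CONDITION = "with_artifacts"


@dataclass(frozen=True)
class SSIMParams:
    """Stabilizing constants of the structural similarity index."""

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 2000.0

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def _roi_views(x, y, roi):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share shape")
    if roi is None:
        return x, y
    if not isinstance(roi, Rect):
        roi = Rect(*roi)
    if not (roi.inside(x.shape[0]) and roi.width + roi.left <= x.shape[1]):
        raise ValueError(f"ROI {roi} out of bounds for image {x.shape}")
    sl = roi.slices()
    return x[sl], y[sl]


def mean_error(x, y, roi: Rect | None = None) -> float:
    """Signed mean HU difference (X - Y) over the ROI (whole image if None)."""
    xv, yv = _roi_views(x, y, roi)
    return float(np.mean(xv - yv))


def mean_abs_error(x, y, roi: Rect | None = None) -> float:
    """Mean absolute HU difference over the ROI (whole image if None)."""
    xv, yv = _roi_views(x, y, roi)
    return float(np.mean(np.abs(xv - yv)))


def ssim_global(x, y, params: SSIMParams = SSIMParams()) -> float:
    """Single-window SSIM using global means, variances and covariance."""
    xv, yv = _roi_views(x, y, None)
    if xv.size == 0:
        raise ValueError("empty images")
    mx, my = xv.mean(), yv.mean()
    vx, vy = xv.var(), yv.var()
    cov = ((xv - mx) * (yv - my)).mean()
    c1, c2 = params.c1, params.c2
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx * mx + my * my + c1) * (vx + vy + c2)))


def ssim_windowed(x, y, params: SSIMParams = SSIMParams()) -> float:
    """Locally-windowed mean SSIM (standard sliding-window variant)."""
    from skimage.metrics import structural_similarity

    xv, yv = _roi_views(x, y, None)
    return float(structural_similarity(
        xv, yv, K1=params.k1, K2=params.k2, data_range=params.dynamic_range))


def psnr(x, y) -> float:
    """Peak signal-to-noise ratio, 10*log10(max(X)^2 / MSE), in dB."""
    xv, yv = _roi_views(x, y, None)
    mse = float(np.mean((xv - yv) ** 2))
    if mse == 0.0:
        raise ValueError("identical images: PSNR is infinite")
    peak = float(np.max(xv))
    return float(10.0 * np.log10(peak ** 2 / mse))


def line_profile(image, orientation: str, index: int) -> pd.DataFrame:
    """HU values along one row (horizontal) or column (vertical)."""
    img = np.asarray(image, dtype=np.float64)
    if orientation not in ("horizontal", "vertical"):
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    axis_len = img.shape[0] if orientation == "horizontal" else img.shape[1]
    if not 0 <= index < axis_len:
        raise ValueError(f"index {index} out of range for {orientation} profile")
    series = img[index, :] if orientation == "horizontal" else img[:, index]
    return pd.DataFrame({"pixel": np.arange(series.size), "hu": series})


def two_tailed_t_test(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed t-test (Welch by default).

    Returns ``(t, p)``.  Identical samples give ``(0, 1)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.array_equal(np.sort(a), np.sort(b)) and a.mean() == b.mean():
        if a.var() == 0.0 and b.var() == 0.0:
            return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


REPORT_COLUMNS = ("model", "view_interval", "region", "metric", "value")


def build_report(per_image: pd.DataFrame,
                 baseline: str = ARTIFACT_CONDITION,
                 equal_var: bool = False) -> pd.DataFrame:
    """Aggregate per-image metric rows into a Tables-style report.

    ``per_image`` needs columns (model, view_interval, region, metric,
    value); ``region`` is a tissue ROI name or ``"whole"``.  Each
    (model, interval, region, metric) cell becomes mean +- sample sd over
    evaluation images; conditions other than the baseline get a two-tailed
    t-test p-value against the baseline's matching cell (when both samples
    have >= 2 images).
    """
    missing = [c for c in REPORT_COLUMNS if c not in per_image.columns]
    if missing:
        raise ValueError(f"per-image metrics missing columns {missing}")
    if per_image.empty:
        raise ValueError("no per-image metrics to aggregate")

    rows = []
    grouped = per_image.groupby(["model", "view_interval", "region", "metric"],
                                sort=True)
    for (model, interval, region, metric), grp in grouped:
        vals = grp["value"].to_numpy(dtype=float)
        row = {
            "model": model,
            "view_interval": interval,
            "region": region,
            "metric": metric,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n_images": int(vals.size),
            "p_vs_artifacts": np.nan,
            "significant": False,
        }
        if model != baseline:
            ref = per_image[
                (per_image["model"] == baseline)
                & (per_image["view_interval"] == interval)
                & (per_image["region"] == region)
                & (per_image["metric"] == metric)]["value"].to_numpy(dtype=float)
            if ref.size >= 2 and vals.size >= 2:
                _, p = two_tailed_t_test(vals, ref, equal_var=equal_var)
                row["p_vs_artifacts"] = p
                row["significant"] = bool(p < P_SIGNIFICANT)
        rows.append(row)
    return pd.DataFrame(rows)
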