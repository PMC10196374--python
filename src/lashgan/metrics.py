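"""Image-quality metrics: PSNR, SSIM and the equivalent number of looks (ENL).

All metrics operate on the 8-bit [0, 255] intensity scale.  PSNR is
``10 log10((2^n - 1)^2 / MSE)`` for bit depth ``n``.  SSIM uses the
single-statistics (whole-image) form by default, with stability constants
``c1 = (k1 L)^2`` and ``c2 = (k2 L)^2`` where ``k1 = 0.01`` and ``k2 = 0.02``
(note the non-standard ``k2``); a sliding-window variant with uniform 11x11
windows is available for cross-checks against common implementations.  ENL is
``mu^2 / sigma^2`` over a region of interest — higher values indicate a
smoother (better restored) region; it is the natural measure inside an
artifact's footprint where no pixel-aligned reference exists.

Variance convention: population variance (divide by N) throughout.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

PSNR_INF = math.inf          # sentinel for identical images / zero variance
MIN_REGION_PIXELS = 64


class RegionTooSmallError(ValueError):
    pass


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error over all pixels and channels (8-bit scale)."""
    _check_shapes(a, b)
    d = a.astype(np.float64) - b.astype(np.float64)
    return float(np.mean(d * d))


def psnr(a: np.ndarray, b: np.ndarray, bit_depth: int = 8) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    err = mse(a, b)
    if err == 0.0:
        return PSNR_INF
    peak = 2 ** bit_depth - 1
    return float(10.0 * math.log10(peak * peak / err))


def _ssim_stats(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()                       # population variance
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx * mx + my * my + c1) * (vx + vy + c2)))


def ssim(a: np.ndarray, b: np.ndarray, k1: float = 0.01, k2: float = 0.02,
         L: float = 255.0, mode: str = "global", window: int = 11) -> float:
    """Structural similarity; 1 means identical, range [-1, 1].

    ``mode="global"`` evaluates the formula once from whole-image statistics;
    ``mode="windowed"`` averages it over uniform sliding windows.  Color
    images are scored per channel and averaged.
    """
    _check_shapes(a, b)
    if L <= 0:
        raise ValueError("dynamic range L must be positive")
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    if a.ndim == 2:
        a, b = a[..., None], b[..., None]
    vals = []
    for c in range(a.shape[-1]):
        x, y = a[..., c], b[..., c]
        if mode == "global":
            vals.append(_ssim_stats(x, y, c1, c2))
        elif mode == "windowed":
            vals.append(_ssim_windowed(x, y, c1, c2, window))
        else:
            raise ValueError(f"unknown ssim mode {mode!r}")
    return float(np.mean(vals))


def _ssim_windowed(x: np.ndarray, y: np.ndarray, c1: float, c2: float,
                   window: int) -> float:
    mx = uniform_filter(x, window)
    my = uniform_filter(y, window)
    mxx = uniform_filter(x * x, window)
    myy = uniform_filter(y * y, window)
    mxy = uniform_filter(x * y, window)
    vx = mxx - mx * mx
    vy = myy - my * my
    cov = mxy - mx * my
    s = ((2 * mx * my + c1) * (2 * cov + c2)) \
        / ((mx * mx + my * my + c1) * (vx + vy + c2))
    # interior windows only (fully inside the image)
    r = window // 2
    return float(s[r:-r or None, r:-r or None].mean())


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        return img.mean(axis=-1)    # unweighted channel mean
    return img


def enl(img: np.ndarray, region: np.ndarray,
        min_region_pixels: int = MIN_REGION_PIXELS) -> float:
    """Equivalent number of looks, mu^2 / sigma^2, over the masked region."""
    region = np.asarray(region, dtype=bool)
    if img.shape[:2] != region.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs region {region.shape}")
    n = int(region.sum())
    if n < min_region_pixels:
        raise RegionTooSmallError(
            f"region has {n} pixels, fewer than min_region_pixels={min_region_pixels}")
    vals = _to_gray(img)[region]
    mu = vals.mean()
    var = vals.var()                                # population variance
    if var == 0.0:
        return PSNR_INF
    return float(mu * mu / var)


def enl_delta_report(before: np.ndarray, after: np.ndarray,
                     regions: list[np.ndarray],
                     min_region_pixels: int = MIN_REGION_PIXELS) -> pd.DataFrame:
    """Per-region ENL before/after restoration, plus a summary row.

    Returns a table with one row per region (enl_before, enl_after, delta)
    and a final ``summary`` row counting regions whose ENL increased.
    """
    _check_shapes(before, after)
    rows = []
    for i, region in enumerate(regions):
        eb = enl(before, region, min_region_pixels)
        ea = enl(after, region, min_region_pixels)
        rows.append({"region": str(i), "enl_before": eb, "enl_after": ea,
                     "delta": ea - eb})
    increased = sum(r["delta"] > 0 for r in rows)
    rows.append({"region": "summary", "enl_before": math.nan,
                 "enl_after": math.nan, "delta": math.nan,
                 "n_regions": len(regions), "n_increased": increased})
    return pd.DataFrame(rows)


__all__ = [
    "MIN_REGION_PIXELS",
    "PSNR_INF",
    "RegionTooSmallError",
    "enl",
    "enl_delta_report",
    "mse",
    "psnr",
    "ssim",
]
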