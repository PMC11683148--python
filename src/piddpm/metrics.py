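"""Image-quality metrics: PSNR, multi-scale SSIM and NRMSE.

PSNR := 20 log10(MAX) - 10 log10(MSE), with MAX the ground-truth peak by
default.  NRMSE := sqrt(MSE) / (y_max - y_min), normalised by the ground
truth range.  MS-SSIM follows the five-scale product form

    MS-SSIM = [l_M]^{a_M} prod_j [c_j]^{b_j} [s_j]^{g_j}

with equal exponents per scale (a_j = b_j = g_j) given by the canonical
weights (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), an 11x11 Gaussian window
(sigma 1.5) and stability constants K1 = 0.01, K2 = 0.03.  Images too small
for five dyadic halvings fall back to fewer scales with renormalised weights
and a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["psnr", "ms_ssim", "nrmse", "MetricsReport", "evaluate_pairs"]

MS_SSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])
MS_SSIM_WEIGHTS = MS_SSIM_WEIGHTS / MS_SSIM_WEIGHTS.sum()
_WIN = 11


def _check_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return x, y


def psnr(x: np.ndarray, y: np.ndarray, max_value: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    x, y = _check_shapes(x, y)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    if max_value is None:
        max_value = float(np.max(y))
    return 20.0 * np.log10(max_value) - 10.0 * np.log10(mse)


def nrmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error normalised by the ground-truth range of y."""
    x, y = _check_shapes(x, y)
    rng = float(y.max() - y.min())
    if rng == 0.0:
        raise ValueError("constant ground truth: NRMSE undefined")
    return float(np.sqrt(np.mean((x - y) ** 2)) / rng)


def _ssim_components(x: np.ndarray, y: np.ndarray, data_range: float,
                     sigma: float = 1.5) -> tuple[float, float]:
    """Mean luminance term and mean contrast*structure term at one scale."""
    trunc = (_WIN - 1) / 2 / sigma
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_x = gaussian_filter(x, sigma, truncate=trunc)
    mu_y = gaussian_filter(y, sigma, truncate=trunc)
    xx = gaussian_filter(x * x, sigma, truncate=trunc) - mu_x ** 2
    yy = gaussian_filter(y * y, sigma, truncate=trunc) - mu_y ** 2
    xy = gaussian_filter(x * y, sigma, truncate=trunc) - mu_x * mu_y
    lum = (2 * mu_x * mu_y + c1) / (mu_x ** 2 + mu_y ** 2 + c1)
    cs = (2 * xy + c2) / (xx + yy + c2)
    return float(lum.mean()), float(cs.mean())


def _downsample2(img: np.ndarray) -> np.ndarray:
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    img = img[:h, :w]
    return img.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def ms_ssim(x: np.ndarray, y: np.ndarray, scales: int = 5,
            weights: np.ndarray | None = None,
            data_range: float | None = None) -> float:
    """Multi-scale structural similarity of x against reference y."""
    x, y = _check_shapes(x, y)
    if weights is None:
        weights = MS_SSIM_WEIGHTS[:scales].copy()
    weights = np.asarray(weights, dtype=float)
    if len(weights) != scales:
        raise ValueError("need one weight per scale")
    weights = weights / weights.sum()
    if data_range is None:
        data_range = float(y.max() - y.min())
        if data_range == 0.0:
            data_range = 1.0
    feasible = 1 + int(np.floor(np.log2(min(x.shape) / _WIN)))
    if feasible < scales:
        warnings.warn(
            f"image too small for {scales} scales; using {max(feasible, 1)}",
            stacklevel=2,
        )
        scales = max(feasible, 1)
        weights = weights[:scales] / weights[:scales].sum()
    value = 1.0
    for j in range(scales):
        lum, cs = _ssim_components(x, y, data_range)
        if j == scales - 1:
            value *= np.sign(lum * cs) * np.abs(lum * cs) ** weights[j]
        else:
            value *= np.sign(cs) * np.abs(cs) ** weights[j]
            x, y = _downsample2(x), _downsample2(y)
    return float(value)


@dataclass
class MetricsReport:
    psnr: list[float]
    ms_ssim: list[float]
    nrmse: list[float]

    def summary(self) -> dict[str, float]:
        out = {}
        for name, vals in (("psnr", self.psnr), ("ms_ssim", self.ms_ssim),
                           ("nrmse", self.nrmse)):
            arr = np.asarray(vals, dtype=float)
            finite = arr[np.isfinite(arr)]
            out[f"{name}_mean"] = float(finite.mean()) if finite.size else float("nan")
            out[f"{name}_sd"] = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
        return out


def evaluate_pairs(preds: list[np.ndarray], truths: list[np.ndarray],
                   max_value: float | None = None) -> MetricsReport:
    """Per-image metrics plus aggregates for matched prediction/truth lists."""
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    report = MetricsReport([], [], [])
    for p, t in zip(preds, truths):
        report.psnr.append(psnr(p, t, max_value))
        report.ms_ssim.append(ms_ssim(p, t))
        report.nrmse.append(nrmse(p, t))
    return report
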