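"""Image quality metrics: PSNR, global-statistics SSIM, RMSE.

SSIM here is the single-window (global) form — means, variances and the
covariance are computed over the whole array with sample (ddof=1) moments, so
the value agrees with a windowed reference implementation whose window covers
the entire image.  A sliding-window variant is available via ``win_size``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["psnr", "ssim", "rmse", "to_hounsfield", "from_hounsfield"]


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error, in the units of the inputs."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(a: np.ndarray, b: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio 20 log10(MAX / RMSE) in dB.

    Identical inputs return the +inf sentinel."""
    if max_val <= 0:
        raise ValueError("max_val must be > 0")
    r = rmse(a, b)
    if r == 0.0:
        return float("inf")
    return float(20.0 * np.log10(max_val / r))


def _global_ssim(a: np.ndarray, b: np.ndarray, c1: float, c2: float, ddof: int) -> float:
    mu_a, mu_b = a.mean(), b.mean()
    n = a.size
    var_a = a.var(ddof=ddof) if n > ddof else 0.0
    var_b = b.var(ddof=ddof) if n > ddof else 0.0
    denom = max(n - ddof, 1)
    cov = float(((a - mu_a) * (b - mu_b)).sum() / denom)
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(num / den)


def ssim(a: np.ndarray, b: np.ndarray, dynamic_range: float = 1.0,
         k1: float = 0.01, k2: float = 0.03, win_size: int | None = None) -> float:
    """Structural similarity with c1 = (k1 L)^2, c2 = (k2 L)^2.

    Default is the global (whole-array statistics) form; pass ``win_size`` for
    a mean-over-sliding-windows variant."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be > 0")
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    if win_size is None:
        return _global_ssim(a, b, c1, c2, ddof=1)
    from numpy.lib.stride_tricks import sliding_window_view

    wins_a = sliding_window_view(a, (win_size,) * a.ndim)
    wins_b = sliding_window_view(b, (win_size,) * a.ndim)
    flat_a = wins_a.reshape(-1, win_size**a.ndim)
    flat_b = wins_b.reshape(-1, win_size**a.ndim)
    vals = [_global_ssim(wa, wb, c1, c2, ddof=1) for wa, wb in zip(flat_a, flat_b)]
    return float(np.mean(vals))


def to_hounsfield(v01: np.ndarray) -> np.ndarray:
    """Affine map from normalized [0, 1] intensities to Hounsfield units:
    0 -> -1000 HU (air), 0.5 -> 0 HU (water), 1 -> +1000 HU."""
    return np.asarray(v01, dtype=np.float64) * 2000.0 - 1000.0


def from_hounsfield(hu: np.ndarray) -> np.ndarray:
    return (np.asarray(hu, dtype=np.float64) + 1000.0) / 2000.0
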