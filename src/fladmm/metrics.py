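"""Image-quality metrics: RMSE, PSNR, SSIM.

RMSE is computed over all pixels with no masking.  PSNR is
``20 log10(data_range / RMSE)`` and is ``inf`` for identical images unless
a finite ``cap`` is supplied.  SSIM uses the standard constants
K1 = 0.01, K2 = 0.03 with a uniform 7x7 window (the scikit-image default).
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["rmse", "psnr", "ssim", "visual_equivalence_rmse"]


def visual_equivalence_rmse(gray_levels: int = 256) -> float:
    """RMSE below which a reconstruction is visually identical to the truth.

    A display quantized to ``gray_levels`` levels over a unit data range
    cannot show differences smaller than one level, so an RMSE under
    ``1/gray_levels`` (~3.9e-3 for 8-bit) means the two images render the
    same.  Exact-recovery checks use the far stricter 1e-4.
    """
    if gray_levels < 2:
        raise ValueError("gray_levels must be >= 2")
    return 1.0 / gray_levels


def _check_pair(u: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if u.shape != truth.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {truth.shape}")
    return u, truth


def rmse(u: np.ndarray, truth: np.ndarray) -> float:
    """Root mean square error over all pixels; 0 iff the images coincide."""
    u, truth = _check_pair(u, truth)
    return float(np.sqrt(np.mean((u - truth) ** 2)))


def psnr(u: np.ndarray, truth: np.ndarray, data_range: float = 1.0, cap: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``cap`` bounds the perfect-match case."""
    err = rmse(u, truth)
    if err == 0:
        return float("inf") if cap is None else float(cap)
    val = 20.0 * np.log10(data_range / err)
    return float(min(val, cap)) if cap is not None else float(val)


def ssim(u: np.ndarray, truth: np.ndarray, data_range: float = 1.0) -> float:
    """Structural similarity index in [-1, 1]; 1 iff the images coincide."""
    u, truth = _check_pair(u, truth)
    return float(structural_similarity(truth, u, data_range=data_range))
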