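"""Image-quality evaluation: SSIM, PSNR, MSE, RMSE.

PSNR is ``10·log10(LD² / MSE)`` with ``LD`` the dynamic range (default the
declared 0-255 range; optionally the observed range of the reference).
Identical images have MSE 0 and PSNR +inf (a sentinel, never an exception).

SSIM defaults to the windowed form standard in practice (11×11 Gaussian
window, σ = 1.5, C1 = (0.01·L)², C2 = (0.03·L)²), i.e. the mean of local
SSIM values; a single-statistic global variant computed from whole-image
means/variances/covariance is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .image_core import as_image

__all__ = [
    "MetricsRecord",
    "mse",
    "rmse",
    "psnr",
    "ssim",
    "ssim_global",
    "evaluate_pair",
]


def _check_pair(x, y):
    x = as_image(x)
    y = as_image(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x, y) -> float:
    """Mean squared elementwise difference."""
    x, y = _check_pair(x, y)
    d = x - y
    return float(np.mean(d * d))


def rmse(x, y) -> float:
    return math.sqrt(mse(x, y))


def psnr(x, y, dynamic_range: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    err = mse(x, y)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(dynamic_range**2 / err)


def ssim(x, y, dynamic_range: float = 255.0) -> float:
    """Mean local SSIM over 11×11 Gaussian-weighted windows (σ = 1.5)."""
    x, y = _check_pair(x, y)
    if min(x.shape) < 11:
        raise ValueError("windowed SSIM needs images of at least 11x11")
    return float(structural_similarity(
        x, y, data_range=dynamic_range, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False, K1=0.01, K2=0.03,
    ))


def ssim_global(x, y, dynamic_range: float = 255.0) -> float:
    """Single-statistic SSIM from whole-image moments (no windowing)."""
    x, y = _check_pair(x, y)
    C1 = (0.01 * dynamic_range) ** 2
    C2 = (0.03 * dynamic_range) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cxy = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + C1) * (2 * cxy + C2))
                 / ((mx**2 + my**2 + C1) * (vx + vy + C2)))


@dataclass(frozen=True)
class MetricsRecord:
    """SSIM/PSNR/MSE/RMSE for one (reference, test) image pair."""

    ssim: float
    psnr: float
    mse: float
    rmse: float

    def as_tsv(self) -> str:
        return f"{self.ssim:.6f}\t{self.psnr:.4f}\t{self.mse:.6g}\t{self.rmse:.6g}"


def evaluate_pair(reference, test, dynamic_range: float = 255.0,
                  ld_observed: bool = False) -> MetricsRecord:
    """All four metrics of ``test`` against ``reference``.

    ``ld_observed=True`` uses the observed max-minus-min intensity of the
    reference image as the dynamic range instead of the declared one.
    """
    reference, test = _check_pair(reference, test)
    ld = float(reference.max() - reference.min()) if ld_observed else dynamic_range
    if ld <= 0:
        raise ValueError("observed dynamic range is degenerate")
    err = mse(reference, test)
    return MetricsRecord(
        ssim=ssim(reference, test, ld),
        psnr=math.inf if err == 0 else 10.0 * math.log10(ld**2 / err),
        mse=err,
        rmse=math.sqrt(err),
    )
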