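"""Gaussian pre-filter producing the blurred guide image.

The guide image drives feature extraction and pre-classification only; the
weighted averaging of the filter always reads intensities from the original
noisy image (restoring from an already-blurred guide would double-smooth).

The kernel is the standard normalised isotropic Gaussian
``G(x, y) ∝ exp(-(x² + y²) / (2 σ²))`` on a ``(2m+1)×(2m+1)`` square mask.
Defaults follow the reference parameterisation: ``σ = 0.5 × σ_noise`` and
``m = 4``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import as_image

__all__ = ["GaussianKernel", "gaussian_kernel", "gaussian_blur"]


@dataclass(frozen=True)
class GaussianKernel:
    """Normalised Gaussian convolution mask of radius ``m``."""

    mask: np.ndarray
    m: int
    sigma: float


def gaussian_kernel(sigma: float, m: int) -> GaussianKernel:
    """Build the normalised ``(2m+1)×(2m+1)`` Gaussian mask.

    Entries sum to 1; the center entry is the maximum; the mask is symmetric
    under transposition and 90° rotation.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if m < 1:
        raise ValueError("kernel radius m must be >= 1")
    y, x = np.mgrid[-m : m + 1, -m : m + 1].astype(np.float64)
    mask = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    mask /= mask.sum()
    return GaussianKernel(mask=mask, m=int(m), sigma=float(sigma))


def gaussian_blur(img, kernel: GaussianKernel) -> np.ndarray:
    """2-D convolution of ``img`` with ``kernel`` under mirror boundaries.

    Output has the same shape as the input; constant images are fixed
    points because the kernel is normalised.
    """
    img = as_image(img)
    size = 2 * kernel.m + 1
    if size > min(img.shape):
        raise ValueError(
            f"kernel of size {size} larger than image of shape {img.shape}"
        )
    # kernel is point-symmetric, so correlation equals convolution
    return ndimage.correlate(img, kernel.mask, mode="mirror")
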