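"""Image containers, I/O and patch plumbing shared by the whole pipeline.

Conventions
-----------
* Images are 2-D ``float64`` arrays on the nominal 0-255 intensity scale,
  indexed ``[row, col]`` with 0-based, row-major coordinates.
* Patches are odd-sized squares described by their *radius* ``r`` (side
  ``2*r + 1``).  Rotation-sensitive computations use the inscribed circular
  support of radius ``r`` so that a rotated support never leaves the square.
* Intensities stay floating point throughout the pipeline; clipping to
  [0, 255] and 8-bit quantisation happen only when an image is written out.
* Border handling is mirror reflection (edge pixel not duplicated), so that
  every pixel — including border pixels — owns a full patch without an
  artificial dark bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ImageFormatError",
    "Patch",
    "as_image",
    "read_image",
    "write_image",
    "pad_reflect",
    "circular_mask",
    "support_offsets",
    "extract_patch",
    "patch_centers",
]

#: file suffixes accepted by :func:`read_image` / :func:`write_image`
_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff"}

# Rec. 601 luma weights used to collapse RGB inputs to a single channel.
_LUMA = np.array([0.299, 0.587, 0.114])


class ImageFormatError(ValueError):
    """Raised when an image file cannot be read or has an unsupported format."""


def as_image(values) -> np.ndarray:
    """Validate and coerce ``values`` into a 2-D float64 image array.

    Raises ``ValueError`` for non-2-D input or non-finite intensities.
    """
    img = np.asarray(values, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite intensities")
    return img


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF file as a single-channel float image on the 0-255 scale.

    Multi-channel inputs are collapsed to luminance (Rec. 601 weights); an
    alpha channel, if present, is dropped.  8-bit data maps to 0-255
    unchanged, 16-bit data is rescaled to 0-255, floating-point data is
    passed through as-is.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ImageFormatError(f"unsupported image format: {path}")
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise ImageFormatError(f"cannot read image file: {path}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr.astype(np.float64) @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ImageFormatError(f"unsupported channel count in {path}")
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    return as_image(arr)


def write_image(path, img) -> None:
    """Write an image as 8-bit grayscale PNG/TIFF.

    Values are clipped to [0, 255] and rounded half-to-even before
    quantisation; this is the only place the pipeline quantises.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ImageFormatError(f"unsupported image format: {path}")
    img = as_image(img)
    data = np.rint(np.clip(img, 0.0, 255.0)).astype(np.uint8)
    iio.imwrite(path, data)


def pad_reflect(img, margin: int) -> np.ndarray:
    """Mirror-pad ``img`` by ``margin`` pixels on every side.

    The edge pixel is not duplicated (``[1,2,3]`` with margin 1 becomes
    ``[2,1,2,3,2]``).  ``margin`` must be smaller than both image dimensions
    for the reflection to be defined.
    """
    img = as_image(img)
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin >= min(img.shape):
        raise ValueError(
            f"margin {margin} too large for image of shape {img.shape}"
        )
    if margin == 0:
        return img.copy()
    return np.pad(img, margin, mode="reflect")


def circular_mask(radius: int) -> np.ndarray:
    """Boolean ``(2r+1, 2r+1)`` mask of pixels within distance ``r`` of center."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return dx * dx + dy * dy <= radius * radius


def support_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(dx, dy)`` integer offsets of the circular support, row-major.

    ``dx`` indexes columns and ``dy`` rows, both relative to the patch
    center.
    """
    mask = circular_mask(radius)
    dy, dx = np.nonzero(mask)
    return (dx - radius).astype(np.int64), (dy - radius).astype(np.int64)


@dataclass(frozen=True)
class Patch:
    """Square intensity window around a center pixel.

    ``values`` is an ``n×n`` copy of the source image (``n = 2*radius+1``,
    odd); mutating it never mutates the image it came from.
    ``circular_mask`` marks the inscribed circular support used by
    rotation-dependent computations.
    """

    values: np.ndarray
    center: tuple[int, int]
    radius: int
    circular_mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        n = 2 * self.radius + 1
        if self.values.shape != (n, n):
            raise ValueError(
                f"patch values shape {self.values.shape} != ({n}, {n})"
            )

    @property
    def size(self) -> int:
        return 2 * self.radius + 1


def extract_patch(img, center: tuple[int, int], radius: int) -> Patch:
    """Extract the ``(2r+1)²`` window centered at ``center`` (row, col).

    The window must lie fully inside ``img``; callers working near borders
    pad first with :func:`pad_reflect`.
    """
    img = as_image(img)
    row, col = center
    h, w = img.shape
    if not (radius <= row < h - radius and radius <= col < w - radius):
        raise IndexError(
            f"patch of radius {radius} at {center} exceeds image bounds {img.shape}"
        )
    window = img[row - radius : row + radius + 1, col - radius : col + radius + 1]
    return Patch(
        values=window.copy(),
        center=(int(row), int(col)),
        radius=int(radius),
        circular_mask=circular_mask(radius),
    )


def patch_centers(height: int, width: int) -> np.ndarray:
    """All patch-center coordinates of an image, row-major, shape ``(h*w, 2)``.

    With stride-1 coverage after reflect padding there is exactly one patch
    per pixel.
    """
    rows, cols = np.mgrid[0:height, 0:width]
    return np.column_stack([rows.ravel(), cols.ravel()])
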