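"""Synthetic ultrasound-like phantoms and noise models.

The generator produces piecewise-smooth anatomy-like test images — elliptical
hypo-/hyper-echoic lesions on a gently textured background — together with two
degradation models:

* ``additive_gaussian`` — zero-mean Gaussian noise with standard deviation
  ``sigma`` on the 0-255 intensity scale (the degradation used by the
  replication experiments, at sigma in {10, 20, 50});
* ``multiplicative_speckle`` — a unit-mean log-normal multiplier per pixel
  whose standard deviation is ``sigma / 255``, emulating the multiplicative
  character of speckle.

Everything is deterministic given the seed; noisy outputs are *not* clipped
(clipping is a write-out concern, see :mod:`ribmnlm.image_core`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_core import as_image

__all__ = [
    "Lesion",
    "PhantomSpec",
    "NoiseSpec",
    "make_phantom",
    "add_noise",
    "default_phantom_spec",
    "make_motif_phantom",
]

NOISE_MODELS = ("additive_gaussian", "multiplicative_speckle")


@dataclass(frozen=True)
class Lesion:
    """Elliptical lesion: intensity offset applied inside a rotated ellipse.

    ``center`` is (row, col); ``semi_axes`` are the half-lengths (a, b) along
    the ellipse's own axes; ``angle_deg`` rotates the ellipse
    counter-clockwise; ``offset`` is added to the background level inside
    (negative = hypo-echoic, positive = hyper-echoic).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float = 0.0
    offset: float = -50.0


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 128
    width: int = 128
    lesions: tuple[Lesion, ...] = ()
    background_level: float = 120.0
    texture_amplitude: float = 0.0
    texture_scale: float = 3.0  # Gaussian correlation length of the texture, px
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be non-negative")
        if not 0.0 <= self.background_level <= 255.0:
            raise ValueError("background_level must lie in [0, 255]")
        for les in self.lesions:
            r, c = les.center
            reach = max(les.semi_axes)
            if not (reach <= r <= self.height - 1 - reach
                    and reach <= c <= self.width - 1 - reach):
                raise ValueError(f"lesion at {les.center} exceeds image bounds")
            if not 0.0 <= self.background_level + les.offset <= 255.0:
                raise ValueError(
                    f"lesion offset {les.offset} leaves the [0, 255] range"
                )


@dataclass(frozen=True)
class NoiseSpec:
    model: str = "additive_gaussian"
    sigma: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.model not in NOISE_MODELS:
            raise ValueError(
                f"unknown noise model {self.model!r}; expected one of {NOISE_MODELS}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def _ellipse_mask(h: int, w: int, les: Lesion) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dy = rows - les.center[0]
    dx = cols - les.center[1]
    th = math.radians(les.angle_deg)
    # rotate coordinates into the ellipse frame
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    a, b = les.semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the noiseless phantom described by ``spec``.

    Background level, plus each lesion's offset inside its ellipse, plus a
    seeded smooth zero-mean texture of standard deviation
    ``texture_amplitude``.  Deterministic given ``spec.seed``; values are
    clipped into [0, 255] (the pre-noise image is a valid 8-bit-range image
    by construction).
    """
    spec.validate()
    img = np.full((spec.height, spec.width), spec.background_level, dtype=np.float64)
    for les in spec.lesions:
        img[_ellipse_mask(spec.height, spec.width, les)] += les.offset
    if spec.texture_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        tex = rng.standard_normal((spec.height, spec.width))
        tex = ndimage.gaussian_filter(tex, spec.texture_scale, mode="mirror")
        sd = tex.std()
        if sd > 0:
            img += tex * (spec.texture_amplitude / sd)
    return np.clip(img, 0.0, 255.0)


def add_noise(img, noise: NoiseSpec) -> np.ndarray:
    """Apply the degradation model of ``noise`` to ``img`` (not clipped)."""
    img = as_image(img)
    noise.validate()
    if noise.sigma == 0:
        return img.copy()
    rng = np.random.default_rng(noise.seed)
    if noise.model == "additive_gaussian":
        return img + rng.normal(0.0, noise.sigma, size=img.shape)
    # multiplicative_speckle: unit-mean log-normal multiplier with
    # sd = sigma/255 (relative scale).
    s = noise.sigma / 255.0
    var_log = math.log1p(s * s)
    mu_log = -0.5 * var_log
    eta = rng.lognormal(mean=mu_log, sigma=math.sqrt(var_log), size=img.shape)
    return img * eta


def default_phantom_spec(height: int = 128, width: int = 128,
                         seed: int = 0) -> PhantomSpec:
    """Standard test phantom: hypo- and hyper-echoic lesions on textured tissue.

    Background 120, one hypoechoic lesion (offset -55, like a cyst/mass), one
    hyperechoic lesion (offset +45), mild smooth texture (sd 8) emulating
    tissue echogenicity variation.  Lesion geometry scales with image size.
    """
    h, w = height, width
    lesions = (
        Lesion(center=(0.38 * h, 0.32 * w),
               semi_axes=(0.16 * h, 0.10 * w), angle_deg=25.0, offset=-55.0),
        Lesion(center=(0.66 * h, 0.70 * w),
               semi_axes=(0.09 * h, 0.14 * w), angle_deg=-40.0, offset=45.0),
    )
    return PhantomSpec(height=h, width=w, lesions=lesions,
                       background_level=120.0, texture_amplitude=8.0,
                       seed=seed)


def make_motif_phantom(angles_deg=(0.0, 45.0, 90.0, 135.0), motif_radius: int = 7,
                       spacing: int = 40, background: float = 100.0,
                       amplitude: float = 100.0):
    """Stamp one anisotropic motif at several orientations on a flat background.

    The motif is an off-center elongated Gaussian blob (strongly anisotropic,
    with a clearly non-zero intensity centroid offset), rotated by each angle
    via continuous spline resampling and stamped on a 2x2 grid.  Used to
    exercise rotation-compensated matching: patches at the stamp centers are
    rotated copies of one another.

    Returns ``(image, centers, angles_deg)`` where ``centers`` is a list of
    (row, col) stamp centers.
    """
    n = 2 * motif_radius + 1
    dy, dx = np.mgrid[-motif_radius:motif_radius + 1,
                      -motif_radius:motif_radius + 1].astype(np.float64)
    # elongated blob, displaced from the patch center so the centroid offset
    # is large and the rotation angle is well determined
    x0, y0 = 3.0, 1.0
    motif = amplitude * np.exp(-(((dx - x0) / 3.5) ** 2 + ((dy - y0) / 1.4) ** 2))

    ncols = 2
    nrows = (len(angles_deg) + 1) // 2
    h = nrows * spacing + spacing
    w = ncols * spacing + spacing
    img = np.full((h, w), background, dtype=np.float64)
    centers = []
    for k, ang in enumerate(angles_deg):
        stamped = ndimage.rotate(motif, ang, reshape=False, order=3,
                                 mode="constant", cval=0.0)
        r0 = spacing // 2 + (k // ncols) * spacing + motif_radius
        c0 = spacing // 2 + (k % ncols) * spacing + motif_radius
        img[r0 - motif_radius:r0 + motif_radius + 1,
            c0 - motif_radius:c0 + motif_radius + 1] += stamped
        centers.append((r0, c0))
    return np.clip(img, 0.0, 255.0), centers, tuple(angles_deg)
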