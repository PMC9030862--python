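"""Intensity-weighted central moments and Hu's seven rotation invariants.

Each patch is summarised by the seven Hu invariants (φ1…φ7) of its
intensity distribution.  φ1…φ6 are invariant to translation, scale and
rotation; φ7 additionally changes sign under mirroring, which is what the
matcher uses to detect mirrored candidates.

Moments are *intensity-weighted* (the gray value acts as the mass density),
so the moment centroid here is the same object as the block-matching
centroid.  The intensity distribution is normalised to unit total mass
before the invariants are formed, which makes the features invariant to
global intensity scaling (gain/brightness differences between patches);
the standard normalisation ``η_pq = μ_pq / μ00^(1 + (p+q)/2)`` applied to
the unit-mass distribution reduces to ``η_pq = μ_pq / μ00``.  (The
classical exponent alone gives geometric-size invariance for binary
shapes but is *not* intensity-invariant for gray-weighted moments; the
patches here have fixed geometry, so intensity invariance is the property
that matters.)

Coordinates: ``x`` indexes columns and ``y`` rows, both measured from the
patch center.  Third-order moments are required by φ3…φ7 and are always
computed.

An all-zero patch has no moment centroid; :func:`central_moments` raises for
it, and the pipeline layer (see :func:`hu_field`) maps such patches to the
zero feature vector instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import Patch, as_image

__all__ = [
    "CentralMomentSet",
    "central_moments",
    "hu_invariants",
    "hu_from_patch",
    "hu_field",
    "mirror_discordant",
]

_ORDERS = [(0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (0, 2),
           (2, 1), (1, 2), (3, 0), (0, 3)]


@dataclass(frozen=True)
class CentralMomentSet:
    """Intensity-weighted central moments μ_pq (p+q ≤ 3) of one patch.

    ``centroid`` is the intensity centroid (xc, yc) relative to the patch
    center; ``mass`` is μ00 = Σv > 0.  By construction μ10 = μ01 = 0.
    """

    mu: dict
    centroid: tuple[float, float]
    mass: float


def central_moments(patch) -> CentralMomentSet:
    """Central moments of a patch's intensity distribution, orders p+q ≤ 3."""
    values = patch.values if isinstance(patch, Patch) else as_image(patch)
    n = values.shape[0]
    if values.shape != (n, n) or n % 2 == 0:
        raise ValueError("patch must be an odd-sized square")
    mass = float(values.sum())
    if mass <= 0:
        raise ValueError("degenerate patch: total intensity mass is not positive")
    r = (n - 1) // 2
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    xc = float((x * values).sum() / mass)
    yc = float((y * values).sum() / mass)
    dx = x - xc
    dy = y - yc
    mu = {
        (p, q): float((values * dx**p * dy**q).sum())
        for (p, q) in _ORDERS
    }
    return CentralMomentSet(mu=mu, centroid=(xc, yc), mass=mass)


def _hu_from_eta(e20, e02, e11, e30, e03, e21, e12):
    """Hu's seven invariants from normalised moments (array-friendly)."""
    a = e30 + e12  # odd in x
    b = e21 + e03  # odd in y
    c = e30 - 3.0 * e12
    d = 3.0 * e21 - e03
    phi1 = e20 + e02
    phi2 = (e20 - e02) ** 2 + 4.0 * e11**2
    phi3 = c**2 + d**2
    phi4 = a**2 + b**2
    phi5 = c * a * (a**2 - 3.0 * b**2) + d * b * (3.0 * a**2 - b**2)
    phi6 = (e20 - e02) * (a**2 - b**2) + 4.0 * e11 * a * b
    phi7 = d * a * (a**2 - 3.0 * b**2) - c * b * (3.0 * a**2 - b**2)
    return phi1, phi2, phi3, phi4, phi5, phi6, phi7


def hu_invariants(moments: CentralMomentSet) -> np.ndarray:
    """The seven Hu invariants (φ1…φ7) as a length-7 vector.

    Central moments are normalised to unit total mass,
    ``η_pq = μ_pq / μ00``, which makes the invariants independent of
    global intensity scaling (see module docstring).
    """
    if moments.mass <= 0:
        raise ValueError("degenerate patch: mass must be positive")
    m = moments.mu
    m00 = moments.mass

    def eta(p, q):
        return m[(p, q)] / m00

    phi = _hu_from_eta(eta(2, 0), eta(0, 2), eta(1, 1),
                       eta(3, 0), eta(0, 3), eta(2, 1), eta(1, 2))
    return np.array(phi, dtype=np.float64)


def hu_from_patch(patch) -> np.ndarray:
    """Convenience: Hu vector straight from a patch (zero vector if massless)."""
    values = patch.values if isinstance(patch, Patch) else np.asarray(patch)
    if float(np.sum(values)) <= 0:
        return np.zeros(7)
    return hu_invariants(central_moments(patch))


def hu_field(guide, radius: int) -> np.ndarray:
    """Per-pixel Hu vectors for every square patch of ``guide``, vectorised.

    Raw patch moments are correlations of the image with monomial kernels
    ``x^p y^q`` over the square support (mirror boundaries, matching
    reflect padding); central moments follow from the binomial shift
    identities.  Equivalent to running :func:`central_moments` +
    :func:`hu_invariants` on every patch, but ~patch-size² faster.

    Mass-free (all-zero) patches yield the zero feature vector.

    Returns an array of shape ``(h, w, 7)``.
    """
    guide = as_image(guide)
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(np.float64)

    def raw(p, q):
        return ndimage.correlate(guide, x**p * y**q, mode="mirror")

    m00 = raw(0, 0)
    m10, m01 = raw(1, 0), raw(0, 1)
    m11 = raw(1, 1)
    m20, m02 = raw(2, 0), raw(0, 2)
    m21, m12 = raw(2, 1), raw(1, 2)
    m30, m03 = raw(3, 0), raw(0, 3)

    ok = m00 > 0
    safe = np.where(ok, m00, 1.0)
    xc = m10 / safe
    yc = m01 / safe

    mu11 = m11 - xc * m01
    mu20 = m20 - xc * m10
    mu02 = m02 - yc * m01
    mu30 = m30 - 3.0 * xc * m20 + 2.0 * xc**2 * m10
    mu03 = m03 - 3.0 * yc * m02 + 2.0 * yc**2 * m01
    mu21 = m21 - 2.0 * xc * m11 - yc * m20 + 2.0 * xc**2 * m01
    mu12 = m12 - 2.0 * yc * m11 - xc * m02 + 2.0 * yc**2 * m10

    phi = _hu_from_eta(mu20 / safe, mu02 / safe, mu11 / safe,
                       mu30 / safe, mu03 / safe, mu21 / safe, mu12 / safe)
    out = np.stack(phi, axis=-1)
    out[~ok] = 0.0
    return out


def mirror_discordant(a, b) -> bool:
    """True iff the two Hu vectors disagree in the sign of φ7.

    ``φ7(a)·φ7(b) < 0`` is the mirror test: a strict inequality, so a zero
    φ7 is never flagged as mirrored.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("Hu vectors must be finite")
    return bool(a[6] * b[6] < 0.0)
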