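"""Rotation- and mirror-compensated block matching (RIBM).

The rotation between a target patch ``N_i`` and a candidate patch ``N_j`` is
estimated from their intensity centroids: each patch's centroid offset from
the patch center defines a direction, and the rotation frame is the 2-D
rotation carrying the target's centroid direction onto the candidate's.
Mirrored candidates (detected upstream by the sign of Hu's φ7) are
compensated by flipping the x component before and after the rotation.

For unit centroid direction ``u = (u1, u2)``, ``R_u = [[u1, -u2], [u2, u1]]``
is the rotation taking (1, 0) to ``u``; the frame is
``R = R_ci^-1 · R_m(cj)`` with the mirror map ``m(u) = (-u1, u2)`` applied to
the candidate's direction in the mirrored branch.  A point ``q`` of the
target patch then corresponds to ``m(R·q)`` in the candidate patch, and the
rotation-invariant distance ``dR`` sums squared intensity differences over
the circular patch support, sampling the candidate at the mapped
(generally fractional) coordinates by bilinear interpolation.

Centroid directions are unit-normalised before entering ``R_u`` — an
unnormalised centroid would make ``R_u`` a rotation-plus-scaling and corrupt
the distance.  Patches whose centroid offset (nearly) vanishes are
isotropic to first order; no rotation is estimable for them and the frame
is flagged invalid, upon which ``dR`` falls back to the plain unrotated
distance over the same support.

Coordinates here are (x, y) = (column offset, row offset) from the patch
center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_core import Patch, as_image, support_offsets

__all__ = [
    "Centroid",
    "RotationFrame",
    "IDENTITY_FRAME",
    "patch_centroid",
    "centroid_field",
    "rotation_frame",
    "frame_angle_deg",
    "map_point",
    "bilinear_sample",
    "distance_dR",
]

#: default threshold below which a centroid offset norm (in pixels) counts
#: as degenerate — no rotation estimable
CENTROID_EPS = 1e-6


@dataclass(frozen=True)
class Centroid:
    """Intensity-centroid offset of a patch from its center.

    ``vec = (cx, cy)`` in pixels; ``unit`` is the normalised direction
    (the zero vector when ``norm`` vanishes).
    """

    vec: tuple[float, float]
    norm: float
    unit: tuple[float, float]


@dataclass(frozen=True)
class RotationFrame:
    """2×2 rotation aligning a candidate patch with a target patch.

    ``valid`` is False when either patch has a degenerate centroid, in
    which case no rotation is estimable and ``R`` is the identity.
    """

    R: np.ndarray
    mirrored: bool
    valid: bool


IDENTITY_FRAME = RotationFrame(R=np.eye(2), mirrored=False, valid=True)


def _make_centroid(cx: float, cy: float, eps: float) -> Centroid:
    norm = float(np.hypot(cx, cy))
    if norm > eps:
        unit = (cx / norm, cy / norm)
    else:
        unit = (0.0, 0.0)
    return Centroid(vec=(float(cx), float(cy)), norm=norm, unit=unit)


def patch_centroid(patch, eps: float = CENTROID_EPS) -> Centroid:
    """Intensity centroid of a patch over its circular support.

    ``cx = Σ x·v / Σ v``, ``cy = Σ y·v / Σ v`` with (x, y) relative to the
    patch center.  A zero-mass patch yields a flagged zero centroid rather
    than an error.
    """
    if isinstance(patch, Patch):
        values = patch.values
        mask = patch.circular_mask
        r = patch.radius
    else:
        values = np.asarray(patch, dtype=np.float64)
        r = (values.shape[0] - 1) // 2
        from .image_core import circular_mask
        mask = circular_mask(r)
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    v = np.where(mask, values, 0.0)
    mass = v.sum()
    if mass <= 0:
        return Centroid(vec=(0.0, 0.0), norm=0.0, unit=(0.0, 0.0))
    return _make_centroid((x * v).sum() / mass, (y * v).sum() / mass, eps)


def centroid_field(guide, radius: int, eps: float = CENTROID_EPS):
    """Per-pixel circular-support centroids of every patch, vectorised.

    Returns ``(ux, uy, valid)`` image-shaped arrays: the unit centroid
    direction per pixel and a boolean flag (False where the centroid is
    degenerate).  Equivalent to :func:`patch_centroid` applied at every
    pixel of the mirror-padded guide.
    """
    from scipy import ndimage

    guide = as_image(guide)
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(np.float64)
    mask = (x * x + y * y <= radius * radius).astype(np.float64)
    mass = ndimage.correlate(guide, mask, mode="mirror")
    sx = ndimage.correlate(guide, x * mask, mode="mirror")
    sy = ndimage.correlate(guide, y * mask, mode="mirror")
    ok = mass > 0
    safe = np.where(ok, mass, 1.0)
    cx = sx / safe
    cy = sy / safe
    norm = np.hypot(cx, cy)
    valid = ok & (norm > eps)
    nsafe = np.where(valid, norm, 1.0)
    ux = np.where(valid, cx / nsafe, 0.0)
    uy = np.where(valid, cy / nsafe, 0.0)
    return ux, uy, valid


def _rot_matrix(u1: float, u2: float) -> np.ndarray:
    return np.array([[u1, -u2], [u2, u1]])


def rotation_frame(ci: Centroid, cj: Centroid, mirrored: bool,
                   eps: float = CENTROID_EPS) -> RotationFrame:
    """Rotation frame carrying target centroid direction ``ci`` onto ``cj``.

    ``R = R_ci^-1 · R_m(cj)`` on unit centroid directions (2-D rotations
    commute, so this is the rotation by the angle from ``ci`` to the
    mirror-compensated ``cj``).  Degenerate centroids give ``valid=False``.
    """
    if ci.norm <= eps or cj.norm <= eps:
        return RotationFrame(R=np.eye(2), mirrored=bool(mirrored), valid=False)
    u1, u2 = cj.unit
    if mirrored:
        u1 = -u1
    R = _rot_matrix(*ci.unit).T @ _rot_matrix(u1, u2)
    return RotationFrame(R=R, mirrored=bool(mirrored), valid=True)


def frame_angle_deg(frame: RotationFrame) -> float:
    """Signed rotation angle of a valid frame, in degrees in (-180, 180]."""
    if not frame.valid:
        raise ValueError("no angle for an invalid rotation frame")
    return float(np.degrees(np.arctan2(frame.R[1, 0], frame.R[0, 0])))


def map_point(frame: RotationFrame, qi) -> tuple[float, float]:
    """Map a target-patch point ``qi = (x, y)`` to the candidate patch.

    ``qj = m(R·qi)`` with the outer mirror flip of the x component applied
    when the frame is mirrored.  Norm-preserving.
    """
    if not frame.valid:
        raise ValueError("cannot map through an invalid rotation frame")
    q = frame.R @ np.asarray(qi, dtype=np.float64)
    if frame.mirrored:
        q = np.array([-q[0], q[1]])
    return (float(q[0]), float(q[1]))


def bilinear_sample(img, center: tuple[int, int], offset) -> float:
    """Bilinear interpolation at ``center + offset``.

    ``center`` is (row, col) integer; ``offset`` is (x, y) = (column, row)
    real displacement.  Exact at integer offsets.  The sampled 2×2
    neighbourhood must lie inside ``img`` (callers guarantee this by
    padding with margin ≥ ceil(r·√2)).
    """
    img = np.asarray(img, dtype=np.float64)
    row = center[0] + offset[1]
    col = center[1] + offset[0]
    if not (0 <= row <= img.shape[0] - 1 and 0 <= col <= img.shape[1] - 1):
        raise IndexError(f"sample point ({row}, {col}) outside image")
    r0 = int(np.floor(row))
    c0 = int(np.floor(col))
    # clamp the +1 neighbour at the exact far edge (its weight is zero there)
    r1 = min(r0 + 1, img.shape[0] - 1)
    c1 = min(c0 + 1, img.shape[1] - 1)
    wr = row - r0
    wc = col - c0
    return float(
        img[r0, c0] * (1 - wr) * (1 - wc)
        + img[r0, c1] * (1 - wr) * wc
        + img[r1, c0] * wr * (1 - wc)
        + img[r1, c1] * wr * wc
    )


def distance_dR(img, i: tuple[int, int], j: tuple[int, int],
                frame: RotationFrame, radius: int) -> float:
    """Rotation-invariant squared distance between the patches at ``i``, ``j``.

    ``dR = Σ_q (v_i(q) - In(v_j, m(R·q)))²`` over the circular support of
    radius ``radius``, where ``In`` is bilinear interpolation in ``img``
    around the candidate center ``j``.  ``img`` must already be padded so
    both supports (and their rotations) stay in bounds; ``i`` and ``j`` are
    coordinates in that padded image.  An invalid frame falls back to the
    plain unrotated squared-difference sum over the same support.
    """
    img = np.asarray(img, dtype=np.float64)
    dx, dy = support_offsets(radius)
    ti = img[i[0] + dy, i[1] + dx]
    if frame.valid:
        # exact identity frames reduce to the plain distance automatically:
        # mapped offsets stay integral and the interpolation is exact there
        R = frame.R
        pts = R @ np.vstack([dx, dy]).astype(np.float64)
        if frame.mirrored:
            pts = np.vstack([-pts[0], pts[1]])
        rows = j[0] + pts[1]
        cols = j[1] + pts[0]
        r0 = np.floor(rows).astype(np.int64)
        c0 = np.floor(cols).astype(np.int64)
        wr = rows - r0
        wc = cols - c0
        tj = (img[r0, c0] * (1 - wr) * (1 - wc)
              + img[r0, c0 + 1] * (1 - wr) * wc
              + img[r0 + 1, c0] * wr * (1 - wc)
              + img[r0 + 1, c0 + 1] * wr * wc)
    else:
        tj = img[j[0] + dy, j[1] + dx]
    diff = ti - tj
    return float(diff @ diff)
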