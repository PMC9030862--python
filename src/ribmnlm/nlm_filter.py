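"""Non-local-means reconstruction: conventional baseline and the
cluster-restricted, rotation-compensated filter.

Conventional NLM restores each pixel as a weighted average over *all* image
pixels, with weights ``exp(-||N_i - N_j||²_{2,α} / h²)`` driven by the
Gaussian-weighted squared patch distance.  It is quadratic in the pixel
count and serves here as the small-image reference baseline.

The cluster-restricted filter replaces the candidate set by the members of
the target pixel's cluster (from the Hu-feature pre-classification LUT) and
the patch distance by the rotation- and mirror-compensated distance ``dR``
(an *unweighted* sum over the circular support; the Gaussian α-weighting
belongs to the conventional baseline only).  The restored intensity is

    NLMp(v)(i) = Σ_{j ∈ cluster(i)} wR(i, j) · v(j),
    wR(i, j) = exp(-dR(i, j) / h²) / ZR(i),

reading ``v`` from the original noisy image; the blurred guide is used only
for feature extraction and clustering.  The self-candidate ``j = i`` keeps
``dR = 0`` (raw weight 1).

The per-pixel loop is compiled with numba; ``weights_ribm`` provides the
equivalent pure-Python path for a single pixel, used as a reference in
tests and for inspection.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from numba import njit

from . import ribm
from .cluster_preclassify import (
    ClusterParams,
    feature_standardize,
    kmeans_fit,
    scale_n_clusters,
)
from .image_core import as_image, pad_reflect, support_offsets
from .moment_features import hu_field
from .preprocess import gaussian_blur, gaussian_kernel

__all__ = [
    "NLMParams",
    "DenoiseConfig",
    "WeightSet",
    "nlm_conventional",
    "weights_ribm",
    "despeckle_ribm_nlm",
]


@dataclass(frozen=True)
class NLMParams:
    """Tunables of the conventional NLM baseline.

    ``h`` is the filtering bandwidth (default 12·σ_noise upstream); ``alpha``
    the width of the Gaussian patch weighting of the similarity term.
    """

    h: float
    radius: int = 7
    alpha: float | None = None  # None -> radius / 2

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    @property
    def resolved_alpha(self) -> float:
        return self.radius / 2.0 if self.alpha is None else self.alpha


@dataclass(frozen=True)
class DenoiseConfig:
    """All tunables of the cluster-restricted filter.

    Defaults derive from the assumed noise level ``sigma_noise`` (σ):
    bandwidth ``h = 12·σ``, guide-blur kernel ``kernel_sigma = 0.5·σ`` with
    radius ``kernel_radius = 4``, 15×15 patches (``patch_radius = 7``), and
    a cluster count scaled with pixel count from the reference
    K = 675 at 225×225.  ``resolve(shape)`` fills every derived field.
    """

    sigma_noise: float = 20.0
    patch_radius: int = 7
    n_clusters: int | None = None
    h: float | None = None
    kernel_sigma: float | None = None
    kernel_radius: int = 4
    seed: int = 0
    standardize_features: bool = True
    rotation_enabled: bool = True
    max_candidates: int | None = None
    restore_from_guide: bool = False
    kmeans_max_iter: int = 100
    kmeans_tol: float = 1e-6
    centroid_eps: float = ribm.CENTROID_EPS

    def resolve(self, shape) -> "DenoiseConfig":
        """Return a copy with every derived default filled in for ``shape``."""
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")
        h = 12.0 * self.sigma_noise if self.h is None else self.h
        ks = 0.5 * self.sigma_noise if self.kernel_sigma is None else self.kernel_sigma
        K = scale_n_clusters(*shape) if self.n_clusters is None else self.n_clusters
        K = min(K, shape[0] * shape[1])
        if h <= 0 or ks <= 0:
            raise ValueError("h and kernel_sigma must be positive")
        return DenoiseConfig(
            sigma_noise=self.sigma_noise, patch_radius=self.patch_radius,
            n_clusters=K, h=h, kernel_sigma=ks,
            kernel_radius=self.kernel_radius, seed=self.seed,
            standardize_features=self.standardize_features,
            rotation_enabled=self.rotation_enabled,
            max_candidates=self.max_candidates,
            restore_from_guide=self.restore_from_guide,
            kmeans_max_iter=self.kmeans_max_iter,
            kmeans_tol=self.kmeans_tol, centroid_eps=self.centroid_eps,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass(frozen=True)
class WeightSet:
    """Normalised candidate weights for one target pixel."""

    candidates: np.ndarray  # (m, 2) candidate centers (row, col)
    raw: np.ndarray
    normalizer: float
    normalized: np.ndarray


# ---------------------------------------------------------------------------
# conventional NLM baseline (Gaussian-weighted patch distance, all candidates)
# ---------------------------------------------------------------------------

def nlm_conventional(img, params: NLMParams) -> np.ndarray:
    """Conventional NLM with every pixel as candidate.

    Quadratic in the pixel count — intended for small images and as the
    reference baseline.  The similarity term is the Gaussian-weighted
    (width α, weights normalised to total 1) squared patch difference over
    the square patch.
    """
    img = as_image(img)
    h, w = img.shape
    n = h * w
    if n > 20000:
        raise ValueError("nlm_conventional is quadratic; image too large")
    r = params.radius
    pad = pad_reflect(img, r)
    win = np.lib.stride_tricks.sliding_window_view(pad, (2 * r + 1, 2 * r + 1))
    A = win.reshape(n, -1)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    a = params.resolved_alpha
    G = np.exp(-(dx * dx + dy * dy) / (2.0 * a * a)).ravel()
    G /= G.sum()
    B = A * np.sqrt(G)
    sq = np.einsum("ij,ij->i", B, B)
    D = sq[:, None] + sq[None, :] - 2.0 * (B @ B.T)
    np.maximum(D, 0.0, out=D)
    W = np.exp(-D / (params.h**2))
    W /= W.sum(axis=1, keepdims=True)
    return (W @ img.ravel()).reshape(h, w)


# ---------------------------------------------------------------------------
# cluster-restricted rotation-compensated filter
# ---------------------------------------------------------------------------

def weights_ribm(img, center, candidates, config: DenoiseConfig, store):
    """Weight set of one target pixel over its cluster's candidates.

    Pure-Python reference path built from the :mod:`ribmnlm.ribm`
    primitives; the full-image filter uses the compiled kernel, which is
    tested for equivalence against this function.

    ``store`` is the feature store returned by :func:`compute_feature_store`
    on the blurred guide.  ``img`` is the (unpadded) image distances and
    restored intensities are read from.
    """
    img = as_image(img)
    candidates = np.asarray(candidates)
    if candidates.size == 0:
        raise ValueError("empty candidate list (cluster repair guarantees members)")
    cfg = config.resolve(img.shape)
    r = cfg.patch_radius
    margin = math.ceil(r * math.sqrt(2.0)) + 1
    padded = pad_reflect(img, margin)
    h2 = cfg.h**2
    ci = _store_centroid(store, center)
    phi7_i = store.phi7[center]
    raw = np.empty(len(candidates))
    for k, (jr, jc) in enumerate(candidates):
        j = (int(jr), int(jc))
        if j == tuple(center):
            raw[k] = 1.0
            continue
        if cfg.rotation_enabled:
            mirrored = bool(phi7_i * store.phi7[j] < 0.0)
            frame = ribm.rotation_frame(ci, _store_centroid(store, j),
                                        mirrored, eps=cfg.centroid_eps)
        else:
            frame = ribm.RotationFrame(R=np.eye(2), mirrored=False, valid=False)
        d = ribm.distance_dR(
            padded,
            (center[0] + margin, center[1] + margin),
            (j[0] + margin, j[1] + margin),
            frame, r,
        )
        raw[k] = math.exp(-d / h2)
    Z = float(raw.sum())
    return WeightSet(candidates=candidates, raw=raw, normalizer=Z,
                     normalized=raw / Z)


@dataclass(frozen=True)
class FeatureStore:
    """Per-pixel guide-image features: Hu φ7, centroid directions, validity."""

    phi7: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    cvalid: np.ndarray
    hu: np.ndarray


def compute_feature_store(guide, radius: int,
                          eps: float = ribm.CENTROID_EPS) -> FeatureStore:
    """Hu vectors and circular-support centroid directions for every patch."""
    hu = hu_field(guide, radius)
    ux, uy, valid = ribm.centroid_field(guide, radius, eps=eps)
    return FeatureStore(phi7=hu[..., 6], ux=ux, uy=uy, cvalid=valid, hu=hu)


def _store_centroid(store: FeatureStore, coord) -> ribm.Centroid:
    c = (int(coord[0]), int(coord[1]))
    if not store.cvalid[c]:
        return ribm.Centroid(vec=(0.0, 0.0), norm=0.0, unit=(0.0, 0.0))
    return ribm.Centroid(vec=(store.ux[c], store.uy[c]), norm=1.0,
                         unit=(store.ux[c], store.uy[c]))


@njit(cache=False, fastmath=True)
def _despeckle_kernel(dist_pad, val_pad, pad, W, labels, member_idx,
                      cluster_start, ux, uy, cvalid, phi7, h2,
                      sup_x, sup_y, rotate):  # pragma: no cover - compiled
    n = labels.size
    S = sup_x.size
    out = np.empty(n)
    tvals = np.empty(S)
    for p in range(n):
        r0 = p // W + pad
        c0 = p % W + pad
        for s in range(S):
            tvals[s] = dist_pad[r0 + sup_y[s], c0 + sup_x[s]]
        k = labels[p]
        num = 0.0
        den = 0.0
        for idx in range(cluster_start[k], cluster_start[k + 1]):
            q = member_idx[idx]
            r1 = q // W + pad
            c1 = q % W + pad
            if q == p:
                d = 0.0
            elif rotate and cvalid[p] and cvalid[q]:
                mirrored = phi7[p] * phi7[q] < 0.0
                a = ux[p]
                b = uy[p]
                u1 = ux[q]
                u2 = uy[q]
                if mirrored:
                    u1 = -u1
                # R = R_ci^T @ R_m(cj)
                r11 = a * u1 + b * u2
                r12 = -a * u2 + b * u1
                r21 = -b * u1 + a * u2
                r22 = b * u2 + a * u1
                d = 0.0
                for s in range(S):
                    x = float(sup_x[s])
                    y = float(sup_y[s])
                    mx = r11 * x + r12 * y
                    my = r21 * x + r22 * y
                    if mirrored:
                        mx = -mx
                    rr = r1 + my
                    cc = c1 + mx
                    fr = int(np.floor(rr))
                    fc = int(np.floor(cc))
                    wr = rr - fr
                    wc = cc - fc
                    val = (dist_pad[fr, fc] * (1.0 - wr) * (1.0 - wc)
                           + dist_pad[fr, fc + 1] * (1.0 - wr) * wc
                           + dist_pad[fr + 1, fc] * wr * (1.0 - wc)
                           + dist_pad[fr + 1, fc + 1] * wr * wc)
                    diff = tvals[s] - val
                    d += diff * diff
            else:
                d = 0.0
                for s in range(S):
                    diff = tvals[s] - dist_pad[r1 + sup_y[s], c1 + sup_x[s]]
                    d += diff * diff
            wgt = np.exp(-d / h2)
            num += wgt * val_pad[r1, c1]
            den += wgt
        out[p] = num / den
    return out


def despeckle_ribm_nlm(img, config: DenoiseConfig | None = None,
                       return_details: bool = False):
    """Full de-speckling pipeline on one image.

    Stages: Gaussian guide blur → per-patch Hu features and centroids on the
    guide → (standardised) k-means pre-classification into the LUT → per
    pixel, rotation/mirror-compensated distances to its cluster's members →
    weighted average of the *noisy* intensities.  Deterministic given
    ``config.seed``.

    Returns the filtered image; with ``return_details=True`` also a dict
    holding the resolved config, cluster table and feature store.
    """
    img = as_image(img)
    cfg = (config or DenoiseConfig()).resolve(img.shape)
    H, Wd = img.shape
    r = cfg.patch_radius

    try:
        kern = gaussian_kernel(cfg.kernel_sigma, cfg.kernel_radius)
        guide = gaussian_blur(img, kern)
    except ValueError as exc:
        raise ValueError(f"preprocess stage: {exc}") from exc

    store = compute_feature_store(guide, r, eps=cfg.centroid_eps)
    feats = store.hu.reshape(-1, 7)
    if cfg.standardize_features and feats.shape[0] >= 2:
        feats, _ = feature_standardize(feats)

    try:
        table = kmeans_fit(
            feats,
            ClusterParams(n_clusters=cfg.n_clusters, max_iter=cfg.kmeans_max_iter,
                          tol=cfg.kmeans_tol, seed=cfg.seed),
            shape=img.shape,
        )
    except ValueError as exc:
        raise ValueError(f"cluster stage: {exc}") from exc

    labels = table.labels.ravel().astype(np.int64)
    member_idx, cluster_start = _member_arrays(labels, cfg)

    margin = math.ceil(r * math.sqrt(2.0)) + 1
    dist_pad = pad_reflect(img, margin)
    val_pad = pad_reflect(guide, margin) if cfg.restore_from_guide else dist_pad
    sup_x, sup_y = support_offsets(r)

    out = _despeckle_kernel(
        dist_pad, val_pad, margin, Wd, labels, member_idx, cluster_start,
        store.ux.ravel(), store.uy.ravel(), store.cvalid.ravel(),
        store.phi7.ravel(), cfg.h**2, sup_x, sup_y, cfg.rotation_enabled,
    ).reshape(H, Wd)

    if return_details:
        return out, {"config": cfg, "cluster_table": table, "store": store}
    return out


def _member_arrays(labels: np.ndarray, cfg: DenoiseConfig):
    """Flat member index array sorted by cluster + cluster start offsets.

    Applies the optional deterministic ``max_candidates`` subsampling per
    cluster (seeded by ``cfg.seed``).
    """
    K = cfg.n_clusters
    order = np.argsort(labels, kind="stable")
    starts = np.searchsorted(labels[order], np.arange(K + 1))
    if cfg.max_candidates is None:
        return order.astype(np.int64), starts.astype(np.int64)
    rng = np.random.default_rng(cfg.seed)
    kept = []
    new_starts = [0]
    for k in range(K):
        mem = order[starts[k]:starts[k + 1]]
        if mem.size > cfg.max_candidates:
            sel = rng.choice(mem.size, size=cfg.max_candidates, replace=False)
            mem = mem[np.sort(sel)]
        kept.append(mem)
        new_starts.append(new_starts[-1] + mem.size)
    return (np.concatenate(kept).astype(np.int64),
            np.asarray(new_starts, dtype=np.int64))
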