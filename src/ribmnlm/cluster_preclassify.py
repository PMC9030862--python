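"""K-means pre-classification of patches on their Hu feature vectors.

Every pixel owns one patch and hence one 7-component Hu vector; Lloyd's
algorithm with k-means++ seeding partitions the vectors into K clusters,
and the resulting look-up table (LUT) lists, per cluster, the patch-center
coordinates of its members.  The filter later restricts each pixel's
candidate search to its own cluster's members.

The Lloyd loop is written out explicitly (rather than delegated to
``sklearn.KMeans``) because the contract requires a per-iteration objective
trace — the within-cluster sum of squares must be non-increasing on every
fit — plus deterministic lowest-index tie-breaking and in-loop empty-cluster
repair.  Initial centers come from :func:`sklearn.cluster.kmeans_plusplus`,
and the assignment step uses :func:`sklearn.metrics.pairwise_distances_argmin_min`
(memory-bounded, ties resolved to the lowest index).

Hu components span wildly different magnitudes (φ1 is typically orders of
magnitude larger than φ5…φ7), so features are standardised to zero mean and
unit variance per component before clustering by default; without this the
Euclidean objective is dominated by φ1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import pairwise_distances_argmin_min

__all__ = [
    "ClusterParams",
    "ClusterTable",
    "StandardizeTransform",
    "feature_standardize",
    "kmeans_fit",
    "build_lut",
    "scale_n_clusters",
    "dump_lut",
]

#: reference pairing of the default cluster count with the image size it was
#: tuned for: K = 675 at 225×225 pixels; other sizes scale K with pixel count.
K_REFERENCE = 675
PIXELS_REFERENCE = 225 * 225


def scale_n_clusters(height: int, width: int) -> int:
    """Cluster count scaled proportionally to pixel count (minimum 1)."""
    return max(1, round(K_REFERENCE * (height * width) / PIXELS_REFERENCE))


@dataclass(frozen=True)
class ClusterParams:
    n_clusters: int
    max_iter: int = 100
    tol: float = 1e-6  # relative change of the objective that stops iteration
    seed: int = 0


@dataclass(frozen=True)
class StandardizeTransform:
    """Recorded per-component affine transform (x - mean) / scale."""

    mean: np.ndarray
    scale: np.ndarray

    def apply(self, features) -> np.ndarray:
        return (np.asarray(features, dtype=np.float64) - self.mean) / self.scale


def feature_standardize(features):
    """Zero-mean, unit-variance transform per feature component.

    Components with zero variance map to zeros.  Returns
    ``(standardized, transform)`` with the transform recorded for
    reproducibility.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two feature vectors")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    scale = np.where(std > 0, std, 1.0)
    tf = StandardizeTransform(mean=mean, scale=scale)
    return tf.apply(X), tf


@dataclass(frozen=True)
class ClusterTable:
    """Result of one k-means fit over image patches.

    ``labels`` is image-shaped; ``members[k]`` lists the patch-center
    (row, col) coordinates of cluster ``k`` in row-major order (the LUT);
    ``centers_feat`` holds the K mean feature vectors; ``objective_trace``
    records the within-cluster sum of squares after every assignment step.
    """

    labels: np.ndarray
    members: list
    centers_feat: np.ndarray
    objective_trace: np.ndarray = field(repr=False)
    n_iter: int = 0


def _assign(X, centers):
    labels, dists = pairwise_distances_argmin_min(X, centers)
    return labels.astype(np.int64), float(np.sum(dists**2))


def _repair_empty(X, centers, labels, trace):
    """Move the feature farthest from its center into each empty cluster.

    The relocated point becomes a singleton with zero contribution, so the
    objective stays non-increasing; relocating directly (rather than
    reseeding + reassigning) also terminates when features are exact
    duplicates and assignment ties would keep reseeded clusters empty.
    """
    K = centers.shape[0]
    counts = np.bincount(labels, minlength=K)
    empties = np.flatnonzero(counts == 0)
    if empties.size == 0:
        return labels
    labels = labels.copy()
    d2 = np.sum((X - centers[labels]) ** 2, axis=1)
    for k in empties:
        far = int(np.argmax(d2))
        centers[k] = X[far]
        labels[far] = k
        d2[far] = -1.0  # do not reuse the same point
    obj = float(np.sum((X - centers[labels]) ** 2))
    trace.append(obj)
    return labels


def kmeans_fit(features, params: ClusterParams, shape=None) -> ClusterTable:
    """Lloyd's algorithm over patch feature vectors.

    ``features`` is ``(n, 7)`` (or any ``(n, d)``); ``shape`` is the image
    shape used to lay labels and LUT coordinates out — defaults to ``(n, 1)``.
    Fully deterministic given ``params.seed``.  Empty clusters are repaired
    by reseeding their center at the feature farthest from its assigned
    center, so no member list is empty on return.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a non-empty 2-D array")
    if not np.all(np.isfinite(X)):
        bad = int(np.flatnonzero(~np.isfinite(X).all(axis=1))[0])
        coord = (tuple(int(i) for i in np.unravel_index(bad, shape))
                 if shape else (bad,))
        raise ValueError(f"non-finite feature vector for patch center {coord}")
    n = X.shape[0]
    K = params.n_clusters
    if not 1 <= K <= n:
        raise ValueError(f"n_clusters={K} must be in [1, {n}]")
    if shape is None:
        shape = (n, 1)
    if shape[0] * shape[1] != n:
        raise ValueError("shape does not match the number of features")

    if K == 1:
        centers = X.mean(axis=0, keepdims=True)
        labels = np.zeros(n, dtype=np.int64)
        obj = float(np.sum((X - centers[0]) ** 2))
        trace = np.array([obj])
    else:
        centers, _ = kmeans_plusplus(
            X, n_clusters=K, random_state=params.seed % (2**32)
        )
        trace = []
        labels = None
        prev_labels = None
        prev_obj = np.inf
        for _ in range(params.max_iter):
            labels, obj = _assign(X, centers)
            trace.append(obj)
            labels = _repair_empty(X, centers, labels, trace)
            obj = trace[-1]
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                break
            if np.isfinite(prev_obj) and \
                    prev_obj - obj <= params.tol * max(abs(prev_obj), 1.0):
                break
            prev_labels = labels
            prev_obj = obj
            # update step: cluster means (no cluster is empty here)
            sums = np.zeros_like(centers)
            np.add.at(sums, labels, X)
            centers = sums / np.bincount(labels, minlength=K)[:, None]
        # report the mean feature vector of each final cluster
        sums = np.zeros_like(centers)
        np.add.at(sums, labels, X)
        centers = sums / np.bincount(labels, minlength=K)[:, None]
        trace = np.asarray(trace)

    label_grid = labels.reshape(shape)
    members = build_lut(label_grid, n_clusters=K)
    return ClusterTable(
        labels=label_grid,
        members=members,
        centers_feat=centers,
        objective_trace=trace,
        n_iter=len(trace),
    )


def build_lut(label_grid, n_clusters: int | None = None) -> list:
    """Per-cluster lists of member patch-center coordinates, row-major.

    ``members[k]`` is an ``(mk, 2)`` int array of (row, col) coordinates.
    Together the lists form a partition of all pixel coordinates.
    """
    label_grid = np.asarray(label_grid)
    flat = label_grid.ravel()
    if n_clusters is None:
        n_clusters = int(flat.max()) + 1 if flat.size else 0
    h, w = label_grid.shape
    order = np.argsort(flat, kind="stable")  # stable => row-major within cluster
    starts = np.searchsorted(flat[order], np.arange(n_clusters + 1))
    coords = np.column_stack(np.divmod(order, w))
    return [coords[starts[k]:starts[k + 1]] for k in range(n_clusters)]


def dump_lut(table: ClusterTable, path) -> None:
    """Write the LUT as plain text: ``cluster_id<TAB>row<TAB>col`` per patch."""
    with open(path, "w") as fh:
        for k, mem in enumerate(table.members):
            for r, c in mem:
                fh.write(f"{k}\t{r}\t{c}\n")
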