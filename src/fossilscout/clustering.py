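"""From-scratch k-means (Lloyd's algorithm) over scene pixels in spectral space.

The objective is the within-cluster sum of squares,

    WCSS = sum_j sum_{i in cluster j} ||x_i - mu_j||^2,

minimized by alternating nearest-centroid assignment and centroid-mean updates.
Iteration stops when the relative WCSS change falls below ``epsilon`` or
``max_iter`` is reached; multiple seeded restarts mitigate the dependence of
the result on the random initial centroids, and the restart with the lowest
final WCSS is kept.

Cluster labels are 1-based (1..k) throughout, matching the convention of
thematic land-cover maps where 0 is reserved for nodata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_io import SpectralScene


class ClusteringError(Exception):
    pass


@dataclass(frozen=True)
class KMeansConfig:
    """Settings for a k-means fit.

    ``epsilon`` is the relative WCSS-change convergence threshold
    |WCSS - WCSS'| / WCSS <= epsilon; scale-free so raw digital numbers and
    0-1 reflectance behave alike. ``init`` is D^2-weighted seeding
    ("kmeans++", default) or plain Forgy random-point selection
    ("random_points"). With many spectrally distinct land covers of very
    unequal abundance, uniform random seeding rarely places a centroid in
    every class and Lloyd iteration can stall in merge/split local optima,
    so the weighted seeding is the default.
    """

    k: int = 8
    epsilon: float = 1e-6
    max_iter: int = 100
    n_restarts: int = 10
    seed: int = 0
    init: str = "kmeans++"
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ClusteringError("k must be >= 1")
        if self.epsilon < 0:
            raise ClusteringError("epsilon must be >= 0")
        if self.n_restarts < 1:
            raise ClusteringError("n_restarts must be >= 1")
        if self.init not in ("random_points", "kmeans++"):
            raise ClusteringError(f"unknown init {self.init!r}")


@dataclass(frozen=True)
class ClusterModel:
    """Result of a k-means fit aligned with a scene grid.

    ``labels`` holds 1..k on unmasked pixels and 0 where nodata; ``centroids``
    is (k, B) in the scene's band units (even when fitted standardized).
    ``wcss`` and ``wcss_trace`` are in the fitting space, i.e. standardized
    units when ``standardized`` is True, raw band units otherwise.
    """

    centroids: np.ndarray
    labels: np.ndarray
    k: int
    wcss: float
    wcss_trace: tuple[float, ...]
    n_iter: int
    converged: bool
    seed_used: int
    bands: tuple[str, ...] = ()
    standardized: bool = False

    def member_mask(self, cluster_id: int) -> np.ndarray:
        return self.labels == cluster_id

    def cluster_sizes(self) -> dict[int, int]:
        return {
            j: int(np.count_nonzero(self.labels == j)) for j in range(1, self.k + 1)
        }


def wcss(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Within-cluster sum of squares of `points` under 1-based `labels`."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    k = centroids.shape[0]
    if labels.min(initial=1) < 1 or labels.max(initial=1) > k:
        raise ClusteringError(f"labels must lie in 1..{k}")
    diff = points - centroids[labels - 1]
    return float(np.einsum("ij,ij->", diff, diff))


def assign_labels(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid (squared Euclidean) labels, 1-based; ties -> lowest index."""
    points = np.asarray(points, dtype=float)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    # ||x - mu||^2 expanded; the constant ||x||^2 does not affect the argmin
    d2 = (
        np.sum(centroids**2, axis=1)[np.newaxis, :]
        - 2.0 * points @ centroids.T
    )
    return np.argmin(d2, axis=1).astype(np.int64) + 1


def update_centroids(
    points: np.ndarray, labels: np.ndarray, k: int
) -> tuple[np.ndarray, list[int]]:
    """Mean of each cluster's members; returns (centroids, empty_cluster_ids).

    Empty clusters keep NaN rows here; :func:`fit_kmeans` re-seeds them.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > k:
        raise ClusteringError(f"labels must lie in 1..{k}")
    b = points.shape[1]
    sums = np.zeros((k, b))
    np.add.at(sums, labels - 1, points)
    counts = np.bincount(labels - 1, minlength=k).astype(float)
    empty = [int(j + 1) for j in np.flatnonzero(counts == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        centroids = sums / counts[:, np.newaxis]
    return centroids, empty


def _init_centroids(
    points: np.ndarray, k: int, rng: np.random.Generator, method: str
) -> np.ndarray:
    n = points.shape[0]
    if method == "random_points":
        idx = rng.choice(n, size=k, replace=False)
        return points[idx].copy()
    # kmeans++: D^2-weighted seeding
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    d2 = np.sum((points - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j:] = points[rng.choice(n, size=k - j)]
            break
        centroids[j] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((points - centroids[j]) ** 2, axis=1))
    return centroids


def _lloyd(
    points: np.ndarray, config: KMeansConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    centroids = _init_centroids(points, config.k, rng, config.init)
    trace: list[float] = []
    converged = False
    labels = assign_labels(points, centroids)
    for _ in range(config.max_iter):
        new_centroids, empty = update_centroids(points, labels, config.k)
        if empty:
            # re-seed each empty cluster with the point currently farthest
            # from its assigned centroid (deterministic given the fit state)
            filled = new_centroids.copy()
            resid = points - np.where(
                np.isnan(new_centroids), 0.0, new_centroids
            )[labels - 1]
            d2 = np.einsum("ij,ij->i", resid, resid)
            for j in empty:
                far = int(np.argmax(d2))
                filled[j - 1] = points[far]
                d2[far] = -1.0  # a point may seed at most one empty cluster
            new_centroids = filled
        centroids = new_centroids
        labels = assign_labels(points, centroids)
        cur = wcss(points, labels, centroids)
        trace.append(cur)
        if len(trace) >= 2:
            prev = trace[-2]
            denom = prev if prev > 0 else 1.0
            if abs(prev - cur) / denom <= config.epsilon:
                converged = True
                break
    return centroids, labels, trace, converged


def fit_kmeans_points(
    points: np.ndarray, config: KMeansConfig
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool, int]:
    """Run restarted Lloyd iterations on an (n, B) table; keep lowest WCSS."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < config.k:
        raise ClusteringError(f"need >= k={config.k} points, got {n}")
    ss = np.random.SeedSequence([config.seed, 0x6B6D])
    best = None
    for restart, child in enumerate(ss.spawn(config.n_restarts)):
        rng = np.random.default_rng(child)
        centroids, labels, trace, converged = _lloyd(points, config, rng)
        final = trace[-1]
        if best is None or final < best[2][-1]:
            best = (centroids, labels, trace, converged, restart)
    centroids, labels, trace, converged, restart = best
    return centroids, labels, trace, len(trace), converged, restart


def fit_kmeans(scene: SpectralScene, config: KMeansConfig) -> ClusterModel:
    """Cluster a scene's unmasked pixels in B-dimensional spectral space."""
    table, flat_idx = scene.pixel_table()
    if table.shape[0] < config.k:
        raise ClusteringError(
            f"scene has {table.shape[0]} unmasked pixels, fewer than k={config.k}"
        )
    work = table
    shift = np.zeros(table.shape[1])
    scale = np.ones(table.shape[1])
    if config.standardize:
        shift = table.mean(axis=0)
        scale = table.std(axis=0)
        scale[scale == 0] = 1.0
        work = (table - shift) / scale
    centroids, labels, trace, n_iter, converged, _ = fit_kmeans_points(work, config)
    label_grid = np.zeros((scene.n_rows, scene.n_cols), dtype=np.int64)
    label_grid.ravel()[flat_idx] = labels
    return ClusterModel(
        centroids=centroids * scale + shift,
        labels=label_grid,
        k=config.k,
        wcss=float(trace[-1]),
        wcss_trace=tuple(trace),
        n_iter=n_iter,
        converged=converged,
        seed_used=config.seed,
        bands=scene.bands,
        standardized=config.standardize,
    )
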