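"""Pre-segmentation: DBSCAN clustering, RANSAC linearity check, noise rule.

The pre-segmentation stage clusters the ground-free scene with DBSCAN,
classifies each cluster as *linear* (pole-like: signs, lamp posts, occluded
trunk stubs) or *nonlinear* (crown-bearing) with a 3D RANSAC line fit at a
0.4 m point-to-line distance threshold, and then drops clusters whose point
count falls below one third of the average count of the nonlinear clusters.
Computing the average over nonlinear clusters only keeps small trunk
fragments — which a naive size filter would discard and thereby turn an
over-segmented tree into a truncated one — in play for the later
footprint-overlay merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .core_io import Cluster, PointCloud

__all__ = [
    "DbscanParams",
    "LineModel",
    "dbscan_cluster",
    "fit_line_ransac",
    "classify_linearity",
    "filter_noise_clusters",
]

#: exhaustive pair search below this size keeps small-cluster fits deterministic
_EXHAUSTIVE_LIMIT = 50


@dataclass(frozen=True)
class DbscanParams:
    """Density-clustering neighborhood parameters.

    eps : neighborhood radius in meters (default 0.6, on the order of MLS
    point spacing within crowns); min_pts : core-point threshold.
    """

    eps: float = 0.6
    min_pts: int = 10

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass(frozen=True)
class LineModel:
    """A 3D line and the fraction of cluster points within the threshold."""

    point: np.ndarray
    direction: np.ndarray
    inlier_ratio: float

    def distances(self, pts: np.ndarray) -> np.ndarray:
        """Perpendicular distance from each point to the line."""
        d = pts - self.point
        proj = d @ self.direction
        return np.linalg.norm(d - np.outer(proj, self.direction), axis=1)


def dbscan_cluster(cloud: PointCloud, params: DbscanParams = DbscanParams()
                   ) -> tuple[list[Cluster], np.ndarray]:
    """Cluster a cloud by density reachability.

    Returns the clusters (disjoint, each with >= min_pts members) and the
    noise index set; together they cover every point.
    """
    if len(cloud) == 0:
        raise ValueError("cannot cluster an empty cloud")
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(
        cloud.coords
    )
    clusters = [
        Cluster(cloud, np.flatnonzero(labels == k))
        for k in range(labels.max() + 1)
    ]
    noise = np.flatnonzero(labels == -1)
    return clusters, noise


def _line_inliers(pts: np.ndarray, p0: np.ndarray, direction: np.ndarray,
                  threshold: float) -> int:
    d = pts - p0
    proj = d @ direction
    dist = np.linalg.norm(d - np.outer(proj, direction), axis=1)
    return int(np.count_nonzero(dist <= threshold))


def fit_line_ransac(cluster: Cluster, dist_threshold: float = 0.4,
                    n_iter: int = 200, seed: int = 0) -> LineModel:
    """Best two-point line through a cluster by RANSAC inlier count.

    Points within ``dist_threshold`` meters (perpendicular) of the candidate
    line are inliers.  Clusters of at most 50 points are searched
    exhaustively over all point pairs, which makes small fits deterministic
    regardless of the seed; larger clusters sample ``n_iter`` random pairs
    from ``numpy.random.default_rng(seed)``.
    """
    pts = cluster.points
    n = len(pts)
    if n < 2:
        raise ValueError("RANSAC line fit needs at least 2 points")

    best = (-1, None, None)  # inliers, p0, direction
    if n <= _EXHAUSTIVE_LIMIT:
        pairs = ((i, j) for i in range(n) for j in range(i + 1, n))
    else:
        rng = np.random.default_rng(seed)
        pairs = (tuple(rng.choice(n, size=2, replace=False)) for _ in range(n_iter))
    for i, j in pairs:
        v = pts[j] - pts[i]
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        direction = v / norm
        count = _line_inliers(pts, pts[i], direction, dist_threshold)
        if count > best[0]:
            best = (count, pts[i], direction)
    if best[1] is None:
        # all points coincident: any direction fits everything
        return LineModel(point=pts[0].copy(),
                         direction=np.array([0.0, 0.0, 1.0]),
                         inlier_ratio=1.0)
    count, p0, direction = best
    return LineModel(point=p0.copy(), direction=direction,
                     inlier_ratio=count / n)


def classify_linearity(cluster: Cluster, linear_ratio_cutoff: float = 0.9,
                       dist_threshold: float = 0.4, n_iter: int = 200,
                       seed: int = 0) -> str:
    """Tag a cluster ``linear`` or ``nonlinear`` by its RANSAC inlier ratio.

    A single point is trivially linear.  The verdict is stored on
    ``cluster.kind`` and returned.
    """
    if len(cluster) == 0:
        raise ValueError("cannot classify an empty cluster")
    if len(cluster) == 1:
        cluster.kind = "linear"
        return cluster.kind
    model = fit_line_ransac(cluster, dist_threshold=dist_threshold,
                            n_iter=n_iter, seed=seed)
    cluster.kind = "linear" if model.inlier_ratio >= linear_ratio_cutoff else "nonlinear"
    return cluster.kind


def filter_noise_clusters(clusters: list[Cluster]
                          ) -> tuple[list[Cluster], list[Cluster]]:
    """Drop small nonlinear clusters by the one-third-of-average rule.

    The mean ``m`` is taken over *nonlinear* clusters only, and a nonlinear
    cluster with count strictly below ``m / 3`` is dropped as noise.  Ties
    at exactly ``m / 3`` are retained.  Linear clusters are exempt: the
    linearity check exists to keep occluded trunk stubs — which are small
    and line-like — alive for the footprint-overlay merge; pole-like
    interference among them is removed downstream instead.  With no
    nonlinear cluster present the rule has no reference scale, so
    everything is retained.
    """
    for c in clusters:
        if c.kind == "unclassified":
            raise ValueError("classify clusters before noise filtering")
    nonlinear_sizes = [len(c) for c in clusters if c.kind == "nonlinear"]
    if not nonlinear_sizes:
        import warnings

        warnings.warn("no nonlinear clusters; noise rule skipped", stacklevel=2)
        return list(clusters), []
    threshold = float(np.mean(nonlinear_sizes)) / 3.0
    retained = [c for c in clusters
                if c.kind == "linear" or len(c) >= threshold]
    dropped = [c for c in clusters
               if c.kind != "linear" and len(c) < threshold]
    return retained, dropped
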