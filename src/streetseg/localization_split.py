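"""Tree localization by breast-height circle fitting and density-valley splits.

A trunk cross-section at breast height (1.3 m above the root collar; the
slab [1.25, 1.35] m is used) is an annulus in XY.  Fitting a circle to it by
linear least squares — minimizing sum((x² + y² + A·x + B·y + C)²) and
recovering the center (a, b) = (−A/2, −B/2) and radius r = sqrt(a² + b² − C)
— yields both the tree's planimetric position and its DBH.  A cluster whose
slab yields two or more plausible circle fits holds two or more trees
(under-segmentation); its XY coordinates are rotated so the trunk-connection
line lies along one axis, point counts are binned into voxels along that
axis, and the cluster is cut at the minimum-density voxel between each
adjacent pair of trunks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import Cluster

__all__ = [
    "CircleFit",
    "SplitPlan",
    "CircleFitError",
    "slice_breast_height",
    "fit_circle_lsq",
    "locate_trees",
    "detect_undersegmentation",
    "align_to_trunk_axis",
    "find_boundary_voxel",
    "split_cluster",
]

BREAST_HEIGHT_LO = 1.25
BREAST_HEIGHT_HI = 1.35


class CircleFitError(ValueError):
    """Degenerate or failed least-squares circle fit."""


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: center (a, b), radius r, RMS radial residual."""

    a: float
    b: float
    r: float
    rms_residual: float
    n_points: int

    @property
    def center(self) -> np.ndarray:
        return np.array([self.a, self.b])

    @property
    def dbh(self) -> float:
        return 2.0 * self.r


@dataclass
class SplitPlan:
    """Boundaries along the trunk-connection axis of an under-segmented cluster.

    ``axis_direction`` is the unit XY vector of the rotated +u axis;
    ``origin`` the XY point mapped to u=0.  ``boundaries`` holds one u
    coordinate per adjacent trunk pair; ``density_profile`` the per-voxel
    counts used to find them (for CSV dumps / debugging).
    """

    axis_direction: np.ndarray
    origin: np.ndarray
    voxel_width: float
    trunk_u: np.ndarray
    boundaries: list[float]
    density_profile: list[tuple[float, int]] = field(default_factory=list)

    def dump_csv(self, path) -> None:
        """Write the per-voxel profile (u_bin, count, boundary flag)."""
        import csv

        half = self.voxel_width / 2
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["u_bin_center", "count", "is_boundary"])
            for u, n in self.density_profile:
                hit = any(abs(b - u) <= half for b in self.boundaries)
                w.writerow([f"{u:.3f}", n, int(hit)])


def slice_breast_height(cluster: Cluster, lo: float = BREAST_HEIGHT_LO,
                        hi: float = BREAST_HEIGHT_HI) -> np.ndarray:
    """XY of points whose height above the cluster root falls in [lo, hi].

    The root is taken as the cluster's minimum z (ground is assumed already
    stripped, so the lowest stem point approximates the root collar).  An
    empty result is valid — e.g. a crown-only fragment.
    """
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    z = cluster.z
    z_root = z.min()
    mask = (z - z_root >= lo) & (z - z_root <= hi)
    return cluster.xy[mask]


def fit_circle_lsq(points2d: np.ndarray) -> CircleFit:
    """Algebraic least-squares (Kåsa) circle fit.

    Solves the normal equations of
    ``sum_i (x_i² + y_i² + A x_i + B y_i + C)²`` for (A, B, C) and maps back
    to center (−A/2, −B/2) and radius sqrt(a² + b² − C).  Exact on noiseless
    circle samples.  Raises :class:`CircleFitError` on collinear input or a
    non-positive squared radius.
    """
    pts = np.asarray(points2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise CircleFitError("need >= 3 2D points")
    x, y = pts[:, 0], pts[:, 1]
    # collinearity check via rank of centered coordinates
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(pts).max())) < 2:
        raise CircleFitError("points are collinear; circle is undetermined")
    M = np.column_stack([x, y, np.ones_like(x)])
    rhs = -(x**2 + y**2)
    (A, B, C), *_ = np.linalg.lstsq(M, rhs, rcond=None)
    a, b = -A / 2.0, -B / 2.0
    r2 = a * a + b * b - C
    if r2 <= 0:
        raise CircleFitError(f"fit produced non-positive r² = {r2:.3g}")
    r = float(np.sqrt(r2))
    residual = np.sqrt(np.mean((np.hypot(x - a, y - b) - r) ** 2))
    return CircleFit(a=float(a), b=float(b), r=r,
                     rms_residual=float(residual), n_points=len(pts))


def _subcluster_slab(xy: np.ndarray, gap: float) -> list[np.ndarray]:
    """Split slab XY points into connected components at single-linkage gap."""
    if len(xy) == 1:
        return [np.array([0])]
    Z = linkage(xy, method="single")
    labels = fcluster(Z, t=gap, criterion="distance")
    return [np.flatnonzero(labels == k) for k in np.unique(labels)]


def locate_trees(clusters: list[Cluster], lo: float = BREAST_HEIGHT_LO,
                 hi: float = BREAST_HEIGHT_HI, gap: float = 0.5,
                 r_min: float = 0.03, r_max: float = 1.5,
                 min_slab_points: int = 5
                 ) -> list[tuple[Cluster, list[CircleFit]]]:
    """Locate trunks in each cluster by breast-height circle fitting.

    The breast-height slab is split into XY connected components (single
    linkage at ``gap`` meters), each component is circle-fitted, and fits
    with radius outside [r_min, r_max] are discarded as implausible trunks.
    A cluster with an empty slab gets zero fits (unlocatable: typically a
    crown-only fragment that the merge stage should have absorbed).
    """
    located = []
    for cluster in clusters:
        xy = slice_breast_height(cluster, lo, hi)
        fits: list[CircleFit] = []
        if len(xy) >= min_slab_points:
            for comp in _subcluster_slab(xy, gap):
                if len(comp) < min_slab_points:
                    continue
                try:
                    fit = fit_circle_lsq(xy[comp])
                except CircleFitError:
                    continue
                if r_min <= fit.r <= r_max:
                    fits.append(fit)
        located.append((cluster, fits))
    return located


def detect_undersegmentation(located: tuple[Cluster, list[CircleFit]]) -> bool:
    """True iff a cluster contains two or more accepted trunk fits."""
    _, fits = located
    return len(fits) >= 2


def align_to_trunk_axis(cluster: Cluster, fits: list[CircleFit]
                        ) -> tuple[np.ndarray, dict]:
    """Rotate XY about Z so the trunk-connection line lies along +u.

    With more than two trunks the axis is the first principal direction of
    the trunk centers; rotation is a pure isometry (distances preserved).
    Returns the rotated (u, v) coordinates and a record holding the axis
    direction, the origin (first trunk center along the axis), and the
    trunks' u positions.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 trunk fits to define an axis")
    centers = np.array([f.center for f in fits])
    if len(fits) == 2:
        v = centers[1] - centers[0]
        if np.linalg.norm(v) < 1e-9:
            raise ValueError("coincident trunk centers: axis undefined")
        direction = v / np.linalg.norm(v)
    else:
        centered = centers - centers.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        direction = vt[0]
    # orient so trunk u positions increase
    u_centers = centers @ direction
    if u_centers.max() - u_centers.min() < 1e-9:
        raise ValueError("trunk centers project to a point: axis undefined")
    order = np.argsort(u_centers)
    origin = centers[order[0]]
    rot = np.array([[direction[0], direction[1]],
                    [-direction[1], direction[0]]])  # maps direction -> +u
    rotated = (cluster.xy - origin) @ rot.T
    trunk_u = (centers - origin) @ direction
    record = {"axis_direction": direction, "origin": origin,
              "trunk_u": np.sort(trunk_u), "rotation": rot,
              "trunk_order": order}
    return rotated, record


def find_boundary_voxel(rotated: np.ndarray, trunk_u: np.ndarray,
                        voxel_width: float = 0.5) -> SplitPlan:
    """Find the density-valley boundary between each adjacent trunk pair.

    Point counts are binned into ``voxel_width`` bins along u.  Between two
    consecutive trunk positions the boundary is the center of the
    minimum-count voxel; ties go to the voxel nearest the trunks' midpoint.
    If fewer than two whole voxels fit between a pair, the midpoint is used
    with a warning.
    """
    if voxel_width <= 0:
        raise ValueError("voxel_width must be > 0")
    trunk_u = np.sort(np.asarray(trunk_u, dtype=float))
    if len(trunk_u) < 2:
        raise ValueError("need >= 2 trunk positions")
    u = rotated[:, 0]
    # anchor the voxel lattice at the first trunk so bin edges are tied to
    # the trunk-connection geometry, not to whichever crown tail happens to
    # reach farthest
    u0 = trunk_u[0]
    lo = u0 + voxel_width * np.floor((u.min() - u0) / voxel_width)
    n_vox = max(int(np.ceil((u.max() - lo) / voxel_width)), 1)
    edges = lo + voxel_width * np.arange(n_vox + 1)
    counts, _ = np.histogram(u, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    profile = list(zip(centers.tolist(), counts.astype(int).tolist()))

    boundaries: list[float] = []
    for ua, ub in zip(trunk_u[:-1], trunk_u[1:]):
        inside = np.flatnonzero((centers > ua) & (centers < ub))
        if len(inside) < 2:
            warnings.warn(
                "fewer than 2 voxels between trunks; splitting at midpoint",
                stacklevel=2,
            )
            boundaries.append(0.5 * (ua + ub))
            continue
        sub_counts = counts[inside]
        min_count = sub_counts.min()
        tied = inside[sub_counts == min_count]
        mid = 0.5 * (ua + ub)
        best = tied[np.argmin(np.abs(centers[tied] - mid))]
        boundaries.append(float(centers[best]))
    return SplitPlan(axis_direction=np.empty(0), origin=np.empty(0),
                     voxel_width=voxel_width, trunk_u=trunk_u,
                     boundaries=boundaries, density_profile=profile)


def split_cluster(cluster: Cluster, rotated: np.ndarray,
                  plan: SplitPlan) -> list[Cluster]:
    """Partition a cluster at the planned boundaries along u.

    k trunks and k−1 boundaries yield k children; children are disjoint and
    conserve the parent's point count.
    """
    bounds = sorted(plan.boundaries)
    u = rotated[:, 0]
    edges = [-np.inf] + bounds + [np.inf]
    children = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (u >= lo) & (u < hi)
        if mask.any():
            children.append(Cluster(cluster.cloud, cluster.indices[mask],
                                    kind=cluster.kind))
    return children
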