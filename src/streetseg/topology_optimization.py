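"""Topology checking: footprint-overlay merging and trunk-skeleton cleanup.

Over-segmentation shows up as a crown fragment floating above a trunk whose
middle was occluded: the fragment's XOY (horizontal-plane) footprint lies
inside the footprint of the cluster holding the rest of the tree.  Merging
is therefore driven by footprint *containment* — area of intersection over
the smaller footprint's area — with "completely overlapping" operationalized
as containment >= 0.9 by default, and closed transitively with union-find so
any number of fragments collapse into one cluster.

Interference removal walks the trunk in Z slabs (voxels along the growth
direction): each slab's XY centroid traces the stem axis, and below the
crown base any point farther than a radius cutoff from that axis is rejected
as a trunk-hugging distractor (sign, parked e-bike, fence post).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .core_io import Cluster

__all__ = [
    "Footprint",
    "TrunkSkeleton",
    "project_xoy",
    "footprint_overlap",
    "merge_oversegmented",
    "build_trunk_skeleton",
    "remove_interference",
]


@dataclass
class Footprint:
    """2D convex footprint of a cluster's XOY projection (CCW vertices)."""

    polygon: np.ndarray  # (M, 2), CCW; empty for degenerate
    degenerate: bool = False
    points_xy: Optional[np.ndarray] = None  # kept for degenerate fallbacks

    @property
    def area(self) -> float:
        if self.degenerate or len(self.polygon) < 3:
            return 0.0
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)

    @property
    def wkt(self) -> str:
        """WKT dump for debugging overlays in GIS tools."""
        return Polygon(self.polygon).wkt if not self.degenerate else "POLYGON EMPTY"


@dataclass
class TrunkSkeleton:
    """Z-slab voxel skeleton of a trunk: per-slab occupancy and XY centroid."""

    z_slabs: list[tuple[float, float, Optional[np.ndarray], bool]]
    slab_height: float
    axis_xy: np.ndarray  # robust trunk-axis XY estimate
    crown_base_z: float
    available: bool = True

    def centroids(self) -> np.ndarray:
        return np.array([c for _, _, c, occ in self.z_slabs if occ])


def project_xoy(cluster: Cluster) -> Footprint:
    """Convex hull of the cluster's XY projection.

    Fewer than 3 distinct non-collinear XY positions yield a zero-area
    footprint flagged degenerate (the raw XY points are retained so overlap
    can still be judged point-in-polygon).
    """
    xy = cluster.xy
    try:
        hull = ConvexHull(xy)
    except (QhullError, ValueError):
        footprint = Footprint(polygon=np.empty((0, 2)), degenerate=True,
                              points_xy=xy.copy())
        cluster.footprint = footprint
        return footprint
    verts = xy[hull.vertices]  # scipy returns CCW order in 2D
    footprint = Footprint(polygon=verts, degenerate=False, points_xy=xy.copy())
    cluster.footprint = footprint
    return footprint


def footprint_overlap(f1: Footprint, f2: Footprint) -> tuple[float, float]:
    """(containment, IoU) of two footprints.

    containment = area(f1 ∩ f2) / min(area f1, area f2); IoU uses the union.
    If either footprint is degenerate (a line or point in XY), containment
    falls back to the fraction of the smaller object's points lying inside
    the other polygon, and IoU is 0.
    """
    if f1.degenerate or f2.degenerate:
        small, big = (f1, f2) if len(f1.points_xy) <= len(f2.points_xy) else (f2, f1)
        if big.degenerate:
            return 0.0, 0.0
        poly = big.shapely().buffer(1e-9)
        from shapely.geometry import Point

        inside = sum(poly.contains(Point(p)) or poly.touches(Point(p))
                     for p in small.points_xy)
        return inside / max(len(small.points_xy), 1), 0.0
    p1, p2 = f1.shapely(), f2.shapely()
    inter = p1.intersection(p2).area
    union = p1.union(p2).area
    containment = inter / min(p1.area, p2.area) if min(p1.area, p2.area) > 0 else 0.0
    iou = inter / union if union > 0 else 0.0
    return min(containment, 1.0), min(iou, 1.0)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_oversegmented(clusters: list[Cluster],
                        containment_cutoff: float = 0.9) -> list[Cluster]:
    """Merge clusters whose footprints overlap (transitively).

    Every pair with containment >= cutoff is joined; union-find closes the
    relation so three mutually contained fragments become one cluster.  The
    output conserves the total point count and is idempotent.
    """
    if not clusters:
        return []
    for c in clusters:
        if c.footprint is None:
            project_xoy(c)
    uf = _UnionFind(len(clusters))
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            containment, _ = footprint_overlap(clusters[i].footprint,
                                               clusters[j].footprint)
            if containment >= containment_cutoff:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(clusters)):
        groups.setdefault(uf.find(i), []).append(i)
    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(clusters[members[0]])
        else:
            idx = np.concatenate([clusters[m].indices for m in members])
            kinds = {clusters[m].kind for m in members}
            kind = "nonlinear" if "nonlinear" in kinds else clusters[members[0]].kind
            cl = Cluster(clusters[members[0]].cloud, idx, kind=kind)
            project_xoy(cl)
            merged.append(cl)
    return merged


def build_trunk_skeleton(cluster: Cluster, slab_height: float = 0.25
                         ) -> TrunkSkeleton:
    """Slice the cluster into Z slabs and record per-slab XY centroids.

    Slabs cover [z_min, z_max] contiguously.  The trunk axis is the XY
    centroid of the radially tightest slab (a trunk-only cross-section);
    slab width is measured as the 95th-percentile radial distance from that
    axis.  The crown base is the top of the highest *narrow* slab below the
    widest slab — narrow meaning width within max(2x, +0.2 m) of the
    tightest slab.  Width, not point count, marks the crown onset: a crown
    widens immediately above its base while its point count ramps up only
    gradually, and a count threshold would place the base a meter or more
    too high and let the interference filter clip crown points.  When no
    narrow slab exists (e.g. a crown-only fragment) the crown base falls to
    z_min and the interference filter has nothing to reject.
    """
    if slab_height <= 0:
        raise ValueError("slab_height must be > 0")
    z = cluster.z
    z_min, z_max = float(z.min()), float(z.max())
    if z_max - z_min < 2 * slab_height:
        return TrunkSkeleton(z_slabs=[], slab_height=slab_height,
                             axis_xy=np.full(2, np.nan),
                             crown_base_z=np.nan, available=False)
    n_slabs = int(np.ceil((z_max - z_min) / slab_height))
    xy = cluster.xy
    slab_of = np.minimum(((z - z_min) / slab_height).astype(int), n_slabs - 1)
    slabs: list[tuple[float, float, Optional[np.ndarray], bool]] = []
    members: list[Optional[np.ndarray]] = []
    for s in range(n_slabs):
        mask = slab_of == s
        lo = z_min + s * slab_height
        hi = lo + slab_height
        if mask.any():
            slabs.append((lo, hi, xy[mask].mean(axis=0), True))
            members.append(xy[mask])
        else:
            slabs.append((lo, hi, None, False))
            members.append(None)

    # tightest slab about its own centroid -> trunk axis
    occupied = [s for s in range(n_slabs) if members[s] is not None]
    own_width = {
        s: float(np.percentile(
            np.linalg.norm(members[s] - members[s].mean(axis=0), axis=1), 95))
        for s in occupied
    }
    s_tight = min(occupied, key=lambda s: own_width[s])
    axis_xy = members[s_tight].mean(axis=0)

    # widths about the common axis; crown base above the last narrow slab
    axis_width = {
        s: float(np.percentile(
            np.linalg.norm(members[s] - axis_xy, axis=1), 95))
        for s in occupied
    }
    w_min = axis_width[s_tight]
    narrow_cut = max(2.0 * w_min, w_min + 0.2)
    s_widest = max(occupied, key=lambda s: axis_width[s])
    narrow = [s for s in occupied if s < s_widest and axis_width[s] <= narrow_cut]
    crown_base_z = slabs[max(narrow)][1] if narrow else z_min
    return TrunkSkeleton(z_slabs=slabs, slab_height=slab_height,
                         axis_xy=axis_xy, crown_base_z=crown_base_z)


def remove_interference(cluster: Cluster, skeleton: TrunkSkeleton,
                        radius_cutoff: float) -> tuple[Cluster, np.ndarray]:
    """Reject below-crown points far from the trunk axis.

    Points with z below the skeleton's crown base and XY distance to the
    trunk axis greater than ``radius_cutoff`` are split off as interference
    (signs, poles, parked vehicles glued to the trunk by DBSCAN); everything
    at or above the crown base is kept unconditionally.  Returns the cleaned
    cluster and the rejected index set; together they partition the input.
    """
    if not skeleton.available:
        raise ValueError("skeleton unavailable; cluster too short to slice")
    z = cluster.z
    dist = np.linalg.norm(cluster.xy - skeleton.axis_xy, axis=1)
    reject_mask = (z < skeleton.crown_base_z) & (dist > radius_cutoff)
    rejected = cluster.indices[reject_mask]
    kept = cluster.indices[~reject_mask]
    tree = Cluster(cluster.cloud, kept, kind=cluster.kind)
    return tree, rejected
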