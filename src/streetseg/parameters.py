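"""Per-tree morphometry: height, stand height, DBH, crown hull metrics.

Height is the z-range of a tree's points (H = max z − min z); the stand
average height is the arithmetic mean over trees.  DBH is twice the radius
of the least-squares circle fitted to the breast-height slab.  Crown extent
comes from the 2D convex hull of the tree's XY projection, built with the
quickhull recursion: take the two extreme points by X as an initial chord,
split the remaining points by side, and recursively promote the point
farthest from the chord until no point lies outside.  The crown diameter is
the maximum spacing between hull vertices (which equals the maximum pairwise
distance over all points); the crown area is the hull's shoelace area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import Cluster, TreeRecord
from .localization_split import (
    BREAST_HEIGHT_HI,
    BREAST_HEIGHT_LO,
    CircleFit,
    CircleFitError,
    fit_circle_lsq,
)

__all__ = [
    "ConvexHull2D",
    "DegenerateHullError",
    "tree_height",
    "stand_average_height",
    "dbh",
    "crown_hull",
    "crown_diameter",
    "crown_area",
    "extract_tree_record",
]


class DegenerateHullError(ValueError):
    """Fewer than 3 non-collinear points: no polygonal hull exists."""


@dataclass
class ConvexHull2D:
    """A CCW convex polygon plus its maximum-spacing vertex pair."""

    vertices: np.ndarray  # (M, 2) CCW
    diameter_pair: tuple[np.ndarray, np.ndarray]

    @property
    def diameter(self) -> float:
        return float(np.linalg.norm(self.diameter_pair[0] - self.diameter_pair[1]))

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def tree_height(points: np.ndarray) -> float:
    """H = max z − min z of a tree's points (meters)."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point set has no height")
    z = pts[:, 2] if pts.ndim == 2 else pts
    return float(z.max() - z.min())


def stand_average_height(heights: Sequence[float]) -> float:
    """Arithmetic mean height of the stand."""
    if len(heights) == 0:
        raise ValueError("no heights to average")
    return float(np.mean(heights))


def dbh(points: np.ndarray, lo: float = BREAST_HEIGHT_LO,
        hi: float = BREAST_HEIGHT_HI) -> tuple[float, CircleFit]:
    """DBH of a tree: 2x the least-squares circle radius at breast height.

    The slab is taken relative to the tree's minimum z.  Raises
    :class:`CircleFitError` when the slab is empty or the fit fails; callers
    record the tree as dbh-unavailable.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise CircleFitError("empty point set")
    z = pts[:, 2]
    rel = z - z.min()
    slab = pts[(rel >= lo) & (rel <= hi), :2]
    if len(slab) < 3:
        raise CircleFitError("breast-height slab has fewer than 3 points")
    fit = fit_circle_lsq(slab)
    return fit.dbh, fit


# ---------------------------------------------------------------------------
# Quickhull

def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _quickhull_side(pts: np.ndarray, a: np.ndarray, b: np.ndarray
                    ) -> list[np.ndarray]:
    """Hull vertices strictly left of directed chord a->b, in order."""
    if len(pts) == 0:
        return []
    cross = (pts[:, 0] - a[0]) * (b[1] - a[1]) - (pts[:, 1] - a[1]) * (b[0] - a[0])
    mask = cross < 0  # strictly left of the directed chord a->b
    left = pts[mask]
    if len(left) == 0:
        return []
    # farthest from the chord (|cross| ∝ distance) becomes a new hull vertex
    far = left[np.argmax(-cross[mask])]
    return (_quickhull_side(left, a, far) + [far] + _quickhull_side(left, far, b))


def _quickhull(pts: np.ndarray) -> np.ndarray:
    """CCW hull via quickhull: X-extreme chord, recursive farthest point."""
    # initial diagonal: extreme points prioritizing the X coordinate
    i_min = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    i_max = np.lexsort((pts[:, 1], pts[:, 0]))[-1]
    a, b = pts[i_min], pts[i_max]
    upper = _quickhull_side(pts, a, b)
    lower = _quickhull_side(pts, b, a)
    hull = [a] + upper + [b] + lower
    arr = np.array(hull)
    # _quickhull_side uses cross<0 (clockwise); flip to CCW
    x, y = arr[:, 0], arr[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if signed < 0:
        arr = arr[::-1]
    return arr


def crown_hull(points: np.ndarray) -> ConvexHull2D:
    """2D convex hull of a tree's XY projection (quickhull construction).

    Duplicated points are collapsed first.  Raises
    :class:`DegenerateHullError` when fewer than 3 distinct points remain or
    all points are collinear.
    """
    pts = np.asarray(points, dtype=float)
    xy = pts[:, :2] if pts.ndim == 2 and pts.shape[1] >= 2 else pts
    xy = np.unique(xy, axis=0)
    if len(xy) < 3:
        raise DegenerateHullError(
            f"{len(xy)} distinct points; a polygon needs 3"
        )
    centered = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(xy).max())) < 2:
        raise DegenerateHullError("points are collinear; hull is a segment")
    verts = _quickhull(xy)
    # maximum-spacing vertex pair (hull vertices suffice: the farthest pair
    # of any point set is attained on its hull)
    d2 = np.sum((verts[:, None, :] - verts[None, :, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return ConvexHull2D(vertices=verts, diameter_pair=(verts[i], verts[j]))


def crown_diameter(hull: ConvexHull2D) -> float:
    """Maximum spacing between convex-hull vertices (meters)."""
    if len(hull.vertices) < 2:
        raise ValueError("hull has fewer than 2 vertices")
    return hull.diameter


def crown_area(hull: ConvexHull2D) -> float:
    """Shoelace area of the crown hull polygon (m²)."""
    if len(hull.vertices) < 3:
        raise ValueError("hull has fewer than 3 vertices")
    return hull.area


def extract_tree_record(tree_id: int, cluster: Cluster,
                        fit: Optional[CircleFit] = None) -> TreeRecord:
    """Assemble the morphometric record for one segmented tree.

    Uses the provided breast-height fit for the location and DBH when
    available, otherwise refits from the cluster's own slab.  Quantities
    that cannot be computed (empty slab, degenerate hull) become NaN with a
    note in ``flags``.
    """
    pts = cluster.points
    flags: list[str] = []
    height = tree_height(pts)
    if fit is None:
        try:
            _, fit = dbh(pts)
        except CircleFitError as exc:
            fit = None
            flags.append(f"dbh-unavailable: {exc}")
    if fit is not None:
        location = (fit.a, fit.b)
        dbh_val = fit.dbh
    else:
        location = tuple(pts[:, :2].mean(axis=0))
        dbh_val = float("nan")
    try:
        hull = crown_hull(pts)
        diam = crown_diameter(hull)
        area = crown_area(hull)
        hull_verts = hull.vertices
    except DegenerateHullError as exc:
        flags.append(f"crown-unavailable: {exc}")
        diam, area, hull_verts = float("nan"), float("nan"), None
    return TreeRecord(tree_id=tree_id, indices=cluster.indices,
                      location=location, height=height, dbh=dbh_val,
                      crown_diameter=diam, crown_area=area,
                      crown_hull=hull_verts, flags=flags)
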