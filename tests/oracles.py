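"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (definitions,
exhaustive enumeration) and share no code with the package.
"""

import numpy as np


def naive_dbscan(X, eps, min_pts):
    """O(N^2) DBSCAN from the textbook density-reachability definition.

    Returns (labels, core_mask); labels -1 for noise, cluster ids arbitrary.
    """
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    neighbor = d <= eps  # includes self
    core = neighbor.sum(axis=1) >= min_pts
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            p = stack.pop()
            if not core[p]:
                continue
            for q in np.flatnonzero(neighbor[p]):
                if labels[q] == -1:
                    labels[q] = cid
                    stack.append(q)
        cid += 1
    return labels, core


def brute_force_hull_vertices(pts):
    """Convex-hull vertex set by the O(N^3) edge test.

    A directed pair (i, j) is a hull edge iff every other point lies on or
    left of it; hull vertices are the endpoints of hull edges.
    """
    pts = np.asarray(pts, float)
    n = len(pts)
    on_hull = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = pts[i], pts[j]
            cross = ((b[0] - a[0]) * (pts[:, 1] - a[1])
                     - (b[1] - a[1]) * (pts[:, 0] - a[0]))
            if (cross >= -1e-12).all():
                on_hull.add(i)
                on_hull.add(j)
    return sorted(on_hull)


def brute_force_diameter(pts):
    """O(N^2) maximum pairwise distance."""
    pts = np.asarray(pts, float)
    d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=2)
    return float(np.sqrt(d2.max()))
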