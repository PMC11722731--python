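"""Seeded generator of labeled street-tree scenes.

Emulates the geometry a vehicle-mounted scanner returns from a tree-lined
street: trunks as cylinder-surface samples, crowns as dense ellipsoid-volume
samples (MLS crowns return points throughout the canopy, not just the
surface), an optional ground plane, and pole-like distractors near trunks.
Two defect types reproduce the pipeline's hard cases:

* ``glued_pair`` — two trees planted close enough that their crowns touch,
  so density clustering fuses them (under-segmentation);
* ``trunk_gap`` — a z-band of trunk points deleted, detaching the crown as
  a floating fragment (over-segmentation from occlusion).

Every point carries a ground-truth label: tree ids >= 0, ground
:data:`GROUND_LABEL`, distractors :data:`DISTRACTOR_LABEL` (one shared
negative class).  A seed fixes the whole point set bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core_io import PointCloud

__all__ = [
    "TreeParams",
    "SceneSpec",
    "GROUND_LABEL",
    "DISTRACTOR_LABEL",
    "generate_tree",
    "generate_scene",
]

GROUND_LABEL = -2
DISTRACTOR_LABEL = -3


@dataclass(frozen=True)
class TreeParams:
    """Geometry of one synthetic street tree (meters)."""

    height: float = 9.0
    trunk_radius: float = 0.12
    crown_radius: float = 2.5
    crown_base: float = 3.0

    def __post_init__(self) -> None:
        if min(self.height, self.trunk_radius, self.crown_radius,
               self.crown_base) <= 0:
            raise ValueError("all tree dimensions must be > 0")
        if self.crown_base >= self.height:
            raise ValueError("crown_base must be below the tree top")


@dataclass(frozen=True)
class SceneSpec:
    """A street of trees with optional defects and distractors.

    Trees are planted along the +x street axis at ``spacing`` meters.
    ``defects`` may contain ``glued_pair`` (trees 0 and 1 moved to
    ``glued_gap`` apart so crowns overlap), ``trunk_gap`` (a 1 m z-band of
    the last tree's trunk removed), and ``crown_fragment`` (alias of
    trunk_gap kept for spec-file compatibility).  ``distractors`` lists
    ``"sign"``, ``"pole"`` or ``"box"`` objects placed near trunks in
    round-robin order.  Densities: trunk/sign/pole surfaces in pts/m²,
    crown volume in pts/m³.
    """

    n_trees: int = 10
    spacing: float = 8.0
    trees: Optional[tuple[TreeParams, ...]] = None
    defects: frozenset = frozenset()
    distractors: tuple[str, ...] = ()
    trunk_density: float = 2000.0  # pts/m² of trunk surface
    crown_density: float = 500.0   # pts/m³ of crown volume
    ground_density: float = 50.0   # pts/m² of ground plane
    noise_sigma: float = 0.01      # isotropic jitter, meters
    glued_gap: float = 4.0         # trunk spacing of the glued pair
    ground: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.spacing <= 0 or self.glued_gap <= 0:
            raise ValueError("spacings must be > 0")
        bad = set(self.defects) - {"glued_pair", "trunk_gap", "crown_fragment"}
        if bad:
            raise ValueError(f"unknown defects: {sorted(bad)}")
        if "glued_pair" in self.defects and self.n_trees < 2:
            raise ValueError("glued_pair needs n_trees >= 2")

    def tree_params(self, rng: np.random.Generator) -> tuple[TreeParams, ...]:
        """Per-tree geometry: explicit list or seeded draws from street-tree
        ranges (heights 6–13 m, trunk radii 0.05–0.15 m).

        When the ``glued_pair`` defect is active and no explicit list is
        given, trees 0 and 1 get crown radii of ``glued_gap / 2 + 0.15`` so
        their crowns interpenetrate by ~0.3 m — the planted-street case of
        adjacent crowns touching, which density clustering cannot separate.
        """
        if self.trees is not None:
            if len(self.trees) != self.n_trees:
                raise ValueError("len(trees) != n_trees")
            return self.trees
        out = []
        for _ in range(self.n_trees):
            h = rng.uniform(6.0, 13.0)
            out.append(TreeParams(
                height=h,
                trunk_radius=rng.uniform(0.05, 0.15),
                crown_radius=rng.uniform(1.8, 3.0),
                crown_base=rng.uniform(2.2, min(3.5, 0.45 * h)),
            ))
        if "glued_pair" in self.defects:
            touch_r = self.glued_gap / 2 + 0.15
            for i in (0, 1):
                out[i] = replace(out[i], crown_radius=touch_r)
        return tuple(out)


def generate_tree(params: TreeParams, seed: int,
                  trunk_density: float = 2000.0, crown_density: float = 500.0,
                  noise_sigma: float = 0.01, label: int = 0,
                  origin: tuple[float, float] = (0.0, 0.0)) -> PointCloud:
    """Sample one labeled tree rooted at ``origin`` with z=0 at the collar.

    Trunk points lie on the cylinder surface over [0, crown_base]; crown
    points fill an axis-aligned ellipsoid whose vertical semi-axis spans
    crown_base..height.  Isotropic Gaussian jitter of ``noise_sigma`` is
    added to every point.
    """
    rng = np.random.default_rng(seed)
    pts = [_sample_trunk(params, rng, trunk_density),
           _sample_crown(params, rng, crown_density)]
    coords = np.vstack(pts)
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    coords[:, 0] += origin[0]
    coords[:, 1] += origin[1]
    labels = np.full(len(coords), label, dtype=int)
    return PointCloud(coords, labels=labels, source=f"synthetic tree seed={seed}")


def _sample_trunk(p: TreeParams, rng: np.random.Generator,
                  density: float) -> np.ndarray:
    area = 2 * np.pi * p.trunk_radius * p.crown_base
    n = max(int(round(area * density)), 20)
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, p.crown_base, n)
    return np.column_stack([p.trunk_radius * np.cos(theta),
                            p.trunk_radius * np.sin(theta), z])


def _sample_crown(p: TreeParams, rng: np.random.Generator,
                  density: float) -> np.ndarray:
    c = (p.height - p.crown_base) / 2.0  # vertical semi-axis
    z_mid = p.crown_base + c
    volume = 4.0 / 3.0 * np.pi * p.crown_radius**2 * c
    n = max(int(round(volume * density)), 50)
    # uniform in the unit ball, scaled per-axis
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    rad = rng.uniform(0, 1, n) ** (1 / 3)
    ball = v * rad[:, None]
    return np.column_stack([ball[:, 0] * p.crown_radius,
                            ball[:, 1] * p.crown_radius,
                            ball[:, 2] * c + z_mid])


def _sample_distractor(kind: str, xy: np.ndarray, rng: np.random.Generator,
                       density: float = 2000.0) -> np.ndarray:
    if kind == "sign":  # thin vertical slab 0.5 x 0.05 x 1 m, z in [1, 2]
        dims, z0 = np.array([0.5, 0.05, 1.0]), 1.0
    elif kind == "pole":  # slender vertical box ~ lamp post
        dims, z0 = np.array([0.08, 0.08, 4.0]), 0.0
    elif kind == "box":  # parked e-bike / utility box
        dims, z0 = np.array([0.6, 0.4, 1.1]), 0.0
    else:
        raise ValueError(f"unknown distractor kind {kind!r}")
    n = max(int(round(2 * (dims[0] * dims[2] + dims[1] * dims[2]) * density)), 50)
    pts = rng.uniform(0, 1, (n, 3)) * dims
    pts[:, 0] += xy[0] - dims[0] / 2
    pts[:, 1] += xy[1] - dims[1] / 2
    pts[:, 2] += z0
    return pts


def generate_scene(spec: SceneSpec) -> tuple[PointCloud, dict]:
    """Build a labeled street scene from a spec.

    Returns the cloud (truth labels attached) and a ground-truth record:
    per-tree parameters, planting positions, defect bookkeeping (which tree
    ids form the glued pair, which tree carries the trunk gap), and the
    spec itself.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.tree_params(rng)
    positions = [np.array([i * spec.spacing, 0.0]) for i in range(spec.n_trees)]
    truth: dict = {"spec": spec, "trees": {}, "glued_pair": None,
                   "trunk_gap_tree": None}

    if "glued_pair" in spec.defects:
        # trees 0 and 1 planted glued_gap apart so their crowns interpenetrate
        positions[1] = positions[0] + np.array([spec.glued_gap, 0.0])
        min_gap = params[0].crown_radius + params[1].crown_radius
        if spec.glued_gap >= min_gap:
            raise ValueError(
                f"glued_gap {spec.glued_gap} >= crown radii sum {min_gap:.2f}: "
                "crowns would not touch"
            )
        if spec.glued_gap <= params[0].trunk_radius + params[1].trunk_radius:
            raise ValueError("trunks would overlap")
        truth["glued_pair"] = (0, 1)

    parts, labels = [], []
    for tid, (p, xy) in enumerate(zip(params, positions)):
        tree = generate_tree(p, seed=int(rng.integers(2**31)),
                             trunk_density=spec.trunk_density,
                             crown_density=spec.crown_density,
                             noise_sigma=spec.noise_sigma, label=tid,
                             origin=tuple(xy))
        coords = tree.coords
        if tid == spec.n_trees - 1 and (
                "trunk_gap" in spec.defects or "crown_fragment" in spec.defects):
            # occlusion gap: delete trunk points in a 1 m band mid-trunk
            gap_lo = 0.35 * p.crown_base
            gap_hi = gap_lo + min(1.0, 0.45 * p.crown_base)
            rel_z = coords[:, 2]
            r_xy = np.linalg.norm(coords[:, :2] - xy, axis=1)
            in_gap = (rel_z > gap_lo) & (rel_z < gap_hi) & (r_xy < 3 * p.trunk_radius)
            coords = coords[~in_gap]
            truth["trunk_gap_tree"] = tid
            truth["trunk_gap_band"] = (gap_lo, gap_hi)
        parts.append(coords)
        labels.append(np.full(len(coords), tid, dtype=int))
        truth["trees"][tid] = {"params": p, "position": xy.copy()}

    for k, kind in enumerate(spec.distractors):
        host = k % spec.n_trees
        offset = rng.uniform(0.5, 1.0) * np.array(
            [np.cos(rng.uniform(0, 2 * np.pi)), np.sin(rng.uniform(0, 2 * np.pi))])
        trunk_r = params[host].trunk_radius
        xy = positions[host] + offset * (1 + trunk_r)
        pts = _sample_distractor(kind, xy, rng)
        if spec.noise_sigma > 0:
            pts = pts + rng.normal(0.0, spec.noise_sigma, pts.shape)
        parts.append(pts)
        labels.append(np.full(len(pts), DISTRACTOR_LABEL, dtype=int))

    if spec.ground:
        x_lo = min(p[0] for p in positions) - 5
        x_hi = max(p[0] for p in positions) + 5
        w = 12.0
        n = int((x_hi - x_lo) * w * spec.ground_density)
        g = np.column_stack([
            rng.uniform(x_lo, x_hi, n),
            rng.uniform(-w / 2, w / 2, n),
            rng.normal(0.0, 0.02, n),
        ])
        parts.append(g)
        labels.append(np.full(n, GROUND_LABEL, dtype=int))

    cloud = PointCloud(np.vstack(parts), labels=np.concatenate(labels),
                       source=f"synthetic scene seed={spec.seed}")
    return cloud, truth
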