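"""End-to-end segmentation pipeline and its validated configuration.

Stage order follows the hierarchical design: optional ground removal →
DBSCAN pre-segmentation → RANSAC linearity tagging → one-third-of-average
noise filter → footprint-overlay merge of over-segmented fragments →
trunk-skeleton interference removal → breast-height localization →
density-valley split of under-segmented clusters → per-tree morphometry.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import numpy as np

from .core_io import Cluster, PointCloud, TreeRecord, remove_ground
from .evaluation import EvalReport, evaluate_labels
from .localization_split import (
    align_to_trunk_axis,
    detect_undersegmentation,
    find_boundary_voxel,
    locate_trees,
    split_cluster,
)
from .parameters import extract_tree_record
from .presegmentation import (
    DbscanParams,
    classify_linearity,
    dbscan_cluster,
    filter_noise_clusters,
)
from .topology_optimization import (
    build_trunk_skeleton,
    merge_oversegmented,
    project_xoy,
    remove_interference,
)

__all__ = ["PipelineConfig", "SegmentationResult", "segment_scene"]

log = logging.getLogger("streetseg")

# dotted config-key aliases -> dataclass field names
_KEY_MAP = {
    "dbscan.eps": "dbscan_eps",
    "dbscan.min_pts": "dbscan_min_pts",
    "ransac.dist_threshold": "ransac_dist_threshold",
    "ransac.n_iter": "ransac_n_iter",
    "ransac.seed": "seed",
    "noise.linear_ratio_cutoff": "linear_ratio_cutoff",
    "merge.containment_cutoff": "merge_containment_cutoff",
    "skeleton.slab_height": "skeleton_slab_height",
    "skeleton.radius_cutoff": "skeleton_radius_cutoff",
    "slab.lo": "slab_lo",
    "slab.hi": "slab_hi",
    "trunk.r_min": "trunk_r_min",
    "trunk.r_max": "trunk_r_max",
    "split.voxel_width": "split_voxel_width",
    "ground.cell": "ground_cell",
    "ground.height_margin": "ground_height_margin",
    "seed": "seed",
    "log_level": "log_level",
}


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their defaults (meters throughout).

    ``skeleton_radius_cutoff`` of None means adaptive: 2x the fitted
    breast-height radius + 0.2 m per cluster, falling back to 0.6 m when no
    fit is available.
    """

    dbscan_eps: float = 0.6
    dbscan_min_pts: int = 10
    ransac_dist_threshold: float = 0.4
    ransac_n_iter: int = 200
    linear_ratio_cutoff: float = 0.9
    merge_containment_cutoff: float = 0.9
    skeleton_slab_height: float = 0.25
    skeleton_radius_cutoff: Optional[float] = None
    slab_lo: float = 1.25
    slab_hi: float = 1.35
    trunk_r_min: float = 0.03
    trunk_r_max: float = 1.5
    split_voxel_width: float = 0.5
    ground_cell: float = 1.0
    ground_height_margin: float = 0.3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        positive = ["dbscan_eps", "ransac_dist_threshold",
                    "merge_containment_cutoff", "skeleton_slab_height",
                    "split_voxel_width", "ground_cell"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dbscan_min_pts < 1:
            raise ValueError("dbscan_min_pts must be >= 1")
        if not 0 < self.linear_ratio_cutoff <= 1:
            raise ValueError("linear_ratio_cutoff must be in (0, 1]")
        if self.slab_lo >= self.slab_hi:
            raise ValueError("slab_lo must be < slab_hi")
        if self.trunk_r_min >= self.trunk_r_max:
            raise ValueError("trunk_r_min must be < trunk_r_max")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a flat dict of dotted keys or field names.

        Unknown keys are rejected so typos never silently fall back to a
        default.
        """
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        for k, v in d.items():
            name = _KEY_MAP.get(k, k)
            if name not in valid:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SegmentationResult:
    """Output of a pipeline run: labels, records, and per-stage counts."""

    cloud: PointCloud
    labels: np.ndarray  # per-point predicted tree id, -1 = unassigned
    trees: list[TreeRecord]
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def evaluate(self, truth_labels: np.ndarray) -> EvalReport:
        return evaluate_labels(self.labels, truth_labels)


def _radius_cutoff(config: PipelineConfig, fits) -> float:
    if config.skeleton_radius_cutoff is not None:
        return config.skeleton_radius_cutoff
    if fits:
        return 2.0 * max(f.r for f in fits) + 0.2
    return 0.6


def segment_scene(cloud: PointCloud, config: PipelineConfig = PipelineConfig(),
                  skip_ground: bool = True) -> SegmentationResult:
    """Run the full segmentation pipeline on a scene.

    ``skip_ground=True`` (the default) assumes the cloud is already
    ground-free; pass False to apply the grid-minimum filter first.
    Returns per-point labels over the *input* cloud (ground and unassigned
    points get -1) and one :class:`~streetseg.core_io.TreeRecord` per tree.
    """
    counts: dict[str, int] = {"input_points": len(cloud)}
    if skip_ground:
        work = cloud
        keep_idx = np.arange(len(cloud))
    else:
        # run the filter on an index-labeled copy so surviving points can be
        # mapped back to positions in the input cloud
        filtered = remove_ground(
            PointCloud(cloud.coords, labels=np.arange(len(cloud))),
            cell=config.ground_cell, height_margin=config.ground_height_margin)
        keep_idx = filtered.labels
        work = PointCloud(cloud.coords[keep_idx], source=cloud.source)
    counts["after_ground"] = len(work)
    if len(work) == 0:
        return SegmentationResult(cloud=cloud, labels=np.full(len(cloud), -1),
                                  trees=[], stage_counts=counts)

    clusters, noise = dbscan_cluster(
        work, DbscanParams(eps=config.dbscan_eps, min_pts=config.dbscan_min_pts))
    counts["dbscan_clusters"] = len(clusters)
    counts["dbscan_noise_points"] = len(noise)
    log.info("DBSCAN: %d clusters, %d noise points", len(clusters), len(noise))
    if not clusters:
        return SegmentationResult(cloud=cloud, labels=np.full(len(cloud), -1),
                                  trees=[], stage_counts=counts)

    for c in clusters:
        classify_linearity(c, linear_ratio_cutoff=config.linear_ratio_cutoff,
                           dist_threshold=config.ransac_dist_threshold,
                           n_iter=config.ransac_n_iter, seed=config.seed)
    retained, dropped = filter_noise_clusters(clusters)
    counts["after_noise_filter"] = len(retained)
    log.info("noise rule: %d retained, %d dropped", len(retained), len(dropped))

    merged = merge_oversegmented(retained,
                                 containment_cutoff=config.merge_containment_cutoff)
    counts["after_merge"] = len(merged)
    log.info("footprint merge: %d clusters", len(merged))

    # linear clusters not absorbed by the merge are pole-like interference
    # (signs, lamp posts, occluded stubs with no matching crown) — drop them
    pole_like = [c for c in merged if c.kind == "linear"]
    merged = [c for c in merged if c.kind != "linear"]
    counts["pole_like_dropped"] = len(pole_like)
    if pole_like:
        log.info("dropped %d unmatched pole-like clusters", len(pole_like))

    located = locate_trees(merged, lo=config.slab_lo, hi=config.slab_hi,
                           r_min=config.trunk_r_min, r_max=config.trunk_r_max)

    # trunk-skeleton interference removal, then re-localize cleaned clusters
    cleaned: list[tuple[Cluster, list]] = []
    for cluster, fits in located:
        skel = build_trunk_skeleton(cluster,
                                    slab_height=config.skeleton_slab_height)
        if skel.available and len(fits) == 1:
            tree, rejected = remove_interference(
                cluster, skel, radius_cutoff=_radius_cutoff(config, fits))
            if len(rejected):
                log.info("interference removal: rejected %d points", len(rejected))
            cleaned.append((tree, fits))
        else:
            cleaned.append((cluster, fits))

    # split under-segmented clusters at the density valley
    final: list[tuple[Cluster, object]] = []  # (cluster, fit-or-None)
    for cluster, fits in cleaned:
        if detect_undersegmentation((cluster, fits)):
            rotated, record = align_to_trunk_axis(cluster, fits)
            plan = find_boundary_voxel(rotated, record["trunk_u"],
                                       voxel_width=config.split_voxel_width)
            children = split_cluster(cluster, rotated, plan)
            ordered_fits = [fits[i] for i in record["trunk_order"]]
            for k, child in enumerate(children):
                fit = ordered_fits[k] if k < len(ordered_fits) else None
                final.append((child, fit))
            log.info("split cluster of %d points into %d trees",
                     len(cluster), len(children))
        else:
            final.append((cluster, fits[0] if fits else None))
    # crown-only leftovers with no trunk fit that survived to here are kept
    # as trees only if nothing else matched them; they keep fit=None
    counts["final_trees"] = len(final)

    labels = np.full(len(cloud), -1, dtype=int)
    trees: list[TreeRecord] = []
    for tid, (cluster, fit) in enumerate(final):
        record = extract_tree_record(tid, cluster, fit=fit)
        trees.append(record)
        labels[keep_idx[cluster.indices]] = tid
    return SegmentationResult(cloud=cloud, labels=labels, trees=trees,
                              stage_counts=counts)
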