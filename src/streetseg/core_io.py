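"""Point-cloud domain types, format I/O, and shared geometry plumbing.

Coordinates are meters in a local right-handed frame with Z up.  Per-point
integer labels follow the clustering convention: ``-1`` marks noise or
unassigned points, tree ids are dense from 0, and negative ids below -1 are
reserved for distractor classes emitted by the synthetic generator.

Supported formats are ASCII XYZ (whitespace-separated ``x y z [label]``
with ``#`` comments) and ASCII PLY (vertex element with ``x, y, z`` and an
optional integer ``label`` property).  A label sidecar CSV with columns
``point_index,tree_id`` may accompany any cloud.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PointCloud",
    "Cluster",
    "TreeRecord",
    "CloudFormatError",
    "UnsupportedFormatError",
    "read_cloud",
    "write_cloud",
    "read_label_sidecar",
    "write_label_sidecar",
    "remove_ground",
]


class CloudFormatError(ValueError):
    """Raised when a point-cloud file does not parse in the named dialect."""


class UnsupportedFormatError(ValueError):
    """Raised for a format this build does not read or write."""


@dataclass(eq=False)
class PointCloud:
    """N points in meters, optionally labeled with integer tree ids.

    Parameters
    ----------
    coords : (N, 3) float array
        XYZ coordinates in meters, Z up.
    labels : (N,) int array, optional
        Per-point labels; ``-1`` = noise/unassigned, ``>=0`` = tree id.
    source : str, optional
        Provenance note (file path or generator spec).
    """

    coords: np.ndarray
    labels: Optional[np.ndarray] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.coords),):
                raise ValueError(
                    f"labels length {self.labels.shape} != N={len(self.coords)}"
                )

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def subset(self, indices: np.ndarray) -> "PointCloud":
        """New cloud restricted to ``indices`` (labels carried along)."""
        idx = np.asarray(indices, dtype=int)
        return PointCloud(
            coords=self.coords[idx],
            labels=None if self.labels is None else self.labels[idx],
            source=self.source,
        )


@dataclass(eq=False)
class Cluster:
    """An index set into a parent cloud with cached geometry.

    ``kind`` records the RANSAC linearity verdict: pole-like objects and
    occluded trunk fragments come out ``linear``, crowns ``nonlinear``.
    """

    cloud: PointCloud
    indices: np.ndarray
    kind: str = "unclassified"  # linear | nonlinear | unclassified
    footprint: Optional[object] = None  # topology_optimization.Footprint

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if len(idx) and (idx[0] < 0 or idx[-1] >= len(self.cloud)):
            raise ValueError("cluster indices out of range")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def points(self) -> np.ndarray:
        return self.cloud.coords[self.indices]

    @property
    def xy(self) -> np.ndarray:
        return self.cloud.coords[self.indices, :2]

    @property
    def z(self) -> np.ndarray:
        return self.cloud.coords[self.indices, 2]

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        pts = self.points
        return pts.min(axis=0), pts.max(axis=0)


@dataclass(eq=False)
class TreeRecord:
    """One segmented tree with its morphometric parameters.

    ``location`` is the breast-height circle-fit center (x, y); ``dbh`` is
    twice the fitted radius.  ``crown_hull`` is the XY convex hull of the
    whole tree, ``crown_area`` its shoelace area.  Unavailable quantities
    (e.g. DBH of a crown-only fragment) are NaN with a note in ``flags``.
    """

    tree_id: int
    indices: np.ndarray
    location: tuple[float, float]
    height: float
    dbh: float
    crown_diameter: float
    crown_area: float
    crown_hull: Optional[np.ndarray] = None  # (M, 2) CCW vertices
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("height", "dbh", "crown_diameter", "crown_area"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


# ---------------------------------------------------------------------------
# Readers / writers

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.csv")


def read_cloud(path, fmt: Optional[str] = None) -> PointCloud:
    """Read a point cloud from ``path``.

    ``fmt`` is one of ``{"xyz", "ply"}``; inferred from the suffix when
    omitted.  LAS/LAZ is not supported by this build and raises
    :class:`UnsupportedFormatError`.  A sidecar ``<path>.labels.csv`` is
    loaded automatically when the file itself carries no label column.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt in ("las", "laz"):
        raise UnsupportedFormatError(
            "LAS/LAZ I/O is not available in this build; convert to ASCII "
            "XYZ or PLY (e.g. with `pdal translate` or CloudCompare)."
        )
    if fmt == "xyz" or fmt == "txt":
        cloud = _read_xyz(path)
    elif fmt == "ply":
        cloud = _read_ply(path)
    else:
        raise UnsupportedFormatError(f"unknown point-cloud format {fmt!r}")
    if cloud.labels is None and _sidecar_path(path).exists():
        cloud.labels = read_label_sidecar(_sidecar_path(path), len(cloud))
    cloud.source = str(path)
    return cloud


def write_cloud(cloud: PointCloud, path, fmt: Optional[str] = None) -> None:
    """Write ``cloud`` so that :func:`read_cloud` reproduces it.

    Labels are emitted as a 4th column (xyz) or a ``label`` vertex property
    (ply) when present.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt in ("las", "laz"):
        raise UnsupportedFormatError("LAS/LAZ I/O is not available in this build")
    if fmt == "xyz" or fmt == "txt":
        _write_xyz(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path)
    else:
        raise UnsupportedFormatError(f"unknown point-cloud format {fmt!r}")


def _read_xyz(path: Path) -> PointCloud:
    coords: list[list[float]] = []
    labels: list[int] = []
    has_labels: Optional[bool] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise CloudFormatError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}"
                )
            try:
                xyz = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise CloudFormatError(f"{path}:{lineno}: {exc}") from None
            row_has_label = len(parts) == 4
            if has_labels is None:
                has_labels = row_has_label
            elif has_labels != row_has_label:
                raise CloudFormatError(
                    f"{path}:{lineno}: inconsistent column count"
                )
            coords.append(xyz)
            if row_has_label:
                try:
                    labels.append(int(parts[3]))
                except ValueError as exc:
                    raise CloudFormatError(f"{path}:{lineno}: {exc}") from None
    arr = np.asarray(coords, dtype=float).reshape(-1, 3)
    return PointCloud(arr, labels=np.asarray(labels, int) if has_labels else None)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        if cloud.labels is None:
            for x, y, z in cloud.coords:
                fh.write(f"{x:.8f} {y:.8f} {z:.8f}\n")
        else:
            for (x, y, z), lab in zip(cloud.coords, cloud.labels):
                fh.write(f"{x:.8f} {y:.8f} {z:.8f} {int(lab)}\n")


def _read_ply(path: Path) -> PointCloud:
    # Minimal ASCII PLY reader: vertex element with float x,y,z and an
    # optional integer "label" property.  Binary PLY is rejected.
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise CloudFormatError(f"{path}: missing 'ply' magic")
        fmt_line = fh.readline().strip()
        if not fmt_line.startswith("format ascii"):
            raise CloudFormatError(f"{path}: only ASCII PLY is supported")
        n_vertex = None
        props: list[str] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path}: unterminated header")
            tok = line.strip().split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                props.append(tok[-1])
            elif tok[0] == "end_header":
                break
        if n_vertex is None:
            raise CloudFormatError(f"{path}: no vertex element")
        for axis in ("x", "y", "z"):
            if axis not in props:
                raise CloudFormatError(f"{path}: vertex lacks property {axis!r}")
        col = {name: i for i, name in enumerate(props)}
        rows = []
        for i in range(n_vertex):
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path}: vertex record {i} missing")
            rows.append(line.split())
        data = np.asarray(rows, dtype=float).reshape(n_vertex, len(props))
    coords = data[:, [col["x"], col["y"], col["z"]]]
    labels = data[:, col["label"]].astype(int) if "label" in col else None
    return PointCloud(coords, labels=labels)


def _write_ply(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if cloud.labels is not None:
            fh.write("property int label\n")
        fh.write("end_header\n")
        if cloud.labels is None:
            for x, y, z in cloud.coords:
                fh.write(f"{x:.8f} {y:.8f} {z:.8f}\n")
        else:
            for (x, y, z), lab in zip(cloud.coords, cloud.labels):
                fh.write(f"{x:.8f} {y:.8f} {z:.8f} {int(lab)}\n")


def read_label_sidecar(path, n_points: int) -> np.ndarray:
    """Load a ``point_index,tree_id`` CSV into a dense label array."""
    labels = np.full(n_points, -1, dtype=int)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return labels
        # tolerate a headerless file
        rows = [header] if header and header[0].strip().lstrip("-").isdigit() else []
        rows.extend(reader)
    for row in rows:
        if not row:
            continue
        i, t = int(row[0]), int(row[1])
        if i < 0 or i >= n_points:
            raise CloudFormatError(f"sidecar index {i} out of range [0, {n_points})")
        labels[i] = t
    return labels


def write_label_sidecar(labels: Sequence[int], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["point_index", "tree_id"])
        for i, t in enumerate(labels):
            writer.writerow([i, int(t)])


# ---------------------------------------------------------------------------
# Ground removal

def remove_ground(cloud: PointCloud, cell: float = 1.0,
                  height_margin: float = 0.3) -> PointCloud:
    """Grid-minimum ground filter.

    Bins points into ``cell`` x ``cell`` XY grid cells and keeps those whose
    z exceeds the cell-local minimum by more than ``height_margin``.  This is
    deliberately simple plumbing — clouds pre-filtered by a cloth-simulation
    or progressive-TIN tool are equally acceptable inputs to the pipeline.

    Returns a new cloud; the output point set is always a subset of the
    input's.
    """
    if cell <= 0:
        raise ValueError("cell must be > 0")
    if height_margin < 0:
        raise ValueError("height_margin must be >= 0")
    if len(cloud) == 0:
        return PointCloud(np.empty((0, 3)), labels=None, source=cloud.source)
    ij = np.floor(cloud.coords[:, :2] / cell).astype(np.int64)
    # group points by cell, take per-cell minimum z with reduceat
    order = np.lexsort((cloud.coords[:, 2], ij[:, 1], ij[:, 0]))
    sij = ij[order]
    new_cell = np.ones(len(order), dtype=bool)
    new_cell[1:] = np.any(sij[1:] != sij[:-1], axis=1)
    starts = np.flatnonzero(new_cell)
    mins = np.minimum.reduceat(cloud.coords[order, 2], starts)
    cell_of_point = np.cumsum(new_cell) - 1
    local_min = mins[cell_of_point]
    keep_sorted = cloud.coords[order, 2] > local_min + height_margin
    keep = np.zeros(len(cloud), dtype=bool)
    keep[order] = keep_sorted
    return cloud.subset(np.flatnonzero(keep))
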