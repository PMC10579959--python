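"""Labeled surface anatomies: in-memory container, file I/O and normal
estimation.

The central data structure is :class:`LabeledSurface` — a triangle mesh or
point cloud in millimetre coordinates where every vertex carries an
anatomical label (left-atrial body, the four pulmonary veins, the appendage,
or the mitral-annulus rim).  Imaging-derived anatomies (CT/MRI segmentations)
are labeled; electro-anatomical mapping (EAM) exports are typically
unlabeled, which is represented as "all BODY".

Supported formats:

* ``xyzl`` — whitespace-delimited ASCII, one point per line:
  ``x y z [label]``, ``#`` starts a comment.  Vendor-neutral stand-in for the
  plain-text anatomy exports produced by segmentation software.
* ``ply`` — read via trimesh (ascii and binary little-endian); written by
  this module as double-precision ASCII with a ``uchar label`` vertex
  property so that labels and coordinates round-trip losslessly.
* ``obj`` / ``stl`` — geometry only via trimesh; labels are lost on write
  and default to BODY on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree
from scipy.spatial import cKDTree

from .exceptions import (
    DegenerateGeometryError,
    SurfaceParseError,
    SurfaceWriteError,
)

__all__ = [
    "AnatomicalLabel",
    "LabeledSurface",
    "NormalField",
    "read_surface",
    "write_surface",
    "estimate_normals",
]


class AnatomicalLabel(enum.IntEnum):
    """Per-vertex anatomical structure labels of the left atrium."""

    BODY = 0
    LSPV = 1  # left superior pulmonary vein
    LIPV = 2  # left inferior pulmonary vein
    RSPV = 3  # right superior pulmonary vein
    RIPV = 4  # right inferior pulmonary vein
    LAA = 5  # left atrial appendage
    MV_ANNULUS = 6  # mitral valve annulus rim


#: Distinctive landmark structures (everything except the atrial body).
LANDMARK_LABELS = frozenset(
    {
        AnatomicalLabel.LSPV,
        AnatomicalLabel.LIPV,
        AnatomicalLabel.RSPV,
        AnatomicalLabel.RIPV,
        AnatomicalLabel.LAA,
        AnatomicalLabel.MV_ANNULUS,
    }
)

_LABEL_BY_TOKEN = {label.name: label for label in AnatomicalLabel}

SOURCE_MODALITIES = ("MRI", "CT", "EAM", "SYNTHETIC")


@dataclass
class LabeledSurface:
    """A surface anatomy: vertices in mm, optional triangles, per-vertex labels.

    Parameters
    ----------
    vertices
        ``(n, 3)`` float array of coordinates in millimetres.
    faces
        Optional ``(m, 3)`` integer array of 0-based triangle indices.
        ``None`` for pure point clouds.
    labels
        Optional ``(n,)`` array of :class:`AnatomicalLabel` values; defaults
        to all BODY (an unlabeled, EAM-like anatomy).
    """

    vertices: np.ndarray
    faces: np.ndarray | None = None
    labels: np.ndarray | None = None
    name: str = ""
    source_modality: str = "SYNTHETIC"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertices contain non-finite coordinates")
        n = len(self.vertices)
        if self.faces is not None:
            self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
            if self.faces.ndim != 2 or self.faces.shape[1] != 3:
                raise ValueError("faces must have shape (m, 3)")
            if len(self.faces) and (
                self.faces.min() < 0 or self.faces.max() >= n
            ):
                raise ValueError("face index out of vertex range")
            if len(self.faces):
                f = self.faces
                degenerate = (
                    (f[:, 0] == f[:, 1])
                    | (f[:, 1] == f[:, 2])
                    | (f[:, 0] == f[:, 2])
                )
                if degenerate.any():
                    raise ValueError(
                        f"{int(degenerate.sum())} degenerate faces "
                        "(repeated vertex indices)"
                    )
        if self.labels is None:
            self.labels = np.zeros(n, dtype=np.uint8)
        else:
            self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
            if self.labels.shape != (n,):
                raise ValueError("labels length must equal vertex count")
            valid = {int(label) for label in AnatomicalLabel}
            if not set(np.unique(self.labels)).issubset(valid):
                raise ValueError("labels contain values outside AnatomicalLabel")
        if self.source_modality not in SOURCE_MODALITIES:
            raise ValueError(
                f"source_modality must be one of {SOURCE_MODALITIES}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def label_counts(self) -> dict[AnatomicalLabel, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {AnatomicalLabel(int(v)): int(c) for v, c in zip(values, counts)}

    def subset(self, keep: np.ndarray, name: str | None = None) -> "LabeledSurface":
        """Return the surface restricted to a boolean vertex mask.

        Faces with any removed vertex are dropped; surviving faces are
        re-indexed.
        """
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_vertices,):
            raise ValueError("mask length must equal vertex count")
        new_faces = None
        if self.faces is not None and len(self.faces):
            remap = np.full(self.n_vertices, -1, dtype=np.int64)
            remap[keep] = np.arange(int(keep.sum()))
            face_ok = keep[self.faces].all(axis=1)
            new_faces = remap[self.faces[face_ok]]
        elif self.faces is not None:
            new_faces = self.faces.copy()
        return LabeledSurface(
            vertices=self.vertices[keep],
            faces=new_faces,
            labels=self.labels[keep],
            name=name if name is not None else self.name,
            source_modality=self.source_modality,
        )

    def without_labels(self, excluded, name: str | None = None) -> "LabeledSurface":
        """Drop all vertices whose label is in ``excluded``."""
        excluded = {int(e) for e in excluded}
        keep = ~np.isin(self.labels, sorted(excluded))
        return self.subset(keep, name=name)

    def copy(self) -> "LabeledSurface":
        return LabeledSurface(
            vertices=self.vertices.copy(),
            faces=None if self.faces is None else self.faces.copy(),
            labels=self.labels.copy(),
            name=self.name,
            source_modality=self.source_modality,
        )


@dataclass
class NormalField:
    """Per-vertex unit normals annotating a surface."""

    normals: np.ndarray
    k_neighbors: int = 0

    def __post_init__(self) -> None:
        self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must have unit length within 1e-6")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"ply", "obj", "stl", "xyzl"}:
        return suffix
    if suffix in {"txt", "xyz"}:
        return "xyzl"
    raise SurfaceParseError(f"cannot infer surface format from '{path.name}'")


def _read_xyzl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    vertices: list[tuple[float, float, float]] = []
    labels: list[int] = []
    with open(path, "r") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) not in (3, 4):
                raise SurfaceParseError(
                    f"{path.name}:{lineno}: expected 'x y z [label]', "
                    f"got {len(tokens)} tokens"
                )
            try:
                x, y, z = (float(t) for t in tokens[:3])
            except ValueError as exc:
                raise SurfaceParseError(
                    f"{path.name}:{lineno}: non-numeric coordinate"
                ) from exc
            if not np.isfinite([x, y, z]).all():
                raise SurfaceParseError(
                    f"{path.name}:{lineno}: non-finite coordinate"
                )
            label = AnatomicalLabel.BODY
            if len(tokens) == 4:
                token = tokens[3].upper()
                if token not in _LABEL_BY_TOKEN:
                    allowed = ", ".join(_LABEL_BY_TOKEN)
                    raise SurfaceParseError(
                        f"{path.name}:{lineno}: unknown label '{tokens[3]}' "
                        f"(allowed: {allowed})"
                    )
                label = _LABEL_BY_TOKEN[token]
            vertices.append((x, y, z))
            labels.append(int(label))
    if not vertices:
        raise SurfaceParseError(f"{path.name}: no points found")
    return np.asarray(vertices, dtype=np.float64), np.asarray(labels, np.uint8)


def _ply_raw_property(mesh, prop: str) -> np.ndarray | None:
    """Pull a named per-vertex property out of trimesh's raw PLY metadata."""
    raw = mesh.metadata.get("_ply_raw") if hasattr(mesh, "metadata") else None
    if not raw or "vertex" not in raw:
        return None
    data = raw["vertex"]["data"]
    if isinstance(data, dict):
        if prop in data:
            return np.asarray(data[prop]).ravel()
    elif data.dtype.names and prop in data.dtype.names:
        return np.asarray(data[prop]).ravel()
    return None


def read_surface(path, fmt: str | None = None) -> LabeledSurface:
    """Read a labeled surface anatomy from ``path``.

    ``fmt`` is one of ``ply``, ``obj``, ``stl``, ``xyzl``; when ``None`` it is
    inferred from the file suffix.  Labels missing from the file (OBJ, STL,
    unlabeled xyzl/PLY) default to BODY.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyzl":
        vertices, labels = _read_xyzl(path)
        return LabeledSurface(vertices, None, labels, name=path.stem)
    if fmt not in {"ply", "obj", "stl"}:
        raise SurfaceParseError(f"unsupported format '{fmt}'")
    try:
        mesh = trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # trimesh raises a zoo of types
        raise SurfaceParseError(f"failed to parse {path.name}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if len(geoms) != 1:
            raise SurfaceParseError(
                f"{path.name}: expected a single geometry, got {len(geoms)}"
            )
        mesh = geoms[0]
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    faces = None
    if isinstance(mesh, trimesh.Trimesh) and len(mesh.faces):
        faces = np.asarray(mesh.faces, dtype=np.int64)
    labels = None
    if fmt == "ply":
        prop = _ply_raw_property(mesh, "label")
        if prop is not None:
            labels = prop.astype(np.uint8)
    try:
        return LabeledSurface(vertices, faces, labels, name=path.stem)
    except ValueError as exc:
        raise SurfaceParseError(f"{path.name}: {exc}") from exc


def _write_ply(surface: LabeledSurface, path: Path, scalars=None,
               scalar_name: str = "residual_mm") -> None:
    """ASCII PLY writer with double-precision coordinates and a label
    property (trimesh's writer stores float32 vertices, which loses
    sub-micrometre precision)."""
    n = surface.n_vertices
    faces = surface.faces
    with open(path, "w") as out:
        out.write("ply\nformat ascii 1.0\n")
        out.write(f"element vertex {n}\n")
        out.write("property double x\nproperty double y\nproperty double z\n")
        out.write("property uchar label\n")
        if scalars is not None:
            out.write(f"property double {scalar_name}\n")
        n_faces = 0 if faces is None else len(faces)
        out.write(f"element face {n_faces}\n")
        out.write("property list uchar int vertex_indices\n")
        out.write("end_header\n")
        for i in range(n):
            x, y, z = surface.vertices[i]
            line = f"{x:.17g} {y:.17g} {z:.17g} {int(surface.labels[i])}"
            if scalars is not None:
                line += f" {scalars[i]:.17g}"
            out.write(line + "\n")
        if faces is not None:
            for f in faces:
                out.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_surface(surface: LabeledSurface, path, fmt: str | None = None) -> None:
    """Write a surface anatomy.

    Labels survive only in ``xyzl`` and ``ply``; ``obj``/``stl`` keep the
    geometry but drop labels.  STL additionally requires faces.
    """
    path = Path(path)
    if surface.n_vertices == 0:
        raise SurfaceWriteError("refusing to write an empty surface")
    fmt = _infer_format(path, fmt)
    if fmt == "xyzl":
        with open(path, "w") as out:
            out.write("# x y z label (mm)\n")
            for v, lab in zip(surface.vertices, surface.labels):
                token = AnatomicalLabel(int(lab)).name
                out.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g} {token}\n")
        return
    if fmt == "ply":
        _write_ply(surface, path)
        return
    if fmt in {"obj", "stl"}:
        if fmt == "stl" and (surface.faces is None or not len(surface.faces)):
            raise SurfaceWriteError("STL requires a triangulated surface")
        if surface.faces is not None and len(surface.faces):
            mesh = trimesh.Trimesh(
                vertices=surface.vertices, faces=surface.faces, process=False
            )
        else:
            mesh = trimesh.PointCloud(surface.vertices)
        mesh.export(str(path), file_type=fmt)
        return
    raise SurfaceWriteError(f"unsupported format '{fmt}'")


def _mesh_vertex_normals(surface: LabeledSurface) -> np.ndarray:
    """Area-weighted average of incident face normals, assuming consistent
    outward face winding."""
    v, f = surface.vertices, surface.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    # |cross| = 2 * area, so accumulating the raw cross product is already
    # area weighting.
    normals = np.zeros_like(v)
    for j in range(3):
        np.add.at(normals, f[:, j], cross)
    lengths = np.linalg.norm(normals, axis=1)
    if (lengths < 1e-300).any():
        raise DegenerateGeometryError(
            "vertex with zero accumulated face normal (isolated or flat fan)"
        )
    return normals / lengths[:, None]


def _pca_normals(points: np.ndarray, k: int) -> np.ndarray:
    """Unoriented normals from principal-component plane fits on k-NN
    neighbourhoods. Collinear neighbourhoods retry with 2k neighbours."""
    n = len(points)
    tree = cKDTree(points)
    k_eff = min(k + 1, n)
    _, idx = tree.query(points, k=k_eff)
    neigh = points[idx]  # (n, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    evals, evecs = np.linalg.eigh(cov)
    normals = evecs[:, :, 0]
    # rank-deficient: two smallest eigenvalues both tiny relative to largest
    scale = np.maximum(evals[:, 2], 1e-300)
    bad = (evals[:, 1] / scale) < 1e-10
    if bad.any():
        k2 = min(2 * k + 1, n)
        if k2 > k_eff:
            _, idx2 = tree.query(points[bad], k=k2)
            neigh2 = points[idx2]
            c2 = neigh2 - neigh2.mean(axis=1, keepdims=True)
            cov2 = np.einsum("nki,nkj->nij", c2, c2)
            e2, v2 = np.linalg.eigh(cov2)
            still = (e2[:, 1] / np.maximum(e2[:, 2], 1e-300)) < 1e-10
            if still.any():
                raise DegenerateGeometryError(
                    "collinear point neighbourhood: normal undefined even "
                    "with doubled neighbourhood size"
                )
            normals[bad] = v2[:, :, 0]
        else:
            raise DegenerateGeometryError(
                "collinear point neighbourhood: normal undefined"
            )
    return normals


def _orient_normals(points: np.ndarray, normals: np.ndarray, k: int) -> np.ndarray:
    """Make normal signs globally consistent by propagating along a minimum
    spanning tree of the k-NN graph (edge weight 1 - |n_i . n_j|), then flip
    globally so normals point outward from the centroid on average."""
    n = len(points)
    tree = cKDTree(points)
    k_eff = min(k + 1, n)
    dist, idx = tree.query(points, k=k_eff)
    rows = np.repeat(np.arange(n), k_eff - 1)
    cols = idx[:, 1:].ravel()
    dots = np.abs(np.einsum("ij,ij->i", normals[rows], normals[cols]))
    weights = 1.0 - dots + 1e-9  # strictly positive so MST keeps all edges
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n))
    mst = minimum_spanning_tree(graph)
    sym = mst + mst.T
    root = int(np.argmax(points[:, 2]))
    order, predecessors = breadth_first_order(sym, root, directed=False)
    oriented = normals.copy()
    for node in order:
        parent = predecessors[node]
        if parent < 0:
            continue
        if np.dot(oriented[node], oriented[parent]) < 0:
            oriented[node] = -oriented[node]
    # global sign: outward from centroid (valid for star-shaped anatomies)
    outward = points - points.mean(axis=0)
    if np.einsum("ij,ij->i", oriented, outward).sum() < 0:
        oriented = -oriented
    return oriented


def estimate_normals(surface: LabeledSurface, k_neighbors: int = 12) -> NormalField:
    """Estimate per-vertex unit normals.

    With faces present, normals are area-weighted averages of incident face
    normals (outward for consistently wound closed meshes).  For point
    clouds, each normal is the smallest principal axis of the ``k_neighbors``
    nearest neighbours, with signs made globally consistent by propagation
    along a minimum-spanning-tree of the neighbour graph and a final
    outward-from-centroid flip.
    """
    if k_neighbors < 3:
        raise ValueError("k_neighbors must be >= 3")
    if surface.faces is not None and len(surface.faces):
        normals = _mesh_vertex_normals(surface)
        return NormalField(normals=normals, k_neighbors=0)
    if surface.n_vertices < k_neighbors:
        raise DegenerateGeometryError(
            f"need at least k_neighbors={k_neighbors} points, "
            f"got {surface.n_vertices}"
        )
    normals = _pca_normals(surface.vertices, k_neighbors)
    normals = _orient_normals(surface.vertices, normals, k_neighbors)
    return NormalField(normals=normals, k_neighbors=k_neighbors)
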