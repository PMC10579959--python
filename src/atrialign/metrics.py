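"""Residual-distance quality metrics for aligned anatomies.

After alignment, quality is quantified by the Euclidean distance from each
retained imaging vertex to the closest point of the EAM anatomy, computed
*after* excluding the distinctive structures (pulmonary veins, appendage,
mitral annulus) whose segmentation differs systematically between
modalities.  The summary reports the median and mean residual and the
percentage of the retained surface below clinically interpretable
thresholds (2.5 mm and 5 mm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .exceptions import AtrialignError, SurfaceParseError
from .surface_io import (
    LANDMARK_LABELS,
    LabeledSurface,
    _ply_raw_property,
    _write_ply,
)

__all__ = [
    "DistanceSummary",
    "residual_distances",
    "distance_map_export",
    "read_distance_map",
    "DEFAULT_THRESHOLDS_MM",
    "SENTINEL_EXCLUDED",
]

DEFAULT_THRESHOLDS_MM = (2.5, 5.0)

#: scalar written for excluded vertices in distance-map exports
SENTINEL_EXCLUDED = -1.0


@dataclass
class DistanceSummary:
    """Per-vertex residual distances over the retained imaging vertices.

    ``retained_indices`` maps each entry of ``per_vertex_distance`` back to
    a vertex of the full imaging surface.  ``pct_below`` maps each threshold
    (mm) to the percentage of retained vertices at or below it.
    """

    per_vertex_distance: np.ndarray
    retained_indices: np.ndarray
    median_mm: float
    mean_mm: float
    pct_below: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.per_vertex_distance, dtype=np.float64)
        if (d < 0).any() or not np.isfinite(d).all():
            raise ValueError("distances must be finite and non-negative")
        self.per_vertex_distance = d
        self.retained_indices = np.asarray(self.retained_indices, np.int64)
        thresholds = sorted(self.pct_below)
        values = [self.pct_below[t] for t in thresholds]
        if any(not 0 <= v <= 100 for v in values):
            raise ValueError("pct_below values must be percentages")
        if any(b < a for a, b in zip(values, values[1:])):
            raise ValueError("pct_below must be monotone in the threshold")

    def to_dict(self) -> dict:
        return {
            "n_retained": int(len(self.per_vertex_distance)),
            "median_mm": self.median_mm,
            "mean_mm": self.mean_mm,
            "pct_below": {f"{t:g}": v for t, v in self.pct_below.items()},
        }


def _nearest_distances(
    points: np.ndarray, target: LabeledSurface, mode: str
) -> np.ndarray:
    if mode == "vertex" or target.faces is None or not len(target.faces):
        distances, _ = cKDTree(target.vertices).query(points)
        return distances
    if mode != "surface":
        raise ValueError("mode must be 'vertex' or 'surface'")
    # candidate triangles = faces incident to the k nearest target vertices,
    # exact point-to-triangle distance on the candidates (upper-bounded by
    # the nearest-vertex distance, since that vertex's faces are candidates)
    faces = target.faces
    incident: list[list[int]] = [[] for _ in range(target.n_vertices)]
    for fi, face in enumerate(faces):
        for v in face:
            incident[v].append(fi)
    k = min(8, target.n_vertices)
    _, knn = cKDTree(target.vertices).query(points, k=k)
    knn = np.atleast_2d(knn)
    triangles = target.vertices[faces]
    out = np.empty(len(points))
    for i, point in enumerate(points):
        cand = sorted({fi for v in knn[i] for fi in incident[v]})
        closest = trimesh.triangles.closest_point(
            triangles[cand], np.tile(point, (len(cand), 1))
        )
        out[i] = np.linalg.norm(closest - point, axis=1).min()
    return out


def residual_distances(
    aligned_imaging: LabeledSurface,
    eam: LabeledSurface,
    excluded_labels=LANDMARK_LABELS,
    thresholds_mm=DEFAULT_THRESHOLDS_MM,
    mode: str = "vertex",
    symmetric: bool = False,
) -> DistanceSummary:
    """Residual Euclidean distances from the aligned imaging anatomy to the
    EAM anatomy after structure exclusion.

    Imaging vertices whose label is in ``excluded_labels`` are removed.
    ``mode='vertex'`` measures to the nearest EAM vertex; ``mode='surface'``
    measures to the nearest point on the EAM triangulation when faces exist
    (never larger than the vertex-mode distance).  With ``symmetric=True``
    the reverse distances (EAM vertices, minus excluded labels when the EAM
    side is labeled, to the imaging cloud) are pooled into the summary
    statistics as well.
    """
    if eam.n_vertices == 0:
        raise AtrialignError("EAM surface is empty")
    excluded = {int(e) for e in excluded_labels}
    retained = ~np.isin(aligned_imaging.labels, sorted(excluded))
    if not retained.any():
        raise AtrialignError(
            "no imaging vertices retained after label exclusion"
        )
    retained_idx = np.flatnonzero(retained)
    forward = _nearest_distances(
        aligned_imaging.vertices[retained_idx], eam, mode
    )
    pooled = forward
    if symmetric:
        eam_keep = ~np.isin(eam.labels, sorted(excluded))
        if not eam_keep.any():
            raise AtrialignError("no EAM vertices retained after exclusion")
        reverse = _nearest_distances(
            eam.vertices[eam_keep], aligned_imaging, mode
        )
        pooled = np.concatenate([forward, reverse])
    pct = {
        float(t): float(100.0 * np.mean(pooled <= t)) for t in thresholds_mm
    }
    return DistanceSummary(
        per_vertex_distance=forward,
        retained_indices=retained_idx,
        median_mm=float(np.median(pooled)),
        mean_mm=float(np.mean(pooled)),
        pct_below=pct,
    )


def distance_map_export(
    summary: DistanceSummary, surface: LabeledSurface, path
) -> None:
    """Write the per-vertex residual distance map as a PLY scalar field.

    Every vertex of ``surface`` gets a ``residual_mm`` property; vertices
    excluded from the metric carry the sentinel value ``-1``.
    """
    idx = summary.retained_indices
    if len(idx) and (idx.min() < 0 or idx.max() >= surface.n_vertices):
        raise AtrialignError(
            "summary indices do not match the surface vertex count"
        )
    if len(idx) != len(summary.per_vertex_distance):
        raise AtrialignError("summary index/distance length mismatch")
    scalars = np.full(surface.n_vertices, SENTINEL_EXCLUDED)
    scalars[idx] = summary.per_vertex_distance
    _write_ply(surface, Path(path), scalars=scalars, scalar_name="residual_mm")


def read_distance_map(path) -> tuple[LabeledSurface, np.ndarray]:
    """Read back a distance-map PLY: the surface plus the residual scalars
    (sentinel ``-1`` marking excluded vertices)."""
    mesh = trimesh.load(str(path), file_type="ply", process=False)
    labels = _ply_raw_property(mesh, "label")
    scalars = _ply_raw_property(mesh, "residual_mm")
    if scalars is None:
        raise SurfaceParseError(f"{path}: no residual_mm vertex property")
    faces = None
    if isinstance(mesh, trimesh.Trimesh) and len(mesh.faces):
        faces = np.asarray(mesh.faces, dtype=np.int64)
    surface = LabeledSurface(
        vertices=np.asarray(mesh.vertices, dtype=np.float64),
        faces=faces,
        labels=None if labels is None else labels.astype(np.uint8),
        name=Path(path).stem,
    )
    return surface, np.asarray(scalars, dtype=np.float64)
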