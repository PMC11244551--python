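"""Polygonal region-of-interest selection on a triangulated surface.

A ROI is specified programmatically by an ordered list of mesh vertex IDs.
Consecutive selections are joined by shortest edge paths (geodesic over the
edge graph), closing a contour that partitions the closed surface into two
components.  The interior is the component containing ``interior_hint`` if
given, otherwise the smaller-area component; contour vertices are interior
(boundary inclusive).  Boundary triangles (mixed interior/exterior
vertices) are assigned to the interior iff at least 2 of their 3 vertices
are interior, so interior and exterior triangle sets exactly partition the
surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .data_model import EAMStudy, FeatureMap, Mesh
from .mesh_maps import interpolate_feature, triangle_areas


@dataclass
class ROI:
    """A closed region on the surface.

    ``contour`` is the full closed loop of vertex IDs (selected vertices
    plus shortest-path fill-in); ``selected`` are the user-specified IDs
    kept for persistence.
    """

    contour: np.ndarray
    interior_vertices: np.ndarray  # bool mask over vertices
    interior_triangles: np.ndarray  # bool mask over triangles
    name: str = "roi"
    selected: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    interior_hint: int | None = None


def _edge_graph(mesh: Mesh) -> csr_matrix:
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    return csr_matrix((np.concatenate([w, w]), (rows, cols)), shape=(n, n))


def _shortest_path(graph: csr_matrix, src: int, dst: int) -> list:
    dist, pred = dijkstra(graph, indices=src, return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise ValueError(f"vertices {src} and {dst} are not connected")
    path = [dst]
    while path[-1] != src:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def _interior_area(mesh: Mesh, interior_mask: np.ndarray, areas: np.ndarray) -> float:
    tri_in = interior_mask[mesh.triangles].sum(axis=1) >= 2
    return float(areas[tri_in].sum())


def define_roi(
    mesh: Mesh,
    contour_vertex_ids,
    interior_hint: int | None = None,
    name: str = "roi",
) -> ROI:
    """Build a ROI from an ordered loop of selected vertex IDs.

    Orientation-independent: the same interior results from the reversed
    selection order.  Raises on a contour that fails to separate the
    surface into two components.
    """
    sel = np.asarray(contour_vertex_ids, dtype=np.int64).ravel()
    if len(np.unique(sel)) < 3:
        raise ValueError("at least 3 distinct contour vertices required")
    if sel.min() < 0 or sel.max() >= mesh.n_vertices:
        raise ValueError("contour vertex ID out of range")

    graph = _edge_graph(mesh)
    contour: list = []
    for i in range(len(sel)):
        seg = _shortest_path(graph, int(sel[i]), int(sel[(i + 1) % len(sel)]))
        contour.extend(seg[:-1])
    contour = np.array(contour, dtype=np.int64)
    on_contour = np.zeros(mesh.n_vertices, dtype=bool)
    on_contour[contour] = True

    # components of the surface with contour vertices removed
    keep = ~on_contour
    sub = graph[keep][:, keep]
    n_comp, labels_sub = connected_components(sub, directed=False)
    if n_comp < 2:
        raise ValueError("degenerate contour: surface not separated")
    labels = np.full(mesh.n_vertices, -1, dtype=int)
    labels[keep] = labels_sub

    areas = triangle_areas(mesh)

    def mask_for(comp: int) -> np.ndarray:
        return (labels == comp) | on_contour

    if interior_hint is not None:
        comp = labels[int(interior_hint)]
        if comp < 0:
            # hint on the contour: boundary-inclusive, default to smaller area
            comp = None
    else:
        comp = None
    if comp is None:
        cand = sorted(
            range(n_comp),
            key=lambda c: (
                _interior_area(mesh, mask_for(c), areas),
                int(np.nonzero(labels == c)[0].min()),
            ),
        )
        comp = cand[0]

    interior_vertices = mask_for(comp)
    interior_triangles = interior_vertices[mesh.triangles].sum(axis=1) >= 2
    return ROI(
        contour=contour,
        interior_vertices=interior_vertices,
        interior_triangles=interior_triangles,
        name=name,
        selected=sel,
        interior_hint=interior_hint,
    )


def roi_membership(roi: ROI, study: EAMStudy) -> np.ndarray:
    """Per-point mask: a point is inside iff its nearest mesh vertex is an
    interior vertex (contour vertices inclusive)."""
    if study.n_points == 0:
        return np.zeros(0, dtype=bool)
    tree = cKDTree(study.mesh.vertices)
    _, nearest = tree.query(study.surface_positions)
    return roi.interior_vertices[nearest]


def restrict_and_reinterpolate(
    study: EAMStudy,
    roi: ROI,
    feature: FeatureMap,
    method: str | None = None,
    max_distance: float | None = None,
) -> FeatureMap:
    """Re-run interpolation using only ROI-interior points, onto interior
    vertices; exterior vertices are missing (NaN)."""
    inside = roi_membership(roi, study)
    vals = feature.point_values
    usable = inside & np.isfinite(vals)
    if not np.any(usable):
        raise ValueError("no valid points inside ROI")
    interior_ids = np.nonzero(roi.interior_vertices)[0]
    return interpolate_feature(
        study.surface_positions[usable],
        vals[usable],
        study.mesh,
        method=method or feature.method,
        max_distance=feature.max_distance if max_distance is None else max_distance,
        name=feature.name,
        target_vertices=interior_ids,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_roi(roi: ROI, path) -> None:
    """Persist the ROI specification (not the derived masks) as JSON."""
    with open(path, "w") as f:
        json.dump(
            {
                "name": roi.name,
                "contour_vertex_ids": [int(i) for i in roi.selected],
                "interior_hint": None if roi.interior_hint is None else int(roi.interior_hint),
            },
            f,
            indent=2,
        )


def load_roi(path, mesh: Mesh) -> ROI:
    """Rebuild a ROI from its JSON specification against ``mesh``."""
    with open(path) as f:
        spec = json.load(f)
    return define_roi(
        mesh,
        spec["contour_vertex_ids"],
        interior_hint=spec.get("interior_hint"),
        name=spec.get("name", "roi"),
    )
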