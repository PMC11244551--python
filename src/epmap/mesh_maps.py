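"""Mesh geometry utilities, scattered-to-mesh interpolation, VTK export.

Scattered electro-anatomical samples are interpolated onto the vertices of
the triangulated chamber surface to form a continuous parametric field.
The default method is nearest neighbor (each vertex takes the value of its
closest sample); ``linear`` performs barycentric interpolation inside the
Delaunay hull of the samples with nearest-neighbor extrapolation outside;
``smooth`` is a thin-plate-spline fallback.  Vertices farther than
``max_distance`` from every sample are marked missing (NaN).

VTK export writes legacy ASCII PolyData with one scalar array per feature,
readable by standard VTK toolchains; a matching minimal reader is provided
for round-trip checks.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .data_model import FeatureMap, Mesh


def triangle_areas(mesh: Mesh) -> np.ndarray:
    """Per-triangle areas in mm^2 (half cross-product magnitude).

    Degenerate (zero-area) triangles yield 0 with a warning.
    """
    a = mesh.vertices[mesh.triangles[:, 0]]
    b = mesh.vertices[mesh.triangles[:, 1]]
    c = mesh.vertices[mesh.triangles[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    if np.any(areas == 0):
        warnings.warn("mesh contains degenerate (zero-area) triangles", stacklevel=2)
    return areas


def total_area(mesh: Mesh) -> float:
    """Total surface area in mm^2."""
    return float(triangle_areas(mesh).sum())


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

_METHODS = ("nearest", "linear", "smooth")


def interpolate_feature(
    point_positions: np.ndarray,
    point_values: np.ndarray,
    mesh: Mesh,
    method: str = "nearest",
    max_distance: float | None = None,
    name: str = "feature",
    target_vertices: np.ndarray | None = None,
) -> FeatureMap:
    """Interpolate scattered per-point values onto mesh vertices.

    Sample points carrying NaN values are ignored.  ``target_vertices``
    optionally restricts interpolation to a subset of vertex IDs (the rest
    are left missing) — used for ROI re-interpolation.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    pos = np.asarray(point_positions, dtype=np.float64).reshape(-1, 3)
    vals = np.asarray(point_values, dtype=np.float64).ravel()
    if len(pos) != len(vals):
        raise ValueError("positions and values must have equal length")
    ok = np.isfinite(vals)
    pos, vals = pos[ok], vals[ok]
    if len(pos) == 0:
        raise ValueError("no valid sample points to interpolate")

    verts = mesh.vertices
    if target_vertices is None:
        target_idx = np.arange(len(verts))
    else:
        target_idx = np.asarray(target_vertices, dtype=np.int64).ravel()
    targets = verts[target_idx]

    tree = cKDTree(pos)
    k = min(2, len(pos))
    dist, nearest = tree.query(targets, k=k)
    if k == 2:
        # deterministic tie rule: equal distances -> lowest sample index
        tie = dist[:, 0] == dist[:, 1]
        nn = np.where(tie, np.minimum(nearest[:, 0], nearest[:, 1]), nearest[:, 0])
        nn_dist = dist[:, 0]
    else:
        nn = np.atleast_1d(nearest)
        nn_dist = np.atleast_1d(dist)

    if method == "nearest" or len(pos) < 4:
        field_t = vals[nn]
    elif method == "linear":
        from scipy.interpolate import LinearNDInterpolator
        from scipy.spatial import QhullError

        try:
            interp = LinearNDInterpolator(pos, vals)
            field_t = interp(targets)
        except QhullError:
            field_t = np.full(len(targets), np.nan)
        outside = ~np.isfinite(field_t)
        field_t[outside] = vals[nn[outside]]  # nearest extrapolation
    else:  # smooth
        from scipy.interpolate import RBFInterpolator

        neighbors = min(len(pos), 64)
        interp = RBFInterpolator(pos, vals, kernel="thin_plate_spline", neighbors=neighbors)
        field_t = interp(targets)

    if max_distance is not None:
        field_t = np.where(nn_dist <= max_distance, field_t, np.nan)

    field = np.full(len(verts), np.nan)
    field[target_idx] = field_t
    return FeatureMap(
        name=name,
        point_values=np.asarray(point_values, dtype=np.float64).ravel(),
        vertex_field=field,
        method=method,
        max_distance=max_distance,
    )


# ---------------------------------------------------------------------------
# Legacy VTK PolyData I/O
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def export_vtk(mesh: Mesh, feature_maps, path) -> None:
    """Write a legacy ASCII VTK PolyData file with one scalar point-data
    array per feature map; missing values are encoded as NaN."""
    maps = list(feature_maps)
    for fm in maps:
        if len(fm.vertex_field) != mesh.n_vertices:
            raise ValueError(f"field {fm.name!r} does not match vertex count")
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("epmap parametric maps\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            f.write(f"{_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}\n")
        f.write(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if maps:
            f.write(f"POINT_DATA {mesh.n_vertices}\n")
            for fm in maps:
                f.write(f"SCALARS {fm.name} double 1\nLOOKUP_TABLE default\n")
                for x in fm.vertex_field:
                    f.write(f"{_fmt(x)}\n")


def read_vtk(path) -> tuple[Mesh, dict]:
    """Minimal reader for files written by :func:`export_vtk`.

    Returns ``(mesh, {array_name: vertex_field})``.
    """
    with open(path) as f:
        tokens_lines = [line.strip() for line in f]
    i = 0
    verts = tris = None
    fields: dict = {}
    n_pts = 0
    while i < len(tokens_lines):
        line = tokens_lines[i]
        if line.startswith("POINTS"):
            n_pts = int(line.split()[1])
            flat = []
            i += 1
            while len(flat) < 3 * n_pts:
                flat.extend(float(x) for x in tokens_lines[i].split())
                i += 1
            verts = np.array(flat).reshape(n_pts, 3)
            continue
        if line.startswith("POLYGONS"):
            n_poly = int(line.split()[1])
            tris = np.array(
                [[int(x) for x in tokens_lines[i + 1 + j].split()[1:]] for j in range(n_poly)],
                dtype=np.int64,
            ).reshape(n_poly, 3)
            i += 1 + n_poly
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            vals = []
            i += 2  # skip LOOKUP_TABLE
            while len(vals) < n_pts:
                vals.extend(float(x) for x in tokens_lines[i].split())
                i += 1
            fields[name] = np.array(vals)
            continue
        i += 1
    if verts is None:
        raise ValueError("no POINTS section found")
    return Mesh(verts, tris if tris is not None else np.zeros((0, 3), dtype=np.int64)), fields
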