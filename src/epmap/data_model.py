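"""Study container, native HDF5 persistence, MAT import and point filtering.

The study container mirrors the layout produced by electro-anatomical
mapping export pipelines: a triangulated chamber surface, a set of sampled
electro-anatomical points (acquisition position, surface projection,
unipolar/bipolar traces, contact force) and a shared 12-lead surface ECG,
plus the timing metadata (reference annotation, window of interest) needed
by all downstream feature extraction.

Units are millimetres, milliseconds, millivolts and grams throughout; all
indices are 0-based.  These conventions are recorded as attributes in the
native HDF5 container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

log = logging.getLogger(__name__)

FORMAT_VERSION = 1

STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


class FormatError(ValueError):
    """Raised when a native container is malformed or incompatible."""


class ImportFieldError(ValueError):
    """Raised when a MAT import lacks required fields."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mesh:
    """Triangulated surface: ``vertices`` (N, 3) in mm, ``triangles`` (M, 3)
    0-based vertex index triples."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        t = np.asarray(self.triangles, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if t.size and (t.ndim != 2 or t.shape[1] != 3):
            raise ValueError("triangles must be (M, 3)")
        t = t.reshape(-1, 3)
        if not np.all(np.isfinite(v)):
            raise ValueError("vertex coordinates must be finite")
        if t.size:
            if t.min() < 0 or t.max() >= len(v):
                raise ValueError("triangle index out of range")
            if (
                np.any(t[:, 0] == t[:, 1])
                or np.any(t[:, 1] == t[:, 2])
                or np.any(t[:, 0] == t[:, 2])
            ):
                raise ValueError("triangle repeats a vertex")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_triangles


@dataclass
class EAPoint:
    """One electro-anatomical sample site."""

    position: np.ndarray
    surface_position: np.ndarray
    unipolar: np.ndarray
    bipolar: np.ndarray | None = None
    contact_force: float | None = None
    valid: bool = True
    reason: str = "ok"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        self.surface_position = np.asarray(
            self.surface_position, dtype=np.float64
        ).reshape(3)
        self.unipolar = np.asarray(self.unipolar, dtype=np.float64).ravel()
        if self.bipolar is not None:
            self.bipolar = np.asarray(self.bipolar, dtype=np.float64).ravel()
        if self.contact_force is not None:
            self.contact_force = float(self.contact_force)
            if self.contact_force < 0:
                raise ValueError("contact_force must be >= 0")


@dataclass
class SurfaceECG:
    """12-lead surface ECG: mapping lead name -> trace (mV)."""

    leads: dict
    sampling_rate: float

    def __post_init__(self) -> None:
        self.leads = {k: np.asarray(v, dtype=np.float64).ravel() for k, v in self.leads.items()}
        unknown = set(self.leads) - set(STANDARD_LEADS)
        if unknown:
            raise ValueError(f"unknown lead names: {sorted(unknown)}")
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) > 1:
            raise ValueError("all leads must share the same length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __getitem__(self, lead: str) -> np.ndarray:
        return self.leads[lead]


@dataclass
class EAMStudy:
    """One acquisition phase: mesh + electro-anatomical points + ECG + timing.

    ``reference_annotation`` is the timing reference in ms from the start of
    every trace; ``woi`` is the window of interest (ms) relative to it.
    """

    mesh: Mesh
    points: list
    ecg: SurfaceECG
    sampling_rate: float
    reference_annotation: float = 2000.0
    woi: tuple = (-100.0, 100.0)
    phase_label: str = ""

    def __post_init__(self) -> None:
        self.woi = (float(self.woi[0]), float(self.woi[1]))
        if self.woi[0] >= self.woi[1]:
            raise ValueError("woi[0] must be < woi[1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.points:
            n = len(self.points[0].unipolar)
            if any(len(p.unipolar) != n for p in self.points):
                raise ValueError("all unipolar traces must share a length")
            t_lo = self.reference_annotation + self.woi[0]
            t_hi = self.reference_annotation + self.woi[1]
            extent_ms = (n - 1) * 1000.0 / self.sampling_rate
            if t_lo < 0 or t_hi > extent_ms:
                raise ValueError("window of interest falls outside trace extent")

    # -- array views ---------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points]).reshape(-1, 3)

    @property
    def surface_positions(self) -> np.ndarray:
        return np.array([p.surface_position for p in self.points]).reshape(-1, 3)

    @property
    def unipolar(self) -> np.ndarray:
        """(P, T) matrix of unipolar traces."""
        if not self.points:
            return np.zeros((0, 0))
        return np.vstack([p.unipolar for p in self.points])

    @property
    def contact_forces(self) -> np.ndarray:
        """(P,) forces in grams; NaN where missing."""
        return np.array(
            [np.nan if p.contact_force is None else p.contact_force for p in self.points]
        )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.array([p.valid for p in self.points], dtype=bool)

    def sample_of_ms(self, t_ms: float) -> int:
        return int(round(t_ms * self.sampling_rate / 1000.0))

    def ms_of_sample(self, i: int) -> float:
        return i * 1000.0 / self.sampling_rate


@dataclass
class FeatureMap:
    """A named scalar feature: per-point values plus an interpolated
    per-vertex field (NaN marks missing vertices)."""

    name: str
    point_values: np.ndarray
    vertex_field: np.ndarray
    method: str = "nearest"
    max_distance: float | None = None

    def __post_init__(self) -> None:
        self.point_values = np.asarray(self.point_values, dtype=np.float64).ravel()
        self.vertex_field = np.asarray(self.vertex_field, dtype=np.float64).ravel()


# ---------------------------------------------------------------------------
# Equality helper (arrays make dataclass eq unusable)
# ---------------------------------------------------------------------------


def _arr_eq(a, b) -> bool:
    a, b = np.asarray(a), np.asarray(b)
    return a.shape == b.shape and np.array_equal(a, b, equal_nan=True)


def studies_equal(a: EAMStudy, b: EAMStudy) -> bool:
    """Bit-exact equality of all arrays and metadata."""
    if a.n_points != b.n_points:
        return False
    if not (_arr_eq(a.mesh.vertices, b.mesh.vertices) and _arr_eq(a.mesh.triangles, b.mesh.triangles)):
        return False
    for pa, pb in zip(a.points, b.points):
        if not (_arr_eq(pa.position, pb.position) and _arr_eq(pa.surface_position, pb.surface_position)):
            return False
        if not _arr_eq(pa.unipolar, pb.unipolar):
            return False
        if (pa.bipolar is None) != (pb.bipolar is None):
            return False
        if pa.bipolar is not None and not _arr_eq(pa.bipolar, pb.bipolar):
            return False
        fa = np.nan if pa.contact_force is None else pa.contact_force
        fb = np.nan if pb.contact_force is None else pb.contact_force
        if not (fa == fb or (np.isnan(fa) and np.isnan(fb))):
            return False
        if pa.valid != pb.valid or pa.reason != pb.reason:
            return False
    if set(a.ecg.leads) != set(b.ecg.leads):
        return False
    for lead in a.ecg.leads:
        if not _arr_eq(a.ecg[lead], b.ecg[lead]):
            return False
    return (
        a.sampling_rate == b.sampling_rate
        and a.reference_annotation == b.reference_annotation
        and a.woi == b.woi
        and a.phase_label == b.phase_label
    )


# ---------------------------------------------------------------------------
# Native HDF5 container
# ---------------------------------------------------------------------------

_REQUIRED_DATASETS = (
    "/mesh/vertices",
    "/mesh/triangles",
    "/points/position",
    "/points/surface_position",
    "/points/contact_force",
    "/signals/unipolar",
)


def save_study(study: EAMStudy, path) -> None:
    """Write ``study`` to the native HDF5 container at ``path``.

    Layout: /mesh/{vertices,triangles}, /points/{position, surface_position,
    contact_force, valid, reason}, /signals/unipolar (P x T, mV),
    /signals/bipolar (optional), /ecg/<lead>; root attributes
    sampling_rate_hz, reference_annotation_ms, woi_ms, phase_label,
    format_version.
    """
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["sampling_rate_hz"] = float(study.sampling_rate)
        f.attrs["reference_annotation_ms"] = float(study.reference_annotation)
        f.attrs["woi_ms"] = np.asarray(study.woi, dtype=np.float64)
        f.attrs["phase_label"] = study.phase_label
        f.attrs["units"] = "mm/ms/mV/grams"
        f.create_dataset("mesh/vertices", data=study.mesh.vertices)
        f.create_dataset("mesh/triangles", data=study.mesh.triangles)
        f.create_dataset("points/position", data=study.positions)
        f.create_dataset("points/surface_position", data=study.surface_positions)
        f.create_dataset("points/contact_force", data=study.contact_forces)
        f.create_dataset("points/valid", data=study.valid_mask)
        f.create_dataset(
            "points/reason",
            data=np.array([p.reason for p in study.points], dtype=object),
            dtype=str_dt,
        )
        f.create_dataset("signals/unipolar", data=study.unipolar)
        bipolars = [p.bipolar for p in study.points]
        if study.points and all(b is not None for b in bipolars):
            f.create_dataset("signals/bipolar", data=np.vstack(bipolars))
        for lead, trace in study.ecg.leads.items():
            f.create_dataset(f"ecg/{lead}", data=trace)


def load_study(path) -> EAMStudy:
    """Read a study written by :func:`save_study`.

    Raises :class:`FormatError` naming the first missing dataset, or on a
    format-version mismatch.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version is None or int(version) != FORMAT_VERSION:
            raise FormatError(
                f"format_version mismatch: expected {FORMAT_VERSION}, got {version}"
            )
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise FormatError(f"missing {name}")
        mesh = Mesh(f["mesh/vertices"][()], f["mesh/triangles"][()])
        pos = f["points/position"][()].reshape(-1, 3)
        spos = f["points/surface_position"][()].reshape(-1, 3)
        force = f["points/contact_force"][()].ravel()
        uni = f["signals/unipolar"][()]
        n = len(pos)
        uni = uni.reshape(n, -1) if n else np.zeros((0, 0))
        bip = f["signals/bipolar"][()] if "signals/bipolar" in f else None
        valid = f["points/valid"][()] if "points/valid" in f else np.ones(n, bool)
        if "points/reason" in f:
            reason = [r.decode() if isinstance(r, bytes) else str(r) for r in f["points/reason"][()]]
        else:
            reason = ["ok"] * n
        points = [
            EAPoint(
                position=pos[i],
                surface_position=spos[i],
                unipolar=uni[i],
                bipolar=None if bip is None else bip[i],
                contact_force=None if np.isnan(force[i]) else float(force[i]),
                valid=bool(valid[i]),
                reason=reason[i],
            )
            for i in range(n)
        ]
        fs = float(f.attrs["sampling_rate_hz"])
        leads = {lead: f["ecg"][lead][()] for lead in f["ecg"]} if "ecg" in f else {}
        ecg = SurfaceECG(leads=leads, sampling_rate=fs)
        return EAMStudy(
            mesh=mesh,
            points=points,
            ecg=ecg,
            sampling_rate=fs,
            reference_annotation=float(f.attrs["reference_annotation_ms"]),
            woi=tuple(np.asarray(f.attrs["woi_ms"], dtype=float)),
            phase_label=str(f.attrs.get("phase_label", "")),
        )


# ---------------------------------------------------------------------------
# OpenEP-style MAT import
# ---------------------------------------------------------------------------


def _mat_get(obj, name):
    """Attribute/key access across scipy mat_struct, dict and h5py groups."""
    if obj is None:
        return None
    if isinstance(obj, Mapping) or isinstance(obj, h5py.Group):
        return obj[name] if name in obj else None
    return getattr(obj, name, None)


def _as_2d(a, width: int) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 1:
        a = a.reshape(-1, width) if a.size else a.reshape(0, width)
    if a.shape[-1] != width and a.shape[0] == width:
        a = a.T
    return a


def import_openep(path) -> EAMStudy:
    """Import an OpenEP-style ``userdata`` MAT container.

    Expected fields (MATLAB struct ``userdata``)::

        surface.triRep.X                (N x 3) surface vertices, mm
        surface.triRep.Triangulation    (M x 3) 1-based triangle indices
        electric.egmX                   (P x 3) acquisition positions
        electric.egmSurfX               (P x 3) surface projections (optional)
        electric.egm                    (P x T) unipolar traces, mV
        electric.egmBipolar             (P x T) bipolar traces (optional)
        electric.force                  (P,)    contact force, g (optional)
        electric.ecg                    (12 x T) or (T,) surface ECG
        electric.sampleFrequency        Hz (optional, default 1000)
        electric.annotations.referenceAnnotation   ms
        electric.annotations.woi        (2,) ms

    Points whose unipolar trace is entirely NaN are flagged invalid.  If
    ``egmSurfX`` is absent, surface positions are computed by projection
    onto the surface and a warning is logged.  Unknown extra fields are
    ignored with a log line.
    """
    import scipy.io

    try:
        mat = scipy.io.loadmat(str(path), squeeze_me=True, struct_as_record=False)
        userdata = mat.get("userdata")
    except NotImplementedError:  # MAT v7.3 is HDF5-backed
        f = h5py.File(path, "r")
        userdata = f.get("userdata")
    if userdata is None:
        raise ImportFieldError("no 'userdata' structure found in MAT file")

    surface = _mat_get(userdata, "surface")
    electric = _mat_get(userdata, "electric")
    missing = []
    tri_rep = _mat_get(surface, "triRep")
    verts = _mat_get(tri_rep, "X")
    tris = _mat_get(tri_rep, "Triangulation")
    egm_x = _mat_get(electric, "egmX")
    egm = _mat_get(electric, "egm")
    annotations = _mat_get(electric, "annotations")
    ref = _mat_get(annotations, "referenceAnnotation")
    woi = _mat_get(annotations, "woi")
    for name, value in [
        ("userdata.surface.triRep.X", verts),
        ("userdata.surface.triRep.Triangulation", tris),
        ("userdata.electric.egmX", egm_x),
        ("userdata.electric.egm", egm),
        ("userdata.electric.annotations.referenceAnnotation", ref),
        ("userdata.electric.annotations.woi", woi),
    ]:
        if value is None:
            missing.append(name)
    if missing:
        raise ImportFieldError("missing userdata fields: " + ", ".join(missing))

    verts = _as_2d(np.asarray(verts)[()], 3)
    tris = np.asarray(np.asarray(tris)[()], dtype=np.int64)
    if tris.ndim == 2 and tris.shape[0] == 3 and tris.shape[1] != 3:
        tris = tris.T
    mesh = Mesh(verts, tris.reshape(-1, 3) - 1)  # MATLAB is 1-based

    egm_x = _as_2d(np.asarray(egm_x)[()], 3)
    n = len(egm_x)
    egm = np.asarray(np.asarray(egm)[()], dtype=np.float64)
    egm = egm.reshape(n, -1) if egm.ndim == 1 or egm.shape[0] == n else egm.T

    surf_x = _mat_get(electric, "egmSurfX")
    if surf_x is not None:
        surf_x = _as_2d(np.asarray(surf_x)[()], 3)
    else:
        log.warning("egmSurfX absent; projecting egmX onto the surface")
        surf_x = project_to_surface(egm_x, mesh)

    bip = _mat_get(electric, "egmBipolar")
    if bip is not None:
        bip = np.asarray(np.asarray(bip)[()], dtype=np.float64)
        bip = bip if bip.shape[0] == n else bip.T
    force = _mat_get(electric, "force")
    force = None if force is None else np.asarray(np.asarray(force)[()], float).ravel()

    fs = _mat_get(electric, "sampleFrequency")
    fs = 1000.0 if fs is None else float(np.asarray(fs)[()].item() if hasattr(np.asarray(fs)[()], "item") else fs)

    ecg_raw = _mat_get(electric, "ecg")
    leads: dict = {}
    if ecg_raw is not None:
        ecg_arr = np.asarray(np.asarray(ecg_raw)[()], dtype=np.float64)
        if ecg_arr.ndim == 1:
            leads = {"V2": ecg_arr}
        else:
            if ecg_arr.shape[0] != 12 and ecg_arr.shape[1] == 12:
                ecg_arr = ecg_arr.T
            for i, lead in enumerate(STANDARD_LEADS[: ecg_arr.shape[0]]):
                leads[lead] = ecg_arr[i]

    points = []
    for i in range(n):
        trace = egm[i]
        has_trace = np.any(np.isfinite(trace))
        points.append(
            EAPoint(
                position=egm_x[i],
                surface_position=surf_x[i],
                unipolar=np.nan_to_num(trace) if not has_trace else trace,
                bipolar=None if bip is None else bip[i],
                contact_force=None if force is None or np.isnan(force[i]) else float(force[i]),
                valid=bool(has_trace),
                reason="ok" if has_trace else "missing_trace",
            )
        )

    woi_arr = np.asarray(np.asarray(woi)[()], dtype=float).ravel()
    if woi_arr.size > 2:  # per-point woi rows: use the first
        woi_arr = woi_arr[:2]
    return EAMStudy(
        mesh=mesh,
        points=points,
        ecg=SurfaceECG(leads=leads, sampling_rate=fs),
        sampling_rate=fs,
        reference_annotation=float(np.asarray(ref, dtype=float).ravel()[0]),
        woi=(float(woi_arr[0]), float(woi_arr[1])),
        phase_label="imported",
    )


# ---------------------------------------------------------------------------
# Acquisition-quality filtering
# ---------------------------------------------------------------------------


def filter_points_by_force(
    study: EAMStudy, min_g: float = 5.0, max_g: float = 25.0
) -> EAMStudy:
    """Return a new study keeping points with ``min_g <= force <= max_g``.

    Bounds are inclusive.  Points with missing force are retained but
    flagged ``force_unknown``.  The input study is not modified.
    """
    if min_g > max_g:
        raise ValueError(f"min_g ({min_g}) must be <= max_g ({max_g})")
    kept = []
    for p in study.points:
        if p.contact_force is None:
            q = replace(
                p,
                position=p.position.copy(),
                surface_position=p.surface_position.copy(),
                unipolar=p.unipolar.copy(),
                bipolar=None if p.bipolar is None else p.bipolar.copy(),
                reason="force_unknown" if p.reason == "ok" else p.reason,
            )
            kept.append(q)
        elif min_g <= p.contact_force <= max_g:
            kept.append(
                replace(
                    p,
                    position=p.position.copy(),
                    surface_position=p.surface_position.copy(),
                    unipolar=p.unipolar.copy(),
                    bipolar=None if p.bipolar is None else p.bipolar.copy(),
                )
            )
    if study.points and not kept:
        warnings.warn("contact-force filter removed every point", stacklevel=2)
    return EAMStudy(
        mesh=study.mesh,
        points=kept,
        ecg=study.ecg,
        sampling_rate=study.sampling_rate,
        reference_annotation=study.reference_annotation,
        woi=study.woi,
        phase_label=study.phase_label,
    )


# ---------------------------------------------------------------------------
# Surface projection
# ---------------------------------------------------------------------------


def _closest_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a, b, c); vectorized over
    triangles (Ericson's region test)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex B
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
        settle((d6 >= 0) & (d5 <= d6), c)  # vertex C
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
        denom_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
        settle(
            (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
            b + w_bc[:, None] * (c - b),
        )
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v = vb / denom
        w = vc / denom
    settle(np.ones(len(a), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


def project_to_surface(positions: np.ndarray, mesh: Mesh) -> np.ndarray:
    """Project each position onto its closest point on the mesh surface
    (faces, edges and vertices all considered)."""
    if mesh.n_triangles == 0:
        raise ValueError("cannot project onto an empty mesh")
    positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
    a = mesh.vertices[mesh.triangles[:, 0]]
    b = mesh.vertices[mesh.triangles[:, 1]]
    c = mesh.vertices[mesh.triangles[:, 2]]
    out = np.empty_like(positions)
    for i, p in enumerate(positions):
        cand = _closest_on_triangles(p, a, b, c)
        d2 = np.einsum("ij,ij->i", cand - p, cand - p)
        out[i] = cand[np.argmin(d2)]
    return out


# ---------------------------------------------------------------------------
# Optional zero-phase band-pass preprocessing (acquisition-side defaults)
# ---------------------------------------------------------------------------


def band_pass(
    traces: np.ndarray, fs: float, lo_hz: float, hi_hz: float, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; defaults mirror common acquisition
    settings (unipolar 1-240 Hz, bipolar 30-500 Hz).  Off by default in all
    pipelines."""
    from scipy.signal import butter, filtfilt

    nyq = fs / 2.0
    hi_hz = min(hi_hz, 0.99 * nyq)
    b, a = butter(order, [lo_hz / nyq, hi_hz / nyq], btype="band")
    return filtfilt(b, a, np.asarray(traces, dtype=np.float64), axis=-1)
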