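"""Synthetic electro-anatomical study generator with known ground truth.

Every downstream stage (feature extraction, mapping, ROI selection, pairing,
reporting) is testable against the values planted here.  The unipolar
electrogram template is a sum of error-function steps — baseline, an R/S
biphasic deflection with a smooth sigmoidal downstroke, an elevated ST
plateau and an asymmetric T wave — chosen so that every fiducial is
analytically placeable:

* the steepest negative slope sits at ``ref_ms + at_offset_ms``;
* the steepest positive T-wave slope sits ``ari_ms`` later;
* the value on the ST plateau (where the study J-point falls) minus the
  baseline equals ``jel_mv`` exactly before noise.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr  # standard normal CDF

from .data_model import EAMStudy, EAPoint, Mesh, SurfaceECG, project_to_surface

# Template geometry (ms).  The ST plateau spans roughly
# [at_offset + 5*RS_DOWN_SIGMA, at_offset + ari - 5*T_UP_SIGMA]; with the
# default J-point offset of 40 ms this requires at_offset <= ~25 and
# ari >= ~150 for the planted jel to be exact to machine precision.
RS_UP_LEAD_MS = 14.0
RS_UP_SIGMA_MS = 5.0
RS_DOWN_SIGMA_MS = 3.0
T_UP_SIGMA_MS = 10.0
T_DOWN_LAG_MS = 80.0
T_DOWN_SIGMA_MS = 25.0

DEFAULT_JPOINT_OFFSET_MS = 40.0

# relative amplitude of each limb lead w.r.t. the generated V2 template
_LEAD_SCALE = {
    "I": 0.35, "II": 0.55, "III": 0.25, "aVR": -0.45, "aVL": 0.15,
    "aVF": 0.4, "V1": 0.8, "V2": 1.0, "V3": 0.9, "V4": 0.7,
    "V5": 0.55, "V6": 0.45,
}


@dataclass
class GroundTruth:
    """Planted per-point truth for a synthetic study."""

    at_ms: np.ndarray
    ari_ms: np.ndarray
    jel_mv: np.ndarray
    jpoint_sample: int
    seed: int


@dataclass
class PrePostTruth:
    """Truth for a pre/post pair: surviving pre indices and per-point
    feature shifts applied in the post phase."""

    pre_indices: np.ndarray
    delta_at_ms: np.ndarray
    delta_ari_ms: np.ndarray
    delta_jel_mv: np.ndarray
    pre: GroundTruth
    post: GroundTruth


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


def _subdivide(v: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One midpoint subdivision step, re-projected to the unit sphere."""
    verts = list(v)
    cache: dict = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = (v[i] + v[j]) / 2.0
            m /= np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    new_f = []
    for a, b, c in f:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_f += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts), np.array(new_f, dtype=np.int64)


def make_rv_mesh(
    n_subdivisions: int = 3,
    bulge_amplitude: float = 8.0,
    seed: int = 0,
    radii: tuple = (30.0, 25.0, 45.0),
    bulge_width_rad: float = 0.5,
) -> tuple[Mesh, np.ndarray]:
    """Closed deformed-ellipsoid surface with a localized bulge (an outflow
    tract analog).

    Returns ``(mesh, patch_vertex_ids)`` where the patch collects the
    vertices inside the bulge region.  Deterministic given ``seed``.
    """
    if n_subdivisions < 0:
        raise ValueError("n_subdivisions must be >= 0")
    v, f = _icosahedron()
    for _ in range(n_subdivisions):
        v, f = _subdivide(v, f)
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    theta = np.arccos(np.clip(v @ direction, -1.0, 1.0))
    patch = np.nonzero(theta < bulge_width_rad)[0]
    scaled = v * np.asarray(radii, dtype=np.float64)
    if bulge_amplitude:
        scaled = scaled + v * (bulge_amplitude * np.exp(-((theta / bulge_width_rad) ** 2)))[:, None]
    return Mesh(scaled, f), patch


# ---------------------------------------------------------------------------
# Electrogram / ECG templates
# ---------------------------------------------------------------------------


def _step(t_ms: np.ndarray, center_ms: float, sigma_ms: float, area: float) -> np.ndarray:
    """Smooth step of total height ``area`` centered at ``center_ms``; the
    derivative is a Gaussian peaking exactly at the center."""
    return area * ndtr((t_ms - center_ms) / sigma_ms)


def make_unipolar_egm(
    fs: float,
    ref_ms: float,
    at_offset_ms: float,
    ari_ms: float,
    rs_amp_mv: float = 2.0,
    t_amp_mv: float = 1.0,
    jel_mv: float = 0.0,
    noise_sd_mv: float = 0.0,
    seed: int | None = None,
    duration_ms: float = 3000.0,
) -> np.ndarray:
    """Synthetic unipolar electrogram with analytically placed fiducials.

    The depolarization fiducial (steepest negative slope) lies at
    ``ref_ms + at_offset_ms``; the repolarization fiducial (steepest
    positive T-wave slope) ``ari_ms`` later; the ST level minus baseline is
    ``jel_mv``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if ari_ms <= 0:
        raise ValueError("ari_ms must be positive")
    t_dep = ref_ms + at_offset_ms
    t_rep = t_dep + ari_ms
    n = int(round(duration_ms * fs / 1000.0))
    if not (4 * RS_UP_SIGMA_MS + RS_UP_LEAD_MS) < t_dep:
        raise ValueError("depolarization fiducial too close to trace start")
    if t_rep + T_DOWN_LAG_MS + 4 * T_DOWN_SIGMA_MS >= duration_ms:
        raise ValueError("repolarization fiducial outside trace")
    t = np.arange(n) * 1000.0 / fs
    if rs_amp_mv + jel_mv <= 0:
        raise ValueError("rs_amp_mv + jel_mv must be positive")
    # QRS downstroke magnitude is rs_amp_mv regardless of jel so the
    # depolarization fiducial stays equally sharp for every planted value.
    u = (
        _step(t, t_dep - RS_UP_LEAD_MS, RS_UP_SIGMA_MS, rs_amp_mv + jel_mv)
        + _step(t, t_dep, RS_DOWN_SIGMA_MS, -rs_amp_mv)
        + _step(t, t_rep, T_UP_SIGMA_MS, t_amp_mv)
        + _step(t, t_rep + T_DOWN_LAG_MS, T_DOWN_SIGMA_MS, -(t_amp_mv + jel_mv))
    )
    if noise_sd_mv > 0:
        u = u + np.random.default_rng(seed).normal(0.0, noise_sd_mv, size=n)
    return u


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((t - center) ** 2) / (2.0 * sigma**2))


def make_v2_trace(
    fs: float,
    ref_ms: float,
    duration_ms: float = 3000.0,
    r_amp_mv: float = 1.2,
    s_amp_mv: float = 1.0,
) -> np.ndarray:
    """Surface-lead template: R wave, an asymmetric S wave whose amplitude
    minimum lies exactly at ``ref_ms`` (the activation reference), a QRS
    offset near ``ref_ms + 40`` ms, and a low broad T wave."""
    n = int(round(duration_ms * fs / 1000.0))
    t = np.arange(n) * 1000.0 / fs
    s_wave = np.where(
        t < ref_ms, _gauss(t, ref_ms, 5.0), _gauss(t, ref_ms, 15.0)
    )
    return (
        r_amp_mv * _gauss(t, ref_ms - 35.0, 7.0)
        - s_amp_mv * s_wave
        + 0.3 * _gauss(t, ref_ms + 300.0, 40.0)
    )


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------


def sample_surface_points(mesh: Mesh, n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted uniform sampling of ``n`` points on the mesh surface."""
    a = mesh.vertices[mesh.triangles[:, 0]]
    b = mesh.vertices[mesh.triangles[:, 1]]
    c = mesh.vertices[mesh.triangles[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    tri = rng.choice(len(areas), size=n, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    w0, w1, w2 = 1.0 - r1, r1 * (1.0 - r2), r1 * r2
    return w0[:, None] * a[tri] + w1[:, None] * b[tri] + w2[:, None] * c[tri]


def _field_values(field, positions: np.ndarray) -> np.ndarray:
    if callable(field):
        return np.asarray(field(positions), dtype=np.float64).reshape(len(positions))
    return np.full(len(positions), float(field))


def make_study(
    mesh: Mesh,
    n_points: int,
    at_field=20.0,
    ari_field=250.0,
    jel_field=1.0,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_annotation: float = 2000.0,
    woi: tuple = (-100.0, 100.0),
    duration_ms: float = 3000.0,
    jpoint_offset_ms: float = DEFAULT_JPOINT_OFFSET_MS,
    force_range: tuple = (2.0, 30.0),
    phase_label: str = "pre",
) -> tuple[EAMStudy, GroundTruth]:
    """Build a complete synthetic study.

    ``at_field``, ``ari_field`` and ``jel_field`` are scalars or callables
    mapping an (n, 3) array of surface positions to per-point values
    (ms / ms / mV).  Contact forces are drawn uniformly from
    ``force_range`` so the 5-25 g acquisition filter is exercised.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    pos = sample_surface_points(mesh, n_points, rng)
    at = _field_values(at_field, pos)
    ari = _field_values(ari_field, pos)
    jel = _field_values(jel_field, pos)
    forces = rng.uniform(force_range[0], force_range[1], size=n_points)

    v2 = make_v2_trace(fs, reference_annotation, duration_ms)
    leads = {name: scale * v2 for name, scale in _LEAD_SCALE.items()}
    ecg = SurfaceECG(leads=leads, sampling_rate=fs)

    child_seeds = rng.integers(0, 2**31 - 1, size=n_points)
    points = []
    for i in range(n_points):
        uni = make_unipolar_egm(
            fs,
            reference_annotation,
            at[i],
            ari[i],
            jel_mv=jel[i],
            noise_sd_mv=noise_sd,
            seed=int(child_seeds[i]),
            duration_ms=duration_ms,
        )
        points.append(
            EAPoint(
                position=pos[i],
                surface_position=pos[i],
                unipolar=uni,
                contact_force=float(forces[i]),
            )
        )
    study = EAMStudy(
        mesh=mesh,
        points=points,
        ecg=ecg,
        sampling_rate=fs,
        reference_annotation=reference_annotation,
        woi=woi,
        phase_label=phase_label,
    )
    truth = GroundTruth(
        at_ms=at,
        ari_ms=ari,
        jel_mv=jel,
        jpoint_sample=int(round((reference_annotation + jpoint_offset_ms) * fs / 1000.0)),
        seed=seed,
    )
    return study, truth


def make_pre_post(
    study: EAMStudy,
    truth: GroundTruth,
    delta_fields: dict | None = None,
    dropout: float = 0.36,
    jitter_mm: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[EAMStudy, EAMStudy, PrePostTruth]:
    """Derive a post-phase study from a pre-phase one.

    Each pre point is dropped independently with probability ``dropout``
    (the default reflects the typical point loss of a short-half-life drug
    challenge), surviving positions are perturbed by isotropic Gaussian
    jitter and re-projected onto the surface, and electrograms are
    regenerated with per-point feature values shifted by ``delta_fields``
    (keys ``at``, ``ari``, ``jel``; scalars or callables of position).
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be >= 0")
    delta_fields = delta_fields or {}
    rng = np.random.default_rng(seed)
    n = study.n_points
    survive = rng.random(n) >= dropout
    idx = np.nonzero(survive)[0]

    pre_pos = study.surface_positions[idx]
    if jitter_mm > 0:
        post_pos = pre_pos + rng.normal(0.0, jitter_mm, size=pre_pos.shape)
        post_pos = project_to_surface(post_pos, study.mesh)
    else:
        post_pos = pre_pos.copy()

    d_at = _field_values(delta_fields.get("at", 0.0), post_pos)
    d_ari = _field_values(delta_fields.get("ari", 0.0), post_pos)
    d_jel = _field_values(delta_fields.get("jel", 0.0), post_pos)

    fs = study.sampling_rate
    duration_ms = study.points[0].unipolar.size * 1000.0 / fs if study.points else 3000.0
    child_seeds = rng.integers(0, 2**31 - 1, size=len(idx))
    at_post = truth.at_ms[idx] + d_at
    ari_post = truth.ari_ms[idx] + d_ari
    jel_post = truth.jel_mv[idx] + d_jel
    points = []
    for k, i in enumerate(idx):
        uni = make_unipolar_egm(
            fs,
            study.reference_annotation,
            at_post[k],
            ari_post[k],
            jel_mv=jel_post[k],
            noise_sd_mv=noise_sd,
            seed=int(child_seeds[k]),
            duration_ms=duration_ms,
        )
        src = study.points[i]
        points.append(
            EAPoint(
                position=post_pos[k],
                surface_position=post_pos[k],
                unipolar=uni,
                contact_force=src.contact_force,
            )
        )
    post = EAMStudy(
        mesh=study.mesh,
        points=points,
        ecg=study.ecg,
        sampling_rate=fs,
        reference_annotation=study.reference_annotation,
        woi=study.woi,
        phase_label="post",
    )
    post_truth = GroundTruth(
        at_ms=at_post,
        ari_ms=ari_post,
        jel_mv=jel_post,
        jpoint_sample=truth.jpoint_sample,
        seed=seed,
    )
    return (
        study,
        post,
        PrePostTruth(
            pre_indices=idx,
            delta_at_ms=d_at,
            delta_ari_ms=d_ari,
            delta_jel_mv=d_jel,
            pre=truth,
            post=post_truth,
        ),
    )
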