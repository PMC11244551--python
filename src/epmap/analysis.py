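"""Threshold-area quantification, summary statistics and report tables.

Areas are quantified per triangle: a triangle counts toward a condition
iff all three of its vertex values satisfy it (missing vertices never
satisfy).  Alternative discretizations (majority vote, centroid value) are
selectable since the choice is a convention.  Percentages are relative to
the total mesh area.

Summary statistics: mean, median, sample SD (n-1 denominator; missing for
n < 2), IQR with linearly interpolated quartiles (type-7 style) and range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import EAMStudy, Mesh
from .mesh_maps import interpolate_feature, total_area, triangle_areas
from .roi import ROI, restrict_and_reinterpolate, roi_membership
from .signal_features import FeatureConfig, extract_features

_OPS = ("<", "<=", ">", ">=", "range")


@dataclass(frozen=True)
class Condition:
    """A per-vertex predicate on a named feature field."""

    feature: str
    op: str
    value: float | tuple

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"op must be one of {_OPS}")
        if self.op == "range":
            lo, hi = self.value
            if lo > hi:
                raise ValueError("range condition requires lo <= hi")

    def evaluate(self, field: np.ndarray) -> np.ndarray:
        """Boolean mask; NaN (missing) values never satisfy."""
        field = np.asarray(field, dtype=np.float64)
        with np.errstate(invalid="ignore"):
            if self.op == "<":
                m = field < self.value
            elif self.op == "<=":
                m = field <= self.value
            elif self.op == ">":
                m = field > self.value
            elif self.op == ">=":
                m = field >= self.value
            else:
                lo, hi = self.value
                m = (field >= lo) & (field <= hi)
        return m & np.isfinite(field)

    def label(self) -> str:
        if self.op == "range":
            return f"{self.feature} in [{self.value[0]}, {self.value[1]}]"
        return f"{self.feature} {self.op} {self.value}"


# Example voltage-abnormality thresholds shipped as named presets.
PRESETS = {
    "uni_le_4_4": Condition("uni_pp_mv", "<=", 4.4),
    "uni_le_5_3": Condition("uni_pp_mv", "<=", 5.3),
}


def _triangle_mask(mesh: Mesh, vertex_mask: np.ndarray, rule: str) -> np.ndarray:
    counts = vertex_mask[mesh.triangles].sum(axis=1)
    if rule == "all":
        return counts == 3
    if rule == "majority":
        return counts >= 2
    raise ValueError("rule must be 'all', 'majority' or 'centroid'")


def area_where(
    mesh: Mesh, vertex_field: np.ndarray, condition: Condition, rule: str = "all"
) -> tuple[float, float]:
    """Surface area (mm^2, percent of total) where the field satisfies the
    condition."""
    vertex_field = np.asarray(vertex_field, dtype=np.float64)
    if len(vertex_field) != mesh.n_vertices:
        raise ValueError("field length does not match vertex count")
    areas = triangle_areas(mesh)
    if rule == "centroid":
        centroid_vals = np.nanmean(vertex_field[mesh.triangles], axis=1)
        tri_mask = condition.evaluate(centroid_vals)
    else:
        tri_mask = _triangle_mask(mesh, condition.evaluate(vertex_field), rule)
    mm2 = float(areas[tri_mask].sum())
    tot = float(areas.sum())
    return mm2, 100.0 * mm2 / tot if tot > 0 else 0.0


def area_where_joint(
    mesh: Mesh,
    field_a: np.ndarray,
    cond_a: Condition,
    field_b: np.ndarray,
    cond_b: Condition,
    rule: str = "all",
) -> tuple[float, float]:
    """Area where both conditions hold; equals :func:`area_where` on the
    logical AND of the two vertex masks."""
    field_a = np.asarray(field_a, dtype=np.float64)
    field_b = np.asarray(field_b, dtype=np.float64)
    if len(field_a) != mesh.n_vertices or len(field_b) != mesh.n_vertices:
        raise ValueError("fields must live on the same mesh")
    if rule == "centroid":
        ca = np.nanmean(field_a[mesh.triangles], axis=1)
        cb = np.nanmean(field_b[mesh.triangles], axis=1)
        tri_mask = cond_a.evaluate(ca) & cond_b.evaluate(cb)
    else:
        tri_mask = _triangle_mask(mesh, cond_a.evaluate(field_a), rule) & _triangle_mask(
            mesh, cond_b.evaluate(field_b), rule
        )
    areas = triangle_areas(mesh)
    mm2 = float(areas[tri_mask].sum())
    tot = float(areas.sum())
    return mm2, 100.0 * mm2 / tot if tot > 0 else 0.0


def binary_field(vertex_field: np.ndarray, condition: Condition) -> np.ndarray:
    """Two-valued field for two-color map rendering: 1 where the condition
    holds, 0 elsewhere, NaN preserved."""
    vertex_field = np.asarray(vertex_field, dtype=np.float64)
    out = condition.evaluate(vertex_field).astype(np.float64)
    out[~np.isfinite(vertex_field)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass
class ReportRow:
    study: str
    roi: str
    feature: str
    n: int
    mean: float
    median: float
    sd: float
    iqr: float
    range: float


def summarize(values, label: str = "", feature: str = "", study: str = "", roi: str = "ALL") -> ReportRow:
    """Summary statistics of a value set (NaNs are dropped).

    SD uses the n-1 denominator and is reported missing for n < 2;
    quartiles use linear interpolation.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    n = len(v)
    if n == 0:
        return ReportRow(study, roi, feature or label, 0, np.nan, np.nan, np.nan, np.nan, np.nan)
    q1, q3 = np.percentile(v, [25, 75])
    return ReportRow(
        study=study,
        roi=roi,
        feature=feature or label,
        n=n,
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        sd=float(np.std(v, ddof=1)) if n > 1 else np.nan,
        iqr=float(q3 - q1),
        range=float(v.max() - v.min()),
    )


def rvat(at_values) -> float:
    """Total activation duration: max - min over accepted activation
    times (ms)."""
    v = np.asarray(at_values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("rvat requires at least 2 accepted AT values")
    return float(v.max() - v.min())


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------

REPORT_VERSION = 1
REPORT_FEATURES = ["uni_jel_mv", "at_ms", "ari_ms", "aric_ms", "uni_pp_mv"]


def build_report(
    studies,
    rois=None,
    conditions=None,
    path=None,
    config: FeatureConfig | None = None,
    features: dict | None = None,
    method: str = "nearest",
) -> pd.DataFrame:
    """One summary row per (study x ROI x feature), plus threshold areas.

    ``studies`` maps label -> :class:`EAMStudy`; ``rois`` maps label ->
    :class:`ROI` (the global surface is always reported as ROI ``ALL``).
    ``conditions`` attach area columns to rows whose feature matches the
    condition's feature.  ``features`` may carry precomputed per-study
    feature tables (label -> DataFrame) to skip re-extraction.  The CSV at
    ``path`` has a fixed, versioned column order and is byte-identical
    across re-runs on identical inputs.
    """
    rois = rois or {}
    conditions = list(conditions or [])
    if isinstance(studies, EAMStudy):
        studies = {"study": studies}

    columns = ["report_version", "study", "roi", "feature", "n", "mean", "median", "sd", "iqr", "range"]
    for i, cond in enumerate(conditions):
        columns += [f"cond{i}_area_mm2", f"cond{i}_area_pct"]

    rows = []
    for label in studies:
        study = studies[label]
        table = features[label] if features and label in features else extract_features(study, config)
        fmaps = {}
        for feat in REPORT_FEATURES:
            vals = table[feat].to_numpy()
            if np.any(np.isfinite(vals)):
                fmaps[feat] = interpolate_feature(
                    study.surface_positions, vals, study.mesh, method=method, name=feat
                )
        for roi_label, roi in [("ALL", None)] + sorted(rois.items()):
            if roi is None:
                member = np.ones(study.n_points, dtype=bool)
            else:
                member = roi_membership(roi, study)
            for feat in REPORT_FEATURES:
                vals = table[feat].to_numpy()[member]
                row = summarize(vals, feature=feat, study=label, roi=roi_label)
                rec = {
                    "report_version": REPORT_VERSION,
                    "study": row.study,
                    "roi": row.roi,
                    "feature": row.feature,
                    "n": row.n,
                    "mean": row.mean,
                    "median": row.median,
                    "sd": row.sd,
                    "iqr": row.iqr,
                    "range": row.range,
                }
                for i, cond in enumerate(conditions):
                    mm2 = pct = np.nan
                    if cond.feature == feat and feat in fmaps:
                        if roi is None:
                            fld = fmaps[feat].vertex_field
                        else:
                            try:
                                fld = restrict_and_reinterpolate(study, roi, fmaps[feat]).vertex_field
                            except ValueError:
                                fld = None
                        if fld is not None:
                            mm2, pct = area_where(study.mesh, fld, cond)
                    rec[f"cond{i}_area_mm2"] = mm2
                    rec[f"cond{i}_area_pct"] = pct
                rows.append(rec)

    df = pd.DataFrame(rows, columns=columns)
    if path is not None:
        df.to_csv(path, index=False)
    return df
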