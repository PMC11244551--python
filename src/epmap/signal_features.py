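"""Per-point electrogram and surface-ECG feature extraction.

Implements the fiducial-based features used throughout the workflow:

* J-point detection on a chosen surface-ECG lead (derivative-threshold QRS
  offset detector behind a pluggable interface) and the study-wide median
  J-point;
* Uni-JEl: unipolar amplitude at the J-point relative to a pre-QRS baseline;
* AT: activation time, steepest unipolar downstroke relative to the chosen
  surface-lead fiducial inside the window of interest;
* ARI: activation recovery interval, from minimum dV/dt of the unipolar QRS
  to maximum dV/dt of the following T wave, with quality rejection
  (noise / premature beat / abnormal T-wave morphology);
* Bazett-corrected ARI and window peak-to-peak unipolar voltage.

All derivatives are central differences of an optionally smoothed trace;
argmin/argmax ties resolve to the earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .data_model import EAMStudy

log = logging.getLogger(__name__)


class DetectionError(ValueError):
    """Raised when a required fiducial cannot be located."""


@dataclass
class FeatureConfig:
    """Tunable parameters for feature extraction.

    ``v2_fiducial`` selects the surface-lead activation reference: the
    literal amplitude minimum (``"minimum"``, default) or the minimum of
    the lead derivative (``"derivative"``).
    """

    lead_for_jpoint: str = "V2"
    baseline_window_ms: float = 40.0
    t_search_min_ms: float = 120.0
    t_search_max_ms: float = 450.0
    noise_rms_max_mv: float = 0.15
    derivative_smoothing_window_ms: float = 5.0
    repol_smoothing_window_ms: float = 25.0
    v2_fiducial: str = "minimum"
    jpoint_threshold_frac: float = 0.05
    jpoint_hold_ms: float = 8.0

    def __post_init__(self) -> None:
        if self.baseline_window_ms <= 0:
            raise ValueError("baseline_window_ms must be positive")
        if not self.t_search_min_ms < self.t_search_max_ms:
            raise ValueError("t_search_min_ms must be < t_search_max_ms")
        if self.v2_fiducial not in ("minimum", "derivative"):
            raise ValueError("v2_fiducial must be 'minimum' or 'derivative'")


@dataclass(frozen=True)
class QualityVerdict:
    accepted: bool
    reason: str  # one of {ok, noise, premature_beat, abnormal_t_morphology}

    def __post_init__(self) -> None:
        if (self.reason == "ok") != self.accepted:
            raise ValueError("reason must be 'ok' iff accepted")


def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def _derivative(trace: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    """Central-difference derivative (mV/ms) of an optionally
    Savitzky-Golay-smoothed trace."""
    trace = np.asarray(trace, dtype=np.float64)
    w = _ms_to_samples(smooth_ms, fs)
    if w >= 3:
        w = w + 1 if w % 2 == 0 else w
        trace = savgol_filter(trace, w, polyorder=2)
    return np.gradient(trace) * fs / 1000.0


# ---------------------------------------------------------------------------
# J-point
# ---------------------------------------------------------------------------


def detect_jpoint(
    ecg_lead_trace: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> int:
    """QRS-offset (J-point) sample on a surface-ECG lead.

    The R peak is located as the global amplitude maximum; the J-point is
    the first sample after it where the smoothed absolute derivative stays
    below ``jpoint_threshold_frac`` of its QRS maximum for
    ``jpoint_hold_ms`` consecutive milliseconds.
    """
    config = config or FeatureConfig()
    trace = np.asarray(ecg_lead_trace, dtype=np.float64)
    if trace.size < 3 or np.ptp(trace) == 0:
        raise DetectionError("no QRS")
    d = np.abs(_derivative(trace, fs, config.derivative_smoothing_window_ms))
    peak_slope = d.max()
    if peak_slope <= 0:
        raise DetectionError("no QRS")
    r_peak = int(np.argmax(trace))
    hold = max(1, _ms_to_samples(config.jpoint_hold_ms, fs))
    below = d < config.jpoint_threshold_frac * peak_slope
    # first index >= r_peak opening a run of `hold` sub-threshold samples
    run = np.convolve(below.astype(int), np.ones(hold, dtype=int), mode="valid")
    candidates = np.nonzero(run[r_peak:] == hold)[0]
    if candidates.size == 0:
        raise DetectionError("no QRS offset found after R peak")
    return r_peak + int(candidates[0])


def median_jpoint(jpoints) -> int:
    """Median of detected J-points; for even counts, the lower of the two
    middle values."""
    jp = sorted(int(j) for j in jpoints)
    if not jp:
        raise ValueError("no J-points supplied")
    return jp[(len(jp) - 1) // 2]


# ---------------------------------------------------------------------------
# Uni-JEl
# ---------------------------------------------------------------------------


def _qrs_onset(trace: np.ndarray, fs: float, config: FeatureConfig) -> int | None:
    """Deflection onset on a unipolar trace: walk backwards from the
    steepest downstroke until the absolute derivative has stayed below a
    fraction of its peak for a hold window.

    The wide (repolarization) smoothing window is used here so baseline
    noise does not defeat the quiet-run test; falls back to a fixed 60 ms
    pre-depolarization offset when no quiet run exists.
    """
    d = _derivative(trace, fs, config.repol_smoothing_window_ms)
    dep = int(np.argmin(d))
    thr = config.jpoint_threshold_frac * abs(d[dep])
    if thr == 0:
        return None
    hold = max(1, _ms_to_samples(config.jpoint_hold_ms, fs))
    below = np.abs(d) < thr
    run = np.convolve(below.astype(int), np.ones(hold, dtype=int), mode="valid")
    quiet_end = np.nonzero(run[: max(dep - hold + 1, 0)] == hold)[0]
    if quiet_end.size == 0:
        fallback = dep - _ms_to_samples(60.0, fs)
        return fallback if fallback >= 0 else None
    return int(quiet_end[-1]) + hold - 1


def compute_uni_jel(
    unipolar_trace: np.ndarray,
    jpoint_sample: int,
    fs: float,
    config: FeatureConfig | None = None,
) -> float:
    """Unipolar amplitude at the J-point minus the pre-QRS baseline.

    Baseline is the median of the ``baseline_window_ms`` segment ending at
    the detected QRS onset of the unipolar trace itself.
    """
    config = config or FeatureConfig()
    trace = np.asarray(unipolar_trace, dtype=np.float64)
    if not 0 <= jpoint_sample < trace.size:
        raise ValueError("J-point outside trace")
    if np.ptp(trace) == 0:
        return 0.0
    onset = _qrs_onset(trace, fs, config)
    w = _ms_to_samples(config.baseline_window_ms, fs)
    if onset is None or onset - w < 0:
        raise ValueError("baseline window out of range")
    baseline = float(np.median(trace[onset - w : onset]))
    return float(trace[jpoint_sample] - baseline)


# ---------------------------------------------------------------------------
# AT / ARI / voltage
# ---------------------------------------------------------------------------


def _window_bounds(
    n: int, reference_annotation: float, woi, fs: float
) -> tuple[int, int]:
    lo = _ms_to_samples(reference_annotation + woi[0], fs)
    hi = _ms_to_samples(reference_annotation + woi[1], fs)
    if lo < 0 or hi >= n or lo > hi:
        raise ValueError("analysis window outside trace")
    return lo, hi


def compute_at(
    unipolar_trace: np.ndarray,
    v2_trace: np.ndarray,
    reference_annotation: float,
    woi,
    fs: float,
    config: FeatureConfig | None = None,
) -> float:
    """Activation time: steepest unipolar downstroke minus the surface-lead
    fiducial, both searched inside the window of interest; in ms."""
    config = config or FeatureConfig()
    uni = np.asarray(unipolar_trace, dtype=np.float64)
    v2 = np.asarray(v2_trace, dtype=np.float64)
    lo, hi = _window_bounds(min(uni.size, v2.size), reference_annotation, woi, fs)
    d_uni = _derivative(uni, fs, config.derivative_smoothing_window_ms)
    dep = lo + int(np.argmin(d_uni[lo : hi + 1]))
    if config.v2_fiducial == "minimum":
        ref_idx = lo + int(np.argmin(v2[lo : hi + 1]))
    else:
        d_v2 = _derivative(v2, fs, config.derivative_smoothing_window_ms)
        ref_idx = lo + int(np.argmin(d_v2[lo : hi + 1]))
    return (dep - ref_idx) * 1000.0 / fs


def compute_ari(
    unipolar_trace: np.ndarray,
    reference_annotation: float,
    woi,
    fs: float,
    config: FeatureConfig | None = None,
) -> tuple[float, QualityVerdict]:
    """Activation recovery interval and a quality verdict.

    Depolarization fiducial: argmin dV/dt inside the window of interest.
    Repolarization fiducial: argmax dV/dt in
    [dep + t_search_min_ms, dep + t_search_max_ms].
    """
    config = config or FeatureConfig()
    uni = np.asarray(unipolar_trace, dtype=np.float64)
    lo, hi = _window_bounds(uni.size, reference_annotation, woi, fs)
    d = _derivative(uni, fs, config.derivative_smoothing_window_ms)
    dep = lo + int(np.argmin(d[lo : hi + 1]))
    t_lo = dep + _ms_to_samples(config.t_search_min_ms, fs)
    t_hi = dep + _ms_to_samples(config.t_search_max_ms, fs)
    if t_hi >= uni.size:
        raise ValueError("T-wave search window exceeds trace")
    d_rep = _derivative(uni, fs, config.repol_smoothing_window_ms)
    rep = t_lo + int(np.argmax(d_rep[t_lo : t_hi + 1]))
    ari = (rep - dep) * 1000.0 / fs
    verdict = assess_quality(
        uni,
        {"dep": dep, "rep": rep, "t_lo": t_lo, "t_hi": t_hi, "woi_lo": lo, "woi_hi": hi},
        fs,
        config,
    )
    return ari, verdict


def compute_aric(ari_ms: float, rr_ms: float) -> float:
    """Bazett heart-rate correction: ARI / sqrt(RR in seconds)."""
    if rr_ms <= 0:
        raise ValueError("RR interval must be positive")
    return float(ari_ms / np.sqrt(rr_ms / 1000.0))


def compute_unipolar_voltage(
    unipolar_trace: np.ndarray, reference_annotation: float, woi, fs: float
) -> float:
    """Peak-to-peak amplitude (max - min) inside the window of interest."""
    uni = np.asarray(unipolar_trace, dtype=np.float64)
    lo, hi = _window_bounds(uni.size, reference_annotation, woi, fs)
    seg = uni[lo : hi + 1]
    return float(seg.max() - seg.min())


# ---------------------------------------------------------------------------
# Quality assessment
# ---------------------------------------------------------------------------


def assess_quality(
    unipolar_trace: np.ndarray,
    fiducials: dict,
    fs: float,
    config: FeatureConfig | None = None,
) -> QualityVerdict:
    """Accept/reject a unipolar electrogram.

    Rejection rules (checked in order):

    * ``noise`` — RMS of the de-medianed pre-depolarization segment exceeds
      ``noise_rms_max_mv``;
    * ``premature_beat`` — a second suprathreshold depolarization downstroke
      inside the window of interest, away from the primary one;
    * ``abnormal_t_morphology`` — two competing dV/dt maxima in the T-search
      window (within 10% of each other), or the repolarization fiducial
      clamped at a search-window boundary.
    """
    config = config or FeatureConfig()
    uni = np.asarray(unipolar_trace, dtype=np.float64)
    dep = int(fiducials["dep"])
    rep = int(fiducials["rep"])
    t_lo = int(fiducials["t_lo"])
    t_hi = int(fiducials["t_hi"])

    # -- noise: flat segment well before the QRS complex
    seg_lo = max(0, dep - _ms_to_samples(150, fs))
    seg_hi = max(seg_lo + 1, dep - _ms_to_samples(50, fs))
    seg = uni[seg_lo:seg_hi]
    rms = float(np.sqrt(np.mean((seg - np.median(seg)) ** 2))) if seg.size else np.inf
    if rms > config.noise_rms_max_mv:
        return QualityVerdict(False, "noise")

    # -- premature beat: second strong downstroke inside the woi
    d = _derivative(uni, fs, config.derivative_smoothing_window_ms)
    lo = int(fiducials.get("woi_lo", 0))
    hi = int(fiducials.get("woi_hi", uni.size - 1))
    guard = _ms_to_samples(15, fs)
    window = d[lo : hi + 1].copy()
    rel = dep - lo
    window[max(0, rel - guard) : rel + guard + 1] = 0.0
    if np.any(window < 0.5 * d[dep]):  # d[dep] < 0
        return QualityVerdict(False, "premature_beat")

    # -- abnormal T morphology
    if rep <= t_lo or rep >= t_hi:
        return QualityVerdict(False, "abnormal_t_morphology")
    d_rep = _derivative(uni, fs, config.repol_smoothing_window_ms)
    t_seg = d_rep[t_lo : t_hi + 1]
    min_sep = _ms_to_samples(10, fs)
    peaks, props = find_peaks(t_seg, distance=min_sep)
    if peaks.size >= 2:
        heights = np.sort(t_seg[peaks])[::-1]
        if heights[0] > 0 and heights[1] >= 0.9 * heights[0]:
            return QualityVerdict(False, "abnormal_t_morphology")
    return QualityVerdict(True, "ok")


# ---------------------------------------------------------------------------
# Study-level pipeline
# ---------------------------------------------------------------------------


def estimate_rr(v2_trace: np.ndarray, fs: float) -> float | None:
    """Median R-R interval (ms) from V2 R peaks; None if < 2 peaks."""
    v2 = np.asarray(v2_trace, dtype=np.float64)
    if v2.size == 0 or np.ptp(v2) == 0:
        return None
    peaks, _ = find_peaks(v2, height=0.5 * v2.max(), distance=_ms_to_samples(200, fs))
    if peaks.size < 2:
        return None
    return float(np.median(np.diff(peaks)) * 1000.0 / fs)


FEATURE_COLUMNS = [
    "point_id", "x", "y", "z",
    "uni_jel_mv", "at_ms", "ari_ms", "aric_ms", "uni_pp_mv",
    "quality", "reason",
]


def extract_features(
    study: EAMStudy,
    config: FeatureConfig | None = None,
    rr_ms: float | None = None,
) -> pd.DataFrame:
    """Run the full per-point feature pipeline on a study.

    Returns a DataFrame with one row per point (columns
    :data:`FEATURE_COLUMNS`); rejected or invalid points carry NaN features
    and their rejection reason.  The Bazett RR interval is taken from
    ``rr_ms`` if given, estimated from the J-point lead otherwise, and
    defaults to 1000 ms (logged) when estimation fails.
    """
    config = config or FeatureConfig()
    fs = study.sampling_rate
    lead = study.ecg[config.lead_for_jpoint]

    jp = detect_jpoint(lead, fs, config)
    median_jp = median_jpoint([jp] * max(study.n_points, 1))

    if rr_ms is None:
        rr_ms = estimate_rr(lead, fs)
        if rr_ms is None:
            rr_ms = 1000.0
            log.info("RR estimation failed; defaulting to 1000 ms for Bazett")

    rows = []
    for i, p in enumerate(study.points):
        x, y, z = p.surface_position
        if not p.valid:
            rows.append((i, x, y, z, np.nan, np.nan, np.nan, np.nan, np.nan, False, p.reason))
            continue
        ari, verdict = compute_ari(p.unipolar, study.reference_annotation, study.woi, fs, config)
        at = compute_at(p.unipolar, lead, study.reference_annotation, study.woi, fs, config)
        jel = compute_uni_jel(p.unipolar, median_jp, fs, config)
        pp = compute_unipolar_voltage(p.unipolar, study.reference_annotation, study.woi, fs)
        if verdict.accepted:
            rows.append((i, x, y, z, jel, at, ari, compute_aric(ari, rr_ms), pp, True, "ok"))
        else:
            rows.append((i, x, y, z, jel, at, np.nan, np.nan, pp, False, verdict.reason))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
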