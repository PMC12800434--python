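"""Data pre-processing: gap filling, box-pose estimation, frame transforms,
low-pass filtering and timeline alignment.

The handle load cells ride inside the moving box, so their records are
expressed in a box-fixed local frame; the box pose recovered from the eight
corner markers (per-frame orthogonal Procrustes) re-expresses them in the
lab frame.  All streams are then low-pass filtered (default 4th-order
Butterworth, 10 Hz cut-off, applied forward-backward for zero phase lag)
and resampled onto a common analysis timeline.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .data import ForceRecord, MarkerSet, ProcessedTrial, TrialBundle
from .errors import ConfigError, GapError, PoseEstimationError, TimelineError

__all__ = ["FilterSpec", "RigidTransformSeries", "fill_marker_gaps",
           "estimate_box_pose", "transform_loads_to_global", "lowpass_filter",
           "resample_to_common_timeline", "preprocess_trial"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter specification.

    ``zero_phase`` applies the filter forward and backward (no lag; the
    effective magnitude response is the squared single-pass response).
    """

    order: int = 4
    cutoff_hz: float = 10.0
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ConfigError("cutoff must be positive")


@dataclass
class RigidTransformSeries:
    """Per-frame proper rigid transform mapping box-local to global coordinates."""

    time: np.ndarray
    rotation: np.ndarray     # (T, 3, 3)
    translation: np.ndarray  # (T, 3)
    rms_residual: np.ndarray  # (T,) fit residual, m

    def __post_init__(self):
        det = np.linalg.det(self.rotation)
        if not np.allclose(det, 1.0, atol=1e-6):
            raise PoseEstimationError("rotation determinant deviates from +1")

    def planar_angle(self) -> np.ndarray:
        """Rotation angle about the out-of-plane (z) axis."""
        return np.arctan2(self.rotation[:, 1, 0], self.rotation[:, 0, 0])

    def interpolated(self, t: np.ndarray) -> "RigidTransformSeries":
        """Resample: linear in translation, angle-linear in rotation.

        The box motion is planar, so rotations are interpolated on the planar
        angle (equivalent to slerp about the z axis).
        """
        t = np.asarray(t, dtype=float)
        if t[0] < self.time[0] - 1e-9 or t[-1] > self.time[-1] + 1e-9:
            raise TimelineError("interpolation times outside pose support")
        ang = np.unwrap(self.planar_angle())
        ai = np.interp(t, self.time, ang)
        c, s = np.cos(ai), np.sin(ai)
        R = np.zeros((t.shape[0], 3, 3))
        R[:, 0, 0], R[:, 0, 1] = c, -s
        R[:, 1, 0], R[:, 1, 1] = s, c
        R[:, 2, 2] = 1.0
        tr = np.stack([np.interp(t, self.time, self.translation[:, k])
                       for k in range(3)], axis=1)
        rms = np.interp(t, self.time, self.rms_residual)
        return RigidTransformSeries(t, R, tr, rms)


# --------------------------------------------------------------------------
def _spike_mask(y: np.ndarray, threshold: float, floor: float = 0.005) -> np.ndarray:
    """Flag samples whose second difference is a robust outlier.

    Uses median absolute deviation of the second difference; ``threshold``
    is the MAD multiplier.  ``floor`` (m) is an absolute lower bound on the
    spike size so that smooth motion over long dwell plateaus (where the MAD
    collapses toward zero) is never flagged.
    """
    n = y.shape[0]
    mask = np.zeros(n, dtype=bool)
    valid = ~np.isnan(y).any(axis=-1) if y.ndim > 1 else ~np.isnan(y)
    if valid.sum() < 5:
        return mask
    d2 = np.full(y.shape, np.nan)
    d2[1:-1] = y[2:] - 2 * y[1:-1] + y[:-2]
    mag = np.abs(d2).max(axis=-1) if y.ndim > 1 else np.abs(d2)
    mad = np.nanmedian(np.abs(mag - np.nanmedian(mag)))
    cut = max(threshold * mad / 0.6745, floor)
    mask[1:-1] = mag[1:-1] > cut
    return mask


def fill_marker_gaps(markers: MarkerSet, spike_threshold: float = 10.0) -> MarkerSet:
    """Replace NaN gaps (and spike outliers) by natural cubic spline interpolation.

    Valid frames are left untouched.  Leading/trailing gaps cannot be filled
    (no extrapolation) and raise :class:`GapError` naming the marker and span.
    """
    out = markers.copy()
    for name, arr in out.data.items():
        invalid = np.isnan(arr).any(axis=1)
        invalid |= _spike_mask(arr, spike_threshold)
        if not invalid.any():
            continue
        valid = ~invalid
        if valid.sum() < 4:
            raise GapError(f"marker {name!r}: fewer than 4 valid frames")
        idx = np.flatnonzero(invalid)
        if invalid[0] or invalid[-1]:
            span = (int(idx[0]), int(idx[-1]))
            raise GapError(
                f"marker {name!r}: leading/trailing gap (frames {span}) cannot "
                "be filled without extrapolation")
        spline = CubicSpline(markers.time[valid], arr[valid], bc_type="natural")
        filled = arr.copy()
        filled[invalid] = spline(markers.time[invalid])
        out.data[name] = filled
    return out


def kabsch(local: np.ndarray, observed: np.ndarray):
    """Least-squares rigid transform local -> observed (orthogonal Procrustes).

    Returns (R, t, rms).  ``local``/``observed`` are (n, 3) point sets.
    """
    lc = local - local.mean(axis=0)
    oc = observed - observed.mean(axis=0)
    H = lc.T @ oc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = observed.mean(axis=0) - R @ local.mean(axis=0)
    res = observed - (local @ R.T + t)
    return R, t, float(np.sqrt((res**2).sum(axis=1).mean()))


def estimate_box_pose(markers: MarkerSet, box) -> RigidTransformSeries:
    """Per-frame rigid pose of the box from its corner markers.

    At least three non-collinear corner markers must be visible in every
    frame; the fit is the Kabsch/orthogonal-Procrustes solution from the
    box-frame corner offsets to the observed positions.
    """
    names = [n for n in box.corner_marker_offsets if n in markers.data]
    if len(names) < 3:
        raise PoseEstimationError("fewer than 3 box corner markers present")
    local = np.stack([box.corner_marker_offsets[n] for n in names])
    obs = np.stack([markers.data[n] for n in names], axis=1)  # (T, n, 3)
    T = obs.shape[0]
    R = np.zeros((T, 3, 3))
    t = np.zeros((T, 3))
    rms = np.zeros(T)
    for i in range(T):
        vis = ~np.isnan(obs[i]).any(axis=1)
        if vis.sum() < 3:
            raise PoseEstimationError(f"frame {i}: fewer than 3 visible corner markers")
        loc = local[vis]
        spread = np.linalg.svd(loc - loc.mean(axis=0), compute_uv=False)
        if spread[1] < 1e-9:
            raise PoseEstimationError(f"frame {i}: visible corner markers are collinear")
        R[i], t[i], rms[i] = kabsch(loc, obs[i][vis])
    return RigidTransformSeries(markers.time.copy(), R, t, rms)


def transform_loads_to_global(record: ForceRecord,
                              poses: RigidTransformSeries) -> ForceRecord:
    """Re-express a local-frame force record in the global frame.

    ``F_g = R F_l``, ``M_g = R M_l`` (moment stays about the transformed
    application point) and ``COP_g = R COP_l + t``.  Poses are interpolated
    onto the record's timeline; the record must lie inside the pose support.
    """
    if record.frame != "local":
        raise ConfigError(f"record {record.name!r} is already global")
    if record.time[0] < poses.time[0] - 1e-9 or record.time[-1] > poses.time[-1] + 1e-9:
        raise TimelineError(
            f"record support [{record.time[0]:.3f}, {record.time[-1]:.3f}] s not "
            f"covered by pose support [{poses.time[0]:.3f}, {poses.time[-1]:.3f}] s")
    p = poses.interpolated(record.time)
    F = np.einsum("tij,tj->ti", p.rotation, record.force)
    M = np.einsum("tij,tj->ti", p.rotation, record.moment)
    C = np.einsum("tij,tj->ti", p.rotation, record.cop) + p.translation
    return ForceRecord(record.name, record.time.copy(), record.rate, F, M, C,
                       frame="global")


def lowpass_filter(series: np.ndarray, rate: float,
                   spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase (or causal) Butterworth low-pass along axis 0."""
    series = np.asarray(series, dtype=float)
    nyq = rate / 2.0
    if spec.cutoff_hz >= nyq:
        raise ConfigError(f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if series.shape[0] <= 3 * spec.order:
        raise ConfigError("series too short for the requested filter order")
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=rate, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, series, axis=0)
    return signal.sosfilt(sos, series, axis=0)


def resample_to_common_timeline(series_time: np.ndarray, series: np.ndarray,
                                target_time: np.ndarray) -> np.ndarray:
    """Cubic-spline resampling of an already anti-aliased series.

    ``target_time`` must lie inside the series support.  Identical timelines
    return the series unchanged.
    """
    series_time = np.asarray(series_time, dtype=float)
    target_time = np.asarray(target_time, dtype=float)
    if series_time.shape == target_time.shape and np.allclose(series_time, target_time):
        return np.asarray(series, dtype=float).copy()
    if target_time[0] < series_time[0] - 1e-9 or target_time[-1] > series_time[-1] + 1e-9:
        raise TimelineError("target timeline extends beyond the series support")
    return CubicSpline(series_time, series, axis=0)(target_time)


def preprocess_trial(trial: TrialBundle, spec: FilterSpec = FilterSpec(),
                     analysis_rate: Optional[float] = None,
                     spike_threshold: float = 10.0) -> ProcessedTrial:
    """Full pre-processing chain onto one analysis timeline.

    Order of operations mirrors standard practice: fill marker gaps; estimate
    the box pose from corner markers; re-express handle loads in the global
    frame; low-pass filter markers and force records; decimate force records
    (and box poses) onto the analysis timeline (default: the marker rate).
    """
    analysis_rate = analysis_rate or trial.meta.marker_rate
    markers = fill_marker_gaps(trial.markers, spike_threshold)
    poses = estimate_box_pose(markers, trial.meta.box)

    ehfm_global = {}
    for side, rec in trial.ehfm.items():
        g = transform_loads_to_global(rec, poses) if rec.frame == "local" else rec.copy()
        ehfm_global[side] = g

    n_out = int(np.floor((markers.time[-1] - markers.time[0]) * analysis_rate + 1e-9)) + 1
    t_target = markers.time[0] + np.arange(n_out) / analysis_rate
    if t_target.shape[0] < 2:
        raise TimelineError("analysis rate incompatible with marker timeline")

    filt_markers = MarkerSet(
        t_target, analysis_rate,
        {k: resample_to_common_timeline(markers.time,
                                        lowpass_filter(v, markers.rate, spec),
                                        t_target)
         for k, v in markers.data.items()})

    def proc(rec: ForceRecord) -> ForceRecord:
        F = lowpass_filter(rec.force, rec.rate, spec)
        M = lowpass_filter(rec.moment, rec.rate, spec)
        C = lowpass_filter(rec.cop, rec.rate, spec)
        return ForceRecord(rec.name, t_target,
                           analysis_rate,
                           resample_to_common_timeline(rec.time, F, t_target),
                           resample_to_common_timeline(rec.time, M, t_target),
                           resample_to_common_timeline(rec.time, C, t_target),
                           frame=rec.frame)

    grf = proc(trial.grf)
    ehfm = {side: proc(rec) for side, rec in ehfm_global.items()}
    box_pose = poses.interpolated(t_target)
    return ProcessedTrial(time=t_target, rate=analysis_rate, markers=filt_markers,
                          grf=grf, ehfm=ehfm, box_pose=box_pose, meta=trial.meta,
                          ground_truth=trial.ground_truth)
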