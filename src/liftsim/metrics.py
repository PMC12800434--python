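"""Grip event detection, phase normalization, and outcome metrics.

Outcome metrics mirror the standard reporting for lifting inverse analyses:
per-phase quartile RMSEs of hand-force and joint-reaction estimates
(normalized by box and body mass respectively), the time and magnitude of
the two joint-reaction peaks per handling phase, compliance of the vertical
ground-pelvis residual force with the 5% peak/RMS recommendation, and
one-way repeated-measures ANOVA with Greenhouse-Geisser correction and
Bonferroni pairwise comparisons across the modeling approaches.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.interpolate import CubicSpline

from .data import MarkerSet
from .errors import EventDetectionError, LiftsimError

__all__ = ["GripEvent", "HandlingPhase", "QuartileRMSE", "PeakSummary",
           "ResidualCompliance", "detect_grip_events", "phases_from_events",
           "segment_and_normalize", "rmse_quartiles", "find_phase_peaks",
           "residual_compliance", "rm_anova_bonferroni", "build_report"]

#: normalized phase grid, percent of phase duration
PHASE_GRID = np.linspace(0.0, 100.0, 101)
#: quartile windows over the 101-point grid; boundary samples (25, 50, 75%)
#: belong to the lower-index window, giving 26/25/25/25 samples
QUARTILE_SLICES = {"Q1": slice(0, 26), "Q2": slice(26, 51),
                   "Q3": slice(51, 76), "Q4": slice(76, 101)}


@dataclass(frozen=True)
class GripEvent:
    time: float
    kind: str  # 'grip_on' | 'grip_off'


@dataclass
class HandlingPhase:
    """A lifting or lowering interval with its normalized time grid."""

    kind: str       # 'lifting' | 'lowering'
    start: float
    end: float
    grid: np.ndarray = field(default_factory=lambda: PHASE_GRID.copy())

    def __post_init__(self):
        if self.start >= self.end:
            raise LiftsimError("phase start must precede its end")
        if self.grid.shape[0] != 101:
            raise LiftsimError("normalized grid must have 101 samples")

    @property
    def times(self) -> np.ndarray:
        """Absolute times of the 101 normalized samples."""
        return self.start + self.grid / 100.0 * (self.end - self.start)


@dataclass
class QuartileRMSE:
    values: dict[str, float]       # Q1..Q4, N
    normalized: dict[str, float]   # Q1..Q4, N/kg
    normalizer: float              # kg


@dataclass
class PeakSummary:
    initial_time: float      # % of phase
    initial_magnitude: float
    final_time: float
    final_magnitude: float
    fallback: bool = False   # True when a half lacked a local maximum

    def __post_init__(self):
        if not (0.0 <= self.initial_time <= 100.0 and 0.0 <= self.final_time <= 100.0):
            raise LiftsimError("peak times must lie in [0, 100]%")
        if self.initial_time >= self.final_time:
            raise LiftsimError("initial peak must precede final peak")


@dataclass
class ResidualCompliance:
    peak_residual: float
    rms_residual: float
    peak_threshold: float
    rms_threshold: float

    @property
    def peak_pass(self) -> bool:
        return self.peak_residual < self.peak_threshold

    @property
    def rms_pass(self) -> bool:
        return self.rms_residual < self.rms_threshold


# --------------------------------------------------------------------------
# grip events
# --------------------------------------------------------------------------
def _noise_scale(y: np.ndarray) -> float:
    """Robust per-sample noise estimate from the second difference.

    Uses a low quantile of |second difference| so that dwell plateaus (where
    only measurement noise remains) dominate the estimate and smooth motion
    curvature does not inflate it.  For white noise the 25th percentile of
    the half-normal |d2| distribution is 0.3186 times its scale, and
    var(d2) = 6 sigma^2.
    """
    d2 = np.abs(np.diff(y, 2))
    return float(np.percentile(d2, 25) / 0.3186 / np.sqrt(6.0))


def detect_grip_events(markers: MarkerSet, box=None,
                       corner_names: Optional[Sequence[str]] = None,
                       prominence_fraction: float = 0.25,
                       min_separation_s: float = 1.0) -> list[GripEvent]:
    """Detect grip on/off instants from the box-top trajectory.

    The average vertical trajectory of the two top-anterior corner markers
    plateaus on the support surfaces; peak finding (with prominence at least
    ``prominence_fraction`` of the trajectory range) locates the plateaus,
    and each departure/arrival instant is refined by walking out from the
    extremum to the last sample still within a noise-scaled tolerance of the
    plateau level.  Departures are grip-on events, arrivals grip-off events.
    """
    if corner_names is None:
        if box is not None:
            corner_names = box.top_anterior_corners()
        else:
            cand = {n: np.nanmean(m[:, 0] + m[:, 1]) for n, m in markers.data.items()
                    if n.upper().startswith("BOX")}
            if len(cand) < 2:
                raise EventDetectionError("cannot identify top-anterior box markers")
            corner_names = sorted(cand, key=cand.get, reverse=True)[:2]
    y = np.mean([markers.data[n][:, 1] for n in corner_names], axis=0)
    t = markers.time
    rng = float(np.nanmax(y) - np.nanmin(y))
    if rng < 1e-6:
        raise EventDetectionError("trajectory is constant: no handling detected")
    dist = max(1, int(min_separation_s * markers.rate))
    prom = prominence_fraction * rng
    hi, _ = signal.find_peaks(y, prominence=prom, distance=dist, plateau_size=1)
    lo, _ = signal.find_peaks(-y, prominence=prom, distance=dist, plateau_size=1)
    # include the boundary plateaus, which find_peaks cannot return
    ext = sorted(set(hi) | set(lo) | {0, y.shape[0] - 1})
    if len(ext) < 2:
        raise EventDetectionError("no trajectory extrema found")
    # robust plateau levels: medians of tight bands at the extremes (the box
    # rests at exactly two heights in a shelf-table transfer task); the band
    # must be narrow so transition samples cannot bias the level
    noise = _noise_scale(y)
    band = max(8.0 * noise, 0.001 * rng)
    level_hi = float(np.median(y[y > np.nanmax(y) - band]))
    level_lo = float(np.median(y[y < np.nanmin(y) + band]))
    tol = max(5.0 * noise, 1e-6)
    events: list[GripEvent] = []
    for a, b in zip(ext[:-1], ext[1:]):
        if abs(y[b] - y[a]) < 0.5 * rng:  # consecutive same-level plateaus
            continue
        la = level_hi if abs(y[a] - level_hi) < abs(y[a] - level_lo) else level_lo
        lb = level_hi if la == level_lo else level_lo
        # departure: last sample in (a, b) still at the start plateau level;
        # arrival: first sample at the end plateau level (the transition is
        # monotone between plateaus, so these are unambiguous)
        near_a = np.flatnonzero(np.abs(y[a:b] - la) <= tol)
        near_b = np.flatnonzero(np.abs(y[a:b + 1] - lb) <= tol)
        if near_a.size == 0 or near_b.size == 0:
            continue
        i = a + int(near_a[-1])
        j = a + int(near_b[0])
        if i >= j:
            continue
        events.append(GripEvent(float(t[i]), "grip_on"))
        events.append(GripEvent(float(t[j]), "grip_off"))
    if not events:
        raise EventDetectionError("no grip events detected")
    kinds = [e.kind for e in events]
    if kinds != ["grip_on", "grip_off"] * (len(events) // 2):
        raise EventDetectionError(
            f"event parity broken: {kinds} (inspect the corner trajectory)")
    return events


def phases_from_events(events: Sequence[GripEvent], markers: MarkerSet,
                       box=None, corner_names: Optional[Sequence[str]] = None
                       ) -> list[HandlingPhase]:
    """Pair grip on/off events into lifting/lowering phases.

    Phase kind is assigned by the direction of the vertical box displacement
    between the bracketing events (upward = lifting).
    """
    if corner_names is None:
        corner_names = box.top_anterior_corners() if box is not None else None
    if corner_names is not None:
        y = np.mean([markers.data[n][:, 1] for n in corner_names], axis=0)
    else:  # any box marker
        name = next(n for n in markers.data if n.upper().startswith("BOX"))
        y = markers.data[name][:, 1]
    phases = []
    for on, off in zip(events[0::2], events[1::2]):
        i0 = int(np.searchsorted(markers.time, on.time))
        i1 = int(np.searchsorted(markers.time, off.time))
        kind = "lifting" if y[min(i1, len(y) - 1)] > y[i0] else "lowering"
        phases.append(HandlingPhase(kind, on.time, off.time))
    return phases


# --------------------------------------------------------------------------
# normalization and error metrics
# --------------------------------------------------------------------------
def segment_and_normalize(time: np.ndarray, series: np.ndarray,
                          phases: Sequence[HandlingPhase],
                          min_samples: int = 5) -> list[np.ndarray]:
    """Resample a series onto each phase's 101-point (0-100%) grid.

    Cubic-spline interpolation of the raw samples inside each phase; phases
    spanning fewer than ``min_samples`` raw samples are rejected.
    """
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    out = []
    for ph in phases:
        sel = (time >= ph.start - 1e-12) & (time <= ph.end + 1e-12)
        if sel.sum() < min_samples:
            raise LiftsimError(
                f"phase [{ph.start:.3f}, {ph.end:.3f}] s spans only "
                f"{int(sel.sum())} samples (minimum {min_samples})")
        ts = time[sel]
        ys = series[sel]
        spline = CubicSpline(ts, ys, axis=0)
        out.append(spline(ph.times))
    return out


def rmse_quartiles(estimate: np.ndarray, reference: np.ndarray,
                   normalizer: float) -> QuartileRMSE:
    """Quartile RMSEs between two 101-point resultant series.

    Windows are 0-25 / 25-50 / 50-75 / 75-100% with boundary samples owned
    by the lower window; ``normalizer`` (kg) yields the N/kg variants (box
    mass for hand forces, body mass for joint reactions).
    """
    estimate = np.asarray(estimate, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if estimate.shape[0] != 101 or reference.shape[0] != 101:
        raise LiftsimError("quartile RMSE requires 101-point series")
    err2 = (estimate - reference) ** 2
    vals = {k: float(np.sqrt(np.mean(err2[s]))) for k, s in QUARTILE_SLICES.items()}
    return QuartileRMSE(vals, {k: v / normalizer for k, v in vals.items()},
                        normalizer)


def find_phase_peaks(resultant: np.ndarray) -> PeakSummary:
    """Initial and final peaks of a 101-point joint-reaction profile.

    The initial peak is the highest local maximum in the first half
    (0-50%), the final peak the highest in the second half; ties break
    toward the earlier sample.  A half without an interior local maximum
    falls back to its global maximum and sets the ``fallback`` flag.
    """
    y = np.asarray(resultant, dtype=float)
    if y.shape[0] != 101:
        raise LiftsimError("peak detection requires a 101-point series")
    maxima, _ = signal.find_peaks(y, plateau_size=1)
    fallback = False

    def pick(sel: np.ndarray, lo: int, hi: int):
        nonlocal fallback
        cand = sel[(sel >= lo) & (sel <= hi)]
        if cand.size == 0:
            fallback = True
            seg = y[lo:hi + 1]
            return lo + int(np.argmax(seg))
        return int(cand[np.argmax(y[cand])])  # argmax keeps earliest on ties

    i0 = pick(maxima, 0, 50)
    i1 = pick(maxima, 51, 100)
    return PeakSummary(float(i0), float(y[i0]), float(i1), float(y[i1]), fallback)


def residual_compliance(residual_vertical: np.ndarray, grf_vertical: np.ndarray,
                        ehf_vertical_total: np.ndarray) -> ResidualCompliance:
    """5% peak/RMS residual-force recommendation.

    The per-frame net external vertical force is |GRF_y + sum EHF_y|; the
    thresholds are 5% of its maximum (for the residual peak) and 5% of its
    RMS (for the residual RMS).
    """
    r = np.asarray(residual_vertical, dtype=float)
    net = np.abs(np.asarray(grf_vertical, dtype=float)
                 + np.asarray(ehf_vertical_total, dtype=float))
    ok = np.isfinite(r) & np.isfinite(net)
    if not ok.any():
        raise LiftsimError("no overlapping finite samples for compliance check")
    r, net = r[ok], net[ok]
    return ResidualCompliance(
        peak_residual=float(np.max(np.abs(r))),
        rms_residual=float(np.sqrt(np.mean(r**2))),
        peak_threshold=float(0.05 * np.max(net)),
        rms_threshold=float(0.05 * np.sqrt(np.mean(net**2))),
    )


# --------------------------------------------------------------------------
# repeated-measures statistics
# --------------------------------------------------------------------------
def rm_anova_bonferroni(values: np.ndarray, condition_names: Sequence[str] =
                        ("APP1", "APP2", "APP3"), alpha: float = 0.05) -> dict:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction
    and Bonferroni-corrected paired comparisons.

    ``values`` is (n_repetitions, 3).  The Greenhouse-Geisser epsilon is
    computed from the double-centered condition covariance matrix and applied
    to the degrees of freedom unconditionally (a conservative choice that
    sidesteps sphericity gatekeeping); pairwise paired t-test p-values are
    multiplied by the number of comparisons and capped at 1.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != len(condition_names):
        raise LiftsimError(f"values must be (n, {len(condition_names)})")
    n, k = Y.shape
    if n < 3:
        raise LiftsimError("need at least 3 repetitions")
    if not np.all(np.isfinite(Y)):
        raise LiftsimError("missing cells are not supported")
    grand = Y.mean()
    cond = Y.mean(axis=0)
    subj = Y.mean(axis=1)
    ss_cond = n * np.sum((cond - grand) ** 2)
    ss_err = np.sum((Y - cond[None, :] - subj[:, None] + grand) ** 2)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    # round-off guard: sums of squares at machine noise count as zero
    floor = 1e-12 * max(float(np.sum((Y - grand) ** 2)), 1.0)
    if ss_err <= floor:
        F = 0.0 if ss_cond <= floor else np.inf
        ms_err = 0.0
    else:
        F = ms_cond / ms_err
    # Greenhouse-Geisser epsilon from the double-centered covariance matrix
    S = np.cov(Y, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    denom = (k - 1) * np.sum(Sc**2)
    eps = float(np.trace(Sc) ** 2 / denom) if denom > 0 else 1.0
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p_gg = float(stats.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    posthoc = {}
    for i, j in pairs:
        d = Y[:, i] - Y[:, j]
        if np.allclose(d, d[0]):
            tstat, p = (0.0, 1.0) if abs(d[0]) < 1e-300 else (np.inf, 0.0)
        else:
            tstat, p = stats.ttest_rel(Y[:, i], Y[:, j])
        posthoc[f"{condition_names[i]}-{condition_names[j]}"] = {
            "t": float(tstat), "p_raw": float(p),
            "p_bonf": float(min(1.0, p * len(pairs)))}
    return {"F": float(F), "df1": df1, "df2": df2, "gg_epsilon": eps,
            "df1_gg": eps * df1, "df2_gg": eps * df2, "p_gg": p_gg,
            "significant": p_gg < alpha, "ss_condition": float(ss_cond),
            "ss_error": float(ss_err), "posthoc": posthoc, "alpha": alpha}


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------
def build_report(per_phase_rows: Sequence[dict],
                 anova_tables: Optional[dict] = None) -> dict:
    """Assemble tidy result tables across phases and approaches.

    ``per_phase_rows`` is a list of dicts with at least ``approach``,
    ``phase_kind`` and metric columns (quartile RMSEs, peak times/magnitudes,
    residual statistics).  Returns a dict with a tidy per-phase DataFrame, a
    mean +- SD summary grouped by approach and phase kind (SD is NaN for a
    single repetition), and any ANOVA tables passed in.
    """
    if not per_phase_rows:
        raise LiftsimError("no rows to report")
    df = pd.DataFrame(per_phase_rows)
    num_cols = [c for c in df.columns if df[c].dtype.kind in "fc"]
    grouped = df.groupby(["approach", "phase_kind"], sort=True)[num_cols]
    summary = grouped.agg(["mean", "std", "count"])
    return {"per_phase": df, "summary": summary, "anova": anova_tables or {}}
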