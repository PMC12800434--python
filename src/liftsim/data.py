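"""In-memory containers for trial data.

A trial couples three synchronized streams: labeled marker trajectories
(nominally 100 Hz), ground-plate records and per-hand handle load-cell
records (nominally 1000 Hz), plus subject/box metadata and — for synthetic
trials — the generating ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import TimelineError

__all__ = ["MarkerSet", "ForceRecord", "GroundTruth", "TrialMeta", "TrialBundle"]


@dataclass
class MarkerSet:
    """Labeled 3D marker trajectories on a uniform timeline.

    ``data`` maps marker name to an (N, 3) array in metres; gaps are NaN.
    """

    time: np.ndarray
    rate: float
    data: dict[str, np.ndarray]

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.shape[0]
        for name, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"marker {name!r}: shape {arr.shape} != ({n}, 3)")
            self.data[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.data)

    def copy(self) -> "MarkerSet":
        return MarkerSet(self.time.copy(), self.rate, {k: v.copy() for k, v in self.data.items()})


@dataclass
class ForceRecord:
    """One force transducer stream: force, moment and application point.

    ``frame`` is ``"global"`` for lab-frame data or ``"local"`` for data
    expressed in a moving body-fixed frame (the handle load cells).
    Moments are reported about the application point (``cop``).
    """

    name: str
    time: np.ndarray
    rate: float
    force: np.ndarray   # (N, 3), N
    moment: np.ndarray  # (N, 3), N*m about cop
    cop: np.ndarray     # (N, 3), m
    frame: str = "global"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.shape[0]
        for attr in ("force", "moment", "cop"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{self.name}.{attr}: shape {arr.shape} != ({n}, 3)")
            setattr(self, attr, arr)
        if self.frame not in ("global", "local"):
            raise ValueError(f"frame must be 'global' or 'local', got {self.frame!r}")

    def copy(self) -> "ForceRecord":
        return ForceRecord(self.name, self.time.copy(), self.rate,
                           self.force.copy(), self.moment.copy(), self.cop.copy(), self.frame)


@dataclass
class GroundTruth:
    """Generating truth of a synthetic trial (absent for recorded data)."""

    grip_times: np.ndarray          # (n_phases, 2) on/off times, s; lifting first
    phase_kinds: list[str]          # 'lifting' | 'lowering', one per row of grip_times
    ehf_global: np.ndarray          # (Nf, 3) per-hand force on the hand, global frame, N
    ehm_global: np.ndarray          # (Nf, 3) per-hand moment about the handle, N*m
    handle_pos: np.ndarray          # (Nf, 3) handle position, m
    q_marker: np.ndarray            # (Nm, 9) generalized coordinates at marker rate
    q_force: np.ndarray             # (Nf, 9) generalized coordinates at force rate
    box_pose: np.ndarray            # (Nf, 3) box centre x, y and planar angle
    grip_fraction: np.ndarray       # (Nf,) transferred-load fraction s(t) in [0, 1]


@dataclass
class TrialMeta:
    body_mass: float
    stature: float
    box: "object"        # BoxSpec (synthetic module); kept loose to avoid cycles
    task: "object"       # TaskConfig
    marker_rate: float
    force_rate: float


@dataclass
class TrialBundle:
    """One lift-lower recording: markers + ground plate + handle load cells."""

    markers: MarkerSet
    grf: ForceRecord
    ehfm: dict[str, ForceRecord]  # 'left'/'right' handle records
    meta: TrialMeta
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self):
        if self.meta.force_rate <= 0 or self.meta.marker_rate <= 0:
            raise ValueError("rates must be positive")
        ratio = self.meta.force_rate / self.meta.marker_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("force_rate must be an integer multiple of marker_rate")
        t0s = [self.markers.time[0], self.grf.time[0]] + [r.time[0] for r in self.ehfm.values()]
        if max(t0s) - min(t0s) > 1e-9:
            raise TimelineError("all streams must share a common start time")


@dataclass
class ProcessedTrial:
    """Preprocessed trial on a single analysis timeline (default 100 Hz).

    Markers are gap-free and low-pass filtered; handle loads are expressed in
    the global frame; all streams share ``time``.
    """

    time: np.ndarray
    rate: float
    markers: MarkerSet
    grf: ForceRecord
    ehfm: dict[str, ForceRecord]
    box_pose: "object"              # RigidTransformSeries on the analysis timeline
    meta: TrialMeta
    ground_truth: Optional[GroundTruth] = None
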