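"""Dynamically consistent synthetic lifting/lowering trials.

Emulates a sagittal-plane, two-handed symmetric transfer of a boxed load
between a low shelf and a table at a paced cadence, producing the same three
streams a motion-capture + force-transducer experiment yields — markers
(100 Hz), ground-plate records and handle load-cell records (1000 Hz, the
latter expressed in the moving box-fixed frame) — with known ground truth
for every downstream stage.

Construction order: a minimum-jerk box pose trajectory; a whole-body posture
trajectory whose hands track the handles (nullspace-regularized inverse
kinematics of the ankle-rooted chain); per-hand external hand forces and
moments from the box's Newton-Euler balance with a smooth grip-fraction
ramp; and ground reaction force/COP from the whole-system momentum balance,
which makes every trial dynamically consistent to numerical precision
before noise injection.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from ._geometry import GRAVITY, central_difference, cross_z, minimum_jerk, smoothstep, unit, unit_perp, wrap_angle
from .data import ForceRecord, GroundTruth, MarkerSet, TrialBundle, TrialMeta
from .errors import ConfigError, OutOfWorkspaceError
from .model import PlanarModel, build_model

__all__ = ["BoxSpec", "TaskConfig", "BoxTrajectory", "plan_box_trajectory",
           "solve_reference_posture", "synthesize_trial"]


def _default_corners(width: float, height: float, depth: float) -> dict[str, np.ndarray]:
    """Eight corner-marker offsets in the box frame (x anterior, y up, z left)."""
    out = {}
    for i, (sx, sy, sz) in enumerate(
            [(sx, sy, sz) for sy in (1, -1) for sx in (1, -1) for sz in (1, -1)], 1):
        out[f"BOX{i}"] = np.array([sx * width / 2, sy * height / 2, sz * depth / 2])
    return out


@dataclass
class BoxSpec:
    """Handled load: a rectangular box gripped at handle height.

    ``handle_offset`` is the handle position above the box centre (m);
    ``corner_marker_offsets`` maps the eight corner-marker names to box-frame
    positions and defaults to the geometric corners.
    """

    mass: float = 15.0
    width: float = 0.40
    depth: float = 0.30
    height: float = 0.30
    handle_offset: float = 0.15
    corner_marker_offsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.mass <= 0:
            raise ConfigError("box mass must be > 0")
        if min(self.width, self.depth, self.height) <= 0:
            raise ConfigError("box dimensions must be > 0")
        if not self.corner_marker_offsets:
            self.corner_marker_offsets = _default_corners(self.width, self.height, self.depth)
        self.corner_marker_offsets = {
            k: np.asarray(v, dtype=float) for k, v in self.corner_marker_offsets.items()}
        if len(self.corner_marker_offsets) != 8:
            raise ConfigError("exactly 8 corner markers required")
        pts = np.stack(list(self.corner_marker_offsets.values()))
        # cuboid check: relative to the centroid the offsets must be the 8
        # sign combinations of one half-extent vector (axis-aligned box frame)
        rel = pts - pts.mean(axis=0)
        half = np.abs(rel)
        if not np.allclose(half, half[0], atol=1e-9):
            raise ConfigError("corner markers do not form a rectangular cuboid")
        signs = {tuple(np.sign(r).astype(int)) for r in rel}
        if len(signs) != 8:
            raise ConfigError("corner markers do not form a rectangular cuboid")

    def top_anterior_corners(self) -> list[str]:
        """Names of the two top-anterior corner markers (max x + y offset)."""
        score = {k: v[0] + v[1] for k, v in self.corner_marker_offsets.items()}
        return sorted(score, key=score.get, reverse=True)[:2]


@dataclass
class TaskConfig:
    """Paced shelf-to-table transfer task.

    One cycle is lift + lower; ``cycle_rate`` is in cycles/min.  Each
    half-cycle splits into a move of duration ``move_fraction * cycle`` and a
    dwell on the support surface.  ``grip_ramp_duration`` is the duration of
    the gradual load transfer between support and hands at the start and end
    of each move (s); ``marker_noise_sd`` adds i.i.d. Gaussian noise per
    marker axis per frame (m).
    """

    shelf_height: float = 0.33
    table_height: float = 0.78
    cycle_rate: float = 10.0
    n_repetitions: int = 1
    grip_ramp_duration: float = 0.3
    marker_noise_sd: float = 0.0
    seed: int = 0
    shelf_reach: float = 0.42
    table_reach: float = 0.50
    move_fraction: float = 1.0 / 3.0
    lead_time: float = 1.0
    marker_rate: float = 100.0
    force_rate: float = 1000.0

    def __post_init__(self):
        if self.shelf_height == self.table_height:
            raise ConfigError("shelf_height must differ from table_height")
        if self.cycle_rate <= 0:
            raise ConfigError("cycle_rate must be > 0")
        if self.grip_ramp_duration < 0:
            raise ConfigError("grip_ramp_duration must be >= 0")
        if self.n_repetitions < 1:
            raise ConfigError("n_repetitions must be >= 1")
        if not (0 < self.move_fraction < 0.5):
            raise ConfigError("move_fraction must lie in (0, 0.5)")
        cycle = 60.0 / self.cycle_rate
        move = self.move_fraction * cycle
        dwell = 0.5 * cycle - move
        if move <= 0 or dwell <= 0:
            raise ConfigError("cycle_rate implies non-positive move or dwell duration")
        if self.grip_ramp_duration > 0.5 * move:
            raise ConfigError("grip_ramp_duration exceeds half the move duration")

    @property
    def cycle_duration(self) -> float:
        return 60.0 / self.cycle_rate

    @property
    def move_duration(self) -> float:
        return self.move_fraction * self.cycle_duration

    @property
    def dwell_duration(self) -> float:
        return 0.5 * self.cycle_duration - self.move_duration


@dataclass
class BoxTrajectory:
    """Piecewise dwell/minimum-jerk box-centre pose trajectory (level box)."""

    boundaries: np.ndarray     # segment end times, (S,)
    kinds: list[str]           # 'dwell' | 'move'
    p0: np.ndarray             # (S, 2) segment start positions
    p1: np.ndarray             # (S, 2) segment end positions
    move_intervals: np.ndarray  # (M, 2) start/end times of the moves, in order
    move_kinds: list[str]      # 'lifting' | 'lowering'
    duration: float

    def _segment(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.boundaries[:-1], t, side="right")
        return t, np.clip(idx, 0, len(self.kinds) - 1)

    def _eval(self, t, derivative: int):
        t, idx = self._segment(t)
        starts = np.concatenate([[0.0], self.boundaries[:-1]])
        T = self.boundaries[idx] - starts[idx]
        tau = (t - starts[idx]) / T
        s = minimum_jerk(tau, derivative) / T**derivative
        dp = self.p1[idx] - self.p0[idx]
        out = dp * s[..., None]
        if derivative == 0:
            out = self.p0[idx] + out
        return out

    def pos(self, t):
        return self._eval(t, 0)

    def vel(self, t):
        return self._eval(t, 1)

    def acc(self, t):
        return self._eval(t, 2)

    def angle(self, t):
        return np.zeros(np.shape(np.asarray(t)))

    def grip_fraction(self, t, ramp: float) -> np.ndarray:
        """Fraction of the load carried by the hands (smoothstep ramps).

        Ramps up over ``ramp`` seconds from each move start and down over the
        last ``ramp`` seconds before each move end; zero outside moves.
        """
        t = np.asarray(t, dtype=float)
        s = np.zeros(t.shape)
        for (t0, t1) in self.move_intervals:
            inside = (t > t0) & (t < t1)
            if ramp <= 0:
                s = np.where(inside, 1.0, s)
            else:
                val = smoothstep((t - t0) / ramp) * smoothstep((t1 - t) / ramp)
                s = np.where(inside, val, s)
        return s


def plan_box_trajectory(task: TaskConfig, box: BoxSpec) -> BoxTrajectory:
    """Plan the level-box centre trajectory for ``n_repetitions`` cycles.

    Minimum-jerk point-to-point moves (C2-continuous, zero end velocity and
    acceleration) alternate with dwells on the shelf and the table; the
    vertical coordinate during dwells is the surface height plus half the box
    height.  Lead-in/lead-out dwells of ``task.lead_time`` bracket the trial.
    """
    p_shelf = np.array([task.shelf_reach, task.shelf_height + box.height / 2])
    p_table = np.array([task.table_reach, task.table_height + box.height / 2])
    segs: list[tuple[float, str, np.ndarray, np.ndarray]] = []
    move_iv, move_kinds = [], []
    t = task.lead_time
    segs.append((t, "dwell", p_shelf, p_shelf))
    for _ in range(task.n_repetitions):
        move_iv.append((t, t + task.move_duration))
        move_kinds.append("lifting")
        t += task.move_duration
        segs.append((t, "move", p_shelf, p_table))
        t += task.dwell_duration
        segs.append((t, "dwell", p_table, p_table))
        move_iv.append((t, t + task.move_duration))
        move_kinds.append("lowering")
        t += task.move_duration
        segs.append((t, "move", p_table, p_shelf))
        t += task.dwell_duration
        segs.append((t, "dwell", p_shelf, p_shelf))
    t += task.lead_time
    segs.append((t, "dwell", p_shelf, p_shelf))
    return BoxTrajectory(
        boundaries=np.array([s[0] for s in segs]),
        kinds=[s[1] for s in segs],
        p0=np.stack([s[2] for s in segs]),
        p1=np.stack([s[3] for s in segs]),
        move_intervals=np.array(move_iv),
        move_kinds=move_kinds,
        duration=t,
    )


# --------------------------------------------------------------------------
# posture synthesis
# --------------------------------------------------------------------------
# reference postures for the nullspace pull, as absolute segment angles
# [shank, thigh, pelvis, torso, upperarm, forearm]; leg axes point distally
# (downward in standing, -pi/2), trunk axes point up (+pi/2), arms hang down.
_REF_UPRIGHT = np.array([-np.pi / 2 - 0.02, -np.pi / 2 + 0.02, np.pi / 2 - 0.05,
                         np.pi / 2 - 0.35, -np.pi / 2 + 0.10, -np.pi / 2])
_REF_CROUCH = np.array([-np.pi / 2 - 0.35, -np.pi / 2 + 0.85, np.pi / 2 - 0.95,
                        np.pi / 2 - 1.25, -np.pi / 2 + 0.10, -np.pi / 2])
# nullspace pull weights: the loaded forearm is kept plumb (a natural carry
# posture) much more strongly than the proximal chain follows its schedule
_REF_WEIGHTS = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 6.0])


def _chain_lengths(model: PlanarModel) -> np.ndarray:
    s = model.segments
    return np.array([s["shank"].length, s["thigh"].length, s["pelvis"].length,
                     s["torso"].length, s["upperarm"].length,
                     s["forearm"].length + s["hand"].length])


def _chain_fk(phi: np.ndarray, lengths: np.ndarray, ankle: np.ndarray):
    """Metacarpal position and its Jacobian for the ankle-rooted chain."""
    signs = np.array([-1.0, -1.0, 1.0, 1.0, 1.0, 1.0])
    u = unit(phi)
    p = ankle + (signs[:, None] * lengths[:, None] * u).sum(axis=0)
    J = (signs[:, None] * lengths[:, None] * unit_perp(phi)).T  # (2, 6)
    return p, J


def solve_reference_posture(targets: np.ndarray, model: PlanarModel,
                            ankle: Optional[np.ndarray] = None,
                            ref_heights: tuple[float, float] = (0.60, 1.10),
                            tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Whole-body posture tracking a handle-point target trajectory.

    Solves, frame by frame with warm starting, the redundant planar chain
    ankle -> shank -> thigh -> pelvis -> torso -> upper arm -> forearm+hand
    so that the metacarpal point coincides with ``targets`` (within ``tol``
    metres) while the nullspace of the task pulls the posture toward a
    height-scheduled crouch-to-upright reference.  Warm starting makes the
    solution continuous across frames (no inverse-kinematics branch flips).

    Returns ``(phi, q)``: absolute segment angles (T, 6) and the model's
    generalized coordinates (T, 9).

    Raises :class:`OutOfWorkspaceError` with the frame index if a target is
    unreachable.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    L = _chain_lengths(model)
    if ankle is None:
        ankle = np.array([0.0, model.anthropometry["ankle_height"]])
    lo, hi = ref_heights
    phi_out = np.zeros((targets.shape[0], 6))
    phi = None
    for i, tgt in enumerate(targets):
        w = np.clip((tgt[1] - lo) / (hi - lo), 0.0, 1.0)
        phi_ref = (1 - w) * _REF_CROUCH + w * _REF_UPRIGHT
        if phi is None:
            phi = phi_ref.copy()
        n_iter = 200 if i == 0 else 60
        for it in range(n_iter):
            p, J = _chain_fk(phi, L, ankle)
            e = tgt - p
            Jp = J.T @ np.linalg.inv(J @ J.T + 1e-12 * np.eye(2))
            null_step = 0.2 * (np.eye(6) - Jp @ J) @ (_REF_WEIGHTS * (phi_ref - phi))
            step = Jp @ e + null_step
            nrm = np.linalg.norm(step)
            if nrm > 0.5:
                step *= 0.5 / nrm
            phi = phi + step
            if np.linalg.norm(e) < tol and np.linalg.norm(null_step) < 1e-8:
                break
        # constraint polish (pure Newton on the task; generous iteration cap
        # because convergence is only linear at the workspace boundary)
        for _ in range(60):
            p, J = _chain_fk(phi, L, ankle)
            e = tgt - p
            if np.linalg.norm(e) < tol:
                break
            phi = phi + J.T @ np.linalg.solve(J @ J.T + 1e-12 * np.eye(2), e)
        if np.linalg.norm(e) > 1e-9:
            raise OutOfWorkspaceError(
                f"handle target {tgt} unreachable (|error| = {np.linalg.norm(e):.3g} m)",
                frame=i)
        phi_out[i] = phi
    return phi_out, _phi_to_q(phi_out, L, ankle)


def _phi_to_q(phi: np.ndarray, L: np.ndarray, ankle: np.ndarray) -> np.ndarray:
    """Convert ankle-rooted absolute angles to pelvis-based coordinates."""
    u_sh, u_th = unit(phi[:, 0]), unit(phi[:, 1])
    knee = ankle - L[0] * u_sh
    hip = knee - L[1] * u_th
    q = np.zeros((phi.shape[0], 9))
    q[:, 0:2] = hip
    q[:, 2] = phi[:, 2]
    q[:, 3] = wrap_angle(phi[:, 3] - phi[:, 2])                 # lumbar
    q[:, 4] = wrap_angle(phi[:, 4] - phi[:, 3] - np.pi)         # shoulder
    q[:, 5] = wrap_angle(phi[:, 5] - phi[:, 4])                 # elbow
    q[:, 6] = wrap_angle(phi[:, 1] - phi[:, 2] - np.pi)         # hip
    q[:, 7] = wrap_angle(phi[:, 0] - phi[:, 1])                 # knee
    q[:, 8] = wrap_angle(-phi[:, 0] - np.pi / 2)                # ankle (foot flat)
    return q


# --------------------------------------------------------------------------
# trial synthesis
# --------------------------------------------------------------------------
def _box_hand_loads(traj: BoxTrajectory, box: BoxSpec, t: np.ndarray, ramp: float):
    """Ground-truth per-hand EHF&M from the box's rigid-body balance.

    The hands carry the grip fraction ``s`` of the box's inertial+gravity
    wrench, the support surface the rest (applied at the box bottom centre).
    The level box neither rotates nor accelerates angularly, so the hand
    couple balances the moment of both force sets about the box centre.
    Returns force/moment *on the hands* plus the handle point and ``s``.
    """
    p_c = traj.pos(t)
    a = traj.acc(t)
    s = traj.grip_fraction(t, ramp)
    f_box = box.mass * (a - GRAVITY)           # total support+hand force on box
    f_hands = s[:, None] * f_box               # hands-on-box
    f_sup = (1.0 - s[:, None]) * f_box
    p_h = p_c + np.array([0.0, box.handle_offset])
    p_s = p_c - np.array([0.0, box.height / 2])
    couple_on_box = -(cross_z(p_h - p_c, f_hands) + cross_z(p_s - p_c, f_sup))
    ehf = -0.5 * f_hands                       # box-on-hand, per hand
    ehm = -0.5 * couple_on_box
    return ehf, ehm, p_h, s


def synthesize_trial(task: TaskConfig, box: BoxSpec, anthropometry: dict,
                     seed: Optional[int] = None,
                     model: Optional[PlanarModel] = None) -> TrialBundle:
    """Generate one dynamically consistent synthetic trial.

    The ground reaction force is the residue of the whole-human momentum
    balance (weight + COM-acceleration rate minus the hand loads), and its
    COP enforces the angular-momentum balance about the lab origin, so the
    human+box system is force- and moment-consistent at every frame before
    marker noise is injected.  Identical seeds give bit-identical bundles.
    """
    seed = task.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = model or build_model(anthropometry)
    traj = plan_box_trajectory(task, box)
    n_f = int(round(traj.duration * task.force_rate)) + 1
    decim = int(round(task.force_rate / task.marker_rate))
    t_f = np.arange(n_f) / task.force_rate
    t_m = t_f[::decim]
    dt_f = 1.0 / task.force_rate

    # posture tracking the handles at marker rate, splined to force rate
    handle_m = traj.pos(t_m) + np.array([0.0, box.handle_offset])
    _, q_m = solve_reference_posture(handle_m, model)
    q_f = CubicSpline(t_m, q_m, axis=0)(t_f)

    # hand loads from box dynamics
    ehf, ehm, p_handle, s = _box_hand_loads(traj, box, t_f, task.grip_ramp_duration)

    # GRF from whole-human momentum balance
    fkf = model.fk(q_f)
    masses = {k: model.segments[k].mass for k in model.segments}
    total_mass = model.total_mass
    coms = {k: fkf["com"][k] for k in model.segments}
    lin_mom = sum(masses[k] * central_difference(coms[k], dt_f) for k in coms)
    mom_rate = central_difference(lin_mom, dt_f)
    ehf_total = 2.0 * ehf
    grf = mom_rate - total_mass * GRAVITY - ehf_total

    # angular momentum about the lab origin -> GRF centre of pressure
    ang = 0.0
    for k in coms:
        v = central_difference(coms[k], dt_f)
        omega = central_difference(fkf["angle"][k], dt_f)
        ang = ang + masses[k] * cross_z(coms[k], v) + model.segments[k].inertia * omega
    ang_rate = central_difference(ang, dt_f)
    m_gravity = sum(cross_z(coms[k], masses[k] * GRAVITY) for k in coms)
    m_hands = cross_z(p_handle, ehf_total) + 2.0 * ehm
    m_grf = ang_rate - m_gravity - m_hands
    cop_x = m_grf / grf[:, 1]

    # --- records ---------------------------------------------------------
    def lift3(v2):
        return np.concatenate([v2, np.zeros((v2.shape[0], 1))], axis=1)

    grf_rec = ForceRecord("ground", t_f, task.force_rate, lift3(grf),
                          np.zeros((n_f, 3)),
                          np.stack([cop_x, np.zeros(n_f), np.zeros(n_f)], axis=1),
                          frame="global")
    # handle records in the box-local frame (level box: pure translation)
    theta = traj.angle(t_f)
    c, si = np.cos(theta), np.sin(theta)
    box_pos = traj.pos(t_f)

    def to_local(vec2):
        return np.stack([c * vec2[:, 0] + si * vec2[:, 1],
                         -si * vec2[:, 0] + c * vec2[:, 1]], axis=1)

    ehf_l = to_local(ehf)
    cop_l = to_local(p_handle - box_pos)
    ehfm = {}
    for side, zoff in (("right", -box.depth / 2), ("left", box.depth / 2)):
        cop3 = lift3(cop_l).copy()
        cop3[:, 2] = zoff
        ehfm[side] = ForceRecord(
            f"handle_{side}", t_f, task.force_rate, lift3(ehf_l),
            np.stack([np.zeros(n_f), np.zeros(n_f), ehm], axis=1),
            cop3, frame="local")

    # markers: anatomical (FK) + box corners, optional Gaussian noise
    fkm = model.fk(q_m)
    data = {name: lift3(pos) for name, pos in fkm["markers"].items()}
    box_pos_m = traj.pos(t_m)
    theta_m = traj.angle(t_m)
    cm, sm = np.cos(theta_m), np.sin(theta_m)
    for name, off in box.corner_marker_offsets.items():
        gx = box_pos_m[:, 0] + cm * off[0] - sm * off[1]
        gy = box_pos_m[:, 1] + sm * off[0] + cm * off[1]
        data[name] = np.stack([gx, gy, np.full(t_m.shape[0], off[2])], axis=1)
    if task.marker_noise_sd > 0:
        for name in data:
            data[name] = data[name] + rng.normal(
                0.0, task.marker_noise_sd, size=data[name].shape)
    markers = MarkerSet(t_m, task.marker_rate, data)

    kinds = list(traj.move_kinds)
    truth = GroundTruth(
        grip_times=traj.move_intervals.copy(),
        phase_kinds=kinds,
        ehf_global=lift3(ehf),
        ehm_global=np.stack([np.zeros(n_f), np.zeros(n_f), ehm], axis=1),
        handle_pos=lift3(p_handle),
        q_marker=q_m,
        q_force=q_f,
        box_pose=np.concatenate([box_pos, theta[:, None]], axis=1),
        grip_fraction=s,
    )
    meta = TrialMeta(body_mass=float(anthropometry["body_mass"]),
                     stature=float(anthropometry["stature"]),
                     box=box, task=task,
                     marker_rate=task.marker_rate, force_rate=task.force_rate)
    return TrialBundle(markers=markers, grf=grf_rec, ehfm=ehfm,
                       meta=meta, ground_truth=truth)
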