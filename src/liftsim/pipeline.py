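"""Four-stage inverse analysis: inverse kinematics, inverse dynamics with
ground-pelvis residuals, static optimization, and joint reaction analysis.

The stages are independent functions over the planar model; ``run_pipeline``
orchestrates them for any of the three external-hand-load modeling
approaches.  The measured-load approach (APP 1) runs over the whole motion
cycle; the simplified approaches (APP 2, APP 3) are only defined while the
load is gripped, so their muscle-level stages run per detected handling
phase.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._geometry import GRAVITY, central_difference, cross_z
from .data import MarkerSet, ProcessedTrial
from .errors import InfeasibleFrameError, LiftsimError, TimelineError
from .model import (JOINTS, SUPERIOR_SEGMENTS, INFERIOR_SEGMENTS,
                    ExternalLoadSet, PlanarModel, loads_app1, loads_app2, loads_app3,
                    _TOPOLOGY, _ORDER)
from .preprocess import FilterSpec, lowpass_filter

__all__ = ["JointTrajectory", "NetJointLoads", "SOResult", "JrfResult",
           "inverse_kinematics", "inverse_dynamics", "static_optimization",
           "joint_reaction_analysis", "run_pipeline", "PipelineResult"]


@dataclass
class JointTrajectory:
    """Generalized-coordinate trajectory with filtered derivatives."""

    time: np.ndarray
    rate: float
    q: np.ndarray       # (T, 9)
    qdot: np.ndarray
    qddot: np.ndarray
    rms_error: np.ndarray  # (T,) marker fit residual, m
    flagged: list[int] = field(default_factory=list)


@dataclass
class NetJointLoads:
    """Net joint torques and the ground-pelvis residual wrench."""

    time: np.ndarray
    torques: dict[str, np.ndarray]   # joint -> (T,), N*m
    residual_force: np.ndarray       # (T, 2), N
    residual_moment: np.ndarray      # (T,), N*m about the pelvis origin


@dataclass
class SOResult:
    """Per-frame static-optimization solution (NaN outside solved frames)."""

    time: np.ndarray
    muscle_names: list[str]
    activations: np.ndarray       # (T, n_m) in [0, 1]
    muscle_forces: np.ndarray     # (T, n_m), N
    reserve_names: list[str]
    reserve_torques: np.ndarray   # (T, n_r), N*m
    residual_force: np.ndarray    # (T, 2) copied from inverse dynamics
    residual_moment: np.ndarray
    objective: np.ndarray         # (T,)
    constraint_residual: np.ndarray  # (T,) max |A x - tau|, N*m


@dataclass
class JrfResult:
    """Joint reaction force at the lumbosacral joint (force on the superior body)."""

    time: np.ndarray
    joint: str
    force: np.ndarray      # (T, 2), global frame, N
    moment: np.ndarray     # (T,), N*m about the joint
    resultant: np.ndarray  # (T,), N
    tag: str


# --------------------------------------------------------------------------
# inverse kinematics
# --------------------------------------------------------------------------
_SEG_MARKER_PAIRS = [
    # (absolute-angle slot, proximal marker, distal marker) for the analytic seed
    ("shank", "KNE", "ANK"), ("thigh", "HIP", "KNE"), ("pelvis", "HIP", "SACR"),
    ("torso", "SACR", "SHO"), ("upperarm", "SHO", "ELB"), ("forearm", "ELB", "WRI"),
]


def _analytic_seed(markers2d: dict[str, np.ndarray]) -> np.ndarray:
    """Closed-form coordinate estimate from marker-pair directions.

    With noise-free markers at the joint centres this seed is already exact;
    Gauss-Newton refinement below handles noise and missing markers.
    """
    from ._geometry import wrap_angle
    T = next(iter(markers2d.values())).shape[0]
    phi = {}
    for seg, a, b in _SEG_MARKER_PAIRS:
        d = markers2d[b] - markers2d[a]
        phi[seg] = np.arctan2(d[:, 1], d[:, 0])
    q = np.zeros((T, 9))
    q[:, 0:2] = markers2d["HIP"]
    q[:, 2] = phi["pelvis"]
    q[:, 3] = wrap_angle(phi["torso"] - phi["pelvis"])
    q[:, 4] = wrap_angle(phi["upperarm"] - phi["torso"] - np.pi)
    q[:, 5] = wrap_angle(phi["forearm"] - phi["upperarm"])
    q[:, 6] = wrap_angle(phi["thigh"] - phi["pelvis"] - np.pi)
    q[:, 7] = wrap_angle(phi["shank"] - phi["thigh"])
    dtoe = markers2d["TOE"] - markers2d["ANK"]
    q[:, 8] = wrap_angle(np.arctan2(dtoe[:, 1], dtoe[:, 0]) - phi["shank"] - np.pi / 2)
    return q


def inverse_kinematics(markers: MarkerSet, model: PlanarModel,
                       deriv_filter: Optional[FilterSpec] = None,
                       max_iter: int = 20, tol: float = 1e-12,
                       flag_rms: float = 0.05) -> JointTrajectory:
    """Weighted least-squares marker fit per frame.

    Each frame minimizes the squared distance between model marker positions
    and observations (planar components) by damped Gauss-Newton with a
    finite-difference Jacobian, batched over all frames and seeded
    analytically from marker-pair directions (exact for noise-free
    joint-centre markers).  Velocities and accelerations come from central
    differences; pass ``deriv_filter`` to low-pass the coordinates first
    when fitting raw (unfiltered) markers.  Frames whose RMS marker error
    exceeds ``flag_rms`` (m) are flagged.
    """
    names = [n for n in model.marker_names() if n in markers.data]
    if len(names) < 5:
        raise LiftsimError("too few anatomical markers for inverse kinematics")
    obs2d = {n: markers.data[n][:, :2] for n in names}
    T = markers.time.shape[0]
    try:
        seed = _analytic_seed(obs2d)
    except KeyError:
        seed = np.zeros((T, 9))

    obs = np.stack([obs2d[n] for n in names], axis=1)  # (T, n, 2)

    def residuals(qb):
        f = model.fk(qb)
        pred = np.stack([f["markers"][n] for n in names], axis=-2)  # (T, n, 2)
        return (pred - obs).reshape(T, -1)

    # batched Gauss-Newton over all frames at once: the analytic seed is
    # exact for noise-free joint-centre markers, so a handful of damped
    # iterations with a finite-difference Jacobian polish every frame
    q = np.where(np.isfinite(seed), seed, 0.0)
    h = 1e-7
    nres = 2 * len(names)
    for _ in range(max_iter):
        r = residuals(q)
        J = np.empty((T, nres, 9))
        for k in range(9):
            dx = np.zeros(9)
            dx[k] = h
            J[:, :, k] = (residuals(q + dx) - residuals(q - dx)) / (2 * h)
        JtJ = np.einsum("tik,til->tkl", J, J) + 1e-12 * np.eye(9)
        Jtr = np.einsum("tik,ti->tk", J, r)
        step = np.linalg.solve(JtJ, -Jtr[..., None])[..., 0]
        q = q + step
        if np.abs(step).max() < tol:
            break
    r = residuals(q).reshape(T, -1, 2)
    rms = np.sqrt(np.mean(np.sum(r**2, axis=2), axis=1))
    flagged = [int(t) for t in np.flatnonzero(rms > flag_rms)]
    dt = 1.0 / markers.rate
    # markers are normally low-pass filtered upstream (preprocess); pass a
    # FilterSpec only when differentiating coordinates fit to raw markers
    qf = lowpass_filter(q, markers.rate, deriv_filter) if deriv_filter else q
    qdot = central_difference(qf, dt)
    qddot = central_difference(qf, dt, order=2)
    return JointTrajectory(markers.time.copy(), markers.rate, q, qdot, qddot,
                           rms, flagged)


# --------------------------------------------------------------------------
# inverse dynamics
# --------------------------------------------------------------------------
_CHILDREN: dict[str, list[str]] = {s: [] for s in _ORDER}
for _c, (_p, *_rest) in _TOPOLOGY.items():
    _CHILDREN[_p].append(_c)


def _segment_kinematics(model: PlanarModel, q: np.ndarray, dt: float):
    fk = model.fk(q)
    acc = {s: central_difference(fk["com"][s], dt, order=2) for s in _ORDER}
    alpha = {s: central_difference(fk["angle"][s], dt, order=2) for s in _ORDER}
    return fk, acc, alpha


def inverse_dynamics(model: PlanarModel, traj: JointTrajectory,
                     loads: ExternalLoadSet,
                     deriv_filter: Optional[FilterSpec] = None) -> NetJointLoads:
    """Recursive Newton-Euler over the planar tree.

    Works leaf-to-root on filtered segment kinematics (COM accelerations and
    angular accelerations by central differences).  The wrench left over at
    the pelvis "free joint" is the residual force/moment that ideal residual
    actuators would have to supply for the motion and the applied loads to
    be dynamically consistent.
    """
    if loads.time.shape != traj.time.shape or not np.allclose(loads.time, traj.time):
        raise TimelineError("external loads and kinematics are on different timelines")
    dt = 1.0 / traj.rate
    qf = lowpass_filter(traj.q, traj.rate, deriv_filter) if deriv_filter else traj.q
    fk, acc, alpha = _segment_kinematics(model, qf, dt)
    T = traj.time.shape[0]
    F_prox: dict[str, np.ndarray] = {}
    M_prox: dict[str, np.ndarray] = {}
    order = [s for s in _ORDER[::-1]]  # leaves before root by construction
    for s in order:
        seg = model.segments[s]
        com, origin = fk["com"][s], fk["origin"][s]
        F = seg.mass * (acc[s] - GRAVITY)
        M = seg.inertia * alpha[s]
        for e in loads.for_body(s):
            F = F - e["force"]
            M = M - cross_z(e["point"] - com, e["force"]) - e["moment"]
        for c in _CHILDREN[s]:
            F = F + F_prox[c]
            M = M + M_prox[c] + cross_z(fk["origin"][c] - com, F_prox[c])
        F_prox[s] = F
        M_prox[s] = M - cross_z(origin - com, F)
    torques = {}
    for child, (parent, coord, *_r) in _TOPOLOGY.items():
        if coord is not None:
            torques[coord] = M_prox[child]
    return NetJointLoads(traj.time.copy(), torques,
                         residual_force=F_prox["pelvis"],
                         residual_moment=M_prox["pelvis"])


# --------------------------------------------------------------------------
# static optimization
# --------------------------------------------------------------------------
def _solve_so_frame(W: np.ndarray, A: np.ndarray, tau: np.ndarray,
                    n_bounded: int) -> np.ndarray:
    """Minimize x' W x subject to A x = tau, 0 <= x_i <= 1 for i < n_bounded.

    Small dense active-set method on the bound constraints (the problem has
    a handful of variables), starting from the equality-only KKT solution.
    """
    n = W.shape[0]
    m = A.shape[0]
    fixed = np.full(n, np.nan)  # NaN = free
    seen: set[tuple] = set()    # visited active sets (cycling guard)

    for _ in range(4 * n + 8):
        key = tuple(-1 if np.isnan(f) else int(f) for f in fixed)
        if key in seen:
            break
        seen.add(key)
        free = np.isnan(fixed)
        xf_fixed = np.where(free, 0.0, fixed)
        nf = int(free.sum())
        K = np.zeros((nf + m, nf + m))
        K[:nf, :nf] = 2.0 * np.diag(W[free, free] if W.ndim == 2 else W[free])
        Af = A[:, free]
        K[:nf, nf:] = Af.T
        K[nf:, :nf] = Af
        rhs = np.concatenate([np.zeros(nf), tau - A @ xf_fixed])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        x = xf_fixed.copy()
        x[free] = sol[:nf]
        lam = sol[nf:]
        if np.abs(A @ x - tau).max() > 1e-8:
            # constraint unsatisfiable with this active set: stop and let the
            # caller diagnose infeasibility from the returned residual
            return x
        # bound violations among free bounded vars
        viol_lo = free & (np.arange(n) < n_bounded) & (x < -1e-10)
        viol_hi = free & (np.arange(n) < n_bounded) & (x > 1.0 + 1e-10)
        if viol_lo.any() or viol_hi.any():
            # fix the single worst violator and re-solve
            excess = np.where(viol_lo, -x, np.where(viol_hi, x - 1.0, -np.inf))
            i = int(np.argmax(excess))
            fixed[i] = 0.0 if viol_lo[i] else 1.0
            continue
        # KKT release check for fixed vars
        grad = 2.0 * (np.diag(W) if W.ndim == 2 else W) * x + A.T @ lam
        release = None
        worst = -1e-8
        for i in np.flatnonzero(~free):
            mult = grad[i] if fixed[i] == 0.0 else -grad[i]
            if mult < worst:
                worst = mult
                release = i
        if release is None:
            return x
        fixed[release] = np.nan
    return x  # pragma: no cover - active-set cycling safeguard


def static_optimization(model: PlanarModel, traj: JointTrajectory,
                        net: NetJointLoads, w_reserve: float = 1.0,
                        frames: Optional[np.ndarray] = None) -> SOResult:
    """Distribute net joint torques among muscles by minimizing sum of
    squared activations.

    Per frame this solves the convex quadratic program::

        minimize    sum_m a_m^2 + w_reserve * sum_k (tau_k / tau_opt_k)^2
        subject to  sum_m a_m F0_m fL fV r_mj + tau_res,j = tau_j   (each joint)
                    0 <= a_m <= 1

    under the rigid-tendon assumption (force-length and force-velocity
    multipliers are frame constants evaluated from the measured path length
    and its rate), which makes the torque constraint linear in the
    activations.  ``frames`` optionally restricts the solved frames (used by
    the simplified hand-load approaches, which are defined only inside
    handling phases); unsolved frames hold NaN.
    """
    T = traj.time.shape[0]
    if frames is None:
        frames = np.arange(T)
    frames = np.asarray(frames, dtype=int)
    n_m = len(model.muscles)
    n_r = len(model.reserves)
    geo = model.muscle_geometry(traj.q)
    dt = 1.0 / traj.rate
    if n_m:
        ldot = central_difference(geo["length"], dt)
        fl = np.stack([m.force_length(geo["length"][:, i] / m.l_opt)
                       for i, m in enumerate(model.muscles)], axis=1)
        fv = np.stack([m.force_velocity(-ldot[:, i] / m.v_max)
                       for i, m in enumerate(model.muscles)], axis=1)
        f_max = np.array([m.f0 for m in model.muscles]) * fl * fv  # (T, n_m)
    else:
        f_max = np.zeros((T, 0))
    arms = geo["arms"]  # (T, n_m, n_j)
    tau = np.stack([net.torques[j] for j in JOINTS], axis=1)  # (T, n_j)

    W = np.concatenate([np.ones(n_m), w_reserve * np.ones(n_r)])
    act = np.full((T, n_m), np.nan)
    res = np.full((T, n_r), np.nan)
    obj = np.full(T, np.nan)
    cres = np.full(T, np.nan)
    joint_index = {j: k for k, j in enumerate(JOINTS)}
    for t in frames:
        A = np.zeros((len(JOINTS), n_m + n_r))
        A[:, :n_m] = (f_max[t][:, None] * arms[t]).T
        for k, r in enumerate(model.reserves):
            A[joint_index[r.joint], n_m + k] = r.opt_torque
        x = _solve_so_frame(W, A, tau[t], n_bounded=n_m)
        resid = np.abs(A @ x - tau[t])
        out_of_bounds = (x[:n_m] < -1e-8) | (x[:n_m] > 1.0 + 1e-8)
        if resid.max() > 1e-6 or out_of_bounds.any():
            if out_of_bounds.any():
                j_bad = model.muscles[int(np.argmax(out_of_bounds))].joint
                deficit = float(np.abs(x[:n_m]).max())
                msg = f"activation {deficit:.3g} outside [0, 1]"
            else:
                j_bad = JOINTS[int(np.argmax(resid))]
                msg = f"torque deficit {resid.max():.3g} N m"
            raise InfeasibleFrameError(
                f"static optimization infeasible at frame {t} (joint {j_bad}, "
                f"{msg})", frame=int(t), joint=j_bad)
        act[t] = x[:n_m]
        res[t] = x[n_m:] * np.array([r.opt_torque for r in model.reserves])
        obj[t] = float(x @ (W * x))
        cres[t] = float(resid.max())
    forces = act * f_max
    return SOResult(traj.time.copy(), [m.name for m in model.muscles], act, forces,
                    [r.joint for r in model.reserves], res,
                    net.residual_force.copy(), net.residual_moment.copy(),
                    obj, cres)


# --------------------------------------------------------------------------
# joint reaction analysis
# --------------------------------------------------------------------------
def joint_reaction_analysis(model: PlanarModel, traj: JointTrajectory,
                            so: SOResult, loads: ExternalLoadSet,
                            joint: str = "lumbar", side: str = "superior",
                            deriv_filter: Optional[FilterSpec] = None) -> JrfResult:
    """Reaction force transmitted across the lumbosacral joint.

    ``side='superior'`` (default) balances the superior body stack — torso,
    arms, hands and whatever is attached to them — under gravity, inertia,
    external hand loads and the pull of the muscles crossing the joint; the
    remainder is the articular reaction on the superior body.
    ``side='inferior'`` does the same bottom-up through pelvis and legs
    (including the ground reaction but not the residual actuators), so the
    two sides differ by exactly the residual wrench of the trial.
    """
    if joint != "lumbar":
        raise LiftsimError("only the lumbosacral (lumbar) joint is reported")
    dt = 1.0 / traj.rate
    qf = lowpass_filter(traj.q, traj.rate, deriv_filter) if deriv_filter else traj.q
    fk, acc, alpha = _segment_kinematics(model, qf, dt)
    stack = SUPERIOR_SEGMENTS if side == "superior" else INFERIOR_SEGMENTS
    sign = 1.0 if side == "superior" else -1.0
    p_joint = fk["joint"]["lumbar"]
    T = traj.time.shape[0]
    F = np.zeros((T, 2))
    M = np.zeros(T)
    for s in stack:
        seg = model.segments[s]
        F += seg.mass * (acc[s] - GRAVITY)
        M += seg.inertia * alpha[s] + cross_z(fk["com"][s] - p_joint,
                                              seg.mass * (acc[s] - GRAVITY))
        for e in loads.for_body(s):
            F -= e["force"]
            M -= cross_z(e["point"] - p_joint, e["force"]) + e["moment"]
    # muscle pulls on the stack: each path node on a stack segment is pulled
    # toward its neighbours with the muscle tension (internal path edges
    # cancel; only joint-crossing edges load the stack)
    geo = model.muscle_geometry(traj.q)
    in_stack = set(stack)
    for i, mus in enumerate(model.muscles):
        node_segs = [s for s, _ in mus.path]
        if all(s in in_stack for s in node_segs) or not any(s in in_stack for s in node_segs):
            continue
        nodes = geo["points"][i]
        tension = np.nan_to_num(so.muscle_forces[:, i])[:, None]
        for k, s in enumerate(node_segs):
            if s not in in_stack:
                continue
            for ka in (k - 1, k + 1):
                if ka < 0 or ka >= len(nodes):
                    continue
                d = nodes[ka] - nodes[k]
                u = d / np.linalg.norm(d, axis=1, keepdims=True)
                fm = tension * u
                F -= fm
                M -= cross_z(nodes[k] - p_joint, fm)
    F, M = sign * F, sign * M
    return JrfResult(traj.time.copy(), joint, F, M,
                     np.linalg.norm(F, axis=1), tag=loads.tag)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------
@dataclass
class PipelineResult:
    approach: str
    trajectory: JointTrajectory
    net_loads: NetJointLoads
    so: SOResult
    jrf: JrfResult
    ehf_estimate: dict            # per-hand force (T, 2) / moment (T,) / time
    phases: list
    model: PlanarModel


def run_pipeline(trial: ProcessedTrial, model: PlanarModel, approach: str,
                 phases: Optional[list] = None, w_reserve: float = 1.0,
                 deriv_filter: Optional[FilterSpec] = None) -> PipelineResult:
    """Run IK -> ID -> SO -> JR for one hand-load modeling approach.

    ``approach`` is ``'APP1'``, ``'APP2'`` or ``'APP3'``.  APP 1 solves the
    whole cycle; APP 2/3 solve muscle-level stages only inside the detected
    handling phases (their hand-load models are undefined off-phase).  All
    stages are deterministic: identical inputs give identical outputs.
    """
    from .metrics import detect_grip_events, phases_from_events

    approach = approach.upper()
    if approach not in ("APP1", "APP2", "APP3"):
        raise LiftsimError(f"unknown approach {approach!r}")
    if phases is None:
        events = detect_grip_events(trial.markers, trial.meta.box)
        phases = phases_from_events(events, trial.markers, trial.meta.box)
    ik = inverse_kinematics(trial.markers, model, deriv_filter)

    box = trial.meta.box
    if approach == "APP1":
        used_model = model
        loads = loads_app1(trial)
        rec = trial.ehfm["right"]
        est = {"force": rec.force[:, :2].copy(),
               "moment": rec.moment[:, 2].copy(),
               "time": trial.time.copy(), "tag": "APP1"}
        frames = None
    else:
        fn = loads_app2 if approach == "APP2" else loads_app3
        used_model, est = fn(model, trial, box, phases, q=ik.q)
        entries = [{"body": "foot", "force": trial.grf.force[:, :2],
                    "moment": trial.grf.moment[:, 2], "point": trial.grf.cop[:, :2]}]
        loads = ExternalLoadSet(entries, approach, trial.time.copy())
        mask = np.zeros(trial.time.shape[0], dtype=bool)
        for ph in phases:
            mask |= (trial.time >= ph.start - 1e-12) & (trial.time <= ph.end + 1e-12)
        frames = np.flatnonzero(mask)

    net = inverse_dynamics(used_model, ik, loads, deriv_filter)
    so = static_optimization(used_model, ik, net, w_reserve, frames)
    jrf = joint_reaction_analysis(used_model, ik, so, loads,
                                  deriv_filter=deriv_filter)
    if frames is not None:
        off = np.ones(trial.time.shape[0], dtype=bool)
        off[frames] = False
        jrf.force[off] = np.nan
        jrf.moment[off] = np.nan
        jrf.resultant[off] = np.nan
    return PipelineResult(approach, ik, net, so, jrf, est, phases, used_model)
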