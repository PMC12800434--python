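"""Small planar-geometry and smooth-trajectory primitives shared across modules.

Conventions (used package-wide): the motion plane is the sagittal plane with
+x anterior and +y vertical (up); the out-of-plane axis +z points to the
subject's left.  Angles are measured counter-clockwise from the +x axis.
"""
from __future__ import annotations

import numpy as np

GRAVITY = np.array([0.0, -9.81])  # m/s^2, global frame


def unit(phi):
    """Direction vector(s) (cos phi, sin phi); phi may be scalar or array."""
    phi = np.asarray(phi, dtype=float)
    return np.stack([np.cos(phi), np.sin(phi)], axis=-1)


def unit_perp(phi):
    """Derivative of :func:`unit` with respect to phi: (-sin, cos)."""
    phi = np.asarray(phi, dtype=float)
    return np.stack([-np.sin(phi), np.cos(phi)], axis=-1)


def rot2(phi):
    """2x2 rotation matrix (or stack thereof) for CCW angle phi."""
    phi = np.asarray(phi, dtype=float)
    c, s = np.cos(phi), np.sin(phi)
    return np.stack(
        [np.stack([c, -s], axis=-1), np.stack([s, c], axis=-1)], axis=-2
    )


def cross_z(a, b):
    """Out-of-plane (z) component of the cross product of planar vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def wrap_angle(phi):
    """Wrap angle(s) to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), 2.0 * np.pi)


def minimum_jerk(tau, derivative: int = 0):
    """Minimum-jerk unit displacement profile s(tau) on tau in [0, 1].

    s = 10 tau^3 - 15 tau^4 + 6 tau^5, the unique quintic with zero velocity
    and acceleration at both ends.  ``derivative`` selects s, s', s'' or s'''
    (derivatives are with respect to tau; divide by T^k for time derivatives).
    Values outside [0, 1] are clamped to the dwell value (0 or 1 for the
    position, 0 for derivatives).
    """
    tau = np.asarray(tau, dtype=float)
    t = np.clip(tau, 0.0, 1.0)
    if derivative == 0:
        out = t**3 * (10.0 - 15.0 * t + 6.0 * t**2)
    elif derivative == 1:
        out = 30.0 * t**2 * (1.0 - t) ** 2
    elif derivative == 2:
        out = 60.0 * t * (1.0 - 3.0 * t + 2.0 * t**2)
    elif derivative == 3:
        out = 60.0 * (1.0 - 6.0 * t + 6.0 * t**2)
    else:  # pragma: no cover - not used beyond jerk
        raise ValueError("derivative must be 0..3")
    if derivative > 0:
        out = np.where((tau < 0.0) | (tau > 1.0), 0.0, out)
    return out


def smoothstep(tau):
    """Cubic smoothstep 3 tau^2 - 2 tau^3, clamped to [0, 1]."""
    t = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def central_difference(y: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    """Second-order accurate time derivative along axis 0.

    Interior points use central differences; the end points use one-sided
    three-point stencils of the same order of accuracy ("quadratic
    differentiation": the stencils are exact for quadratics).
    """
    y = np.asarray(y, dtype=float)
    if order == 2:
        return central_difference(central_difference(y, dt, 1), dt, 1)
    if order != 1:
        raise ValueError("order must be 1 or 2")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    d = np.empty_like(y)
    d[1:-1] = (y[2:] - y[:-2]) / (2.0 * dt)
    d[0] = (-3.0 * y[0] + 4.0 * y[1] - y[2]) / (2.0 * dt)
    d[-1] = (3.0 * y[-1] - 4.0 * y[-2] + y[-3]) / (2.0 * dt)
    return d
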