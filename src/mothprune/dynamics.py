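"""Planar two-segment rigid-body model of a hovering hawkmoth.

The body is two rigid segments — head-thorax and abdomen — joined at a pin
joint with a torsional spring (stiffness ``K``, rest angle ``beta0``) and a
torsional damper (``C``).  The joint sits at ``(x, y)``; the head-thorax
centroid lies at ``(x, y) + (L1/2)(cos(theta), sin(theta))`` and the abdomen
centroid at ``(x, y) - (L2/2)(cos(phi), sin(phi))``, so with ``phi == theta``
the abdomen extends directly opposite the head-thorax axis (a straight body).
Angles are measured counterclockwise from the positive x-axis.

Three stroke-averaged controls act on the body: a wing force of magnitude
``F`` applied in direction ``theta + alpha`` at a point ``rF`` along the
head-thorax axis from the joint, and an abdominal torque ``tau`` about the
joint (with its equal-and-opposite reaction on the head-thorax).  Gravity
and per-segment drag at the centroids complete the force balance.  The
system is underactuated: four degrees of freedom ``(x, y, theta, phi)`` and
three controls.

The equations of motion are derived from the Lagrangian in the generalized
coordinates ``q = (x, y, theta, phi)``:

    M(q) qdd + c(q, qd) = Q(q, qd, u)

with the 4x4 mass matrix ``M``, centripetal terms ``c`` and generalized
forces ``Q`` written out in :func:`_mass_matrix` and :func:`_forcing`.
Controls are held constant over one 20 ms stroke (half a 25 Hz wingbeat),
integrated with an adaptive Runge-Kutta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BodyParams",
    "State",
    "Controls",
    "Trajectory",
    "SolverOptions",
    "state_derivative",
    "simulate_segment",
    "mechanical_energy",
    "com_state",
    "STATE_FIELDS",
]

STATE_FIELDS = ("x", "y", "theta", "phi", "xdot", "ydot", "thetadot", "phidot")


@dataclass(frozen=True)
class BodyParams:
    """Physical parameters of the two-segment body, SI units.

    The shipped defaults are hawkmoth-scale stand-ins (total mass ~2 g,
    body length ~4.5 cm, abdominal flexion resonance ~10 Hz); every physics
    test in the suite is an invariant that holds for any valid parameter set.
    """

    m1: float = 1.1e-3  # head-thorax mass (kg)
    m2: float = 0.9e-3  # abdomen mass (kg)
    L1: float = 2.0e-2  # head-thorax length (m)
    L2: float = 2.5e-2  # abdomen length (m)
    I1: float = 4.0e-8  # head-thorax moment of inertia about its centroid (kg m^2)
    I2: float = 5.0e-8  # abdomen moment of inertia about its centroid (kg m^2)
    K: float = 1.0e-3   # torsional spring stiffness (N m / rad)
    C: float = 1.0e-5   # torsional damping coefficient (N m s / rad)
    beta0: float = 0.0  # spring rest angle phi - theta (rad); 0 = straight body
    cd1: float = 5.0e-3  # head-thorax translational drag coefficient (N s/m)
    cd2: float = 5.0e-3  # abdomen translational drag coefficient (N s/m)
    g: float = 9.81     # gravitational acceleration (m/s^2)
    rF: float = 0.0     # force application offset from the joint (m)
    drag_law: Literal["linear", "quadratic"] = "linear"

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "L1", "L2", "I1", "I2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"BodyParams.{name} must be positive")
        for name in ("K", "C", "cd1", "cd2", "g"):
            if getattr(self, name) < 0:
                raise ValueError(f"BodyParams.{name} must be non-negative")
        if not 0 <= self.rF <= self.L1:
            raise ValueError("BodyParams.rF must lie in [0, L1]")
        if self.drag_law not in ("linear", "quadratic"):
            raise ValueError("drag_law must be 'linear' or 'quadratic'")

    @property
    def total_mass(self) -> float:
        return self.m1 + self.m2

    def replace(self, **kwargs) -> "BodyParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class State:
    """Joint position, segment angles and their time derivatives."""

    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0
    phi: float = 0.0
    xdot: float = 0.0
    ydot: float = 0.0
    thetadot: float = 0.0
    phidot: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("State entries must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x, self.y, self.theta, self.phi,
             self.xdot, self.ydot, self.thetadot, self.phidot],
            dtype=float,
        )

    @classmethod
    def from_array(cls, arr) -> "State":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError("State array must have shape (8,)")
        return cls(*arr)


@dataclass(frozen=True)
class Controls:
    """Stroke-averaged controls: force magnitude, force angle, abdominal torque."""

    F: float = 0.0      # wing force magnitude (N)
    alpha: float = 0.0  # force direction relative to the head-thorax midline (rad)
    tau: float = 0.0    # abdominal torque about the joint (N m)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.F, self.alpha, self.tau])):
            raise ValueError("Controls entries must be finite")
        if self.F < 0:
            raise ValueError("Controls.F must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.F, self.alpha, self.tau], dtype=float)


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive integrator settings with a fixed reporting grid."""

    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10
    report_dt: float = 1e-3  # dense-output grid spacing (s)


@dataclass
class Trajectory:
    """A time grid starting at 0 and one state row per time point."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 8), columns = STATE_FIELDS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.times[0] != 0.0:
            raise ValueError("times must be 1-D and start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, 8):
            raise ValueError("states must have shape (len(times), 8)")

    @property
    def final_state(self) -> State:
        return State.from_array(self.states[-1])

    def state_at(self, i: int) -> State:
        return State.from_array(self.states[i])

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Equations of motion (batched over trailing sample axis where arrays given)
# ---------------------------------------------------------------------------

def _mass_matrix(theta, phi, p: BodyParams) -> np.ndarray:
    """M(q) for q=(x,y,theta,phi); shape (..., 4, 4)."""
    theta = np.asarray(theta, dtype=float)
    a1, a2 = p.L1 / 2.0, p.L2 / 2.0
    mt = p.m1 + p.m2
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    z = np.zeros_like(theta)
    M = np.stack(
        [
            np.stack([np.full_like(theta, mt), z, -p.m1 * a1 * st, p.m2 * a2 * sp], axis=-1),
            np.stack([z, np.full_like(theta, mt), p.m1 * a1 * ct, -p.m2 * a2 * cp], axis=-1),
            np.stack([-p.m1 * a1 * st, p.m1 * a1 * ct,
                      np.full_like(theta, p.I1 + p.m1 * a1 ** 2), z], axis=-1),
            np.stack([p.m2 * a2 * sp, -p.m2 * a2 * cp, z,
                      np.full_like(theta, p.I2 + p.m2 * a2 ** 2)], axis=-1),
        ],
        axis=-2,
    )
    return M


def _segment_velocities(q, qd, p: BodyParams):
    """Centroid velocities of both segments; each shape (..., 2)."""
    _, _, theta, phi = q
    xd, yd, thd, phd = qd
    a1, a2 = p.L1 / 2.0, p.L2 / 2.0
    v1 = np.stack([xd - a1 * np.sin(theta) * thd, yd + a1 * np.cos(theta) * thd], axis=-1)
    v2 = np.stack([xd + a2 * np.sin(phi) * phd, yd - a2 * np.cos(phi) * phd], axis=-1)
    return v1, v2


def _drag_force(v: np.ndarray, cd: float, law: str) -> np.ndarray:
    if law == "linear":
        return -cd * v
    speed = np.linalg.norm(v, axis=-1, keepdims=True)
    return -cd * speed * v


def _forcing(q, qd, u, p: BodyParams) -> np.ndarray:
    """Q - c: generalized forces minus centripetal terms; shape (..., 4)."""
    x, y, theta, phi = q
    xd, yd, thd, phd = qd
    F, alpha, tau = u
    a1, a2 = p.L1 / 2.0, p.L2 / 2.0

    # centripetal terms c(q, qd) moved to the right-hand side
    c_x = -p.m1 * a1 * np.cos(theta) * thd ** 2 + p.m2 * a2 * np.cos(phi) * phd ** 2
    c_y = -p.m1 * a1 * np.sin(theta) * thd ** 2 + p.m2 * a2 * np.sin(phi) * phd ** 2

    # applied wing force, direction theta + alpha, acting at rF along the axis
    Fx = F * np.cos(theta + alpha)
    Fy = F * np.sin(theta + alpha)
    Q_x = Fx
    Q_y = Fy - (p.m1 + p.m2) * p.g
    # moment of the applied force about the joint: rF * F * sin(alpha)
    Q_th = p.rF * F * np.sin(alpha) - p.m1 * p.g * a1 * np.cos(theta)
    Q_ph = p.m2 * p.g * a2 * np.cos(phi)

    # internal joint torque (spring + damper) and the control torque: both act
    # on the abdomen with equal-and-opposite reaction on the head-thorax, so
    # they cancel in the (x, y) equations and never change linear momentum.
    joint = p.K * ((phi - theta) - p.beta0) + p.C * (phd - thd)
    Q_th += joint - tau
    Q_ph += -joint + tau

    # drag at each centroid, mapped through the segment Jacobians
    v1, v2 = _segment_velocities(q, qd, p)
    f1 = _drag_force(v1, p.cd1, p.drag_law)
    f2 = _drag_force(v2, p.cd2, p.drag_law)
    Q_x = Q_x + f1[..., 0] + f2[..., 0]
    Q_y = Q_y + f1[..., 1] + f2[..., 1]
    Q_th = Q_th + a1 * (-np.sin(theta) * f1[..., 0] + np.cos(theta) * f1[..., 1])
    Q_ph = Q_ph + a2 * (np.sin(phi) * f2[..., 0] - np.cos(phi) * f2[..., 1])

    return np.stack([Q_x - c_x, Q_y - c_y, Q_th, Q_ph], axis=-1)


def state_derivative_array(states: np.ndarray, controls: np.ndarray,
                           params: BodyParams) -> np.ndarray:
    """Vectorized time derivative.

    Parameters
    ----------
    states : array (..., 8) ordered as STATE_FIELDS
    controls : array (..., 3) ordered (F, alpha, tau)
    """
    states = np.asarray(states, dtype=float)
    controls = np.asarray(controls, dtype=float)
    q = tuple(states[..., i] for i in range(4))
    qd = tuple(states[..., i] for i in range(4, 8))
    u = tuple(controls[..., i] for i in range(3))
    M = _mass_matrix(q[2], q[3], params)
    rhs = _forcing(q, qd, u, params)
    qdd = np.linalg.solve(M, rhs[..., None])[..., 0]
    return np.concatenate([states[..., 4:8], qdd], axis=-1)


def state_derivative(state: State, controls: Controls,
                     params: BodyParams) -> np.ndarray:
    """Time derivative (xdot, ydot, thetadot, phidot, xddot, yddot, thetaddot, phiddot)."""
    return state_derivative_array(state.as_array(), controls.as_array(), params)


def simulate_segment(state0: State, controls: Controls, params: BodyParams,
                     duration: float = 0.02,
                     options: SolverOptions | None = None) -> Trajectory:
    """Integrate one constant-control stroke from ``state0`` for ``duration`` seconds.

    Returns a :class:`Trajectory` sampled on a fixed reporting grid (1 ms by
    default) that always includes t=0 and t=duration.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    opts = options or SolverOptions()
    u = controls.as_array()

    def rhs(t, yvec):
        return state_derivative_array(yvec, u, params)

    n_report = max(int(round(duration / opts.report_dt)), 1)
    t_eval = np.linspace(0.0, duration, n_report + 1)
    sol = solve_ivp(rhs, (0.0, duration), state0.as_array(), method=opts.method,
                    rtol=opts.rtol, atol=opts.atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message}; last state {sol.y[:, -1]}")
    return Trajectory(times=sol.t, states=sol.y.T)


def simulate_batch_final(states0: np.ndarray, controls: np.ndarray,
                         params: BodyParams, duration: float = 0.02,
                         options: SolverOptions | None = None) -> np.ndarray:
    """Final states of many constant-control strokes, integrated jointly.

    All samples are stacked into one ODE system so the adaptive integrator's
    per-component error control applies to every trajectory while the
    right-hand side stays fully vectorized.  Returns array (n, 8).
    """
    opts = options or SolverOptions()
    states0 = np.asarray(states0, dtype=float)
    controls = np.asarray(controls, dtype=float)
    n = states0.shape[0]

    def rhs(t, yflat):
        return state_derivative_array(
            yflat.reshape(n, 8), controls, params).ravel()

    sol = solve_ivp(rhs, (0.0, duration), states0.ravel(), method=opts.method,
                    rtol=opts.rtol, atol=opts.atol, t_eval=[duration])
    if not sol.success:
        raise RuntimeError(f"batched integration failed: {sol.message}")
    return sol.y[:, -1].reshape(n, 8)


def mechanical_energy(state: State, params: BodyParams) -> float:
    """Kinetic + gravitational + spring potential energy (J).

    Gravitational reference: centroid height 0.
    """
    q = (state.x, state.y, state.theta, state.phi)
    qd = (state.xdot, state.ydot, state.thetadot, state.phidot)
    v1, v2 = _segment_velocities(q, qd, params)
    ke = (0.5 * params.m1 * np.dot(v1, v1) + 0.5 * params.I1 * state.thetadot ** 2
          + 0.5 * params.m2 * np.dot(v2, v2) + 0.5 * params.I2 * state.phidot ** 2)
    a1, a2 = params.L1 / 2.0, params.L2 / 2.0
    y1 = state.y + a1 * np.sin(state.theta)
    y2 = state.y - a2 * np.sin(state.phi)
    pe = params.m1 * params.g * y1 + params.m2 * params.g * y2
    spring = 0.5 * params.K * ((state.phi - state.theta) - params.beta0) ** 2
    return float(ke + pe + spring)


def com_state(state: State, params: BodyParams) -> tuple[np.ndarray, np.ndarray]:
    """Centre-of-mass position and velocity (mass-weighted over both segments)."""
    a1, a2 = params.L1 / 2.0, params.L2 / 2.0
    r1 = np.array([state.x + a1 * np.cos(state.theta),
                   state.y + a1 * np.sin(state.theta)])
    r2 = np.array([state.x - a2 * np.cos(state.phi),
                   state.y - a2 * np.sin(state.phi)])
    q = (state.x, state.y, state.theta, state.phi)
    qd = (state.xdot, state.ydot, state.thetadot, state.phidot)
    v1, v2 = _segment_velocities(q, qd, params)
    mt = params.total_mass
    pos = (params.m1 * r1 + params.m2 * r2) / mt
    vel = (params.m1 * np.asarray(v1) + params.m2 * np.asarray(v2)) / mt
    return pos, vel
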