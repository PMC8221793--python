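"""Feedforward planning by stochastic optimal open-loop control (SOOC).

The stochastic reaching problem is reformulated as a deterministic optimal
control problem on the mean ``m(t)`` and covariance ``P(t)`` of the arm state
(second-order Taylor closure of the SDE moments).  The open-loop torque-change
command minimizes

    r * tr[J(q_T) P_q(T) J(q_T)'] + int_0^T ( u'u + alpha * |hand jerk|^2 ) dt

subject to hard terminal constraints on the mean (hand on target, zero joint
velocity, zero torque).  Movement duration T is either fixed or a free
decision variable (time-scaling transform), in which case the optimal
duration emerges from the effort/variance trade-off created by constant and
signal-dependent motor noise.

The transcription is single shooting: the control is piecewise linear on a
uniform grid in normalized time, the moment ODEs are integrated with
fixed-step RK4, and the resulting nonlinear program is solved with SLSQP
using batched finite-difference gradients (all perturbed trajectories are
propagated in one vectorized pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import arm as _arm
from .arm import ArmParams, NoiseParams, STATE_DIM
from ._codegen import get_derivatives, vech, unvech, VECH_DIM

__all__ = [
    "OCPSpec",
    "FeedforwardPlan",
    "propagate_mean_cov",
    "terminal_variance_cost",
    "running_cost",
    "solve_fixed_time",
    "solve_free_time",
    "cost_vs_duration_scan",
    "make_task",
    "log_endpoint_variance",
]

_M2_TO_MM2 = 1.0e6


def make_task(q0_deg: Sequence[float], direction_deg: float, distance: float,
              params: ArmParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Initial state and hand target for a planar reach.

    ``q0_deg`` is the initial joint configuration in degrees, the target lies
    at ``distance`` metres from the initial hand position along
    ``direction_deg`` (screen convention: 0 = E, 90 = N, 135 = N-W).
    The arm starts at rest with zero torque.
    """
    params = params or ArmParams()
    q0 = np.deg2rad(np.asarray(q0_deg, dtype=float))
    x0 = np.zeros(STATE_DIM)
    x0[:2] = q0
    p0 = _arm.forward_kinematics(q0, params)
    ang = np.deg2rad(direction_deg)
    target = p0 + distance * np.array([np.cos(ang), np.sin(ang)])
    return x0, target


@dataclass
class OCPSpec:
    """Specification of one open-loop planning problem."""

    x0: np.ndarray
    target: np.ndarray
    r: float = 2000.0
    alpha: float = 0.02
    params: ArmParams = field(default_factory=ArmParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    P0: np.ndarray | None = None
    n_controls: int = 21        # control nodes (piecewise-linear u)
    n_steps: int = 100          # RK4 steps of the moment ODEs
    ftol: float = 1e-10
    maxiter: int = 400
    T_bounds: tuple[float, float] = (0.15, 3.0)

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.x0.shape != (STATE_DIM,):
            raise ValueError("x0 must be a 6-vector [q, qd, tau]")
        if self.target.shape != (2,):
            raise ValueError("target must be a hand position (2,)")
        if self.r < 0 or self.alpha < 0:
            raise ValueError("cost weights r and alpha must be non-negative")
        if self.P0 is None:
            self.P0 = np.zeros((STATE_DIM, STATE_DIM))
        self.P0 = np.asarray(self.P0, dtype=float)


@dataclass
class FeedforwardPlan:
    """Open-loop plan: time grid, control, mean and covariance trajectories."""

    t: np.ndarray               # (n+1,)
    u: np.ndarray               # (n+1, 2) control on the dense grid
    m: np.ndarray               # (n+1, 6) mean state
    P: np.ndarray               # (n+1, 6, 6) state covariance
    T: float                    # planned duration (s)
    u_nodes: np.ndarray         # (K, 2) decision-variable control values
    cost_total: float
    cost_terms: dict            # {"variance", "effort", "jerk"}
    spec: OCPSpec
    status: dict

    @property
    def hand(self) -> np.ndarray:
        """Mean hand path (n+1, 2)."""
        return _arm.forward_kinematics(self.m[:, :2], self.spec.params)

    @property
    def hand_speed(self) -> np.ndarray:
        v = np.einsum("...ij,...j->...i",
                      _arm.jacobian(self.m[:, :2], self.spec.params),
                      self.m[:, 2:4])
        return np.linalg.norm(v, axis=-1)

    @property
    def log_endpoint_variance(self) -> float:
        """ln of the endpoint positional variance, in log(mm^2)."""
        return log_endpoint_variance(self.m[-1], self.P[-1], self.spec.params)

    def interp_u(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.stack([np.interp(t, self.t, self.u[:, k], right=0.0)
                         for k in range(2)], axis=-1)

    def interp_m(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.stack([np.interp(t, self.t, self.m[:, k])
                         for k in range(STATE_DIM)], axis=-1)


def terminal_variance_cost(mT: np.ndarray, PT: np.ndarray,
                           params: ArmParams) -> float:
    """tr[J(q_T) P_q(T) J(q_T)'] — Cartesian endpoint position variance (m^2)."""
    J = _arm.jacobian(np.asarray(mT)[:2], params)
    Pq = np.asarray(PT)[:2, :2]
    return float(np.trace(J @ Pq @ J.T))


def log_endpoint_variance(mT: np.ndarray, PT: np.ndarray,
                          params: ArmParams) -> float:
    """Natural log of the endpoint positional variance expressed in mm^2."""
    return float(np.log(terminal_variance_cost(mT, PT, params) * _M2_TO_MM2))


# ---------------------------------------------------------------------------
# moment propagation
# ---------------------------------------------------------------------------

def _control_stage_tables(n_controls: int, n_steps: int):
    """Interpolation (index, weight) of the piecewise-linear control at the
    three distinct RK4 stage times of every step, on normalized time."""
    s_nodes = np.linspace(0.0, 1.0, n_controls)
    tables = []
    for offset in (0.0, 0.5, 1.0):
        s = (np.arange(n_steps) + offset) / n_steps
        i = np.clip(np.searchsorted(s_nodes, s, side="right") - 1,
                    0, n_controls - 2)
        w = (s - s_nodes[i]) / (s_nodes[i + 1] - s_nodes[i])
        tables.append((i, np.clip(w, 0.0, 1.0)))
    return tables


def _u_at(U: np.ndarray, table, k: int) -> np.ndarray:
    i, w = table
    return (1.0 - w[k]) * U[..., i[k], :] + w[k] * U[..., i[k] + 1, :]


def _integrate_batch(deriv, x0: np.ndarray, P0: np.ndarray, U: np.ndarray,
                     T: np.ndarray, noise_vec, n_steps: int,
                     store: bool = False):
    """RK4 propagation of [m, vech(P), effort, jerk-integral] over s in [0,1].

    ``U`` has shape (..., K, 2) and ``T`` shape (...,); all leading axes are
    propagated simultaneously.  Returns the final augmented state
    (..., 29) or, with ``store=True``, the full trajectory (n+1, ..., 29).
    """
    U = np.asarray(U, dtype=float)
    T = np.asarray(T, dtype=float)
    batch = np.broadcast_shapes(U.shape[:-2], T.shape)
    n_controls = U.shape[-2]
    tables = _control_stage_tables(n_controls, n_steps)
    h = 1.0 / n_steps

    y = np.zeros(batch + (6 + VECH_DIM + 2,))
    y[..., :6] = x0
    y[..., 6:6 + VECH_DIM] = vech(np.asarray(P0, dtype=float))
    Tb = np.broadcast_to(T, batch)[..., None]

    def rhs(yk, u):
        out = deriv.rhs(yk[..., :6 + VECH_DIM], u, noise_vec)
        effort = np.sum(u * u, axis=-1)
        return Tb * np.concatenate(
            [out[..., :6 + VECH_DIM],
             effort[..., None], out[..., 6 + VECH_DIM:]], axis=-1)

    traj = None
    if store:
        traj = np.zeros((n_steps + 1,) + y.shape)
        traj[0] = y
    for k in range(n_steps):
        u0 = _u_at(U, tables[0], k)
        um = _u_at(U, tables[1], k)
        u1 = _u_at(U, tables[2], k)
        k1 = rhs(y, u0)
        k2 = rhs(y + 0.5 * h * k1, um)
        k3 = rhs(y + 0.5 * h * k2, um)
        k4 = rhs(y + h * k3, u1)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if store:
            traj[k + 1] = y
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(
            "moment propagation diverged (non-finite state); "
            "check controls/duration")
    return traj if store else y


def propagate_mean_cov(u: Callable[[np.ndarray], np.ndarray] | np.ndarray,
                       x0: np.ndarray, P0: np.ndarray,
                       params: ArmParams, noise: NoiseParams,
                       T: float, n_steps: int = 200):
    """Integrate the coupled mean/covariance ODEs under a given control.

    ``u`` is either a callable ``u(t) -> (..., 2)`` or an array of control
    values (K, 2) interpreted on a uniform grid over [0, T].  Returns
    ``(t, m, P)`` with ``m`` (n+1, 6) and ``P`` (n+1, 6, 6); ``P`` is
    symmetric PSD at every node (symmetric storage by construction).
    """
    deriv = get_derivatives(params)
    if callable(u):
        tg = np.linspace(0.0, T, 4 * n_steps + 1)
        U = np.asarray(u(tg), dtype=float).reshape(len(tg), 2)
    else:
        U = np.asarray(u, dtype=float)
        if U.ndim != 2 or U.shape[1] != 2:
            raise ValueError("control array must have shape (K, 2)")
    noise_vec = (noise.sigma1, noise.sigma2, noise.d1, noise.d2)
    traj = _integrate_batch(deriv, np.asarray(x0, float), P0, U,
                            np.asarray(T, float), noise_vec, n_steps,
                            store=True)
    t = np.linspace(0.0, T, n_steps + 1)
    m = traj[:, :6]
    P = unvech(traj[:, 6:6 + VECH_DIM])
    return t, m, P


def running_cost(t: np.ndarray, m: np.ndarray, u: np.ndarray, alpha: float,
                 params: ArmParams | None = None) -> float:
    """int_0^T ( u'u + alpha |hand jerk|^2 ) dt on a mean trajectory.

    Hand jerk is evaluated analytically by chain-differentiating the forward
    kinematics along the drift (torque rate = u).
    """
    params = params or ArmParams()
    deriv = get_derivatives(params)
    effort = np.sum(np.asarray(u) ** 2, axis=-1)
    jerk2 = deriv.hand_jerk_sq(np.asarray(m), np.asarray(u))
    return float(np.trapezoid(effort + alpha * jerk2, t))


# ---------------------------------------------------------------------------
# transcription
# ---------------------------------------------------------------------------

def _min_jerk_guess(spec: OCPSpec, T: float) -> np.ndarray:
    """Initial control guess: minimum-jerk hand path -> IK -> inverse dynamics."""
    params = spec.params
    K = spec.n_controls
    n = 8 * K
    t = np.linspace(0.0, T, n + 1)
    s = t / T
    blend = 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5
    p0 = _arm.forward_kinematics(spec.x0[:2], params)
    path = p0 + blend[:, None] * (spec.target - p0)
    q = _arm.inverse_kinematics(path, params,
                                elbow_up=spec.x0[1] >= 0)
    dt = t[1] - t[0]
    qd = np.gradient(q, dt, axis=0)
    qdd = np.gradient(qd, dt, axis=0)
    M = _arm.inertia_matrix(q, params)
    C = _arm.coriolis_matrix(q, qd, params)
    tau = (np.einsum("...ij,...j->...i", M, qdd)
           + np.einsum("...ij,...j->...i", C, qd)
           + qd @ np.asarray(params.B).T)
    u = np.gradient(tau, dt, axis=0)
    si = np.linspace(0.0, 1.0, K)
    return np.stack([np.interp(si, s, u[:, k]) for k in range(2)], axis=-1)


class _ShootingProblem:
    """Cost/constraint evaluation with a shared batched FD Jacobian."""

    def __init__(self, spec: OCPSpec, free_time: bool, T_fixed: float | None):
        self.spec = spec
        self.free_time = free_time
        self.T_fixed = T_fixed
        self.deriv = get_derivatives(spec.params)
        self.noise_vec = (spec.noise.sigma1, spec.noise.sigma2,
                          spec.noise.d1, spec.noise.d2)
        self.K = spec.n_controls
        self.nu = 2 * self.K
        self.n_var = self.nu + (1 if free_time else 0)
        self.fd_step = 1e-6
        self._cache_w = None
        self._cache = None
        self.nfev = 0

    def _unpack(self, w: np.ndarray):
        U = w[..., :self.nu].reshape(w.shape[:-1] + (self.K, 2))
        if self.free_time:
            T = w[..., self.nu]
        else:
            T = np.full(w.shape[:-1], self.T_fixed)
        return U, T

    def _terminal(self, y_end: np.ndarray, T: np.ndarray):
        spec = self.spec
        mT = y_end[..., :6]
        PT = unvech(y_end[..., 6:6 + VECH_DIM])
        J = _arm.jacobian(mT[..., :2], spec.params)
        Pq = PT[..., :2, :2]
        var_term = np.trace(J @ Pq @ np.swapaxes(J, -1, -2),
                            axis1=-2, axis2=-1)
        effort = y_end[..., 6 + VECH_DIM]
        jerk = y_end[..., 6 + VECH_DIM + 1]
        cost = spec.r * var_term + effort + spec.alpha * jerk
        hand = _arm.forward_kinematics(mT[..., :2], spec.params)
        cons = np.concatenate([hand - spec.target,
                               mT[..., 2:4], mT[..., 4:6]], axis=-1)
        return cost, cons, (var_term, effort, jerk)

    def evaluate(self, w: np.ndarray):
        U, T = self._unpack(w)
        y_end = _integrate_batch(self.deriv, self.spec.x0, self.spec.P0, U, T,
                                 self.noise_vec, self.spec.n_steps)
        self.nfev += int(np.prod(w.shape[:-1])) if w.ndim > 1 else 1
        return self._terminal(y_end, T)

    def value_and_jac(self, w: np.ndarray):
        key = w.tobytes()
        if self._cache_w == key:
            return self._cache
        n = self.n_var
        W = np.tile(w, (n + 1, 1))
        h = self.fd_step * np.maximum(1.0, np.abs(w))
        W[1:] += np.diag(h)
        cost, cons, _ = self.evaluate(W)
        f0, c0 = cost[0], cons[0]
        fjac = (cost[1:] - f0) / h
        cjac = (cons[1:] - c0) / h[:, None]
        self._cache_w = key
        self._cache = (f0, c0, fjac, cjac.T)
        return self._cache


def _solve(spec: OCPSpec, free_time: bool, T_fixed: float | None = None,
           T_guess: float | None = None,
           u_guess: np.ndarray | None = None) -> FeedforwardPlan:
    prob = _ShootingProblem(spec, free_time, T_fixed)
    T0 = T_guess if free_time else T_fixed
    if u_guess is None:
        u_guess = _min_jerk_guess(spec, T0)
    w0 = np.asarray(u_guess, dtype=float).ravel()
    if w0.size != prob.nu:
        raise ValueError("control guess has wrong number of nodes")
    bounds = [(None, None)] * prob.nu
    if free_time:
        w0 = np.append(w0, T0)
        bounds.append(spec.T_bounds)

    res = minimize(
        lambda w: prob.value_and_jac(w)[0], w0,
        jac=lambda w: prob.value_and_jac(w)[2],
        constraints=[{
            "type": "eq",
            "fun": lambda w: prob.value_and_jac(w)[1],
            "jac": lambda w: prob.value_and_jac(w)[3],
        }],
        bounds=bounds, method="SLSQP",
        options={"ftol": spec.ftol, "maxiter": spec.maxiter},
    )
    cost, cons, _ = prob.evaluate(res.x)
    cviol = float(np.max(np.abs(cons)))
    if not (res.success or cviol < 1e-6):
        raise RuntimeError(
            f"SOOC transcription did not converge: {res.message} "
            f"(iter={res.nit}, constraint violation={cviol:.2e})")

    U, T = prob._unpack(res.x)
    T = float(T)
    traj = _integrate_batch(prob.deriv, spec.x0, spec.P0, U, np.asarray(T),
                            prob.noise_vec, spec.n_steps, store=True)
    _, _, (var_term, effort, jerk) = prob._terminal(traj[-1], np.asarray(T))
    t = np.linspace(0.0, T, spec.n_steps + 1)
    s_nodes = np.linspace(0.0, 1.0, spec.n_controls)
    u_dense = np.stack([np.interp(t / T, s_nodes, U[:, k]) for k in range(2)],
                       axis=-1)
    return FeedforwardPlan(
        t=t, u=u_dense, m=traj[:, :6],
        P=unvech(traj[:, 6:6 + VECH_DIM]), T=T, u_nodes=U,
        cost_total=float(cost),
        cost_terms={
            "variance": float(spec.r * var_term),
            "effort": float(effort),
            "jerk": float(spec.alpha * jerk),
        },
        spec=spec,
        status={"converged": bool(res.success), "n_iter": int(res.nit),
                "nfev": prob.nfev, "constraint_violation": cviol,
                "message": str(res.message)},
    )


def solve_fixed_time(spec: OCPSpec, T: float,
                     u_guess: np.ndarray | None = None) -> FeedforwardPlan:
    """Solve the SOOC problem at a preset movement duration ``T``."""
    if not T > 0:
        raise ValueError("fixed duration T must be positive")
    return _solve(spec, free_time=False, T_fixed=float(T), u_guess=u_guess)


def solve_free_time(spec: OCPSpec, T_guess: float = 1.0,
                    u_guess: np.ndarray | None = None) -> FeedforwardPlan:
    """Solve the SOOC problem with the duration as a decision variable.

    A finite interior optimum requires constant (additive) motor noise: with
    sigma = 0 the total cost typically decreases monotonically with duration
    and no finite preferred time exists; a warning is emitted in that case.
    """
    if spec.noise.sigma1 == 0.0 and spec.noise.sigma2 == 0.0:
        warnings.warn("sigma = 0: no finite optimal duration is guaranteed "
                      "(cost may decrease monotonically with T)",
                      stacklevel=2)
    return _solve(spec, free_time=True, T_guess=float(T_guess),
                  u_guess=u_guess)


def cost_vs_duration_scan(spec: OCPSpec, durations: Sequence[float],
                          warm_start: bool = True) -> pd.DataFrame:
    """One fixed-time solve per duration; returns all cost components.

    Failures of individual solves are recorded (``converged`` False, NaN
    costs) and the scan continues.  Consecutive solves are warm-started with
    the previous control solution (same normalized-time node grid).
    """
    rows = []
    u_prev = None
    for T in durations:
        try:
            plan = solve_fixed_time(spec, T, u_guess=u_prev)
            if warm_start:
                u_prev = plan.u_nodes
            rows.append({
                "T": T, "total": plan.cost_total,
                "variance": plan.cost_terms["variance"],
                "effort": plan.cost_terms["effort"],
                "jerk": plan.cost_terms["jerk"],
                "log_endpoint_variance": plan.log_endpoint_variance,
                "converged": plan.status["converged"],
            })
        except (RuntimeError, FloatingPointError) as exc:
            rows.append({"T": T, "total": np.nan, "variance": np.nan,
                         "effort": np.nan, "jerk": np.nan,
                         "log_endpoint_variance": np.nan,
                         "converged": False, "error": str(exc)})
    return pd.DataFrame(rows)
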