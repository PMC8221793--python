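"""Locally-optimal LQG feedback around a feedforward plan.

The arm dynamics are linearized along the planned mean/control trajectory in
deviation coordinates ``z = x - m(t)``, ``v = u - u(t)``; the horizon is
extended beyond the planned duration (``T' = T + 1 s`` by default, the system
held at rest for ``t >= T``), the system is discretized at ``dt = 0.005 s``,
optionally augmented with delayed state copies to model sensory latency, and
the optimal feedback gains K(t) (backward Riccati recursion) and Kalman
filter gains L(t) (forward recursion) are computed.

State deviations are penalized only during the post-movement interval
(``R_state = rho * diag(1,1,0,0,0,0)`` on [T, T']), so feedback corrects
deviations of the final arm posture — task-related errors — rather than
tracking the planned trajectory, in line with the minimal intervention
principle.  Because the diffusion in deviation coordinates depends on the
nominal command only (additive from the controller's viewpoint), certainty
equivalence holds and controller and filter are computed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import arm as _arm
from .arm import ArmParams, NoiseParams, STATE_DIM
from ._codegen import get_derivatives
from .planner import FeedforwardPlan

__all__ = [
    "LinearizedSystem",
    "DiscreteSystem",
    "LQGController",
    "linearize_and_extend",
    "discretize",
    "augment_delay",
    "feedback_gains",
    "filter_gains",
    "build_controller",
    "predicted_deviation_covariance",
]

_POSTURE_WEIGHT = np.diag([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])


@dataclass
class LinearizedSystem:
    """Continuous-time linearization on the extended grid [0, T']."""

    t: np.ndarray          # (N+1,) grid, spacing dt
    A: np.ndarray          # (N+1, 6, 6) drift Jacobian along the plan
    B: np.ndarray          # (6, 2) control Jacobian (constant: u enters tau-dot)
    G: np.ndarray          # (N+1, 6, 4) diffusion at the nominal command
    C: np.ndarray          # (L, 6) output matrix
    D: np.ndarray          # (L, L) observation-noise matrix beta * I
    dt: float
    T: float               # planned movement duration
    T_prime: float         # extended horizon
    m_ext: np.ndarray      # (N+1, 6) extended nominal mean (rest beyond T)
    u_ext: np.ndarray      # (N+1, 2) extended nominal control (0 beyond T)


@dataclass
class DiscreteSystem:
    """Per-step discrete-time LQG quantities.

    Conventions: transition ``Phi_k = I + A_k dt``, control matrix ``B dt``,
    process-noise covariance ``W_k = G_k G_k' dt``, measurement-noise
    covariance ``V = (D D') / dt`` (the integrated-observation form of the
    continuous output equation preserves the information rate under this
    scaling).
    """

    t: np.ndarray          # (N+1,)
    Phi: np.ndarray        # (N, n, n)
    Bd: np.ndarray         # (N, n, 2)
    W: np.ndarray          # (N, n, n)
    C: np.ndarray          # (L, n)
    V: np.ndarray          # (L, L)
    dt: float
    T: float
    T_prime: float
    delay_steps: int = 0

    @property
    def n(self) -> int:
        return self.Phi.shape[-1]

    @property
    def n_steps(self) -> int:
        return self.Phi.shape[0]


@dataclass
class LQGController:
    """Feedback gains K(t) and filter gains L(t) over the extended horizon."""

    sys: DiscreteSystem
    K: np.ndarray          # (N, 2, n)
    L: np.ndarray          # (N, n, L_obs)
    rho: float
    beta: float

    @property
    def dt(self) -> float:
        return self.sys.dt

    @property
    def delay_steps(self) -> int:
        return self.sys.delay_steps


def linearize_and_extend(plan: FeedforwardPlan,
                         params: ArmParams | None = None,
                         noise: NoiseParams | None = None,
                         T_prime: float | None = None,
                         dt: float = 0.005,
                         observed: str = "full") -> LinearizedSystem:
    """Linearize the arm dynamics along a plan and extend the horizon.

    For ``t <= T`` the Jacobians are evaluated at (m(t), u(t)); beyond T the
    system is held at the terminal rest state with u = 0.  ``observed`` is
    ``"full"`` (C = I6) or ``"posvel"`` (position and velocity rows only).
    """
    params = params or plan.spec.params
    noise = noise or plan.spec.noise
    T = plan.T
    T_prime = T + 1.0 if T_prime is None else T_prime
    if T_prime < T:
        raise ValueError("extended horizon T' must be >= plan duration T")
    N = int(round(T_prime / dt))
    t = np.arange(N + 1) * dt

    m_ext = plan.interp_m(np.minimum(t, T))
    rest = plan.m[-1].copy()
    rest[2:] = 0.0
    m_ext[t > T] = rest
    u_ext = plan.interp_u(t)
    u_ext[t > T] = 0.0

    deriv = get_derivatives(params)
    A = deriv.drift_jacobian(m_ext)
    if not np.all(np.isfinite(A)):
        raise FloatingPointError("non-finite Jacobian along the plan")
    B = np.zeros((STATE_DIM, 2))
    B[4, 0] = 1.0
    B[5, 1] = 1.0
    G = _arm.diffusion(u_ext, noise)

    if observed == "full":
        C = np.eye(STATE_DIM)
    elif observed == "posvel":
        C = np.eye(STATE_DIM)[:4]
    else:
        raise ValueError("observed must be 'full' or 'posvel'")
    D = noise.beta * np.eye(C.shape[0])
    return LinearizedSystem(t=t, A=A, B=B, G=G, C=C, D=D, dt=dt, T=T,
                            T_prime=T_prime, m_ext=m_ext, u_ext=u_ext)


def discretize(sys: LinearizedSystem, dt: float | None = None) -> DiscreteSystem:
    """Euler discretization of the linearized system (see class docstring)."""
    if dt is not None and not np.isclose(dt, sys.dt):
        raise ValueError("discretization step must match the linearization grid")
    dt = sys.dt
    N = len(sys.t) - 1
    eye = np.eye(STATE_DIM)
    Phi = eye[None] + sys.A[:N] * dt
    Bd = np.broadcast_to(sys.B * dt, (N, STATE_DIM, 2)).copy()
    GT = np.swapaxes(sys.G[:N], -1, -2)
    W = sys.G[:N] @ GT * dt
    V = (sys.D @ sys.D.T) / dt
    return DiscreteSystem(t=sys.t, Phi=Phi, Bd=Bd, W=W, C=sys.C.copy(), V=V,
                          dt=dt, T=sys.T, T_prime=sys.T_prime)


def augment_delay(sys: DiscreteSystem, delay: float = 0.05) -> DiscreteSystem:
    """Augment the state with past copies so the observation is delayed.

    ``delay`` must be an integer multiple of dt; k = delay/dt past states are
    appended and the output matrix reads the k-step-old block.  With k = 0
    the system is returned unchanged.
    """
    k = delay / sys.dt
    if abs(k - round(k)) > 1e-9:
        raise ValueError("delay must be an integer multiple of dt")
    k = int(round(k))
    if k == 0:
        return sys
    if sys.delay_steps:
        raise ValueError("system is already delay-augmented")
    n = sys.n
    na = n * (k + 1)
    N = sys.n_steps
    Phi = np.zeros((N, na, na))
    Phi[:, :n, :n] = sys.Phi
    Phi[:, n:, :n * k] += np.eye(n * k)
    Bd = np.zeros((N, na, 2))
    Bd[:, :n, :] = sys.Bd
    W = np.zeros((N, na, na))
    W[:, :n, :n] = sys.W
    C = np.zeros((sys.C.shape[0], na))
    C[:, n * k:] = sys.C
    return replace(sys, Phi=Phi, Bd=Bd, W=W, C=C, delay_steps=k)


def _state_weight(sys: DiscreteSystem, rho: float) -> np.ndarray:
    """Per-step state-cost schedule: zero before T, rho*diag(1,1,0,...)*dt after."""
    Q = np.zeros((sys.n_steps + 1, sys.n, sys.n))
    active = sys.t >= sys.T - 1e-12
    Q[active, :STATE_DIM, :STATE_DIM] = rho * _POSTURE_WEIGHT * sys.dt
    return Q


def feedback_gains(sys: DiscreteSystem, rho: float) -> np.ndarray:
    """Optimal feedback gains K_k by backward Riccati recursion.

    State deviations are penalized only on the post-movement interval
    [T, T'] (posture rows), control effort at every step.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    N, n = sys.n_steps, sys.n
    Q = _state_weight(sys, rho)
    R = np.eye(2) * sys.dt
    K = np.zeros((N, 2, n))
    S = Q[N].copy()
    for k in range(N - 1, -1, -1):
        Phi, Bd = sys.Phi[k], sys.Bd[k]
        BS = Bd.T @ S
        K[k] = np.linalg.solve(R + BS @ Bd, BS @ Phi)
        S = Q[k] + Phi.T @ S @ (Phi - Bd @ K[k])
        S = 0.5 * (S + S.T)
        if not np.all(np.isfinite(S)):
            raise FloatingPointError(f"Riccati recursion diverged at step {k}")
    return K


def filter_gains(sys: DiscreteSystem, beta: float | None = None) -> np.ndarray:
    """Kalman gains L_k by the forward Riccati recursion (Sigma_0 = 0).

    ``beta`` overrides the observation-noise magnitude baked into ``sys.V``
    (V = beta^2/dt * I); the estimator starts from the known initial state,
    consistent with P0 = 0 at movement onset.
    """
    N, n = sys.n_steps, sys.n
    C = sys.C
    V = sys.V if beta is None else (beta ** 2 / sys.dt) * np.eye(C.shape[0])
    L = np.zeros((N, n, C.shape[0]))
    Sig = np.zeros((n, n))
    for k in range(N):
        Phi = sys.Phi[k]
        S_ct = Sig @ C.T
        L[k] = np.linalg.solve((C @ S_ct + V).T, (Phi @ S_ct).T).T
        Sig = sys.W[k] + (Phi - L[k] @ C) @ Sig @ Phi.T
        Sig = 0.5 * (Sig + Sig.T)
        if not np.all(np.isfinite(Sig)):
            raise FloatingPointError(f"filter recursion diverged at step {k}")
    return L


def build_controller(plan: FeedforwardPlan,
                     rho: float = 1000.0,
                     beta: float | None = None,
                     delay: float | None = None,
                     T_prime: float | None = None,
                     dt: float = 0.005,
                     observed: str = "full") -> LQGController:
    """Linearize, extend, discretize, (optionally) delay-augment, compute gains."""
    noise = plan.spec.noise if beta is None else \
        replace(plan.spec.noise, beta=beta)
    delay = noise.delay if delay is None else delay
    lin = linearize_and_extend(plan, noise=noise, T_prime=T_prime, dt=dt,
                               observed=observed)
    dsys = discretize(lin)
    if delay:
        dsys = augment_delay(dsys, delay)
    K = feedback_gains(dsys, rho)
    L = filter_gains(dsys)
    return LQGController(sys=dsys, K=K, L=L, rho=rho, beta=noise.beta)


def predicted_deviation_covariance(ctl: LQGController) -> np.ndarray:
    """Closed-loop state-deviation covariance cov(z_k), shape (N+1, n, n).

    Exact linear-Gaussian propagation of the joint covariance of
    (z, estimation error) under the computed gains; the analytic counterpart
    of Monte-Carlo rollouts.  In deviation coordinates the process noise is
    exogenous (it depends on the nominal command only), so the recursion is
    exact for the linearized system.
    """
    sys, K, L = ctl.sys, ctl.K, ctl.L
    N, n = sys.n_steps, sys.n
    C = sys.C
    out = np.zeros((N + 1, n, n))
    # joint state [z; e] with e = z - zhat; plant noise enters both blocks,
    # measurement noise enters the error block through -L
    J = np.zeros((2 * n, 2 * n))
    for k in range(N):
        Phi, Bd, W = sys.Phi[k], sys.Bd[k], sys.W[k]
        BK = Bd @ K[k]
        LC = L[k] @ C
        F = np.block([[Phi - BK, BK], [np.zeros((n, n)), Phi - LC]])
        noise = np.zeros((2 * n, 2 * n))
        noise[:n, :n] = W
        noise[:n, n:] = W
        noise[n:, :n] = W
        noise[n:, n:] = W + L[k] @ sys.V @ L[k].T
        J = F @ J @ F.T + noise
        J = 0.5 * (J + J.T)
        out[k + 1] = J[:n, :n]
    return out
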