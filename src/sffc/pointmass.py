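"""Point-mass benchmark: expected cost versus movement duration under
stochastic optimal feedback control with signal-dependent motor noise.

A 10-cm reach of a point mass (second-order plant with a muscle-like
first-order force filter) is controlled by the extended LQG scheme in which
the control-multiplicative noise couples the optimal controller and the
optimal state estimator; the two are computed by fixed-point iteration.
With baseline observation noise (the visually guided regime) the expected
total cost decreases with movement duration and plateaus — no finite optimal
duration exists.  With observation noise scaled x10 (movements without
vision) the endpoint variance grows with duration and the total cost has an
interior minimum.

The plant constants are this package's own documented defaults; the
benchmark asserts the qualitative regime structure, not axis values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PointMassConfig",
    "PointMassPlant",
    "build_plant",
    "solve_soc",
    "rollout",
    "cost_curve",
]


@dataclass(frozen=True)
class PointMassConfig:
    """Configuration of the point-mass reaching benchmark (SI units)."""

    mass: float = 1.0            # kg
    tau_f: float = 0.05          # s, muscle force low-pass time constant
    dt: float = 0.01             # s
    distance: float = 0.10       # m reach amplitude
    mult_noise: float = 0.5      # signal-dependent noise fraction of u
    add_noise: float = 0.2       # N s^-1/2 additive force noise
    obs_sd: tuple = (0.01, 0.1, 1.0)   # (m, m/s, N) baseline observation sd
    obs_scale: float = 1.0       # 1 = vision, 10 = no vision
    w_pos: float = 1.0e4         # terminal position-error weight (1/m^2)
    w_vel: float = 1.0e2         # terminal velocity weight
    w_force: float = 1.0e-2      # terminal force weight
    r_u: float = 1.0e-3          # control-effort weight per step-second
    n_samples: int = 10_000      # Monte-Carlo sample count
    seed: int = 1

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.tau_f <= 0 or self.dt <= 0 or self.distance <= 0:
            raise ValueError("tau_f, dt and distance must be positive")


@dataclass
class PointMassPlant:
    """Discrete-time linear plant with control-multiplicative noise.

    State ``x = [p, v, f, 1]`` (the constant coordinate carries the target
    offset into the quadratic terminal cost).  Dynamics
    ``x_{k+1} = A x_k + B u_k + xi_k + eps_k * Cmult u_k`` with additive
    Gaussian noise covariance ``W`` and scalar standard-normal ``eps``;
    observations ``y = H x + omega``, ``cov(omega) = V``.
    """

    A: np.ndarray
    B: np.ndarray
    Cmult: np.ndarray
    W: np.ndarray
    H: np.ndarray
    V: np.ndarray
    dt: float
    x0: np.ndarray
    QN: np.ndarray
    R: np.ndarray
    config: PointMassConfig

    @property
    def n(self) -> int:
        return self.A.shape[0]


def build_plant(config: PointMassConfig) -> PointMassPlant:
    """Point-mass plant matrices for the extended-LQG benchmark.

    The "no-vision" variant is obtained with ``obs_scale=10``: the
    observation-noise matrix is exactly 10x the baseline one.
    """
    c = config
    dt = c.dt
    A = np.array([
        [1.0, dt, 0.0, 0.0],
        [0.0, 1.0, dt / c.mass, 0.0],
        [0.0, 0.0, 1.0 - dt / c.tau_f, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    B = np.array([[0.0], [0.0], [dt / c.tau_f], [0.0]])
    Cmult = c.mult_noise * B
    W = np.zeros((4, 4))
    W[2, 2] = c.add_noise ** 2 * dt
    H = np.eye(3, 4)
    V = np.diag(np.asarray(c.obs_sd, dtype=float) ** 2) * c.obs_scale ** 2
    x0 = np.array([0.0, 0.0, 0.0, 1.0])
    # terminal cost: w_pos (p - distance)^2 + w_vel v^2 + w_force f^2
    e_p = np.array([1.0, 0.0, 0.0, -c.distance])
    e_v = np.array([0.0, 1.0, 0.0, 0.0])
    e_f = np.array([0.0, 0.0, 1.0, 0.0])
    QN = (c.w_pos * np.outer(e_p, e_p) + c.w_vel * np.outer(e_v, e_v)
          + c.w_force * np.outer(e_f, e_f))
    R = np.array([[c.r_u * dt]])
    return PointMassPlant(A=A, B=B, Cmult=Cmult, W=W, H=H, V=V, dt=dt,
                          x0=x0, QN=QN, R=R, config=config)


def _controller_given_filter(plant: PointMassPlant, N: int,
                             L: np.ndarray) -> np.ndarray:
    """Backward sweep: optimal K under control-multiplicative noise.

    Cost-to-go is quadratic in the state and in the estimation error; the
    multiplicative noise adds ``Cmult'(S_x + S_e)Cmult`` to the control
    Hessian, which is what penalizes large commands beyond the effort cost.
    """
    A, B, C, H = plant.A, plant.B, plant.Cmult, plant.H
    Sx = plant.QN.copy()
    Se = np.zeros_like(Sx)
    K = np.zeros((N, B.shape[1], plant.n))
    for k in range(N - 1, -1, -1):
        M = plant.R + B.T @ Sx @ B + C.T @ (Sx + Se) @ C
        K[k] = np.linalg.solve(M, B.T @ Sx @ A)
        AL = A - L[k] @ H
        Se_new = A.T @ Sx @ B @ K[k] + AL.T @ Se @ AL
        Sx = A.T @ Sx @ (A - B @ K[k])
        Sx = 0.5 * (Sx + Sx.T)
        Se = 0.5 * (Se_new + Se_new.T)
    return K


def _filter_given_controller(plant: PointMassPlant, N: int,
                             K: np.ndarray) -> np.ndarray:
    """Forward sweep: Kalman-like gains given the control law.

    Propagates the exact joint second moments of (estimate, estimation
    error); the signal-dependent noise feeds the error covariance through
    the uncentered second moment of the command u = -K xhat.
    """
    A, B, C, H = plant.A, plant.B, plant.Cmult, plant.H
    n = plant.n
    L = np.zeros((N, n, H.shape[0]))
    Sxh = np.outer(plant.x0, plant.x0)   # uncentered E[xhat xhat']
    Se = np.zeros((n, n))
    Sxe = np.zeros((n, n))               # E[xhat e']
    for k in range(N):
        L[k] = np.linalg.solve((H @ Se @ H.T + plant.V).T,
                               (A @ Se @ H.T).T).T
        ABK = A - B @ K[k]
        AL = A - L[k] @ H
        LH = L[k] @ H
        Euu = K[k] @ Sxh @ K[k].T
        mult = C @ Euu @ C.T
        LVL = L[k] @ plant.V @ L[k].T
        Sxh_new = (ABK @ Sxh @ ABK.T + LH @ Se @ LH.T
                   + ABK @ Sxe @ LH.T + LH @ Sxe.T @ ABK.T + LVL)
        Se_new = AL @ Se @ AL.T + plant.W + mult + LVL
        Sxe_new = ABK @ Sxe @ AL.T + LH @ Se @ AL.T - LVL
        Sxh, Se, Sxe = (0.5 * (Sxh_new + Sxh_new.T),
                        0.5 * (Se_new + Se_new.T), Sxe_new)
    return L


def solve_soc(plant: PointMassPlant, T: float,
              max_iter: int = 500, tol: float = 1e-12):
    """Coupled controller/filter fixed point for horizon T.

    Returns ``(K, L, residuals)``; ``residuals`` is the per-iteration relative
    change of the feedback gains (decreases below ``tol`` at convergence; the
    contraction is geometric).  With ``mult_noise = 0`` the controller does
    not depend on the filter and the fixed point is reached immediately: K
    equals the standard LQG (Riccati) solution.
    """
    N = int(round(T / plant.dt))
    if N < 2:
        raise ValueError("horizon too short for the benchmark time step")
    n = plant.n
    L = np.zeros((N, n, plant.H.shape[0]))
    K = _controller_given_filter(plant, N, L)
    residuals = []
    for _ in range(max_iter):
        L = _filter_given_controller(plant, N, K)
        K_new = _controller_given_filter(plant, N, L)
        res = float(np.max(np.abs(K_new - K)) / (1.0 + np.max(np.abs(K_new))))
        residuals.append(res)
        K = K_new
        if res < tol:
            break
    else:
        raise RuntimeError(
            f"extended-LQG iteration did not converge: residual {res:.2e}")
    return K, L, np.asarray(residuals)


def rollout(plant: PointMassPlant, K: np.ndarray, L: np.ndarray,
            n_samples: int, seed: int):
    """Monte-Carlo rollouts; returns per-sample effort, terminal error, x_N."""
    N = K.shape[0]
    rng = np.random.default_rng(seed)
    n = plant.n
    x = np.tile(plant.x0, (n_samples, 1))
    xh = x.copy()
    effort = np.zeros(n_samples)
    A, B, C, H = plant.A, plant.B, plant.Cmult, plant.H
    sd_obs = np.sqrt(np.diag(plant.V))
    sd_add = np.sqrt(np.diag(plant.W))
    for k in range(N):
        u = -xh @ K[k].T
        effort += (u[:, 0] ** 2) * plant.R[0, 0]
        y = x @ H.T + rng.standard_normal((n_samples, H.shape[0])) * sd_obs
        xh = xh @ A.T + u @ B.T + (y - xh @ H.T) @ L[k].T
        eps = rng.standard_normal((n_samples, 1))
        xi = rng.standard_normal((n_samples, n)) * sd_add
        x = x @ A.T + u @ B.T + xi + eps * (u @ C.T)
    terminal = np.einsum("ni,ij,nj->n", x, plant.QN, x)
    return effort, terminal, x


def cost_curve(config: PointMassConfig,
               durations=np.arange(0.2, 1.41, 0.1)) -> pd.DataFrame:
    """Monte-Carlo expected costs and endpoint variance per duration.

    One extended-LQG solve and one seeded MC ensemble per duration; returns
    effort, terminal-error and total expected costs with standard errors,
    and the endpoint positional variance.  Per-duration failures are
    recorded and the scan continues.
    """
    plant = build_plant(config)
    rows = []
    for T in np.asarray(durations, dtype=float):
        try:
            K, L, res = solve_soc(plant, T)
            eff, term, xN = rollout(plant, K, L, config.n_samples, config.seed)
            total = eff + term
            ns = config.n_samples
            rows.append({
                "T": float(T),
                "effort": float(eff.mean()),
                "terminal": float(term.mean()),
                "total": float(total.mean()),
                "total_se": float(total.std(ddof=1) / np.sqrt(ns)),
                "endpoint_var": float(xN[:, 0].var(ddof=1)),
                "endpoint_var_se": float(xN[:, 0].var(ddof=1)
                                          * np.sqrt(2.0 / (ns - 1))),
                "iterations": len(res),
                "converged": True,
            })
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            rows.append({"T": float(T), "converged": False, "error": str(exc)})
    return pd.DataFrame(rows)


def no_vision_config(config: PointMassConfig) -> PointMassConfig:
    """The x10-observation-noise variant of a baseline configuration."""
    return replace(config, obs_scale=10.0 * config.obs_scale)
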