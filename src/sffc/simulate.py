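"""Monte-Carlo execution of the composed feedforward/feedback controller.

Trials are Euler–Maruyama rollouts of the nonlinear arm SDE driven either by
the open-loop command alone (feedforward-only, the behaviour expected without
any online state feedback) or by the open-loop command plus the LQG
correction ``v_t = -K(t) zhat_t`` computed from noisy delayed observations
(the full feedforward-feedback scheme).  A stopping mechanism raises joint
friction shortly before the planned movement end — mimicking the higher
muscle viscosity at low speed — so that feedforward-only and no-vision
movements come to rest; durations and endpoints are extracted with the same
1 cm/s hand-speed threshold applied to experimental recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import arm as _arm
from .arm import ArmParams, NoiseParams, STATE_DIM
from .planner import (OCPSpec, FeedforwardPlan, make_task, solve_free_time,
                      log_endpoint_variance)
from .lqg import LQGController, build_controller

__all__ = [
    "SimConfig",
    "TrialEnsemble",
    "EndpointStats",
    "simulate_trials",
    "apply_stopping_mechanism",
    "endpoint_statistics",
    "run_condition_grid",
    "BETA_WITH_VISION",
    "BETA_WITHOUT_VISION",
    "STOPPING_VISCOSITY_BOOST",
    "STOPPING_LEAD_TIME",
]

BETA_WITH_VISION = 0.003
BETA_WITHOUT_VISION = 0.03     # x10: degraded hand-state estimate
STOPPING_VISCOSITY_BOOST = 3.5  # kg m^2 / s added to both B_ii
STOPPING_LEAD_TIME = 0.05       # s before planned end


@dataclass
class SimConfig:
    """Settings of one Monte-Carlo condition."""

    n_trials: int = 1000
    seed: int = 0
    dt: float = 0.005
    mode: str = "sffc"              # "sffc" | "sooc_only"
    vision: str = "with"            # "with" | "without"
    stopping: bool | None = None    # default: without vision / without feedback
    speed_threshold: float = 0.01   # m/s
    T_prime: float | None = None    # horizon; default plan.T + 1 s

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.mode not in ("sffc", "sooc_only"):
            raise ValueError("mode must be 'sffc' or 'sooc_only'")
        if self.vision not in ("with", "without"):
            raise ValueError("vision must be 'with' or 'without'")

    @property
    def stopping_on(self) -> bool:
        if self.stopping is not None:
            return self.stopping
        return self.vision == "without" or self.mode == "sooc_only"

    @property
    def default_beta(self) -> float:
        return BETA_WITH_VISION if self.vision == "with" else BETA_WITHOUT_VISION


@dataclass
class TrialEnsemble:
    """Stochastic rollouts of one condition on a shared time grid."""

    t: np.ndarray            # (N+1,)
    x: np.ndarray            # (n_trials, N+1, 6)
    hand: np.ndarray         # (n_trials, N+1, 2)
    speed: np.ndarray        # (n_trials, N+1)
    endpoints: np.ndarray    # (n_trials, 2) positions at the velocity cut
    start_idx: np.ndarray    # (n_trials,)
    end_idx: np.ndarray      # (n_trials,)
    durations: np.ndarray    # (n_trials,) velocity-threshold durations (s)
    truncated: np.ndarray    # (n_trials,) bool: still moving at T'
    no_movement: np.ndarray  # (n_trials,) bool: speed never above threshold
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.x.shape[0]

    @property
    def peak_speed(self) -> np.ndarray:
        return self.speed.max(axis=1)


@dataclass
class EndpointStats:
    cov: np.ndarray                 # 2x2 Cartesian endpoint covariance (m^2)
    log_variance: float             # ln(trace of cov in mm^2)
    ellipse_center: np.ndarray      # mean endpoint (m)
    ellipse_axes: np.ndarray        # 90% confidence semi-axes (m), descending
    ellipse_angle: float            # orientation of the major axis (rad)


def apply_stopping_mechanism(params: ArmParams, plan_T: float,
                             t: np.ndarray,
                             boost: float = STOPPING_VISCOSITY_BOOST,
                             lead: float = STOPPING_LEAD_TIME):
    """Viscosity schedule implementing the stopping mechanism.

    Returns ``(params_normal, params_boosted, boosted_mask)`` where the mask
    marks grid times ``t >= plan_T - lead`` at which both diagonal viscosity
    entries are raised by ``boost``.
    """
    mask = np.asarray(t) >= plan_T - lead - 1e-12
    return params, params.with_viscosity_boost(boost), mask


def _nominal_on_grid(plan: FeedforwardPlan, t: np.ndarray):
    """Extended nominal mean and control: plan values, rest beyond T."""
    m = plan.interp_m(np.minimum(t, plan.T))
    rest = plan.m[-1].copy()
    rest[2:] = 0.0
    m[t > plan.T] = rest
    u = plan.interp_u(t)
    u[t > plan.T] = 0.0
    return m, u


def simulate_trials(plan: FeedforwardPlan,
                    controller: LQGController | None,
                    noise: NoiseParams | None = None,
                    config: SimConfig | None = None) -> TrialEnsemble:
    """Euler–Maruyama rollouts of the arm under the composed controller.

    ``controller=None`` (or ``config.mode == "sooc_only"``) simulates pure
    feedforward execution.  Reproducible: a fixed seed gives bit-identical
    ensembles.
    """
    config = config or SimConfig()
    noise = noise or plan.spec.noise
    params = plan.spec.params
    if config.mode == "sooc_only":
        controller = None
    dt = config.dt
    if controller is not None:
        if not np.isclose(controller.dt, dt):
            raise ValueError("config.dt must match the controller grid")
        t = controller.sys.t
    else:
        T_prime = config.T_prime if config.T_prime is not None else plan.T + 1.0
        t = np.arange(int(round(T_prime / dt)) + 1) * dt
    N = len(t) - 1
    n = config.n_trials
    m_nom, u_nom = _nominal_on_grid(plan, t)

    use_stop = config.stopping_on
    _, params_stop, stop_mask = apply_stopping_mechanism(params, plan.T, t)

    rng = np.random.default_rng(config.seed)
    x = np.zeros((n, N + 1, STATE_DIM))
    x[:, 0] = plan.spec.x0
    sqdt = np.sqrt(dt)

    if controller is not None:
        na = controller.sys.n
        kd = controller.delay_steps
        C = controller.sys.C
        C_phys = C[:, -STATE_DIM:]  # physical block read by the observation
        zhat = np.zeros((n, na))
        z_hist = np.zeros((kd + 1, n, STATE_DIM))  # ring buffer of past z
        # per-step measurement noise follows the controller's discretization
        sd_meas = np.sqrt(np.diag(controller.sys.V))

    for k in range(N):
        xk = x[:, k]
        u_k = np.broadcast_to(u_nom[k], (n, 2))
        if controller is not None:
            z = xk - m_nom[k]
            if kd:
                z_hist[k % (kd + 1)] = z
                z_del = z_hist[(k - kd) % (kd + 1)] if k >= kd \
                    else np.zeros_like(z)
            else:
                z_del = z
            h = (z_del @ C_phys.T
                 + sd_meas * rng.standard_normal((n, C.shape[0])))
            v = -np.einsum("ij,nj->ni", controller.K[k], zhat)
            u_k = u_k + v
            innov = h - zhat @ C.T
            zhat = (np.einsum("ij,nj->ni", controller.sys.Phi[k], zhat)
                    + v @ controller.sys.Bd[k].T
                    + np.einsum("ij,nj->ni", controller.L[k], innov))
        p_k = params_stop if (use_stop and stop_mask[k]) else params
        f = _arm.drift(xk, u_k, p_k)
        G = _arm.diffusion(u_k, noise)
        dW = rng.standard_normal((n, _arm.BROWNIAN_DIM)) * sqdt
        x_next = xk + f * dt + np.einsum("nij,nj->ni", G, dW)
        if not np.all(np.isfinite(x_next)):
            bad = ~np.all(np.isfinite(x_next), axis=-1)
            raise FloatingPointError(
                f"{bad.sum()} trial(s) diverged at t={t[k]:.3f}s")
        x[:, k + 1] = x_next

    hand = _arm.forward_kinematics(x[..., :2], params)
    vel = np.einsum("...ij,...j->...i", _arm.jacobian(x[..., :2], params),
                    x[..., 2:4])
    speed = np.linalg.norm(vel, axis=-1)

    above = speed > config.speed_threshold
    any_above = above.any(axis=1)
    start_idx = np.argmax(above, axis=1)
    end_idx = N - np.argmax(above[:, ::-1], axis=1)
    truncated = above[:, -1] & any_above
    start_idx[~any_above] = 0
    end_idx[~any_above] = 0
    endpoints = hand[np.arange(n), end_idx]
    durations = t[end_idx] - t[start_idx]

    meta = {"mode": config.mode if controller is None else "sffc",
            "vision": config.vision, "seed": config.seed,
            "stopping": use_stop, "T": plan.T,
            "beta": None if controller is None else controller.beta}
    return TrialEnsemble(t=t, x=x, hand=hand, speed=speed,
                         endpoints=endpoints, start_idx=start_idx,
                         end_idx=end_idx, durations=durations,
                         truncated=truncated, no_movement=~any_above,
                         meta=meta)


def endpoint_statistics(ensemble: TrialEnsemble | np.ndarray,
                        level: float = 0.90) -> EndpointStats:
    """Endpoint covariance, ln(trace) in log(mm^2) and confidence ellipse."""
    pts = ensemble.endpoints if isinstance(ensemble, TrialEnsemble) \
        else np.asarray(ensemble, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 trials for endpoint statistics")
    cov = np.cov(pts.T)
    tr = float(np.trace(cov))
    if tr <= 0:
        raise ValueError("degenerate endpoint distribution: zero variance")
    logvar = float(np.log(tr * 1.0e6))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = stats.chi2.ppf(level, df=2)
    axes = np.sqrt(np.maximum(evals, 0.0) * scale)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return EndpointStats(cov=cov, log_variance=logvar,
                         ellipse_center=pts.mean(axis=0),
                         ellipse_axes=axes, ellipse_angle=angle)


# --------------------------------------------------------------------------
# condition grids (direction x distance x vision)
# --------------------------------------------------------------------------

DIRECTIONS_DEG = {"E": 0.0, "N-E": 45.0, "N-W": 135.0, "W": 180.0}

# start positions (m, shoulder-centred) per movement direction
START_POSITIONS = {
    "N-E": np.array([-0.15, 0.30]),
    "N-W": np.array([-0.15, 0.30]),
    "E": np.array([-0.29, 0.345]),
    "W": np.array([0.05, 0.345]),
}


def run_condition_grid(directions: Sequence[str] = ("E", "N-E", "N-W", "W"),
                       distances: Sequence[float] = (0.06, 0.12, 0.18, 0.24),
                       vision_states: Sequence[str] = ("with", "without"),
                       params: ArmParams | None = None,
                       sigma: float = 0.025, d: float = 0.01,
                       r: float = 6000.0, alpha: float = 0.02,
                       rho: float = 1000.0, delay: float = 0.05,
                       n_trials: int = 1000, seed: int = 0,
                       n_controls: int = 15, n_steps: int = 70,
                       mode: str = "sffc") -> pd.DataFrame:
    """Full pipeline over a direction x distance x vision grid.

    One free-time plan per (direction, distance) — the feedforward command is
    shared between vision conditions — then per vision state an LQG
    controller (beta = 0.003 with vision, 0.03 without) and a seeded
    Monte-Carlo ensemble, summarized as duration (1 cm/s threshold), peak
    velocity (cm/s) and log endpoint variance (log mm^2).  Per-condition
    failures are recorded and the grid continues.
    """
    params = params or ArmParams()
    rows = []
    for di, dname in enumerate(directions):
        p_start = START_POSITIONS[dname]
        q0 = np.rad2deg(_arm.inverse_kinematics(p_start, params))
        u_warm, T_warm = None, 0.7
        for dj, dist in enumerate(distances):
            cond = {"direction": dname, "distance": dist}
            try:
                x0, target = make_task(q0, DIRECTIONS_DEG[dname], dist, params)
                spec = OCPSpec(x0=x0, target=target, r=r, alpha=alpha,
                               params=params,
                               noise=NoiseParams.symmetric(sigma, d,
                                                           delay=delay),
                               n_controls=n_controls, n_steps=n_steps)
                plan = solve_free_time(spec, T_guess=T_warm, u_guess=u_warm)
                u_warm, T_warm = plan.u_nodes, plan.T
            except (RuntimeError, FloatingPointError, ValueError) as exc:
                for vis in vision_states:
                    rows.append({**cond, "vision": vis, "error": str(exc)})
                continue
            for vi, vis in enumerate(vision_states):
                beta = BETA_WITH_VISION if vis == "with" \
                    else BETA_WITHOUT_VISION
                cfg = SimConfig(n_trials=n_trials,
                                seed=seed + 1000 * di + 10 * dj + vi,
                                vision=vis, mode=mode)
                try:
                    if mode == "sffc":
                        ctl = build_controller(plan, rho=rho, beta=beta,
                                               delay=delay)
                    else:
                        ctl = None
                    ens = simulate_trials(plan, ctl, config=cfg)
                    st = endpoint_statistics(ens)
                    ok = ~(ens.truncated | ens.no_movement)
                    rows.append({
                        **cond, "vision": vis,
                        "T_star": plan.T,
                        "duration": float(ens.durations[ok].mean()),
                        "peak_velocity": float(ens.peak_speed.mean() * 100.0),
                        "log_endpoint_variance": st.log_variance,
                        "plan_log_endpoint_variance":
                            plan.log_endpoint_variance,
                        "n_valid": int(ok.sum()),
                    })
                except (RuntimeError, FloatingPointError, ValueError) as exc:
                    rows.append({**cond, "vision": vis, "error": str(exc)})
    return pd.DataFrame(rows)
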