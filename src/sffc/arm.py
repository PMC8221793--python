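"""Two-link planar arm dynamics, kinematics and motor-noise structure.

State convention: ``x = [q1, q2, q1d, q2d, tau1, tau2]`` (joint angles in rad,
velocities in rad/s, net joint torques in N*m).  The control variable is the
torque change ``u = dtau/dt`` (N*m/s), so the drift is

    f(x, u) = [qd, M(q)^-1 (tau - C(q, qd) qd - B qd), u]

Gravity is identically zero for the horizontal planar task.  Motor noise
enters the torque rows only, through four independent Brownian channels: two
additive (magnitude ``sigma_i``) and two signal-dependent (``d_i * u_i``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ArmParams",
    "NoiseParams",
    "STATE_DIM",
    "CONTROL_DIM",
    "BROWNIAN_DIM",
    "inertia_matrix",
    "coriolis_matrix",
    "accel",
    "drift",
    "diffusion",
    "diffusion_squared",
    "forward_kinematics",
    "jacobian",
    "inverse_kinematics",
    "pointmass_plant",
]

STATE_DIM = 6
CONTROL_DIM = 2
BROWNIAN_DIM = 4


def _default_viscosity() -> np.ndarray:
    return np.zeros((2, 2))


@dataclass(frozen=True)
class ArmParams:
    """Physical constants of the two-link planar arm (SI units).

    Defaults are the standard human-arm set used throughout the planar
    reaching literature: upper-arm / forearm+hand segments with moments of
    inertia about the joints ``I1, I2``, masses ``M1, M2``, lengths
    ``L1, L2``, centre-of-mass distances ``Lg1, Lg2`` and a symmetric joint
    viscosity matrix ``B``.  The default viscosity is zero: for horizontal
    planar reaching the noise calibration of the model (additive noise
    magnitude fixed on slow movements) is consistent with negligible passive
    joint damping during planning; the simulation-time stopping mechanism
    raises it explicitly near movement end.
    """

    I1: float = 0.025
    I2: float = 0.045
    M1: float = 1.4
    M2: float = 1.0
    L1: float = 0.30
    L2: float = 0.33
    Lg1: float = 0.11
    Lg2: float = 0.16
    B: np.ndarray = field(default_factory=_default_viscosity)

    def __post_init__(self):
        B = np.asarray(self.B, dtype=float)
        if B.shape != (2, 2):
            raise ValueError("viscosity matrix B must be 2x2")
        if not np.allclose(B, B.T):
            raise ValueError("viscosity matrix B must be symmetric")
        if np.any(np.diag(B) < 0):
            raise ValueError("viscosity diagonal must be non-negative")
        object.__setattr__(self, "B", B)
        for name in ("I1", "I2", "M1", "M2", "L1", "L2", "Lg1", "Lg2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"arm parameter {name} must be strictly positive")
        if self.Lg1 > self.L1 or self.Lg2 > self.L2:
            raise ValueError("centre-of-mass distance exceeds segment length")

    def key(self) -> tuple:
        """Hashable identity used to cache generated derivative code."""
        return (
            self.I1, self.I2, self.M1, self.M2,
            self.L1, self.L2, self.Lg1, self.Lg2,
            tuple(np.asarray(self.B).ravel()),
        )

    def with_viscosity_boost(self, delta: float) -> "ArmParams":
        """Return a copy with ``delta`` added to both diagonal viscosity terms."""
        B = np.asarray(self.B, dtype=float).copy()
        B[0, 0] += delta
        B[1, 1] += delta
        return replace(self, B=B)


@dataclass(frozen=True)
class NoiseParams:
    """Motor- and observation-noise magnitudes.

    ``sigma_i`` scale the additive (constant-variance) torque-rate noise,
    ``d_i`` the signal-dependent noise whose standard deviation grows with
    the command magnitude.  Both joints share the same magnitudes by default.
    ``beta`` scales the additive observation noise D = beta*I, and ``delay``
    is the sensory feedback delay in seconds.
    """

    sigma1: float = 0.005
    sigma2: float = 0.005
    d1: float = 0.01
    d2: float = 0.01
    beta: float = 0.003
    delay: float = 0.0

    def __post_init__(self):
        for name in ("sigma1", "sigma2", "d1", "d2", "beta", "delay"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise parameter {name} must be non-negative")

    @classmethod
    def symmetric(cls, sigma: float, d: float, beta: float = 0.003,
                  delay: float = 0.0) -> "NoiseParams":
        return cls(sigma1=sigma, sigma2=sigma, d1=d, d2=d, beta=beta, delay=delay)


def _check_finite(name, value):
    value = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite")
    return value


def inertia_matrix(q: np.ndarray, params: ArmParams) -> np.ndarray:
    """Configuration-dependent inertia matrix M(q).

    Broadcasts over leading axes: ``q`` of shape (..., 2) gives (..., 2, 2).
    """
    q = _check_finite("q", q)
    c2 = np.cos(q[..., 1])
    a = params.M2 * params.L1 * params.Lg2
    m11 = params.I1 + params.I2 + params.M2 * params.L1 ** 2 + 2.0 * a * c2
    m12 = params.I2 + a * c2
    m22 = np.broadcast_to(np.asarray(params.I2, dtype=float), m11.shape)
    M = np.stack([
        np.stack([m11, m12], axis=-1),
        np.stack([m12, m22], axis=-1),
    ], axis=-2)
    return M


def coriolis_matrix(q: np.ndarray, qdot: np.ndarray, params: ArmParams) -> np.ndarray:
    """Coriolis/centripetal matrix C(q, qd) with C(q, qd) @ qd the torque."""
    q = _check_finite("q", q)
    qdot = _check_finite("qdot", qdot)
    s2 = np.sin(q[..., 1])
    a = params.M2 * params.L1 * params.Lg2
    q1d = qdot[..., 0]
    q2d = qdot[..., 1]
    c11 = -2.0 * a * s2 * q2d
    c12 = -a * s2 * q2d
    c21 = a * s2 * q1d
    c22 = np.zeros_like(c11)
    C = np.stack([
        np.stack([c11, c12], axis=-1),
        np.stack([c21, c22], axis=-1),
    ], axis=-2)
    return C


def accel(q: np.ndarray, qdot: np.ndarray, tau: np.ndarray,
          params: ArmParams) -> np.ndarray:
    """Forward-dynamics joint acceleration  M(q)^-1 (tau - C qd - B qd).

    Vectorized over leading axes; uses the closed-form 2x2 inverse.
    """
    M = inertia_matrix(q, params)
    C = coriolis_matrix(q, qdot, params)
    B = np.asarray(params.B)
    rhs = np.asarray(tau, dtype=float) \
        - np.einsum("...ij,...j->...i", C, qdot) \
        - np.einsum("ij,...j->...i", B, qdot)
    det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
    if np.any(np.abs(det) < 1e-12):
        raise np.linalg.LinAlgError("inertia matrix numerically singular")
    inv_det = 1.0 / det
    a0 = (M[..., 1, 1] * rhs[..., 0] - M[..., 0, 1] * rhs[..., 1]) * inv_det
    a1 = (-M[..., 1, 0] * rhs[..., 0] + M[..., 0, 0] * rhs[..., 1]) * inv_det
    return np.stack([a0, a1], axis=-1)


def drift(x: np.ndarray, u: np.ndarray, params: ArmParams) -> np.ndarray:
    """Deterministic drift f(x, u) of the arm SDE; broadcasts over leading axes."""
    x = _check_finite("x", x)
    u = np.asarray(u, dtype=float)
    if x.shape[-1] != STATE_DIM:
        raise ValueError(f"state must have last dimension {STATE_DIM}")
    q = x[..., 0:2]
    qd = x[..., 2:4]
    tau = x[..., 4:6]
    qdd = accel(q, qd, tau, params)
    u = np.broadcast_to(u, qdd.shape)
    return np.concatenate([qd, qdd, u], axis=-1)


def diffusion(u: np.ndarray, noise: NoiseParams) -> np.ndarray:
    """Diffusion matrix G(u) of shape (..., 6, 4).

    Columns 0-1 are the additive channels (sigma_i), columns 2-3 the
    signal-dependent channels (d_i * u_i); only the torque rows are nonzero.
    """
    u = np.asarray(u, dtype=float)
    shape = u.shape[:-1]
    G = np.zeros(shape + (STATE_DIM, BROWNIAN_DIM))
    G[..., 4, 0] = noise.sigma1
    G[..., 5, 1] = noise.sigma2
    G[..., 4, 2] = noise.d1 * u[..., 0]
    G[..., 5, 3] = noise.d2 * u[..., 1]
    return G


def diffusion_squared(u: np.ndarray, noise: NoiseParams) -> np.ndarray:
    """G(u) G(u)' (6x6); only the lower-right torque block is nonzero."""
    G = diffusion(u, noise)
    return G @ np.swapaxes(G, -1, -2)


def forward_kinematics(q: np.ndarray, params: ArmParams) -> np.ndarray:
    """Hand position in a shoulder-centred frame (x rightward, y away)."""
    q = _check_finite("q", q)
    q1 = q[..., 0]
    q12 = q1 + q[..., 1]
    x = params.L1 * np.cos(q1) + params.L2 * np.cos(q12)
    y = params.L1 * np.sin(q1) + params.L2 * np.sin(q12)
    return np.stack([x, y], axis=-1)


def jacobian(q: np.ndarray, params: ArmParams) -> np.ndarray:
    """Hand Jacobian J = d(hand)/dq, shape (..., 2, 2)."""
    q = _check_finite("q", q)
    q1 = q[..., 0]
    q12 = q1 + q[..., 1]
    s1, c1 = np.sin(q1), np.cos(q1)
    s12, c12 = np.sin(q12), np.cos(q12)
    j11 = -params.L1 * s1 - params.L2 * s12
    j12 = -params.L2 * s12
    j21 = params.L1 * c1 + params.L2 * c12
    j22 = params.L2 * c12
    return np.stack([
        np.stack([j11, j12], axis=-1),
        np.stack([j21, j22], axis=-1),
    ], axis=-2)


def inverse_kinematics(hand: np.ndarray, params: ArmParams,
                       elbow_up: bool = True) -> np.ndarray:
    """Joint angles reaching the given hand position (elbow-flexed branch).

    ``elbow_up=True`` selects q2 > 0, matching the natural right-arm posture
    of the reaching task (initial configuration q2 = 100 deg > 0).
    """
    hand = _check_finite("hand", hand)
    x, y = hand[..., 0], hand[..., 1]
    L1, L2 = params.L1, params.L2
    r2 = x ** 2 + y ** 2
    c2 = (r2 - L1 ** 2 - L2 ** 2) / (2.0 * L1 * L2)
    if np.any(c2 > 1.0 + 1e-12) or np.any(c2 < -1.0 - 1e-12):
        raise ValueError("hand target outside arm workspace")
    c2 = np.clip(c2, -1.0, 1.0)
    s2 = np.sqrt(1.0 - c2 ** 2)
    if not elbow_up:
        s2 = -s2
    q2 = np.arctan2(s2, c2)
    q1 = np.arctan2(y, x) - np.arctan2(L2 * s2, L1 + L2 * c2)
    return np.stack([q1, q2], axis=-1)


def pointmass_plant(config):
    """Linear point-mass plant with control-multiplicative and additive noise.

    Thin constructor for the benchmark plant; see :mod:`sffc.pointmass` for
    the state convention and noise structure.
    """
    from .pointmass import build_plant
    return build_plant(config)
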