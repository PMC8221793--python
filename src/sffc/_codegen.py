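"""Symbolically generated derivatives of the arm dynamics.

The mean/covariance propagation and the LQG linearization need the drift
Jacobian A = df/dx, the second-order Taylor correction tr(Hess(f_i) P) of the
mean dynamics, and the Cartesian hand jerk of the mean trajectory (third
total time derivative of the forward kinematics along the drift).  These are
derived once per arm-parameter set with sympy and compiled to vectorized
numpy functions; all evaluation is batched over leading axes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

from .arm import ArmParams, STATE_DIM

# upper-triangle (row-major) indexing of symmetric 6x6 matrices
VECH_IDX = [(i, j) for i in range(STATE_DIM) for j in range(i, STATE_DIM)]
VECH_DIM = len(VECH_IDX)  # 21


def vech(P: np.ndarray) -> np.ndarray:
    """Stack the upper triangle of symmetric (..., 6, 6) into (..., 21)."""
    return np.stack([P[..., i, j] for (i, j) in VECH_IDX], axis=-1)


def unvech(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vech`."""
    shape = v.shape[:-1]
    P = np.zeros(shape + (STATE_DIM, STATE_DIM))
    for k, (i, j) in enumerate(VECH_IDX):
        P[..., i, j] = v[..., k]
        P[..., j, i] = v[..., k]
    return P


class ArmDerivatives:
    """Compiled drift derivatives for one arm-parameter set.

    ``rhs(y, u, noise_vec)`` evaluates the coupled mean/covariance dynamics
    plus the squared hand jerk: input ``y = [m(6), vech(P)(21)]`` and
    ``noise_vec = (sigma1, sigma2, d1, d2)``, output ``[mdot(6),
    vech(Pdot)(21), |hand jerk|^2 (1)]``, broadcasting over leading axes.
    """

    def __init__(self, params: ArmParams):
        self.params = params
        self._build()

    def _build(self) -> None:
        p = self.params
        q1, q2, dq1, dq2, t1, t2, u1, u2 = sp.symbols(
            "q1 q2 dq1 dq2 t1 t2 u1 u2", real=True)
        s1, s2, d1, d2 = sp.symbols("s1 s2 d1 d2", real=True)
        xs = [q1, q2, dq1, dq2, t1, t2]

        a = p.M2 * p.L1 * p.Lg2
        m11 = p.I1 + p.I2 + p.M2 * p.L1 ** 2 + 2 * a * sp.cos(q2)
        m12 = p.I2 + a * sp.cos(q2)
        M = sp.Matrix([[m11, m12], [m12, p.I2]])
        C = sp.Matrix([[-2 * a * sp.sin(q2) * dq2, -a * sp.sin(q2) * dq2],
                       [a * sp.sin(q2) * dq1, sp.Integer(0)]])
        Bm = sp.Matrix(np.asarray(p.B, dtype=float).tolist())
        qd = sp.Matrix([dq1, dq2])
        tau = sp.Matrix([t1, t2])
        w = tau - C * qd - Bm * qd
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        acc = sp.Matrix([(M[1, 1] * w[0] - M[0, 1] * w[1]) / det,
                         (-M[1, 0] * w[0] + M[0, 0] * w[1]) / det])
        f = sp.Matrix([dq1, dq2, acc[0], acc[1], u1, u2])
        A = f.jacobian(sp.Matrix(xs))

        psyms = {ij: sp.Symbol(f"P{ij[0]}{ij[1]}") for ij in VECH_IDX}
        P = sp.Matrix(STATE_DIM, STATE_DIM,
                      lambda i, j: psyms[(i, j)] if i <= j else psyms[(j, i)])
        GG = sp.zeros(STATE_DIM, STATE_DIM)
        GG[4, 4] = s1 ** 2 + d1 ** 2 * u1 ** 2
        GG[5, 5] = s2 ** 2 + d2 ** 2 * u2 ** 2
        Pdot = A * P + P * A.T + GG

        # second-order Taylor correction of the mean: only the acceleration
        # rows of f are nonlinear in x
        corr = []
        for i in range(2):
            H = sp.hessian(acc[i], xs)
            corr.append(sum(H[r, c] * P[r, c]
                            for r in range(STATE_DIM)
                            for c in range(STATE_DIM)) / 2)
        mdot = [f[0], f[1], f[2] + corr[0], f[3] + corr[1], f[4], f[5]]

        pos = sp.Matrix([p.L1 * sp.cos(q1) + p.L2 * sp.cos(q1 + q2),
                         p.L1 * sp.sin(q1) + p.L2 * sp.sin(q1 + q2)])

        def total_derivative(e):
            return e.jacobian(sp.Matrix(xs)) * f

        vel = total_derivative(pos)
        acc_h = total_derivative(vel)
        jerk = total_derivative(acc_h)
        jerk_sq = jerk[0] ** 2 + jerk[1] ** 2

        args = xs + [psyms[ij] for ij in VECH_IDX] + [u1, u2, s1, s2, d1, d2]
        outs = mdot + [Pdot[i, j] for (i, j) in VECH_IDX] + [jerk_sq]
        self._rhs = sp.lambdify(args, outs, modules="numpy", cse=True)
        self._A = sp.lambdify(xs, [A[i, j] for i in range(STATE_DIM)
                                   for j in range(STATE_DIM)],
                              modules="numpy", cse=True)
        self._jerk_sq = sp.lambdify(xs + [u1, u2], jerk_sq,
                                    modules="numpy", cse=True)

    def rhs(self, y: np.ndarray, u: np.ndarray,
            noise_vec: tuple[float, float, float, float]) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        u = np.asarray(u, dtype=float)
        shape = np.broadcast_shapes(y.shape[:-1], u.shape[:-1])
        cols = [y[..., i] for i in range(6 + VECH_DIM)]
        cols += [u[..., 0], u[..., 1], *noise_vec]
        out = self._rhs(*cols)
        return np.stack([np.broadcast_to(np.asarray(o, dtype=float), shape)
                         for o in out], axis=-1)

    def drift_jacobian(self, x: np.ndarray) -> np.ndarray:
        """A(x) = df/dx, shape (..., 6, 6); independent of u."""
        x = np.asarray(x, dtype=float)
        shape = x.shape[:-1]
        out = self._A(*[x[..., i] for i in range(STATE_DIM)])
        cols = [np.broadcast_to(np.asarray(o, dtype=float), shape) for o in out]
        return np.stack(cols, axis=-1).reshape(shape + (STATE_DIM, STATE_DIM))

    def hand_jerk_sq(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Squared Cartesian hand jerk along the drift, shape (...,)."""
        x = np.asarray(x, dtype=float)
        u = np.asarray(u, dtype=float)
        shape = np.broadcast_shapes(x.shape[:-1], u.shape[:-1])
        out = self._jerk_sq(*[x[..., i] for i in range(STATE_DIM)],
                            u[..., 0], u[..., 1])
        return np.broadcast_to(np.asarray(out, dtype=float), shape)


@lru_cache(maxsize=8)
def _cached(key: tuple) -> ArmDerivatives:
    I1, I2, M1, M2, L1, L2, Lg1, Lg2, Bflat = key
    B = np.asarray(Bflat).reshape(2, 2)
    return ArmDerivatives(ArmParams(I1=I1, I2=I2, M1=M1, M2=M2, L1=L1, L2=L2,
                                    Lg1=Lg1, Lg2=Lg2, B=B))


def get_derivatives(params: ArmParams) -> ArmDerivatives:
    """Cached compiled derivatives for the given arm parameters."""
    return _cached(params.key())
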