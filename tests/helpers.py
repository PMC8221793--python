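"""Independent numerical oracles shared by unit and acceptance tests."""

import numpy as np
from scipy.linalg import expm

import sffc.arm as arm
from sffc._codegen import get_derivatives


def euler_maruyama_ensemble(x0, U, T, params, noise, n_samples, dt, seed,
                            rk4_drift=True):
    """SDE rollouts with piecewise-linear control U on a uniform grid [0, T].

    The deterministic drift is advanced with RK4 substeps (so that the sample
    mean isolates the stochastic part of the dynamics), the Brownian
    increment with Euler–Maruyama.  Returns final states (n_samples, 6).
    """
    rng = np.random.default_rng(seed)
    steps = int(round(T / dt))
    tg = np.arange(steps) * dt
    s_nodes = np.linspace(0.0, T, len(U))

    def u_at(tq):
        return np.stack([np.interp(tq, s_nodes, U[:, k]) for k in range(2)],
                        axis=-1)

    U0, Um, U1 = u_at(tg), u_at(tg + dt / 2), u_at(tg + dt)
    x = np.tile(np.asarray(x0, float), (n_samples, 1))
    sq = np.sqrt(dt)
    for k in range(steps):
        if rk4_drift:
            k1 = arm.drift(x, U0[k], params)
            k2 = arm.drift(x + 0.5 * dt * k1, Um[k], params)
            k3 = arm.drift(x + 0.5 * dt * k2, Um[k], params)
            k4 = arm.drift(x + dt * k3, U1[k], params)
            incr = dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            incr = arm.drift(x, U0[k], params) * dt
        G = arm.diffusion(np.broadcast_to(Um[k], (n_samples, 2)), noise)
        x = x + incr + np.einsum("nij,nj->ni", G,
                                 rng.standard_normal((n_samples, 4)) * sq)
    return x


def min_effort_cost_linear(params, x0, qf, T, n_quad=4000):
    """Analytic minimum-effort cost of the linearized arm.

    For the plant linearized at the rest state x0, the minimum of
    int_0^T u'u dt steering the state to [qf, 0, 0] is
    xi' W(T)^{-1} xi with W the controllability Gramian and
    xi = xf - e^{AT} x0; evaluated by high-resolution quadrature.
    """
    deriv = get_derivatives(params)
    A = deriv.drift_jacobian(np.asarray(x0, float))
    B = np.zeros((6, 2))
    B[4, 0] = B[5, 1] = 1.0
    s = np.linspace(0.0, T, n_quad + 1)
    mats = np.stack([expm(A * si) @ B for si in s])
    integrand = mats @ np.swapaxes(mats, -1, -2)
    W = np.trapezoid(integrand, s, axis=0)
    xf = np.concatenate([np.asarray(qf, float), np.zeros(4)])
    xi = xf - expm(A * T) @ np.asarray(x0, float)
    return float(xi @ np.linalg.solve(W, xi))


def finite_difference_jacobian(f, x, h=1e-6):
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x))
    J = np.zeros((f0.size, x.size))
    for j in range(x.size):
        e = np.zeros_like(x)
        e[j] = h
        J[:, j] = (np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2 * h)
    return J


def scalar_dare_solution(a, b, q, r):
    """Closed-form positive root of the scalar discrete Riccati equation."""
    # S = q + a^2 S - a^2 b^2 S^2 / (r + b^2 S)
    # <=> b^2 S^2 + (r (1 - a^2) - q b^2) S - q r = 0, take the positive root
    A2 = b * b
    B2 = r * (1 - a * a) - q * A2
    C2 = -q * r
    S = (-B2 + np.sqrt(B2 * B2 - 4 * A2 * C2)) / (2 * A2)
    K = a * b * S / (r + b * b * S)
    return S, K
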