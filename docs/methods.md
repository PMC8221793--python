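# Methods

## Model

### Plant

The arm is a planar two-link rigid body (shoulder and elbow) with state
`x = [q, q̇, τ] ∈ R⁶` and torque-change control `u = τ̇ ∈ R²`:

    τ = M(q) q̈ + C(q, q̇) q̇ + B q̇,          u = τ̇,

with the standard inertia/Coriolis entries for segment inertias `I₁, I₂`,
forearm mass `M₂`, segment lengths `L₁, L₂` and centre-of-mass distance
`Lg₂`. Gravity is identically zero (horizontal movements). Motor noise enters
the torque rows through four independent Brownian channels: two additive
(magnitude σᵢ, constant variance) and two signal-dependent (magnitude
`dᵢ·uᵢ`, standard deviation proportional to the command).

Default physical constants (SI): `I₁ = 0.025`, `I₂ = 0.045` kg·m²,
`M₁ = 1.4`, `M₂ = 1.0` kg, `L₁ = 0.30`, `L₂ = 0.33` m, `Lg₁ = 0.11`,
`Lg₂ = 0.16` m — the standard human-arm set of the planar-reaching
literature. The joint viscosity matrix `B` defaults to zero: with the
model's noise calibration (σ = 0.005 fixed on slow 1.4 s movements,
d = 0.01 on fast 0.35 s movements) a dissipative `B` of the commonly used
0.05 N·m·s/rad scale suppresses the variance accumulation that the
calibration requires, so passive damping during planning is taken as
negligible and viscosity is modelled explicitly only where it matters — the
stopping mechanism at movement end (below). `B` is configurable throughout.

### Moment closure

With a deterministic (open-loop) control, the mean and covariance of the
state follow

    ṁ = f(m, u) + ½ (∂²f/∂x² • P),     Ṗ = A P + P Aᵀ + G(u) G(u)ᵀ,

where `A = ∂f/∂x(m, u)` and the bullet is the trace contraction of the
per-component Hessians of the drift with `P`. This second-order closure is
exact for linear dynamics and accurate while third-order effects are small.
Its error is measured, not assumed: the test suite compares `(m(T), P(T))`
against 10⁵ seeded SDE rollouts and agrees within 3 standard errors for
movements at the preferred-duration scale (T ≈ 1 s). For very fast
movements (0.35 s, peak joint speeds of several rad/s) the closure departs
from Monte-Carlo endpoint variance by about 1–2 % — larger than 10⁵-sample
Monte-Carlo noise and visible in such a comparison, but immaterial at the
reported log-variance precision.

All drift derivatives (Jacobian, Hessian contraction) and the Cartesian hand
jerk (third total time derivative of the forward kinematics along the drift)
are derived symbolically with sympy per arm-parameter set, compiled once to
vectorized numpy functions and cached.

### Feedforward planning problem

    min_{u(·), T}   r · tr[J(m_q(T)) P_q(T) J(m_q(T))ᵀ]
                    + ∫₀ᵀ ( uᵀu + α ‖hand jerk of the mean path‖² ) dt

- Terminal mean constraints are hard: hand position on target (hand space,
  so the two joints determine the final posture), `q̇(T) = 0`, `τ(T) = 0`.
- Terminal covariance is free but penalized (weight `r`), which is what
  creates a finite optimal duration under constant noise.
- Initial state: rest at a known configuration, `P₀ = 0`, `τ(0) = 0`.
- Defaults: `r = 2000`, `α = 0.02`, σ = 0.005 rad·s^(-3/2),
  d = 0.01 rad·(N·m)⁻¹·s^(-1/2). A second calibration for a
  higher-variance/faster regime (σ = 0.025, r = 6000) is used by the
  condition-grid pipeline when requested.

### Transcription

Single shooting: the control is piecewise linear on `n_controls = 21`
uniformly spaced nodes in normalized time `s ∈ [0, 1]`; the 27-dimensional
augmented state (mean, upper triangle of `P`, cost quadratures) is
integrated with fixed-step RK4 (`n_steps = 100`); free final time enters as
a decision variable multiplying the dynamics (time-scaling transform). The
NLP is solved by SLSQP with equality constraints on the terminal mean.
Gradients are forward finite differences (step 1e-6, relative), evaluated in
a single batched integration pass — all perturbed trajectories propagate
simultaneously as one vectorized array — so one gradient costs roughly two
function evaluations of wall time. Symmetry of `P` is structural (vech
storage); positive semidefiniteness is monitored a posteriori
(eigenvalues ≥ −1e-10 in tests).

A direct-collocation transcription with an interior-point NLP solver would
be the textbook alternative; shooting was chosen because the plant is stable
over the horizons of interest and it keeps the whole solver inside
numpy/scipy. Mesh sufficiency is tested: doubling both node counts moves the
free-time optimum by < 2 % and deterministic costs by < 0.5 %. The initial
guess is a minimum-jerk hand path mapped through inverse kinematics and
inverse dynamics; duration scans warm-start each solve with the previous
control solution.

Free-time caveat: with σ = 0 the total cost typically decreases
monotonically with duration (signal-dependent noise and effort both favour
slow movements) and no interior optimum exists; `solve_free_time` warns in
that case.

### Feedback corrector

Linearization along the plan in deviation coordinates, extended horizon
`T′ = T + 1 s` with the system held at rest beyond `T`, Euler
discretization at `dt = 5 ms` (`Φ = I + A·dt`, process noise `G Gᵀ dt`).
The continuous observation `dy = g(x) dt + β dη` is implemented as a
per-step measurement with covariance `β² I / dt`, which preserves the
continuous-time information rate; the simulator draws its measurement noise
from the same convention, so controller and plant are consistent. The
estimator starts at the known initial state (error covariance zero), and
certainty equivalence holds because the diffusion depends on the nominal
command only.

- Feedback gains: backward Riccati recursion with state cost
  `ρ·diag(1,1,0,0,0,0)·dt` on `[T, T′]` (zero before `T`) and control cost
  `I·dt`; only the final *posture* is corrected, there is no trajectory
  tracking. Default `ρ = 1000`; an optional `ρβ = const` variant is
  supported through the parameters but off by default.
- Filter gains: forward (Kalman) recursion; `β = 0.003` with vision,
  `β = 0.03` without.
- Sensory delay: the discrete state is augmented with `k = delay/dt` past
  copies (50 ms → k = 10, dimension 66) and the observation reads the
  oldest block. Simulated endpoint variance with and without the 50 ms
  delay differs by a few percent only.
- Observation matrix: full state by default (`C = I₆`); a
  position+velocity variant (`observed="posvel"`) gives closely similar
  results.

### Simulation and measurement

Trials are Euler–Maruyama rollouts at `dt = 5 ms` of the nonlinear plant
driven by `u(t) − K(t) ẑ_t` (or `u(t)` alone for feedforward-only
execution); the signal-dependent noise uses the actually executed command.
One master seed drives each ensemble; identical configurations are
bit-identical. For movements without vision (and for feedforward-only
rollouts) a stopping mechanism adds 3.5 kg·m²/s to both diagonal viscosity
entries from 50 ms before the planned end — a proxy for the higher muscle
viscosity at low speed — which brings terminal hand speed below the
measurement threshold in ≥ 99 % of trials.

Durations and endpoints use the same rule as experimental processing: the
movement spans the first to the last sample with hand speed above 1 cm/s,
and the endpoint is the position at that last sample. Trials still above
threshold at `T′` are flagged as truncated (their endpoint is the final
sample); with strong visual feedback a substantial fraction of trials
dithers around the 1 cm/s threshold, which inflates with-vision duration
estimates — a known property of threshold segmentation on noisy speed
profiles, shared by any pipeline using this rule. Recorded trajectories are
smoothed with a zero-phase (forward–backward) 5th-order Butterworth filter,
12.5 Hz cutoff — the bidirectional pass removes phase delay and doubles the
effective order — before numerical differentiation; simulated trajectories
are band-limited by the plant and are segmented directly. Endpoint
variability is reported as the natural logarithm of the trace of the
endpoint covariance expressed in mm² (log base is a convention; natural log
is used everywhere), and confidence ellipses are 90 % χ²₂ level sets of the
Gaussian fit.

### Synthetic trial generator

`metrics.generate_synthetic_trials` emulates what the pipeline assumes of
tablet recordings: minimum-jerk paths at 125 Hz with per-trial endpoint
scatter, multiplicative timing jitter, additive measurement noise
(default 0.05 mm) and rest padding. It provides exact ground truth for
duration, peak velocity and endpoint covariance, so pipeline bias is
testable (duration within 2 samples, peak velocity within 1 %, log variance
consistent in the large-n limit). It does not emulate feedback corrections,
asymmetric speed profiles, or movement-dependent noise, so passing these
tests validates the measurement code, not the biological realism of the
fixture.

### Point-mass benchmark

A 10 cm reach of a 1 kg point mass whose force passes through a 50 ms
first-order muscle filter, controlled by the extended LQG scheme in which
control-multiplicative noise couples the optimal controller and estimator;
the coupled fixed point is computed by alternating backward (controller)
and forward (moment/filter) sweeps, with geometric convergence of the gain
residual. Benchmark defaults: multiplicative noise 0.5·u, additive force
noise 0.2 N·s^(-1/2), observation SDs (0.01 m, 0.1 m/s, 1 N) — ×10 in the
no-vision variant — terminal weights (10⁴, 10², 10⁻²) on position error,
velocity and force, control weight 10⁻³ per step-second. These constants
are this package's own documented choices, sized so that open-loop drift
over a second is of centimetre scale; the benchmark asserts the regime
structure (cost plateau with good vision; interior minimum of expected cost
with degraded vision), not particular axis values. Monte-Carlo estimates
default to 10⁴ samples (configurable upward) with per-duration standard
errors, cross-checked against the exact linear-Gaussian covariance
recursion in the additive-noise case.

## Numerical choices and degenerate inputs

- SLSQP tolerances: `ftol = 1e-10`, up to 400 iterations; terminal
  constraint violations are verified `< 1e-6` (m, rad/s, N·m) after the
  solve and a failure raises with diagnostics.
- Moment ODEs: fixed-step RK4; non-finite states raise with the failure
  time. Covariance storage is symmetric by construction.
- Scans and grids record per-item failures and continue.
- Degenerate endpoint distributions (zero variance) raise in
  `endpoint_statistics`; `summarize` reports −inf log variance and omits
  the ellipse.
- Delay must be an integer multiple of `dt`; `delay = 0` returns the
  system unchanged.
- Seeds: every stochastic routine takes an explicit integer seed;
  ensembles record it in their metadata.

## Known limitations

- The moment closure is second order; its bias is percent-scale for very
  fast movements (see above) and untested far outside the reaching regime.
- Shooting transcriptions can stall on poor initial guesses for extreme
  durations (< 0.2 s with strong noise); the scan machinery treats such
  cases as recorded failures.
- The planner's covariance assumes noise at the nominal command; closed-loop
  rollouts add small signal-dependent noise from the corrective command
  itself, so closed-loop variance is bounded below by estimation quality
  rather than matching the linearized prediction exactly.
- The point-mass benchmark is qualitative by design; its constants are not
  fitted to any dataset.
- Exact replication of published duration/variance values depends on the
  arm-parameter transcription (see the viscosity note above): with the
  defaults here the preferred duration of the reference task computes to
  ~1.14 s and the no-vision closed-loop endpoint variance to ~4.2 log(mm²).
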