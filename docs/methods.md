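# Methods

## Model

Each node of the network is a Rössler-like chaotic oscillator — the
piecewise-linear electronic-circuit variant — with three state variables
per node:

```
dx_i/dt = -alpha1 * (x_i + beta*y_i + Gamma*z_i)
dy_i/dt = -alpha2 * (-gamma*x_i + (1 - delta)*y_i - K*phi * sum_j A_ij*(y_j - y_i))
dz_i/dt = -alpha3 * (-eta*G(x_i) + z_i)

G(x) = 0            if x <= V_th
     = mu*(x - V_th) if x  > V_th
```

Nodes are diffusively coupled through their `y` variables.  `A` is a binary
symmetric adjacency matrix with zero diagonal (no self-loops) and `K` is the
common coupling strength; `K*A_ij` is the effective per-edge coupling.  The
origin is a fixed point of the drift (`G(0) = 0`), and for typical parameters
trajectories settle onto a bounded chaotic attractor with |state| of a few
volts.

Two named presets ship with the package (any field can be overridden):

| parameter    | `n1_2` (1–2 nodes) | `n28` (large networks) |
|--------------|--------------------|------------------------|
| alpha1       | 500 s⁻¹            | 500 s⁻¹                |
| alpha2       | 200 s⁻¹            | 200 s⁻¹                |
| alpha3       | 10 000 s⁻¹         | 10 000 s⁻¹             |
| beta         | 10                 | 10                     |
| Gamma        | 20                 | 20                     |
| gamma        | 50                 | 50                     |
| delta        | 8.3333             | 8.6207                 |
| phi          | 1                  | 0.0210                 |
| eta          | 1                  | 1                      |
| mu           | 15                 | 15                     |
| V_th         | 3.0088 V           | 2.1265 V               |
| sigma_omega  | 0.02               | 0.001                  |
| sigma_nu     | 0.5                | 0.001                  |
| f_s          | 37 000 S/s         | 30 000 S/s             |
| n_steps      | 100 000            | 15 000                 |

## Discretisation and noise

The simulator realises a discrete-time Markov map on a uniform grid with
`dt = 1/f_s` (dt is always derived, never set independently):

```
u_{k+1} = RK4(u_k; dt) + omega_k,        omega_k ~ N(0, sigma_omega^2 I)
w_k     = (y_1, ..., y_N)(u_k) + nu_k,   nu_k    ~ N(0, sigma_nu^2  I)
```

where `RK4` is one classical fourth-order Runge–Kutta step of the drift.
Process noise is added **once per completed RK4 step** with standard
deviation `sigma_omega` per component — no `sqrt(dt)` scaling — because the
noise is defined on the discrete map that the filter assumes, not on a
continuous SDE.  Measurements observe only the `y` variable of each node.

The initial condition defaults to a uniform draw from `[-0.1, 0.1]^{3N}`
(the model is silent on it); a configurable number of noise-free warm-up
steps can be discarded.  One master seed per run is split with numpy's
`SeedSequence` into independent streams for the initial condition, process
noise, measurement noise and network generation, so changing one consumer
never shifts the others.

## Filter

The estimator is an additive-noise unscented Kalman filter (UKF) with
scaled sigma points.  The transition map is the same RK4 step the simulator
uses; the measurement map selects the observed variables.  Unknown coupling
parameters are appended to the state with constant dynamics (`p_dot = 0`)
and **zero process noise**: the extended process covariance has the
estimated `Q_omega` in the dynamical block and exactly zero rows/columns in
the parameter block, so parameter uncertainty can only shrink as evidence
accumulates.

Estimation modes:

- `single_k` — adjacency known, one unknown `K`;
- `directional_pair` — two nodes, `K12` and `K21` estimated separately;
- `all_pairs` — all `N(N-1)/2` effective couplings `K*A_ij` estimated
  jointly (the basis of topology reconstruction).

Filter defaults (all configurable, all logged with run outputs):

- initial coupling guess 0.5 — the middle of the working range [0, 1];
- initial covariance: identity for the dynamical block, 0.25 for the
  parameter block (a std of 0.5 spans a guess of 0.5 over [0, 1]);
- the `y_i` components of the initial mean are set to the first
  measurement row; `x_i`, `z_i` start at 0;
- `Q_omega` and `Q_nu` are *sample* covariances of 100 000-draw
  realizations at the nominal `sigma_omega` / `sigma_nu`, emulating noise
  statistics characterised from data rather than known exactly;
- parameter estimates are unconstrained — no clipping to [0, 1];
- sigma-point hyperparameters `alpha_sp=1.0`, `beta_sp=2.0`, `kappa_sp=0`.

### Why `alpha_sp = 1`

The common small-spread convention (`alpha_sp ~ 1e-3`) shrinks the sigma
points to an infinitesimal neighbourhood of the mean, which makes the UKF
behave like an extended Kalman filter.  For this model that is measurably
harmful: the diode gain `G(x)` has a kink at `V_th`, and a sigma-point cloud
much narrower than the state uncertainty never straddles the kink, so the
propagated covariance is wrong exactly where the dynamics are most
nonlinear.  Empirically (see the test suite) the full spread improves
hidden-`z` recovery correlation from ~0.88–0.97 to >= 0.98 and removes an
attenuation-type bias in coupling estimates under heavy measurement noise.
`alpha_sp=1, beta_sp=2, kappa_sp=0` is Julier's original unscented transform
and is the package default; the scaled parametrisation remains available.

### Numerical safeguards

- every covariance is symmetrised (`(P + P^T)/2`) each step;
- Cholesky factorisations retry with escalating diagonal jitter
  (1e-12 → 1e-6); failure beyond the maximal jitter is a hard error
  (`IndefiniteCovarianceError`);
- a singular innovation covariance skips the update with a warning;
- non-finite states or estimates abort with the failing step index;
- plain covariance form (no square-root variant): adequate at the
  dimensions used here (extended state <= ~500).

## Reconstruction

An all-pairs run yields one estimate trace per unordered node pair.  Each
trace is summarised after discarding the first 10% (burn-in) by its median
plus boxplot statistics (quartiles, min/max whiskers, outliers beyond
1.5×IQR — the standard boxplot rule).  Medians are thresholded at 0.5:
strictly above → link, otherwise (including exactly 0.5) → no link.
Reconstruction quality against a known truth is the root-sum-of-squares
distance `D = sqrt(sum_ij (K_ij - K^est_ij)^2)` over **all** ordered
entries, so symmetric discrepancies count twice; a per-pair binary accuracy
is reported alongside as a more interpretable score.  In converged runs the
edge medians are strongly bimodal (near 0 and near K) and the binary result
is insensitive to any threshold in [0.3, 0.7].

The "D tends to zero" convergence property is checked on the 100-step
moving average of the distance trace, sampled every 500 steps over the
final half of the run, allowing increases of at most 0.05 per sample —
strict monotonicity is violated at the 1e-2 level by measurement noise even
in fully converged runs.

## What the synthetic generator does and does not emulate

The generator produces exactly the data the inference method assumes: the
discrete Markov map above with Gaussian process and measurement noise and
y-only observations.  It does **not** emulate real acquisition chains —
anti-aliasing/temporal filtering, quantisation, drifting component values,
parameter mismatch between nodes, or non-Gaussian disturbances.  Passing
tests therefore demonstrate correctness of the estimator under its own
model class, not robustness to the model errors of laboratory data.

## Problem sizes and statistical limits

Default study sizes: two-node runs use 100 000 steps (the `n1_2` preset);
the coupling-strength sweep uses 50 000 steps per grid point; the
scaled-down topology study uses N=8 nodes, 10 random edges, K=1 and 15 000
steps at the `n28` preset.  The full 28-node, 378-parameter reconstruction
(extended state dimension 462) is the same code path — `NetworkReconstructor`
on a 28-column measurement matrix — and takes on the order of an hour of
single-core time; it is not part of the default test runs.

A hard limit worth stating: with process noise injected into the *data*,
the per-step information about K scales as
`(alpha2*phi*dt*|y_j - y_i| / sigma_omega)^2`.  At the `n1_2` preset and
K=0.7 this puts a Cramér–Rao bound of roughly 0.006–0.007 on the standard
error of *any* K estimator after 100 000 steps (about 1% relative).  Final
estimates should be judged against the filter's own ±sigma band — which the
band-coverage test shows is well calibrated — rather than against a fixed
tiny tolerance.  Accuracy far beyond this bound is only possible when the
data itself carries (near-)zero process noise.

## Known limitations

- Robustness to a *misspecified* filter noise model is asymmetric: telling
  the filter the process noise is smaller than it is (or the measurement
  noise larger) degrades the estimate gracefully, while a grossly inflated
  `Q_omega` or a near-zero `Q_nu` biases K strongly (the filter then
  explains coupling effects as noise, or treats measurement noise as
  signal).  The robustness test asserts the graceful half plus finiteness
  everywhere.
- Directional-pair estimates are noticeably more dispersed than the
  symmetric single-K estimates; no corrective mechanism is applied.
- No smoothing (RTS), no adaptive noise estimation, no square-root filter,
  no time-varying couplings.
- Estimates of the oscillator constants themselves (alpha's, delta, ...)
  are out of scope; only coupling parameters are identified.
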