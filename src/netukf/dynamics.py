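"""Networks of diffusively coupled Rössler-like chaotic oscillators.

The model is the piecewise-linear electronic-circuit variant of the Rössler
system.  Each node carries three voltage-like variables (x, y, z):

    dx_i/dt = -alpha1 * (x_i + beta * y_i + Gamma * z_i)
    dy_i/dt = -alpha2 * (-gamma * x_i + (1 - delta) * y_i
                         - K * phi * sum_j A_ij * (y_j - y_i))
    dz_i/dt = -alpha3 * (-eta * G(x_i) + z_i)

with the piecewise-linear gain G(x) = 0 for x <= V_th and mu * (x - V_th)
above threshold.  Nodes are coupled diffusively through their y variables,
with binary adjacency A and a common (or per-edge) coupling strength K.

Time is discretised on a uniform grid dt = 1/f_s; one step of the discrete
Markov map is a classical fourth-order Runge-Kutta advance of the drift,
followed by additive zero-mean Gaussian process noise (std ``sigma_omega``
per component per step, no sqrt(dt) scaling: the noise is defined on the
discrete map, not on the continuous SDE).  Measurements are the y variables
only, contaminated by additive Gaussian noise of std ``sigma_nu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import networkx as nx
import numpy as np

__all__ = [
    "OscillatorParams",
    "NetworkModel",
    "SamplingGrid",
    "NoiseSpec",
    "Trajectory",
    "MeasurementSeries",
    "Preset",
    "PRESETS",
    "get_preset",
    "g_nonlinearity",
    "drift",
    "rk4",
    "rk4_step",
    "simulate",
    "measure",
    "random_network",
    "child_seeds",
    "SimulationBlowUpError",
]


class SimulationBlowUpError(RuntimeError):
    """Raised when the integrated state becomes non-finite."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"state became non-finite at step {step}")


def child_seeds(master: Optional[int], n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (< 2**31) from a master seed.

    Uses numpy's SeedSequence so that streams for process noise, measurement
    noise, network generation etc. are statistically independent and changing
    one consumer does not shift the others.
    """
    ss = np.random.SeedSequence(master)
    state = ss.generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OscillatorParams:
    """Rate constants and dimensionless coefficients of one oscillator.

    alpha1, alpha2, alpha3 are rates in s^-1; V_th is the diode threshold in
    volts; the remaining coefficients are dimensionless.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    beta: float
    Gamma: float
    gamma: float
    delta: float
    phi: float
    eta: float
    mu: float
    V_th: float

    def __post_init__(self):
        vals = {f: getattr(self, f) for f in self.__dataclass_fields__}
        for name, v in vals.items():
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
        if self.alpha1 <= 0 or self.alpha2 <= 0 or self.alpha3 <= 0:
            raise ValueError("rate constants alpha1, alpha2, alpha3 must be > 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    def replace(self, **kw) -> "OscillatorParams":
        return replace(self, **kw)


@dataclass
class NetworkModel:
    """Coupling topology and strength: binary adjacency A plus K.

    ``K`` may be a scalar (common coupling) or an NxN matrix of per-ordered-
    pair couplings when directionality is modelled.  ``A`` is binary with
    zero diagonal; symmetry is enforced unless ``symmetric=False``.
    """

    N: int
    A: np.ndarray
    K: Union[float, np.ndarray] = 0.0
    symmetric: bool = True

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.shape != (self.N, self.N):
            raise ValueError(f"adjacency must be {self.N}x{self.N}, got {A.shape}")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if self.symmetric and not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        self.A = A

    @property
    def coupling_matrix(self) -> np.ndarray:
        """Effective per-edge weights W = K * A (or element-wise K_ij * A_ij)."""
        K = np.asarray(self.K, dtype=float)
        return K * self.A

    @property
    def n_pairs(self) -> int:
        return self.N * (self.N - 1) // 2


@dataclass(frozen=True)
class SamplingGrid:
    """Uniform time grid: dt is always derived as 1/f_s, never set directly."""

    f_s: float
    n_steps: int

    def __post_init__(self):
        if self.f_s <= 0:
            raise ValueError("sampling rate f_s must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def dt(self) -> float:
        return 1.0 / self.f_s

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt


@dataclass(frozen=True)
class NoiseSpec:
    sigma_omega: float  # process-noise std per state component per step
    sigma_nu: float  # measurement-noise std per observed component

    def __post_init__(self):
        if self.sigma_omega < 0 or self.sigma_nu < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class Trajectory:
    """Full-state time series: states[k] = (x1, y1, z1, ..., xN, yN, zN)."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times and states must have the same length")
        if self.states.shape[1] % 3:
            raise ValueError("state dimension must be a multiple of 3")

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def N(self) -> int:
        return self.states.shape[1] // 3

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0::3]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1::3]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2::3]


@dataclass
class MeasurementSeries:
    """Observed noisy per-node y traces on the simulation grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times and values must have the same length")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Presets (per-regime parameter sets used throughout the validation studies)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Preset:
    """A named, fully concrete simulation regime (any field overridable)."""

    params: OscillatorParams
    f_s: float
    sigma_omega: float
    sigma_nu: float
    n_steps: int

    def grid(self, n_steps: Optional[int] = None) -> SamplingGrid:
        return SamplingGrid(f_s=self.f_s, n_steps=self.n_steps if n_steps is None else n_steps)

    def noise(self) -> NoiseSpec:
        return NoiseSpec(sigma_omega=self.sigma_omega, sigma_nu=self.sigma_nu)


#: Small-motif regime (isolated node and two coupled nodes).
PRESET_N1_2 = Preset(
    params=OscillatorParams(
        alpha1=500.0,
        alpha2=200.0,
        alpha3=10_000.0,
        beta=10.0,
        Gamma=20.0,
        gamma=50.0,
        delta=8.3333,
        phi=1.0,
        eta=1.0,
        mu=15.0,
        V_th=3.0088,
    ),
    f_s=37_000.0,
    sigma_omega=0.02,
    sigma_nu=0.5,
    n_steps=100_000,
)

#: Large-network regime (28-node topology studies; lower noise, shorter runs).
PRESET_N28 = Preset(
    params=PRESET_N1_2.params.replace(delta=8.6207, phi=0.0210, V_th=2.1265),
    f_s=30_000.0,
    sigma_omega=0.001,
    sigma_nu=0.001,
    n_steps=15_000,
)

PRESETS: dict[str, Preset] = {"n1_2": PRESET_N1_2, "n28": PRESET_N28}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# Drift, RK4 and simulation
# ---------------------------------------------------------------------------


def g_nonlinearity(x, V_th: float, mu: float):
    """Piecewise-linear diode gain: 0 below threshold, mu*(x - V_th) above.

    Continuous at x = V_th (the boundary belongs to the zero branch).
    Vectorised over ``x``.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x > V_th, mu * (x - V_th), 0.0)
    return out if out.ndim else float(out)


def _drift_batch(
    states: np.ndarray,
    p: OscillatorParams,
    W: np.ndarray,
    k_scale: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Drift of a batch of network states.

    states : (m, 3N) array of states (one row per sigma point / trajectory).
    W      : effective coupling weights.  Either (N, N) shared by all rows or
             (m, N, N) per-row weights; phi is applied here, not in W.
    k_scale: optional (m, 1) per-row scalar multiplying the coupling sum
             (fast path for a scalar K with shared adjacency, W = A).
    """
    x = states[:, 0::3]
    y = states[:, 1::3]
    z = states[:, 2::3]
    G = np.where(x > p.V_th, p.mu * (x - p.V_th), 0.0)
    if W.ndim == 2:
        S = y @ W.T - W.sum(axis=1) * y
    else:
        S = np.einsum("mij,mj->mi", W, y) - W.sum(axis=2) * y
    if k_scale is not None:
        S = k_scale * S
    out = np.empty_like(states)
    out[:, 0::3] = -p.alpha1 * (x + p.beta * y + p.Gamma * z)
    out[:, 1::3] = -p.alpha2 * (-p.gamma * x + (1.0 - p.delta) * y - p.phi * S)
    out[:, 2::3] = -p.alpha3 * (-p.eta * G + z)
    return out


def drift(state: np.ndarray, params: OscillatorParams, net: NetworkModel) -> np.ndarray:
    """Deterministic time derivative of the full network state.

    Accepts a (3N,) vector or an (m, 3N) batch; returns the same shape.
    """
    state = np.asarray(state, dtype=float)
    squeeze = state.ndim == 1
    batch = np.atleast_2d(state)
    if batch.shape[1] != 3 * net.N:
        raise ValueError(
            f"state dimension {batch.shape[1]} does not match 3N = {3 * net.N}"
        )
    out = _drift_batch(batch, params, net.coupling_matrix)
    return out[0] if squeeze else out


def rk4(f: Callable[[np.ndarray], np.ndarray], state: np.ndarray, dt: float) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step of an arbitrary drift f."""
    k1 = f(state)
    k2 = f(state + 0.5 * dt * k1)
    k3 = f(state + 0.5 * dt * k2)
    k4 = f(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _rk4_batch(states, dt, p, W, k_scale=None):
    k1 = _drift_batch(states, p, W, k_scale)
    k2 = _drift_batch(states + 0.5 * dt * k1, p, W, k_scale)
    k3 = _drift_batch(states + 0.5 * dt * k2, p, W, k_scale)
    k4 = _drift_batch(states + dt * k3, p, W, k_scale)
    return states + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def rk4_step(
    state: np.ndarray, dt: float, params: OscillatorParams, net: NetworkModel
) -> np.ndarray:
    """Advance the network state by dt with classical RK4 (deterministic).

    Raises SimulationBlowUpError if the output is non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state = np.asarray(state, dtype=float)
    squeeze = state.ndim == 1
    batch = np.atleast_2d(state)
    if batch.shape[1] != 3 * net.N:
        raise ValueError(
            f"state dimension {batch.shape[1]} does not match 3N = {3 * net.N}"
        )
    out = _rk4_batch(batch, dt, params, net.coupling_matrix)
    if not np.isfinite(out).all():
        raise SimulationBlowUpError(step=0)
    return out[0] if squeeze else out


def simulate(
    net: NetworkModel,
    params: OscillatorParams,
    grid: SamplingGrid,
    noise: NoiseSpec,
    init: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    process_noise: Optional[np.ndarray] = None,
    transient: int = 0,
) -> Trajectory:
    """Simulate the noisy discrete-time map u_{k+1} = RK4(u_k) + omega_k.

    Parameters
    ----------
    init
        Initial 3N state.  Default: uniform on [-0.1, 0.1]^{3N}, drawn from
        the run seed.
    seed
        Master seed; internally split into independent streams for the
        initial condition and the process noise.
    process_noise
        Optional pre-drawn (n_steps - 1, 3N) noise array (overrides seed for
        the noise; useful for matched-noise experiments).
    transient
        Number of noise-free RK4 warm-up steps discarded before recording.
    """
    n, d = grid.n_steps, 3 * net.N
    init_seed, noise_seed = child_seeds(seed, 2)
    if init is None:
        init = np.random.default_rng(init_seed).uniform(-0.1, 0.1, size=d)
    state = np.asarray(init, dtype=float).copy()
    if state.shape != (d,):
        raise ValueError(f"init must have shape ({d},), got {state.shape}")

    if process_noise is None:
        if noise.sigma_omega > 0 and n > 1:
            rng = np.random.default_rng(noise_seed)
            process_noise = rng.normal(0.0, noise.sigma_omega, size=(n - 1, d))
        else:
            process_noise = np.zeros((max(n - 1, 0), d))
    else:
        process_noise = np.asarray(process_noise, dtype=float)
        if process_noise.shape != (n - 1, d):
            raise ValueError(f"process_noise must have shape ({n - 1}, {d})")

    p, W = params, net.coupling_matrix
    dt = grid.dt
    buf = state[None, :].copy()
    for _ in range(transient):
        buf = _rk4_batch(buf, dt, p, W)

    states = np.empty((n, d))
    states[0] = buf[0]
    for k in range(n - 1):
        buf = _rk4_batch(buf, dt, p, W)
        buf += process_noise[k]
        if not np.isfinite(buf).all():
            raise SimulationBlowUpError(step=k + 1)
        states[k + 1] = buf[0]
    return Trajectory(times=grid.times, states=states)


def measure(
    traj: Trajectory, noise: NoiseSpec, seed: Optional[int] = None
) -> MeasurementSeries:
    """Observe the y variables of every node, plus i.i.d. Gaussian noise."""
    y = traj.y.copy()
    if noise.sigma_nu > 0:
        rng = np.random.default_rng(child_seeds(seed, 1)[0])
        y += rng.normal(0.0, noise.sigma_nu, size=y.shape)
    return MeasurementSeries(times=traj.times.copy(), values=y)


def random_network(
    N: int,
    n_edges: Optional[int] = None,
    edge_density: Optional[float] = None,
    seed: Optional[int] = None,
    K: float = 1.0,
) -> NetworkModel:
    """Uniformly random symmetric binary network with ``n_edges`` links.

    Exactly one of ``n_edges`` / ``edge_density`` must be given; density is
    relative to the N(N-1)/2 possible undirected edges.
    """
    max_edges = N * (N - 1) // 2
    if (n_edges is None) == (edge_density is None):
        raise ValueError("specify exactly one of n_edges or edge_density")
    if n_edges is None:
        if not 0.0 <= edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        n_edges = int(round(edge_density * max_edges))
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must be in [0, {max_edges}] for N={N}")
    g = nx.gnm_random_graph(N, n_edges, seed=child_seeds(seed, 1)[0])
    A = nx.to_numpy_array(g, nodelist=range(N), dtype=float)
    return NetworkModel(N=N, A=A, K=K)
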