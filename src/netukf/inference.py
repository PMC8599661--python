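"""Joint state-parameter estimation of coupling strengths from y-only data.

Unknown couplings are appended to the dynamical state with trivial dynamics
(p_dot = 0), turning parameter inference into nonlinear filtering: the UKF
tracks the extended state (x_1, y_1, z_1, ..., x_N, y_N, z_N, p_1, ..., p_q)
from noisy observations of the y variables alone.  The extended process
covariance keeps exactly zero rows/columns for the parameter block — the
parameters carry no process noise, so their posterior variance can only
shrink as evidence accumulates.

Three estimation modes are supported:

``single_k``
    The adjacency matrix is known; only the common coupling strength K is
    estimated (q = 1).
``directional_pair``
    Two nodes, no symmetry assumption: K12 and K21 estimated separately
    (q = 2).
``all_pairs``
    Every unordered pair's effective coupling K*A_ij is estimated
    (q = N(N-1)/2), which is the basis of topology reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from . import dynamics as dyn
from .dynamics import (
    MeasurementSeries,
    NetworkModel,
    OscillatorParams,
    Preset,
    Trajectory,
    child_seeds,
    get_preset,
)
from .ukf import FilterResult, GaussianBelief, UKFConfig, run_filter

__all__ = [
    "MODES",
    "ParameterSet",
    "EstimateTrace",
    "estimate_noise_covariance",
    "build_extended_covariance",
    "make_extended_transition",
    "make_measurement_map",
    "parameter_labels",
    "pair_index",
    "CouplingEstimator",
    "HiddenStateEstimator",
    "estimate_coupling",
    "recover_hidden_states",
]

MODES = ("single_k", "directional_pair", "all_pairs")

_OBS_OFFSET = {"x": 0, "y": 1, "z": 2}


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------


def pair_index(N: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, the canonical order
    of the all-pairs parameter vector: (1,2), (1,3), ..., (N-1,N)."""
    return np.triu_indices(N, k=1)


def parameter_labels(mode: str, N: int) -> tuple[str, ...]:
    """Human-readable labels of the estimated parameters (1-based nodes)."""
    if mode == "single_k":
        return ("K",)
    if mode == "directional_pair":
        return ("K12", "K21")
    if mode == "all_pairs":
        iu, ju = pair_index(N)
        return tuple(f"K{i + 1}_{j + 1}" for i, j in zip(iu, ju))
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


@dataclass
class ParameterSet:
    """Ordered labels, current values and starting guesses of the unknowns."""

    names: tuple[str, ...]
    values: np.ndarray
    init_guess: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.init_guess = np.asarray(self.init_guess, dtype=float).ravel()
        q = len(self.names)
        if q < 1:
            raise ValueError("at least one parameter is required")
        if len(set(self.names)) != q:
            raise ValueError("parameter labels must be unique")
        if self.values.size != q or self.init_guess.size != q:
            raise ValueError("values/init_guess must match the number of labels")

    @property
    def q(self) -> int:
        return len(self.names)


@dataclass
class EstimateTrace:
    """Per-parameter estimate and one-standard-deviation band over time.

    The band is the square root of the parameter's diagonal entry of the
    filter's covariance estimate.
    """

    names: tuple[str, ...]
    values: np.ndarray  # (n_steps, q)
    sigmas: np.ndarray  # (n_steps, q)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        if self.values.shape != self.sigmas.shape:
            raise ValueError("values and sigmas must have the same shape")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count must match the number of labels")
        if (self.sigmas < 0).any():
            raise ValueError("uncertainty bands must be non-negative")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return len(self.names)

    @property
    def final(self) -> np.ndarray:
        return self.values[-1]

    def median(self, burn_fraction: float = 0.1) -> np.ndarray:
        """Per-parameter median after discarding the initial burn-in."""
        start = int(burn_fraction * self.n_steps)
        if start >= self.n_steps:
            raise ValueError("burn-in leaves no samples")
        return np.median(self.values[start:], axis=0)

    def to_frame(self):
        import pandas as pd

        data = {"step": np.arange(self.n_steps)}
        for j, name in enumerate(self.names):
            data[name] = self.values[:, j]
            data[f"{name}_sigma"] = self.sigmas[:, j]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Filter ingredients
# ---------------------------------------------------------------------------


def estimate_noise_covariance(
    sigma: float, dim: int, n_samples: int = 100_000, seed: Optional[int] = None
) -> np.ndarray:
    """Sample covariance of a realization of i.i.d. N(0, sigma^2 I) noise.

    The filter is deliberately run with an *estimated* covariance rather
    than the exact sigma^2 I, emulating the realistic situation where the
    noise statistics are characterised from data.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if sigma == 0.0:
        return np.zeros((dim, dim))
    rng = np.random.default_rng(child_seeds(seed, 1)[0])
    draws = rng.normal(0.0, sigma, size=(n_samples, dim))
    C = np.cov(draws, rowvar=False).reshape(dim, dim)
    return 0.5 * (C + C.T)


def build_extended_covariance(Q_omega: np.ndarray, q: int) -> np.ndarray:
    """Extended process covariance: Q_omega in the state block, zeros for
    the q constant parameters (they have no process noise by construction)."""
    Q_omega = np.asarray(Q_omega, dtype=float)
    n = Q_omega.shape[0]
    if Q_omega.shape != (n, n):
        raise ValueError("Q_omega must be square")
    if q < 0:
        raise ValueError("q must be >= 0")
    Qe = np.zeros((n + q, n + q))
    Qe[:n, :n] = Q_omega
    return Qe


def make_extended_transition(
    params: OscillatorParams,
    dt: float,
    N: int,
    mode: str,
    adjacency: Optional[np.ndarray] = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Transition map on the extended state (3N dynamical + q parameters).

    The returned map acts on batches (m, 3N+q): the dynamical block advances
    by one RK4 step using each row's *own* parameter block as coupling
    values; the parameter block is copied unchanged (constant dynamics).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    n_dyn = 3 * N
    if mode == "single_k":
        if adjacency is None:
            raise ValueError("single_k mode requires the known adjacency matrix")
        A = np.asarray(adjacency, dtype=float)
        if A.shape != (N, N):
            raise ValueError(f"adjacency must be {N}x{N}")

        def transition(X: np.ndarray) -> np.ndarray:
            X = np.atleast_2d(X)
            out = X.copy()
            out[:, :n_dyn] = dyn._rk4_batch(
                X[:, :n_dyn], dt, params, A, k_scale=X[:, n_dyn : n_dyn + 1]
            )
            return out

        return transition

    if mode == "directional_pair":
        if N != 2:
            raise ValueError("directional_pair mode requires N = 2")

        def transition(X: np.ndarray) -> np.ndarray:
            X = np.atleast_2d(X)
            m = X.shape[0]
            W = np.zeros((m, 2, 2))
            W[:, 0, 1] = X[:, n_dyn]  # K12: influence of node 2 on node 1
            W[:, 1, 0] = X[:, n_dyn + 1]
            out = X.copy()
            out[:, :n_dyn] = dyn._rk4_batch(X[:, :n_dyn], dt, params, W)
            return out

        return transition

    iu, ju = pair_index(N)

    def transition(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        m = X.shape[0]
        par = X[:, n_dyn:]
        W = np.zeros((m, N, N))
        W[:, iu, ju] = par
        W[:, ju, iu] = par
        out = X.copy()
        out[:, :n_dyn] = dyn._rk4_batch(X[:, :n_dyn], dt, params, W)
        return out

    return transition


def make_measurement_map(N: int, observed: str = "y") -> Callable[[np.ndarray], np.ndarray]:
    """Measurement map selecting one variable per node (default y) from the
    (possibly extended) state; parameter slots are never observed."""
    off = _OBS_OFFSET[observed]

    def measurement(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return X[:, off : 3 * N : 3]

    return measurement


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def _resolve(value, default):
    return default if value is None else value


class CouplingEstimator(BaseEstimator):
    """Estimate coupling strengths of a known oscillator model by UKF.

    Fit on a measurement matrix X of shape (n_steps, N) — one noisy y trace
    per node — and obtain per-parameter estimate trajectories plus the
    filter's one-sigma uncertainty bands.

    Parameters
    ----------
    mode : {"single_k", "directional_pair", "all_pairs"}
        What is estimated; see the module docstring.
    preset : str
        Named parameter regime supplying every unset field ("n1_2" or "n28").
    adjacency : array-like of shape (N, N), optional
        Known adjacency, required for single_k with N > 2 (for N = 2 the
        single connected pair is assumed).
    oscillator_params, f_s, sigma_omega, sigma_nu
        Overrides of the preset's model constants, sampling rate and noise
        levels assumed by the filter.
    coupling_init : float or array-like
        Starting estimate of every unknown coupling (default 0.5, the middle
        of the working range [0, 1]).
    state_var0, param_var0 : float
        Initial posterior variances of the dynamical block and of the
        parameter block (0.25 spans a guess of 0.5 over [0, 1]).
    n_noise_samples : int
        Realization length used to estimate the filter's noise covariances.
    burn_fraction : float
        Initial fraction of the trace discarded by summary statistics.
    random_state : int, optional
        Seed for the noise-covariance realizations.

    Attributes
    ----------
    names_ : tuple of str
        Labels of the estimated parameters.
    trace_ : EstimateTrace
        Estimate and band trajectories, one row per measurement.
    coupling_ : ndarray of shape (q,)
        Post-burn-in median of each parameter trace.
    coupling_sigma_ : ndarray of shape (q,)
        Final one-sigma band of each parameter.
    filter_result_ : FilterResult
        Full filter output (extended-state means and variances).
    """

    def __init__(
        self,
        mode: str = "single_k",
        preset: str = "n1_2",
        adjacency=None,
        oscillator_params: Optional[OscillatorParams] = None,
        f_s: Optional[float] = None,
        sigma_omega: Optional[float] = None,
        sigma_nu: Optional[float] = None,
        coupling_init: Union[float, Sequence[float]] = 0.5,
        state_var0: float = 1.0,
        param_var0: float = 0.25,
        alpha_sp: float = 1.0,
        beta_sp: float = 2.0,
        kappa_sp: float = 0.0,
        n_noise_samples: int = 100_000,
        burn_fraction: float = 0.1,
        random_state: Optional[int] = None,
    ):
        self.mode = mode
        self.preset = preset
        self.adjacency = adjacency
        self.oscillator_params = oscillator_params
        self.f_s = f_s
        self.sigma_omega = sigma_omega
        self.sigma_nu = sigma_nu
        self.coupling_init = coupling_init
        self.state_var0 = state_var0
        self.param_var0 = param_var0
        self.alpha_sp = alpha_sp
        self.beta_sp = beta_sp
        self.kappa_sp = kappa_sp
        self.n_noise_samples = n_noise_samples
        self.burn_fraction = burn_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if isinstance(X, np.ndarray) and X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a 2-D (n_steps, N) array with n_steps >= 2")
        if not np.isfinite(X).all():
            raise ValueError("X must be finite")
        return X

    def fit(self, X, y=None):
        """Run the augmented-state UKF over the measurement matrix X."""
        if isinstance(X, MeasurementSeries):
            X = X.values
        X = self._validate_X(X)
        n_steps, N = X.shape
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "directional_pair" and N != 2:
            raise ValueError("directional_pair mode requires exactly 2 columns")

        pre = get_preset(self.preset)
        params = _resolve(self.oscillator_params, pre.params)
        f_s = _resolve(self.f_s, pre.f_s)
        s_omega = _resolve(self.sigma_omega, pre.sigma_omega)
        s_nu = _resolve(self.sigma_nu, pre.sigma_nu)
        dt = 1.0 / f_s

        names = parameter_labels(self.mode, N)
        q = len(names)
        ci = np.asarray(self.coupling_init, dtype=float).ravel()
        guess = np.full(q, ci[0]) if ci.size == 1 else ci
        if guess.size != q:
            raise ValueError(f"coupling_init must be scalar or length {q}")

        A = self.adjacency
        if self.mode == "single_k":
            if A is None:
                if N != 2:
                    raise ValueError(
                        "single_k with N > 2 requires the adjacency matrix"
                    )
                A = np.array([[0.0, 1.0], [1.0, 0.0]])
            A = np.asarray(A, dtype=float)

        seed_w, seed_nu = child_seeds(self.random_state, 2)
        Q_omega = estimate_noise_covariance(s_omega, 3 * N, self.n_noise_samples, seed_w)
        Q_e = build_extended_covariance(Q_omega, q)
        Q_nu = estimate_noise_covariance(s_nu, N, self.n_noise_samples, seed_nu)

        transition = make_extended_transition(params, dt, N, self.mode, adjacency=A)
        measurement = make_measurement_map(N)

        mean0 = np.zeros(3 * N + q)
        mean0[1 : 3 * N : 3] = X[0]  # y components start at the first observation
        mean0[3 * N :] = guess
        var0 = np.concatenate(
            [np.full(3 * N, float(self.state_var0)), np.full(q, float(self.param_var0))]
        )
        init = GaussianBelief(mean=mean0, cov=np.diag(var0))
        cfg = UKFConfig(
            Q_omega=Q_e,
            Q_nu=Q_nu,
            alpha_sp=self.alpha_sp,
            beta_sp=self.beta_sp,
            kappa_sp=self.kappa_sp,
        )
        result = run_filter(X, transition, measurement, init, cfg)

        self.n_features_in_ = N
        self.names_ = names
        self.dt_ = dt
        self.Q_omega_ext_ = Q_e
        self.Q_nu_ = Q_nu
        self.filter_result_ = result
        self.trace_ = EstimateTrace(
            names=names,
            values=result.means[:, 3 * N :],
            sigmas=result.sigmas[:, 3 * N :],
        )
        self.coupling_ = self.trace_.median(self.burn_fraction)
        self.coupling_sigma_ = self.trace_.sigmas[-1]
        return self

    def predict(self, X=None) -> np.ndarray:
        """Return the fitted coupling estimates (post-burn-in medians)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "coupling_")
        return self.coupling_


class HiddenStateEstimator(BaseEstimator):
    """Recover the full (x, y, z) state of a single oscillator from noisy
    observations of one variable.

    Fit on X of shape (n_steps, 1) (or 1-D), the noisy trace of the observed
    variable; ``states_`` then holds the filtered mean of all three
    variables at every step.

    Parameters are as in CouplingEstimator, plus ``observed`` selecting
    which variable is measured ("x", "y" or "z"; the validation studies
    observe y).
    """

    def __init__(
        self,
        observed: str = "y",
        preset: str = "n1_2",
        oscillator_params: Optional[OscillatorParams] = None,
        f_s: Optional[float] = None,
        sigma_omega: Optional[float] = None,
        sigma_nu: Optional[float] = None,
        state_var0: float = 1.0,
        alpha_sp: float = 1.0,
        beta_sp: float = 2.0,
        kappa_sp: float = 0.0,
        n_noise_samples: int = 100_000,
        random_state: Optional[int] = None,
    ):
        self.observed = observed
        self.preset = preset
        self.oscillator_params = oscillator_params
        self.f_s = f_s
        self.sigma_omega = sigma_omega
        self.sigma_nu = sigma_nu
        self.state_var0 = state_var0
        self.alpha_sp = alpha_sp
        self.beta_sp = beta_sp
        self.kappa_sp = kappa_sp
        self.n_noise_samples = n_noise_samples
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, MeasurementSeries):
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be (n_steps, 1): one observed variable")
        if not np.isfinite(X).all():
            raise ValueError("X must be finite")
        if self.observed not in _OBS_OFFSET:
            raise ValueError("observed must be one of 'x', 'y', 'z'")

        pre = get_preset(self.preset)
        params = _resolve(self.oscillator_params, pre.params)
        f_s = _resolve(self.f_s, pre.f_s)
        s_omega = _resolve(self.sigma_omega, pre.sigma_omega)
        s_nu = _resolve(self.sigma_nu, pre.sigma_nu)
        dt = 1.0 / f_s

        net = NetworkModel(N=1, A=np.zeros((1, 1)), K=0.0)
        W = net.coupling_matrix

        def transition(Xb):
            return dyn._rk4_batch(np.atleast_2d(Xb), dt, params, W)

        measurement = make_measurement_map(1, observed=self.observed)

        seed_w, seed_nu = child_seeds(self.random_state, 2)
        cfg = UKFConfig(
            Q_omega=estimate_noise_covariance(s_omega, 3, self.n_noise_samples, seed_w),
            Q_nu=estimate_noise_covariance(s_nu, 1, self.n_noise_samples, seed_nu),
            alpha_sp=self.alpha_sp,
            beta_sp=self.beta_sp,
            kappa_sp=self.kappa_sp,
        )
        mean0 = np.zeros(3)
        mean0[_OBS_OFFSET[self.observed]] = X[0, 0]
        init = GaussianBelief(mean=mean0, cov=float(self.state_var0) * np.eye(3))
        result = run_filter(X, transition, measurement, init, cfg)

        self.n_features_in_ = 1
        self.dt_ = dt
        self.filter_result_ = result
        self.states_ = result.means
        self.sigmas_ = result.sigmas
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the filtered (n_steps, 3) state means."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "states_")
        return self.states_


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def estimate_coupling(
    measurements: Union[MeasurementSeries, np.ndarray],
    mode: str = "single_k",
    preset: str = "n1_2",
    adjacency: Optional[np.ndarray] = None,
    init_guess: Union[float, Sequence[float]] = 0.5,
    seed: Optional[int] = None,
    **kwargs,
) -> EstimateTrace:
    """Thin functional wrapper over CouplingEstimator.fit; returns the
    per-parameter estimate/band trace."""
    est = CouplingEstimator(
        mode=mode,
        preset=preset,
        adjacency=adjacency,
        coupling_init=init_guess,
        random_state=seed,
        **kwargs,
    )
    est.fit(measurements)
    return est.trace_


def recover_hidden_states(
    measurements: Union[MeasurementSeries, np.ndarray],
    observed: str = "y",
    preset: str = "n1_2",
    seed: Optional[int] = None,
    **kwargs,
) -> Trajectory:
    """Recover the full single-oscillator state from one observed variable.

    Returns a Trajectory whose states are the filtered (x, y, z) means.
    """
    times = None
    if isinstance(measurements, MeasurementSeries):
        times = measurements.times
    est = HiddenStateEstimator(
        observed=observed, preset=preset, random_state=seed, **kwargs
    )
    est.fit(measurements)
    n = est.states_.shape[0]
    if times is None:
        times = np.arange(n) * est.dt_
    return Trajectory(times=times, states=est.states_)
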