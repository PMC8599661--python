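"""Unscented Kalman Filter with scaled sigma points and additive noise.

The filter is model-agnostic: transition and measurement maps are supplied
as pure functions acting on *batches* of state vectors — ``f(X)`` with ``X``
of shape (m, d) must return (m, d), and ``h(X)`` must return (m, p).  The
batch convention lets the 2d+1 sigma points be propagated in one vectorised
call, which dominates the runtime for long series.

The additive-noise (non-augmented) form is used: both process and
measurement noise enter as fixed covariances added after the unscented
propagation, matching a discrete Markov model u_{k+1} = a(u_k) + omega_k
with measurements w_k = b(u_k) + nu_k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "GaussianBelief",
    "UKFConfig",
    "FilterResult",
    "sigma_points",
    "predict",
    "update",
    "run_filter",
    "FilterDivergenceError",
    "IndefiniteCovarianceError",
]

#: escalating diagonal jitter tried when a covariance Cholesky fails
_JITTERS = (0.0, 1e-12, 1e-10, 1e-8, 1e-6)


class FilterDivergenceError(RuntimeError):
    """A propagated state or estimate became non-finite."""

    def __init__(self, step: Optional[int] = None, what: str = "state"):
        self.step = step
        at = f" at step {step}" if step is not None else ""
        super().__init__(f"filter divergence: non-finite {what}{at}")


class IndefiniteCovarianceError(np.linalg.LinAlgError):
    """Covariance not positive definite even after maximal jitter."""


@dataclass
class GaussianBelief:
    """Gaussian state belief: mean vector and covariance matrix."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.mean.size
        if self.cov.shape != (d, d):
            raise ValueError(f"cov must be {d}x{d}, got {self.cov.shape}")

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def sigma(self) -> np.ndarray:
        """Per-component standard deviations (sqrt of the cov diagonal)."""
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


@dataclass
class UKFConfig:
    """Sigma-point spread hyperparameters plus the two noise covariances.

    Defaults alpha_sp=1, beta_sp=2, kappa_sp=0 give the full-spread unscented
    transform (beta_sp=2 optimal for Gaussian priors).  Small alpha_sp values
    shrink the sigma-point cloud towards the mean and degenerate into an
    EKF-style local linearization — a poor fit for dynamics with
    piecewise-linear kinks, where the full spread is markedly less biased.
    Q_omega / Q_nu are the process / measurement covariances added in the
    predict / update steps.
    """

    Q_omega: np.ndarray
    Q_nu: np.ndarray
    alpha_sp: float = 1.0
    beta_sp: float = 2.0
    kappa_sp: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.alpha_sp <= 1.0:
            raise ValueError("alpha_sp must be in (0, 1]")
        self.Q_omega = _check_symmetric(np.asarray(self.Q_omega, dtype=float), "Q_omega")
        self.Q_nu = _check_symmetric(np.asarray(self.Q_nu, dtype=float), "Q_nu")


def _check_symmetric(Q: np.ndarray, name: str) -> np.ndarray:
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError(f"{name} must be square, got shape {Q.shape}")
    if not np.allclose(Q, Q.T, atol=1e-9):
        raise ValueError(f"{name} must be symmetric")
    return Q


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def _safe_cholesky(P: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of a symmetrized P, with escalating jitter."""
    P = _symmetrize(P)
    for jit in _JITTERS:
        try:
            return np.linalg.cholesky(P if jit == 0.0 else P + jit * np.eye(P.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise IndefiniteCovarianceError(
        f"covariance not PSD after jitter up to {_JITTERS[-1]}"
    )


def sigma_points(
    belief: GaussianBelief, cfg: UKFConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled-unscented sigma points of a Gaussian belief.

    Returns (points, mean_weights, cov_weights): 2d+1 points of shape
    (2d+1, d), symmetric about the mean along the columns of the Cholesky
    factor; mean weights sum to 1.
    """
    d = belief.dim
    lam = cfg.alpha_sp**2 * (d + cfg.kappa_sp) - d
    c = d + lam
    L = _safe_cholesky(belief.cov)
    scaled = np.sqrt(c) * L.T  # row i = sqrt(c) * column i of L
    pts = np.empty((2 * d + 1, d))
    pts[0] = belief.mean
    pts[1 : d + 1] = belief.mean + scaled
    pts[d + 1 :] = belief.mean - scaled
    wm = np.full(2 * d + 1, 1.0 / (2.0 * c))
    wc = wm.copy()
    wm[0] = lam / c
    wc[0] = lam / c + (1.0 - cfg.alpha_sp**2 + cfg.beta_sp)
    return pts, wm, wc


def _unscented_moments(Y: np.ndarray, wm: np.ndarray, wc: np.ndarray):
    mean = wm @ Y
    dev = Y - mean
    cov = (wc[:, None] * dev).T @ dev
    return mean, _symmetrize(cov), dev


def predict(
    belief: GaussianBelief,
    transition: Callable[[np.ndarray], np.ndarray],
    cfg: UKFConfig,
) -> GaussianBelief:
    """Unscented time update: propagate sigma points, add Q_omega."""
    pts, wm, wc = sigma_points(belief, cfg)
    Y = np.asarray(transition(pts), dtype=float)
    if not np.isfinite(Y).all():
        raise FilterDivergenceError(what="propagated sigma point")
    mean, cov, _ = _unscented_moments(Y, wm, wc)
    return GaussianBelief(mean=mean, cov=_symmetrize(cov + cfg.Q_omega))


def update(
    predicted: GaussianBelief,
    observation: np.ndarray,
    measurement: Callable[[np.ndarray], np.ndarray],
    cfg: UKFConfig,
) -> GaussianBelief:
    """Unscented measurement update (correction) of a predicted belief.

    A singular innovation covariance is flagged with a warning and the
    update is skipped (the predicted belief is returned unchanged).
    """
    z = np.asarray(observation, dtype=float).ravel()
    pts, wm, wc = sigma_points(predicted, cfg)
    Z = np.atleast_2d(np.asarray(measurement(pts), dtype=float))
    if Z.shape[0] != pts.shape[0]:
        raise ValueError("measurement map must return one row per sigma point")
    if z.size != Z.shape[1]:
        raise ValueError(
            f"observation dim {z.size} does not match measurement dim {Z.shape[1]}"
        )
    z_mean, S, z_dev = _unscented_moments(Z, wm, wc)
    S = S + cfg.Q_nu
    x_dev = pts - predicted.mean
    C = (wc[:, None] * x_dev).T @ z_dev  # cross covariance (d x p)
    try:
        gain = np.linalg.solve(S, C.T).T
    except np.linalg.LinAlgError:
        warnings.warn("singular innovation covariance; update skipped", RuntimeWarning)
        return predicted
    mean = predicted.mean + gain @ (z - z_mean)
    cov = _symmetrize(predicted.cov - gain @ S @ gain.T)
    if not np.isfinite(mean).all():
        raise FilterDivergenceError(what="posterior mean")
    return GaussianBelief(mean=mean, cov=cov)


@dataclass
class FilterResult:
    """Belief sequence of a filter run.

    ``means`` and ``variances`` hold the per-step posterior mean and
    covariance diagonal (n_steps x d); full covariances are stored only on
    request (``covs``) since they are rarely needed and O(n d^2) in memory.
    """

    means: np.ndarray
    variances: np.ndarray
    final: GaussianBelief
    covs: Optional[np.ndarray] = None

    @property
    def n_steps(self) -> int:
        return self.means.shape[0]

    @property
    def sigmas(self) -> np.ndarray:
        return np.sqrt(np.clip(self.variances, 0.0, None))

    def beliefs(self) -> list[GaussianBelief]:
        if self.covs is None:
            raise ValueError("run_filter(..., store_covariances=True) required")
        return [GaussianBelief(m, P) for m, P in zip(self.means, self.covs)]


def run_filter(
    measurements: np.ndarray,
    transition: Callable[[np.ndarray], np.ndarray],
    measurement: Callable[[np.ndarray], np.ndarray],
    init: GaussianBelief,
    cfg: UKFConfig,
    store_covariances: bool = False,
) -> FilterResult:
    """Run the full predict-correct recursion over a measurement sequence.

    One posterior belief is emitted per measurement row; the run is
    deterministic given its inputs.  Errors raised in predict/update are
    re-raised annotated with the failing step index.
    """
    Z = np.atleast_2d(np.asarray(measurements, dtype=float))
    n = Z.shape[0]
    if n == 0:
        raise ValueError("measurements must be non-empty")
    d = init.dim
    means = np.empty((n, d))
    variances = np.empty((n, d))
    covs = np.empty((n, d, d)) if store_covariances else None
    belief = init
    for k in range(n):
        try:
            belief = predict(belief, transition, cfg)
            belief = update(belief, Z[k], measurement, cfg)
        except FilterDivergenceError as err:
            raise FilterDivergenceError(step=k, what=str(err)) from err
        means[k] = belief.mean
        variances[k] = np.diag(belief.cov)
        if store_covariances:
            covs[k] = belief.cov
    return FilterResult(means=means, variances=variances, final=belief, covs=covs)
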