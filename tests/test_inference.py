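"""Inference tests: extended state, noise covariances, coupling recovery."""

import numpy as np
import pytest
from sklearn.base import clone

import netukf as nk
from netukf.dynamics import child_seeds
from netukf.inference import (
    CouplingEstimator,
    ParameterSet,
    build_extended_covariance,
    estimate_noise_covariance,
    make_extended_transition,
    make_measurement_map,
    parameter_labels,
)

from .conftest import TWO_NODE_A, simulate_two_node

P12 = nk.get_preset("n1_2")


# ---------------------------------------------------------------------------
# noise covariance estimation
# ---------------------------------------------------------------------------


def test_noise_covariance_zero_sigma():
    assert np.array_equal(estimate_noise_covariance(0.0, 4, 100, seed=1), np.zeros((4, 4)))


def test_noise_covariance_sampling_moments():
    C = estimate_noise_covariance(0.02, 6, 100_000, seed=2)
    assert np.array_equal(C, C.T)
    assert np.allclose(np.diag(C), 4e-4, rtol=0.05)
    # off-diagonals within 3 standard errors of zero (se ~ sigma^2 / sqrt(n))
    off = C[~np.eye(6, dtype=bool)]
    assert np.abs(off).max() < 3 * 4e-4 / np.sqrt(100_000)


def test_noise_covariance_requires_samples():
    with pytest.raises(ValueError):
        estimate_noise_covariance(0.1, 2, 1, seed=3)


# ---------------------------------------------------------------------------
# extended covariance / transition
# ---------------------------------------------------------------------------


def test_extended_covariance_blocks():
    Q = estimate_noise_covariance(0.02, 6, 1000, seed=4)
    Qe = build_extended_covariance(Q, 1)
    assert Qe.shape == (7, 7)
    assert np.array_equal(Qe[:6, :6], Q)
    assert np.all(Qe[6, :] == 0.0) and np.all(Qe[:, 6] == 0.0)
    assert np.array_equal(build_extended_covariance(Q, 0), Q)


def test_extended_covariance_full_network_case():
    Qe = build_extended_covariance(np.eye(84), 378)
    assert Qe.shape == (462, 462)
    assert np.all(Qe[84:, :] == 0.0) and np.all(Qe[:, 84:] == 0.0)


@pytest.mark.parametrize("mode,q", [("single_k", 1), ("directional_pair", 2), ("all_pairs", 1)])
def test_extended_transition_parameters_constant(mode, q):
    N = 2
    f = make_extended_transition(P12.params, P12.grid(2).dt, N, mode, adjacency=TWO_NODE_A)
    rng = np.random.default_rng(5)
    X = rng.normal(size=(7, 3 * N + q))
    out = f(X)
    assert np.array_equal(out[:, 3 * N :], X[:, 3 * N :])
    assert out.shape == X.shape


def test_extended_transition_consistent_with_simulator():
    """With the parameter frozen at the true K the dynamical block advances
    exactly like the simulator's RK4 step."""
    K = 0.37
    net = nk.NetworkModel(N=2, A=TWO_NODE_A, K=K)
    f = make_extended_transition(P12.params, P12.grid(2).dt, 2, "single_k", adjacency=TWO_NODE_A)
    rng = np.random.default_rng(6)
    state = rng.normal(size=6)
    ext = f(np.concatenate([state, [K]])[None, :])[0]
    ref = nk.rk4_step(state, P12.grid(2).dt, P12.params, net)
    assert np.allclose(ext[:6], ref, rtol=1e-12, atol=1e-12)


def test_all_pairs_zero_couplings_decouple_nodes():
    N = 3
    f = make_extended_transition(P12.params, P12.grid(2).dt, N, "all_pairs")
    rng = np.random.default_rng(7)
    state = rng.normal(size=3 * N)
    ext = f(np.concatenate([state, np.zeros(3)])[None, :])[0]
    single = nk.NetworkModel(N=1, A=np.zeros((1, 1)), K=0.0)
    for i in range(N):
        ref = nk.rk4_step(state[3 * i : 3 * i + 3], P12.grid(2).dt, P12.params, single)
        assert np.allclose(ext[3 * i : 3 * i + 3], ref, rtol=1e-12, atol=1e-12)


def test_parameter_labels_and_counts():
    assert parameter_labels("single_k", 5) == ("K",)
    assert parameter_labels("directional_pair", 2) == ("K12", "K21")
    labels = parameter_labels("all_pairs", 28)
    assert len(labels) == 378
    assert labels[0] == "K1_2" and labels[-1] == "K27_28"
    with pytest.raises(ValueError):
        parameter_labels("bogus", 2)


def test_parameter_set_validation():
    with pytest.raises(ValueError, match="unique"):
        ParameterSet(names=("K", "K"), values=[0.1, 0.2], init_guess=[0.5, 0.5])


def test_measurement_map_selects_variable():
    X = np.arange(14.0)[None, :]  # extended state, N=2, q=2
    assert np.array_equal(make_measurement_map(2, "y")(X), [[1.0, 4.0]])
    assert np.array_equal(make_measurement_map(2, "x")(X), [[0.0, 3.0]])
    assert np.array_equal(make_measurement_map(2, "z")(X), [[2.0, 5.0]])


# ---------------------------------------------------------------------------
# coupling estimation
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def k01_measurements():
    _, meas, filt_seed = simulate_two_node(0.1, 20_000, master_seed=11)
    return meas, filt_seed


def test_weak_coupling_recovered(k01_measurements):
    """K=0.1 is recovered within +-0.05 after a short run, starting from 0.5."""
    meas, filt_seed = k01_measurements
    trace = nk.estimate_coupling(
        meas, mode="single_k", preset="n1_2", init_guess=0.5, seed=filt_seed
    )
    assert trace.names == ("K",)
    assert abs(trace.final[0] - 0.1) <= 0.05
    assert np.all(trace.sigmas >= 0.0)
    # uncertainty shrinks monotonically in the large: end << start
    assert trace.sigmas[-1, 0] < 0.2 * trace.sigmas[0, 0]


def test_directional_pair_symmetric_truth():
    """On a symmetric truth the two directional estimates must agree within
    their uncertainty bands."""
    _, meas, filt_seed = simulate_two_node(0.4, 40_000, master_seed=77)
    trace = nk.estimate_coupling(
        meas, mode="directional_pair", preset="n1_2", init_guess=0.5, seed=filt_seed
    )
    (k12, k21), (s12, s21) = trace.final, trace.sigmas[-1]
    # intervals K12 +- sigma and K21 +- sigma overlap
    assert abs(k12 - k21) <= s12 + s21
    for k, s in [(k12, s12), (k21, s21)]:
        assert abs(k - 0.4) <= 3 * s


def test_extended_covariance_structure_preserved(k01_measurements):
    meas, filt_seed = k01_measurements
    est = CouplingEstimator(mode="single_k", preset="n1_2", random_state=filt_seed)
    est.fit(meas.values[:200])
    q_block = est.Q_omega_ext_[6:, :]
    assert np.all(q_block == 0.0) and np.all(est.Q_omega_ext_[:, 6:] == 0.0)
    assert est.names_ == ("K",)


def test_band_coverage_at_weak_coupling():
    """True K lies inside the final mean +- 2 sigma band in >= 90% of 20
    seeded replicates."""
    hits = 0
    for r in range(20):
        _, meas, filt_seed = simulate_two_node(0.1, 15_000, master_seed=5000 + r)
        trace = nk.estimate_coupling(
            meas, mode="single_k", preset="n1_2", init_guess=0.5, seed=filt_seed
        )
        if abs(trace.final[0] - 0.1) <= 2.0 * trace.sigmas[-1, 0]:
            hits += 1
    assert hits >= 18


def test_robustness_to_misspecified_noise(k01_measurements):
    """Under-specified process noise and over-specified measurement noise in
    the filter still recover K; wildly misspecified settings at least stay
    finite (the estimate quality degrades, see the methods note)."""
    meas, filt_seed = k01_measurements
    for s_omega, s_nu in [(0.001, 0.5), (0.004, 0.5), (0.02, 1.0)]:
        trace = nk.estimate_coupling(
            meas, mode="single_k", preset="n1_2",
            sigma_omega=s_omega, sigma_nu=s_nu, seed=filt_seed,
        )
        assert abs(trace.median(0.1)[0] - 0.1) <= 0.1
    for s_omega, s_nu in [(5.0, 0.5), (0.02, 0.001)]:
        trace = nk.estimate_coupling(
            meas, mode="single_k", preset="n1_2",
            sigma_omega=s_omega, sigma_nu=s_nu, seed=filt_seed,
        )
        assert np.isfinite(trace.values).all()


def test_estimator_sklearn_api(k01_measurements):
    meas, _ = k01_measurements
    est = CouplingEstimator(mode="single_k", preset="n1_2", random_state=0)
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    est.set_params(coupling_init=0.3)
    assert est.coupling_init == 0.3
    est.fit(meas.values[:300])
    assert est.predict().shape == (1,)
    assert est.n_features_in_ == 2


def test_estimator_input_validation():
    est = CouplingEstimator(mode="directional_pair")
    with pytest.raises(ValueError, match="2 columns"):
        est.fit(np.zeros((100, 3)))
    est = CouplingEstimator(mode="single_k")
    with pytest.raises(ValueError, match="adjacency"):
        est.fit(np.random.default_rng(0).normal(size=(50, 3)))
    with pytest.raises(ValueError, match="finite"):
        CouplingEstimator().fit(np.full((50, 2), np.nan))


# ---------------------------------------------------------------------------
# hidden-state recovery
# ---------------------------------------------------------------------------


def test_hidden_states_recovered_from_y(hidden_state_run):
    """Observing only noisy y recovers x and z (correlation >= 0.95) and
    denoises y below both the noise floor and the raw-measurement error."""
    traj, est = hidden_state_run["traj"], hidden_state_run["est_y"]
    burn = traj.n_steps // 10
    for var in ("x", "z"):
        c = np.corrcoef(
            getattr(est, var)[burn:, 0], getattr(traj, var)[burn:, 0]
        )[0, 1]
        assert c >= 0.95, f"{var} correlation {c:.3f}"
    rmse_est = np.sqrt(((est.y[burn:, 0] - traj.y[burn:, 0]) ** 2).mean())
    rmse_raw = np.sqrt(
        ((hidden_state_run["meas_y"].values[burn:, 0] - traj.y[burn:, 0]) ** 2).mean()
    )
    assert rmse_est < P12.sigma_nu
    assert rmse_est < rmse_raw


def test_hidden_states_recovered_from_x(hidden_state_run):
    traj, est = hidden_state_run["traj"], hidden_state_run["est_x"]
    burn = traj.n_steps // 10
    for var in ("y", "z"):
        c = np.corrcoef(
            getattr(est, var)[burn:, 0], getattr(traj, var)[burn:, 0]
        )[0, 1]
        assert c >= 0.95, f"{var} correlation {c:.3f}"
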