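"""Shared fixtures: expensive filter runs are session-scoped so the
validation-study tests and the invariant tests reuse one computation."""

from __future__ import annotations

import numpy as np
import pytest

import netukf as nk
from netukf.dynamics import child_seeds


def linear_kalman_filter(zs, F, H, Q, R, m0, P0):
    """Textbook linear Kalman filter recursion (independent oracle).

    Returns per-step posterior means and covariances.
    """
    m, P = np.asarray(m0, dtype=float), np.asarray(P0, dtype=float)
    means, covs = [], []
    for z in np.atleast_2d(zs):
        m = F @ m
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        m = m + K @ (z - H @ m)
        P = P - K @ S @ K.T
        means.append(m.copy())
        covs.append(P.copy())
    return np.array(means), np.array(covs)


TWO_NODE_A = np.array([[0.0, 1.0], [1.0, 0.0]])


def simulate_two_node(K, n_steps, master_seed, preset="n1_2"):
    """Simulate a coupled pair and measure y1, y2 at the preset noise."""
    p = nk.get_preset(preset)
    net = nk.NetworkModel(N=2, A=TWO_NODE_A, K=K)
    s = child_seeds(master_seed, 3)
    traj = nk.simulate(net, p.params, p.grid(n_steps), p.noise(), seed=s[0])
    meas = nk.measure(traj, p.noise(), seed=s[1])
    return traj, meas, s[2]


@pytest.fixture(scope="session")
def k07_estimate():
    """Full-length two-node run at K=0.7: simulate 100k steps, estimate K."""
    traj, meas, filt_seed = simulate_two_node(0.7, 100_000, master_seed=2024)
    trace = nk.estimate_coupling(
        meas, mode="single_k", preset="n1_2", init_guess=0.5, seed=filt_seed
    )
    return {"trace": trace, "truth": 0.7}


@pytest.fixture(scope="session")
def k_grid_sweep():
    """Coupling sweep K in {0, 0.2, ..., 1.0}, 50k steps per point."""
    out = {}
    for i, K in enumerate([0.0, 0.2, 0.4, 0.6, 0.8, 1.0]):
        traj, meas, filt_seed = simulate_two_node(K, 50_000, master_seed=1000 + i)
        out[K] = nk.estimate_coupling(
            meas, mode="single_k", preset="n1_2", init_guess=0.5, seed=filt_seed
        )
    return out


@pytest.fixture(scope="session")
def n8_reconstruction():
    """Scaled-down topology recovery: N=8 random net, K=1, low-noise preset."""
    p = nk.get_preset("n28")
    s = child_seeds(42, 4)
    net = nk.random_network(8, n_edges=10, seed=s[0], K=1.0)
    traj = nk.simulate(net, p.params, p.grid(15_000), p.noise(), seed=s[1])
    meas = nk.measure(traj, p.noise(), seed=s[2])
    result = nk.reconstruct_network(
        meas, truth=net.coupling_matrix, preset="n28", seed=s[3]
    )
    return {"net": net, "result": result}


@pytest.fixture(scope="session")
def hidden_state_run():
    """Single-oscillator hidden-state recovery from noisy y (and from x)."""
    p = nk.get_preset("n1_2")
    net = nk.NetworkModel(N=1, A=np.zeros((1, 1)), K=0.0)
    s = child_seeds(7, 4)
    traj = nk.simulate(net, p.params, p.grid(40_000), p.noise(), seed=s[0])
    meas_y = nk.measure(traj, p.noise(), seed=s[1])
    est_y = nk.recover_hidden_states(meas_y, observed="y", preset="n1_2", seed=s[2])
    x_noisy = traj.x + np.random.default_rng(s[3]).normal(0.0, 0.5, traj.x.shape)
    meas_x = nk.MeasurementSeries(traj.times, x_noisy)
    est_x = nk.recover_hidden_states(meas_x, observed="x", preset="n1_2", seed=s[2])
    return {"traj": traj, "meas_y": meas_y, "est_y": est_y, "est_x": est_x}
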