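"""File formats: delimited time-series tables, adjacency files, configs.

Conventions (user-facing):
- trajectory / measurement files are CSV with a leading ``time`` column in
  seconds and headers ``x1,y1,z1,...`` / ``y1,...,yN``;
- adjacency files are either a whitespace-delimited dense matrix or a
  two-column edge list with **1-based** node indices;
- run configs are YAML with nested ``params`` / ``noise`` / ``grid`` /
  ``network`` sections mirroring the model's parameter names.

An ``.npz`` container is offered for large runs where CSV is wasteful.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .dynamics import (
    PRESETS,
    MeasurementSeries,
    NetworkModel,
    NoiseSpec,
    OscillatorParams,
    SamplingGrid,
    Trajectory,
    get_preset,
    random_network,
)

__all__ = [
    "ConfigError",
    "write_trajectory",
    "read_trajectory",
    "write_measurements",
    "read_measurements",
    "write_adjacency",
    "read_adjacency",
    "save_trajectory_npz",
    "load_trajectory_npz",
    "load_config",
    "dump_config",
    "resolve_config",
    "build_network",
]

_PARAM_FIELDS = tuple(OscillatorParams.__dataclass_fields__)


class ConfigError(ValueError):
    """A run configuration is missing or malforms a required field."""


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------


def _state_columns(N: int) -> list[str]:
    cols = []
    for i in range(1, N + 1):
        cols += [f"x{i}", f"y{i}", f"z{i}"]
    return cols


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    df = pd.DataFrame(traj.states, columns=_state_columns(traj.N))
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    return Trajectory(times=df["time"].to_numpy(), states=df.drop(columns="time").to_numpy())


def write_measurements(meas: MeasurementSeries, path: Union[str, Path]) -> None:
    df = pd.DataFrame(meas.values, columns=[f"y{i}" for i in range(1, meas.N + 1)])
    df.insert(0, "time", meas.times)
    df.to_csv(path, index=False)


def read_measurements(path: Union[str, Path]) -> MeasurementSeries:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    return MeasurementSeries(
        times=df["time"].to_numpy(), values=df.drop(columns="time").to_numpy()
    )


def save_trajectory_npz(traj: Trajectory, path: Union[str, Path]) -> None:
    np.savez_compressed(path, times=traj.times, states=traj.states)


def load_trajectory_npz(path: Union[str, Path]) -> Trajectory:
    with np.load(path) as f:
        return Trajectory(times=f["times"], states=f["states"])


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------


def write_adjacency(A: np.ndarray, path: Union[str, Path], fmt: str = "dense") -> None:
    """Write an adjacency matrix, dense or as a 1-based i<j edge list."""
    A = np.asarray(A)
    if fmt == "dense":
        np.savetxt(path, A, fmt="%d")
    elif fmt == "edges":
        iu, ju = np.nonzero(np.triu(A, k=1))
        np.savetxt(path, np.column_stack([iu + 1, ju + 1]), fmt="%d")
    else:
        raise ValueError("fmt must be 'dense' or 'edges'")


def read_adjacency(
    path: Union[str, Path], fmt: str = "dense", N: Optional[int] = None
) -> np.ndarray:
    """Read a dense matrix or a 1-based edge list (fmt='edges', N required)."""
    raw = np.loadtxt(path, ndmin=2)
    if fmt == "dense":
        if raw.shape[0] != raw.shape[1]:
            raise ValueError(f"{path}: dense adjacency must be square, got {raw.shape}")
        return raw
    if fmt == "edges":
        if N is None:
            raise ValueError("reading an edge list requires N")
        A = np.zeros((N, N))
        if raw.size:
            idx = raw.astype(int)
            if idx.min() < 1 or idx.max() > N:
                raise ValueError(f"{path}: edge-list node indices must be in 1..{N}")
            A[idx[:, 0] - 1, idx[:, 1] - 1] = 1.0
            A[idx[:, 1] - 1, idx[:, 0] - 1] = 1.0
        return A
    raise ValueError("fmt must be 'dense' or 'edges'")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def resolve_config(raw: dict) -> dict:
    """Resolve a raw config mapping into a fully concrete one.

    Preset fields fill everything left unset; without a preset every model
    field must be given explicitly.  Raises ConfigError naming the first
    missing field.
    """
    raw = dict(raw or {})
    preset_name = raw.get("preset")
    preset = get_preset(preset_name) if preset_name else None

    params_over = dict(raw.get("params") or {})
    unknown = set(params_over) - set(_PARAM_FIELDS)
    if unknown:
        raise ConfigError(f"unknown oscillator parameters: {sorted(unknown)}")
    if preset is not None:
        params = {f: getattr(preset.params, f) for f in _PARAM_FIELDS}
        params.update(params_over)
    else:
        missing = [f for f in _PARAM_FIELDS if f not in params_over]
        if missing:
            raise ConfigError(f"missing oscillator parameters (no preset): {missing}")
        params = {f: float(params_over[f]) for f in _PARAM_FIELDS}

    grid = dict(raw.get("grid") or {})
    noise = dict(raw.get("noise") or {})

    def _field(section: dict, key: str, preset_attr: str):
        if key in section and section[key] is not None:
            return float(section[key])
        if preset is not None:
            return float(getattr(preset, preset_attr))
        raise ConfigError(f"missing required field '{key}' and no preset given")

    resolved = {
        "preset": preset_name,
        "params": {k: float(v) for k, v in params.items()},
        "grid": {
            "f_s": _field(grid, "f_s", "f_s"),
            "n_steps": int(_field(grid, "n_steps", "n_steps")),
        },
        "noise": {
            "sigma_omega": _field(noise, "sigma_omega", "sigma_omega"),
            "sigma_nu": _field(noise, "sigma_nu", "sigma_nu"),
        },
        "network": dict(raw.get("network") or {}),
        "mode": raw.get("mode", "single_k"),
        "coupling_init": float(raw.get("coupling_init", 0.5)),
        "threshold": float(raw.get("threshold", 0.5)),
        "burn_fraction": float(raw.get("burn_fraction", 0.1)),
        "seed": raw.get("seed"),
    }
    return resolved


def build_network(cfg: dict, seed: Optional[int] = None) -> NetworkModel:
    """Construct the NetworkModel described by a resolved config.

    The ``network`` section must give ``N`` and ``K`` plus one of:
    ``edges`` (1-based pairs), ``adjacency`` (inline matrix or file path),
    or ``random`` ({n_edges | edge_density}).
    """
    net = cfg.get("network") or {}
    if "N" not in net:
        raise ConfigError("network section must give N")
    N = int(net["N"])
    K = float(net.get("K", 0.0))
    if "edges" in net:
        A = np.zeros((N, N))
        for i, j in net["edges"]:
            if not (1 <= i <= N and 1 <= j <= N):
                raise ConfigError(f"edge ({i}, {j}) out of range for N={N} (1-based)")
            A[i - 1, j - 1] = A[j - 1, i - 1] = 1.0
        return NetworkModel(N=N, A=A, K=K)
    if "adjacency" in net:
        adj = net["adjacency"]
        A = read_adjacency(adj) if isinstance(adj, str) else np.asarray(adj, dtype=float)
        return NetworkModel(N=N, A=A, K=K)
    if "random" in net:
        r = dict(net["random"] or {})
        return random_network(
            N,
            n_edges=r.get("n_edges"),
            edge_density=r.get("edge_density"),
            seed=seed,
            K=K,
        )
    if N == 1:
        return NetworkModel(N=1, A=np.zeros((1, 1)), K=K)
    raise ConfigError("network section must give edges, adjacency or random")
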