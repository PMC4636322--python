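"""File I/O helpers: sampler trajectories, spike events, network snapshots.

Formats are deliberately plain: HDF5 for large numeric arrays, two-column
CSV for spike events (neuron_id, time_s), JSON-in-attribute for configs.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "save_trajectory_hdf5",
    "load_trajectory_hdf5",
    "save_trajectory_csv",
    "spikes_to_frame",
    "save_spikes_csv",
    "load_spikes_csv",
    "save_network_snapshot",
    "load_network_snapshot",
    "read_idx",
]


def save_trajectory_hdf5(path, theta: np.ndarray, time: np.ndarray, seed: int,
                         config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("theta", data=np.asarray(theta, dtype=float))
        f.create_dataset("time", data=np.asarray(time, dtype=float))
        f.create_dataset("seed", data=int(seed))
        f.attrs["config"] = json.dumps(config or {})


def load_trajectory_hdf5(path):
    with h5py.File(path, "r") as f:
        theta = f["theta"][...]
        time = f["time"][...]
        seed = int(f["seed"][()])
        config = json.loads(f.attrs["config"])
    return theta, time, seed, config


def save_trajectory_csv(path, theta: np.ndarray, time: np.ndarray) -> None:
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    df = pd.DataFrame(theta, columns=[f"theta_{i}" for i in range(theta.shape[1])])
    df.insert(0, "time", np.asarray(time, dtype=float))
    df.to_csv(path, index=False)


def spikes_to_frame(spikes) -> pd.DataFrame:
    """Normalize a list of (neuron_id, time_s) events to a sorted DataFrame."""
    if len(spikes) == 0:
        return pd.DataFrame({"neuron_id": pd.Series(dtype=int),
                             "time_s": pd.Series(dtype=float)})
    arr = np.asarray(spikes)
    df = pd.DataFrame({"neuron_id": arr[:, 0].astype(int),
                       "time_s": arr[:, 1].astype(float)})
    return df.sort_values(["time_s", "neuron_id"], kind="stable").reset_index(drop=True)


def save_spikes_csv(path, spikes) -> None:
    spikes_to_frame(spikes).to_csv(path, index=False)


def load_spikes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"neuron_id": int, "time_s": float})


def save_network_snapshot(path, theta_matrices: dict, masks: dict | None = None,
                          config: dict | None = None) -> None:
    """Store named theta matrices and boolean masks with a JSON config attribute."""
    with h5py.File(path, "w") as f:
        g = f.create_group("theta")
        for name, mat in theta_matrices.items():
            g.create_dataset(name, data=np.asarray(mat, dtype=float))
        if masks:
            m = f.create_group("masks")
            for name, mat in masks.items():
                m.create_dataset(name, data=np.asarray(mat, dtype=bool))
        f.attrs["config"] = json.dumps(config or {})


def load_network_snapshot(path):
    with h5py.File(path, "r") as f:
        theta = {k: v[...] for k, v in f["theta"].items()}
        masks = {k: v[...] for k, v in f["masks"].items()} if "masks" in f else {}
        config = json.loads(f.attrs["config"])
    return theta, masks, config


def read_idx(path) -> np.ndarray:
    """Read an IDX-format array file (the MNIST container format).

    Returns the raw array; image files come back as (n, rows, cols) uint8.
    Provided as a drop-in so real handwritten-digit data can replace the
    synthetic pattern generator; no data ships with the package.
    """
    path = Path(path)
    with open(path, "rb") as f:
        header = f.read(4)
        if header[0] != 0 or header[1] != 0:
            raise ValueError(f"{path} is not an IDX file")
        dtype = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
                 0x0D: ">f4", 0x0E: ">f8"}[header[2]]
        ndim = header[3]
        shape = tuple(int.from_bytes(f.read(4), "big") for _ in range(ndim))
        data = np.frombuffer(f.read(), dtype=dtype)
    return data.reshape(shape)
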