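"""Sliding-window regression dataset construction and participant splits.

The regression problem pairs a strictly causal window of the four load-cell
channels — the N samples at indices [t-N, t-1] — with the concurrent BP
sample BP(t). Successive 1-sample shifts cover every target index from N to
L-1, so the whole waveform is reconstructable except for the initial N
samples. With N = 50 at 100 Hz, each window spans 500 ms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import numpy as np

from .synthetic import Recording

__all__ = ["WindowDataset", "build_windows", "concat_datasets",
           "partition_participants", "save_dataset_hdf5", "load_dataset_hdf5",
           "DEFAULT_WINDOW_SAMPLES"]

DEFAULT_WINDOW_SAMPLES = 50


@dataclass
class WindowDataset:
    """Ordered {window, target} pairs from one or more recordings.

    ``inputs`` has shape (M, N, 4): M windows of N time steps x 4 load-cell
    features, channel order LC0..LC3. ``targets`` are the concurrent BP
    samples in mmHg (or normalized units after scaling).
    """

    inputs: np.ndarray
    targets: np.ndarray
    target_indices: np.ndarray
    participant_id: str
    N: int

    def __post_init__(self) -> None:
        if self.inputs.ndim != 3 or self.inputs.shape[1:] != (self.N, 4):
            raise ValueError("inputs must have shape (M, N, 4)")
        if len(self.targets) != len(self.inputs):
            raise ValueError("inputs/targets length mismatch")

    def __len__(self) -> int:
        return len(self.targets)


def build_windows(rec: Recording, N: int = DEFAULT_WINDOW_SAMPLES,
                  dtype=np.float32) -> WindowDataset:
    """Build the sliding-matrix dataset for one 100 Hz recording.

    For each target index t in [N, L-1] the input is the 4-channel slice at
    indices [t-N, t-1] and the target is BP(t); L - N pairs in total,
    ordering preserved.
    """
    if rec.fs != 100:
        raise ValueError("windowing expects a 100 Hz recording")
    L = rec.n_samples
    if L <= N:
        raise ValueError(f"recording too short: L={L} <= N={N}")
    # (4, L-N+1, N) strided view; window ending at t-1 starts at t-N
    sw = np.lib.stride_tricks.sliding_window_view(rec.load_cells, N, axis=1)
    inputs = np.ascontiguousarray(
        sw[:, :L - N, :].transpose(1, 2, 0), dtype=dtype)  # (M, N, 4)
    targets = rec.bp[N:].astype(dtype)
    return WindowDataset(inputs=inputs, targets=targets,
                         target_indices=np.arange(N, L),
                         participant_id=rec.participant_id, N=N)


def concat_datasets(datasets: list[WindowDataset]) -> WindowDataset:
    """Concatenate per-recording datasets; windows never span recordings."""
    if not datasets:
        raise ValueError("no datasets to concatenate")
    N = datasets[0].N
    if any(d.N != N for d in datasets):
        raise ValueError("datasets have differing window lengths")
    return WindowDataset(
        inputs=np.concatenate([d.inputs for d in datasets]),
        targets=np.concatenate([d.targets for d in datasets]),
        target_indices=np.concatenate([d.target_indices for d in datasets]),
        participant_id=",".join(d.participant_id for d in datasets),
        N=N)


def partition_participants(ids: list[str],
                           fractions: tuple[float, float, float],
                           seed: int) -> tuple[list[str], list[str], list[str]]:
    """Split participant ids into disjoint train/validation/test sets.

    The ids are randomly permuted (seeded) and split by rounded fractions,
    so all of a participant's samples land in exactly one phase.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(ids) < 3:
        raise ValueError("need at least 3 participants to split")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    train = perm[:n_train]
    val = perm[n_train:n_train + n_val]
    test = perm[n_train + n_val:]
    if not (train and val and test):
        raise ValueError(f"empty split: sizes ({len(train)}, {len(val)}, "
                         f"{len(test)}) from n={n}")
    return train, val, test


def save_dataset_hdf5(ds: WindowDataset, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=ds.inputs)
        f.create_dataset("targets", data=ds.targets)
        f.create_dataset("target_indices", data=ds.target_indices)
        f.attrs["participant_id"] = ds.participant_id
        f.attrs["N"] = ds.N


def load_dataset_hdf5(path: str | os.PathLike) -> WindowDataset:
    with h5py.File(path, "r") as f:
        return WindowDataset(
            inputs=f["inputs"][()], targets=f["targets"][()],
            target_indices=f["target_indices"][()],
            participant_id=str(f.attrs["participant_id"]),
            N=int(f.attrs["N"]))
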