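"""Reading and writing recordings as CSV and HDF5.

CSV layout: one file per recording with header ``t,lc0,lc1,lc2,lc3,bp``
(t in seconds, 6-decimal fixed point). HDF5 layout: groups
``/participants/<id>`` holding ``load_cells`` (4 x L) and ``bp`` (L), with
the sampling rate stored as a group attribute ``fs``.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import Recording

__all__ = [
    "write_recording_csv", "read_recording_csv",
    "write_cohort_hdf5", "read_cohort_hdf5",
    "write_cohort_csv", "read_cohort_csv",
]


def write_recording_csv(rec: Recording, path: str | os.PathLike) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({
        "t": t,
        "lc0": rec.load_cells[0], "lc1": rec.load_cells[1],
        "lc2": rec.load_cells[2], "lc3": rec.load_cells[3],
        "bp": rec.bp,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path: str | os.PathLike,
                       participant_id: str | None = None) -> Recording:
    df = pd.read_csv(path)
    required = {"t", "lc0", "lc1", "lc2", "lc3", "bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CSV missing columns: {sorted(missing)}")
    dt = np.diff(df["t"].to_numpy())
    if len(dt) == 0:
        raise ValueError("recording CSV has fewer than 2 samples")
    fs = 1.0 / np.median(dt)
    fs = float(round(fs))
    if participant_id is None:
        participant_id = Path(path).stem
    lcs = np.vstack([df[f"lc{j}"].to_numpy() for j in range(4)])
    return Recording(participant_id=participant_id, fs=fs,
                     load_cells=lcs, bp=df["bp"].to_numpy())


def write_cohort_csv(recordings: list[Recording],
                     out_dir: str | os.PathLike) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        p = out / f"{rec.participant_id}.csv"
        write_recording_csv(rec, p)
        paths.append(p)
    return paths


def read_cohort_csv(in_dir: str | os.PathLike) -> list[Recording]:
    paths = sorted(Path(in_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no recording CSVs in {in_dir}")
    return [read_recording_csv(p) for p in paths]


def write_cohort_hdf5(recordings: list[Recording],
                      path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("participants")
        for rec in recordings:
            g = root.create_group(rec.participant_id)
            g.create_dataset("load_cells", data=rec.load_cells)
            g.create_dataset("bp", data=rec.bp)
            g.attrs["fs"] = rec.fs


def read_cohort_hdf5(path: str | os.PathLike) -> list[Recording]:
    out = []
    with h5py.File(path, "r") as f:
        for pid in sorted(f["participants"]):
            g = f["participants"][pid]
            out.append(Recording(
                participant_id=pid, fs=float(g.attrs["fs"]),
                load_cells=g["load_cells"][()], bp=g["bp"][()]))
    return out
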