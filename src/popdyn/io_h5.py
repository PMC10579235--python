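"""HDF5 serialization for rate tensors and PC spaces.

One file holds one object; axes and labels are stored alongside the data so
a container round-trips losslessly (NaN patterns included).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .geometry import PCSpace
from .rates import RateTensor

__all__ = ["save_rate_tensor", "load_rate_tensor", "save_pcspace", "load_pcspace"]


def save_rate_tensor(tensor: RateTensor, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values, compression="gzip", track_times=False)
        f.create_dataset("time_axis", data=tensor.time_axis, track_times=False)
        f.attrs["event"] = tensor.event
        f.attrs["choices"] = list(tensor.choices)
        f.create_dataset("condition_labels", data=np.array([str(c) for c in tensor.condition_labels], dtype="S"), track_times=False)
        f.create_dataset("unit_ids", data=np.array(tensor.unit_ids, dtype="S"),
                         track_times=False)
        if tensor.trial_counts is not None:
            f.create_dataset("trial_counts", data=tensor.trial_counts, track_times=False)
        if tensor.window_end_ms is not None:
            f.create_dataset("window_end_ms", data=tensor.window_end_ms, track_times=False)
    return path


def load_rate_tensor(path: str | Path) -> RateTensor:
    with h5py.File(path, "r") as f:
        return RateTensor(
            values=f["values"][()],
            time_axis=f["time_axis"][()],
            condition_labels=[c.decode() for c in f["condition_labels"][()]],
            choices=tuple(f.attrs["choices"]),
            unit_ids=[u.decode() for u in f["unit_ids"][()]],
            trial_counts=f["trial_counts"][()] if "trial_counts" in f else None,
            window_end_ms=f["window_end_ms"][()] if "window_end_ms" in f else None,
            event=str(f.attrs["event"]),
        )


def save_pcspace(pcs: PCSpace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for name in ("loadings", "eigenvalues", "column_means", "normalizers"):
            f.create_dataset(name, data=getattr(pcs, name), track_times=False)
        if pcs.n_signal_dims is not None:
            f.attrs["n_signal_dims"] = int(pcs.n_signal_dims)
    return path


def load_pcspace(path: str | Path) -> PCSpace:
    with h5py.File(path, "r") as f:
        return PCSpace(
            loadings=f["loadings"][()],
            eigenvalues=f["eigenvalues"][()],
            column_means=f["column_means"][()],
            normalizers=f["normalizers"][()],
            n_signal_dims=(
                int(f.attrs["n_signal_dims"]) if "n_signal_dims" in f.attrs else None
            ),
        )
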