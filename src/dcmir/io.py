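"""HDF5 / CSV / JSON serialization for the pipeline's domain objects."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from dcmir.car import CurrentDensityMap
from dcmir.tfr import ModeBasis, Spectrogram, TrialSet


def _write_labels(group: h5py.Group, labels: dict) -> None:
    for key, value in labels.items():
        group.attrs[f"label_{key}"] = "" if value is None else value


def _read_labels(group: h5py.Group) -> dict:
    out = {}
    for key, value in group.attrs.items():
        if key.startswith("label_"):
            if isinstance(value, (np.integer, int)):
                value = int(value)
            elif isinstance(value, bytes):
                value = value.decode()
            out[key[len("label_"):]] = value
    return out


def save_trialset(path: str | Path, trials: TrialSet, name: str = "trials") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("data", data=trials.data, compression="gzip")
        g.create_dataset("t_grid", data=trials.t_grid)
        g.attrs["fs"] = trials.fs
        g.attrs["onset_index"] = trials.onset_index
        _write_labels(g, trials.labels)


def load_trialset(path: str | Path, name: str = "trials") -> TrialSet:
    with h5py.File(path, "r") as f:
        g = f[name]
        return TrialSet(
            data=g["data"][()],
            fs=float(g.attrs["fs"]),
            t_grid=g["t_grid"][()],
            labels=_read_labels(g),
        )


def save_spectrogram(path: str | Path, spec: Spectrogram, name: str) -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("power", data=spec.power, compression="gzip")
        g.create_dataset("freq_grid", data=spec.freq_grid)
        g.create_dataset("t_grid", data=spec.t_grid)
        g.attrs["baseline_corrected"] = spec.baseline_corrected
        g.attrs["n_trials_used"] = spec.n_trials_used
        _write_labels(g, spec.labels)


def load_spectrogram(path: str | Path, name: str) -> Spectrogram:
    with h5py.File(path, "r") as f:
        g = f[name]
        return Spectrogram(
            power=g["power"][()],
            freq_grid=g["freq_grid"][()],
            t_grid=g["t_grid"][()],
            baseline_corrected=bool(g.attrs["baseline_corrected"]),
            n_trials_used=int(g.attrs["n_trials_used"]),
            labels=_read_labels(g),
        )


def list_groups(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(f.keys())


def save_basis(path: str | Path, basis: ModeBasis, name: str = "basis") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("V", data=basis.V)
        g.create_dataset("singular_values", data=basis.singular_values)
        g.create_dataset("freq_grid", data=basis.freq_grid)
        g.attrs["variance_preserved"] = basis.variance_preserved


def load_basis(path: str | Path, name: str = "basis") -> ModeBasis:
    with h5py.File(path, "r") as f:
        g = f[name]
        return ModeBasis(
            V=g["V"][()],
            variance_preserved=float(g.attrs["variance_preserved"]),
            singular_values=g["singular_values"][()],
            freq_grid=g["freq_grid"][()],
        )


def save_current_density_csv(path: str | Path, cd_map: CurrentDensityMap) -> None:
    n = cd_map.node_strength.size
    xyz = cd_map.node_xyz if cd_map.node_xyz is not None else np.zeros((n, 3))
    df = pd.DataFrame(
        {
            "node_id": np.arange(n),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "roi": cd_map.node_roi,
            "strength": cd_map.node_strength,
        }
    )
    df.to_csv(path, index=False)


def load_current_density_csv(path: str | Path, labels: dict | None = None) -> CurrentDensityMap:
    df = pd.read_csv(path)
    return CurrentDensityMap(
        node_strength=df["strength"].to_numpy(),
        node_roi=df["roi"].to_numpy(dtype=object),
        labels=dict(labels or {}),
        node_xyz=df[["x", "y", "z"]].to_numpy(),
    )


def save_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
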