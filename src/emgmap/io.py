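"""HDF5 persistence for synthetic recordings and YAML for grid descriptors."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .grid import GridLayout
from .recording import EmgRecording
from .synthetic import SyntheticRecording

__all__ = ["save_recording", "load_recording", "save_grid_yaml", "load_grid_yaml"]


def save_recording(path: str | Path, sim: SyntheticRecording) -> None:
    """Write a synthetic recording: /emg, /angle, and /truth/* datasets."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("emg", data=sim.emg.data, compression="gzip")
        d.attrs["fs"] = sim.emg.fs
        a = f.create_dataset("angle", data=sim.angle_raw)
        a.attrs["fs"] = sim.kinematics_fs
        g = f.create_group("grid")
        g.attrs["n_cols"] = sim.grid.n_cols
        g.attrs["n_rows"] = sim.grid.n_rows
        g.attrs["ied_mm"] = sim.grid.ied_mm
        t = f.create_group("truth")
        for key, val in sim.truth.items():
            if key == "boundaries":
                t.create_dataset(key, data=np.asarray(val, dtype=np.int64))
            elif key == "source_labels":
                t.create_dataset(
                    key, data=np.array(val, dtype=h5py.string_dtype())
                )
            elif np.isscalar(val):
                t.attrs[key] = val
            else:
                t.create_dataset(key, data=np.asarray(val))
        for key, val in sim.emg.meta.items():
            if isinstance(val, (str, int, float)):
                f.attrs[key] = val


def load_recording(path: str | Path) -> SyntheticRecording:
    with h5py.File(path, "r") as f:
        grid = GridLayout(
            n_cols=int(f["grid"].attrs["n_cols"]),
            n_rows=int(f["grid"].attrs["n_rows"]),
            ied_mm=float(f["grid"].attrs["ied_mm"]),
        )
        rec = EmgRecording(
            data=f["emg"][...],
            fs=float(f["emg"].attrs["fs"]),
            grid=grid,
            meta={k: v for k, v in f.attrs.items()},
        )
        truth: dict = {k: v for k, v in f["truth"].attrs.items()}
        for key, ds in f["truth"].items():
            if key == "boundaries":
                truth[key] = [tuple(map(int, row)) for row in ds[...]]
            elif key == "source_labels":
                truth[key] = [s.decode() for s in ds[...]]
            else:
                truth[key] = ds[...]
        return SyntheticRecording(
            emg=rec,
            angle_raw=f["angle"][...],
            kinematics_fs=float(f["angle"].attrs["fs"]),
            truth=truth,
        )


def save_grid_yaml(path: str | Path, grid: GridLayout, meta: dict | None = None) -> None:
    doc = {
        "grid": {"n_cols": grid.n_cols, "n_rows": grid.n_rows, "ied_mm": grid.ied_mm},
        **({"task": meta} if meta else {}),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_grid_yaml(path: str | Path) -> GridLayout:
    doc = yaml.safe_load(Path(path).read_text())
    g = doc["grid"]
    return GridLayout(n_cols=g["n_cols"], n_rows=g["n_rows"], ied_mm=g["ied_mm"])
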