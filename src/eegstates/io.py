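"""HDF5 / CSV / JSON serialization for pipeline artifacts.

A TrialTensor is stored as an HDF5 group holding a ``data`` dataset of
shape (channels, samples, trials), string attributes ``fs`` and
``channel_names``, and a ``condition`` dataset of length trials.  Window
features go to an HDF5 dataset plus a CSV index; reports, Markov models
and test results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import TrialTensor
from .markov import MarkovModel
from .smvar import WindowedNetworks

__all__ = [
    "write_tensor", "read_tensor",
    "write_features", "read_features",
    "write_symbols", "read_symbols",
    "write_markov", "read_markov",
    "write_mvar_model", "read_mvar_model",
    "write_report",
]


class SchemaError(ValueError):
    """Raised when a file is missing required fields."""


def write_tensor(path, t: TrialTensor) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=t.data)
        d.attrs["fs"] = t.fs
        d.attrs["channel_names"] = [str(c) for c in t.channel_names]
        f.create_dataset("condition", data=np.asarray([str(c) for c in t.condition], dtype="S"))


def read_tensor(path) -> TrialTensor:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise SchemaError(f"{path}: missing dataset 'data'")
        d = f["data"]
        if "fs" not in d.attrs:
            raise SchemaError(f"{path}: dataset 'data' lacks attribute 'fs'")
        if "condition" not in f:
            raise SchemaError(f"{path}: missing dataset 'condition'")
        names = [c.decode() if isinstance(c, bytes) else str(c)
                 for c in d.attrs.get("channel_names", [])]
        cond = np.asarray([c.decode() for c in f["condition"][()]])
        return TrialTensor(data=d[()], fs=float(d.attrs["fs"]),
                           channel_names=names, condition=cond)


def write_features(path_h5, path_csv, feats: WindowedNetworks) -> None:
    with h5py.File(path_h5, "w") as f:
        d = f.create_dataset("features", data=feats.V)
        d.attrs["m"] = feats.m
        d.attrs["n_windows"] = feats.n_windows
    feats.index.to_csv(path_csv, index=False)


def read_features(path_h5, path_csv) -> WindowedNetworks:
    with h5py.File(path_h5, "r") as f:
        if "features" not in f:
            raise SchemaError(f"{path_h5}: missing dataset 'features'")
        V = f["features"][()]
        m = int(f["features"].attrs["m"])
        n_windows = int(f["features"].attrs["n_windows"])
    index = pd.read_csv(path_csv)
    gpc = index.groupby("condition")["grouped_trial"].nunique().to_dict()
    return WindowedNetworks(V=V, index=index, m=m, n_windows=n_windows,
                            groups_per_condition=gpc)


def write_symbols(directory, symbols: dict) -> list:
    """One CSV per condition, rows = grouped trials, columns = windows."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, S in symbols.items():
        p = directory / f"symbols_{label}.csv"
        pd.DataFrame(S).to_csv(p, index=False, header=False)
        paths.append(p)
    return paths


def read_symbols(path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(dtype=int)


def write_mvar_model(path, model) -> None:
    """MVARModel to HDF5 (coefficients plus scalar attributes)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("A", data=model.A)
        d.attrs["p"] = model.p
        d.attrs["m"] = model.m
        d.attrs["lam"] = model.lam
        f.create_dataset("resid_var", data=np.asarray(model.resid_var))


def read_mvar_model(path):
    from .smvar import MVARModel

    with h5py.File(path, "r") as f:
        if "A" not in f:
            raise SchemaError(f"{path}: missing dataset 'A'")
        d = f["A"]
        return MVARModel(A=d[()], p=int(d.attrs["p"]), m=int(d.attrs["m"]),
                         lam=float(d.attrs["lam"]), resid_var=f["resid_var"][()])


def write_markov(path, model: MarkovModel, extra: dict | None = None) -> None:
    doc = {"pi": model.pi.tolist(), "Tm": model.Tm.tolist()}
    doc.update(extra or {})
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_markov(path) -> MarkovModel:
    doc = json.loads(Path(path).read_text())
    if "pi" not in doc or "Tm" not in doc:
        raise SchemaError(f"{path}: missing 'pi' or 'Tm'")
    return MarkovModel(pi=np.asarray(doc["pi"]), Tm=np.asarray(doc["Tm"]))


def write_report(path, report) -> None:
    Path(path).write_text(report.to_json())
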