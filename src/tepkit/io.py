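"""HDF5 serialization for epoched containers.

Layout: ``/data`` (trials x channels x samples, µV), ``/times`` (ms),
``/channels`` (UTF-8 labels), ``/trials/<column>`` (one dataset per
trial-table column), with ``srate`` as a root attribute. Evoked and
TEP matrices can be stored under ``/evoked`` and ``/tep`` groups.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .simulate import EpochSet

__all__ = ["save_epochs", "load_epochs"]


def save_epochs(epochs: EpochSet, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset(
            "channels", data=np.array(epochs.channel_names, dtype=h5py.string_dtype())
        )
        f.attrs["srate"] = epochs.srate
        g = f.create_group("trials")
        for col in epochs.trial_table.columns:
            vals = epochs.trial_table[col].to_numpy()
            if vals.dtype == object or str(vals.dtype).startswith("str"):
                vals = np.array([str(v) for v in vals], dtype=h5py.string_dtype())
            g.create_dataset(col, data=vals)
        g.attrs["columns"] = list(epochs.trial_table.columns)


def load_epochs(path: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
        srate = float(f.attrs["srate"])
        g = f["trials"]
        cols = list(g.attrs["columns"])
        table = {}
        for col in cols:
            vals = g[col][()]
            if vals.dtype.kind in ("S", "O"):
                vals = np.array([v.decode() if isinstance(v, bytes) else str(v) for v in vals])
            table[col] = vals
    return EpochSet(
        data=data,
        times=times,
        channel_names=channels,
        srate=srate,
        trial_table=pd.DataFrame(table, columns=cols),
    )
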