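"""Dataset I/O: long-format CSV recordings and the packed window container.

Two native on-disk formats:

* long CSV — one row per timestep with columns ``user, activity, t, ch0..chK``;
  the natural export of a labeled recording session.
* packed HDF5 — model-ready windows: datasets ``X (N, C, L)``, ``y_act (N)``,
  ``y_user (N)`` plus attrs ``rate`` and ``n_classes``. Written without HDF5
  object timestamps so identical data produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .prep import SensorRecording, WindowSet

__all__ = [
    "write_long_csv",
    "read_long_csv",
    "write_packed",
    "read_packed",
]


def write_long_csv(recs: Sequence[SensorRecording], path: str | Path) -> None:
    frames = []
    for rec in recs:
        k = rec.n_channels
        df = pd.DataFrame(rec.values.T, columns=[f"ch{i}" for i in range(k)])
        df.insert(0, "t", np.arange(rec.n_timesteps) / rec.sampling_rate)
        df.insert(0, "activity", rec.activity_label)
        df.insert(0, "user", rec.user_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def read_long_csv(path: str | Path, sampling_rate: float | None = None) -> list[SensorRecording]:
    """Read recordings back; one per contiguous (user, activity) run.

    The sampling rate is inferred from the ``t`` column unless given.
    """
    df = pd.read_csv(path)
    chans = [c for c in df.columns if c.startswith("ch")]
    if not chans:
        raise ValueError("long CSV has no channel columns (ch0..chK)")
    recs = []
    for (user, act), grp in df.groupby(["user", "activity"], sort=False):
        t = grp["t"].to_numpy()
        if sampling_rate is None:
            if len(t) < 2:
                raise ValueError("cannot infer sampling rate from one sample")
            rate = 1.0 / float(np.median(np.diff(t)))
        else:
            rate = sampling_rate
        recs.append(
            SensorRecording(grp[chans].to_numpy().T, round(rate, 6),
                            user_id=str(user), activity_label=int(act))
        )
    return recs


def write_packed(ws: WindowSet, path: str | Path) -> None:
    with h5py.File(path, "w", track_order=False) as f:
        f.create_dataset("X", data=ws.X, track_times=False)
        f.create_dataset("y_act", data=ws.y_act, track_times=False)
        users = np.asarray([str(u) for u in ws.y_user], dtype="S")
        f.create_dataset("y_user", data=users, track_times=False)
        f.create_dataset("starts", data=ws.starts, track_times=False)
        f.attrs["rate"] = float(ws.sampling_rate)
        f.attrs["n_classes"] = int(ws.n_classes)


def read_packed(path: str | Path) -> WindowSet:
    with h5py.File(path, "r") as f:
        return WindowSet(
            f["X"][()],
            f["y_act"][()],
            np.array([u.decode() for u in f["y_user"][()]], dtype=object),
            n_classes=int(f.attrs["n_classes"]),
            sampling_rate=float(f.attrs["rate"]),
            starts=f["starts"][()],
        )
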