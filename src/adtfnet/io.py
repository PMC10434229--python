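"""Plain-text dataset layout: delimited matrices with JSON sidecars.

An epoched recording is a directory of one ``epoch_XXXX.csv`` file per epoch
(channels x samples) plus ``recording.json`` holding the sampling rate,
epoch start time, channel names and provenance. Lead fields and reaction
times are single delimited files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import EpochedRecording


def write_recording(rec: EpochedRecording, directory, extra_meta: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for e in range(rec.n_epochs):
        np.savetxt(directory / f"epoch_{e:04d}.csv", rec.data[:, :, e], delimiter=",")
    meta = {
        "sampling_rate": rec.sampling_rate,
        "tmin": rec.tmin,
        "channel_names": rec.channel_names,
        "n_epochs": rec.n_epochs,
    }
    if extra_meta:
        meta.update(extra_meta)
    (directory / "recording.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_recording(directory) -> EpochedRecording:
    directory = Path(directory)
    meta = json.loads((directory / "recording.json").read_text())
    epochs = sorted(directory.glob("epoch_*.csv"))
    if not epochs:
        raise FileNotFoundError(f"no epoch files under {directory}")
    data = np.stack([np.loadtxt(f, delimiter=",", ndmin=2) for f in epochs], axis=2)
    return EpochedRecording(
        data, sampling_rate=meta["sampling_rate"], tmin=meta["tmin"],
        channel_names=list(meta["channel_names"]),
    )


def write_leadfield(L: np.ndarray, path) -> None:
    np.savetxt(path, L, delimiter=",")


def read_leadfield(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_rts(rts: np.ndarray, path) -> None:
    pd.DataFrame({"subject": np.arange(len(rts)), "RT_ms": rts}).to_csv(path, index=False)


def read_rts(path) -> np.ndarray:
    return pd.read_csv(path)["RT_ms"].to_numpy(dtype=float)
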