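"""File formats: trial/anxiety tables as CSV, epoched EEG as HDF5.

The HDF5 layout is ``/data`` (trials x channels x time), ``/times`` (s),
``/channels`` (UTF-8 strings) with attributes ``sfreq`` (Hz) and ``lock``
("stimulus" or "response").  Reading then writing reproduces the file's
arrays bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import TRIAL_COLUMNS


@dataclass
class EEGEpochs:
    """Epoched multichannel EEG: trials x channels x time plus metadata."""

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channel_names: list[str]
    lock: str = "stimulus"

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match data's channel axis")
        if self.data.shape[2] != len(self.times):
            raise ValueError("times must match data's time axis")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.sfreq,
                                                           rtol=1e-6, atol=1e-9)):
            raise ValueError("times must increase uniformly at 1/sfreq")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, names) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.channel_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return np.array([lookup[n] for n in names])

    def time_index(self, t: float) -> int:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(f"time {t} s outside epoch "
                             f"[{self.times[0]}, {self.times[-1]}]")
        return int(np.argmin(np.abs(self.times - t)))


def write_eeg_h5(path, eeg: EEGEpochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=eeg.data)
        f.create_dataset("times", data=eeg.times)
        f.create_dataset(
            "channels", data=np.array(eeg.channel_names, dtype=h5py.string_dtype())
        )
        f.attrs["sfreq"] = eeg.sfreq
        f.attrs["lock"] = eeg.lock


def read_eeg_h5(path) -> EEGEpochs:
    with h5py.File(path, "r") as f:
        return EEGEpochs(
            data=f["data"][()],
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            channel_names=[c.decode() if isinstance(c, bytes) else str(c)
                           for c in f["channels"][()]],
            lock=str(f.attrs["lock"]),
        )


def write_trials_csv(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df["choice"] = df["choice"].fillna("")
    return df[TRIAL_COLUMNS]


def write_anxiety_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_anxiety_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "state_score", "trait_score"):
        if col not in df.columns:
            raise ValueError(f"anxiety table missing column {col!r}")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
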