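"""Core in-memory containers and their on-disk formats.

A *trial table* is a plain :class:`pandas.DataFrame` with one row per
trial and the canonical columns

``trial, condition, direction, cue, congruent, choice, correct, rt,
coh_e1..coh_e8``

where ``direction``/``cue``/``choice`` are signed (+1 = rightward,
-1 = leftward), ``condition`` is one of ``acoustic``, ``precue``,
``postcue``, and ``coh_e*`` hold the per-epoch motion coherence in
percent.  :class:`EpochArray` wraps the trials x channels x time EEG
tensor together with its time axis and channel metadata; it round-trips
through HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

CONDITIONS = ("acoustic", "precue", "postcue")
TRIAL_COLUMNS = ["trial", "condition", "direction", "cue", "congruent",
                 "choice", "correct", "rt"]
N_EPOCHS = 8  # 96 frames / 12 frames per coherence epoch


def coherence_columns(n_epochs: int = N_EPOCHS) -> list[str]:
    return [f"coh_e{i + 1}" for i in range(n_epochs)]


def validate_trial_table(table: pd.DataFrame, require_choice: bool = False) -> None:
    missing = [c for c in TRIAL_COLUMNS[:5] if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if require_choice and table["choice"].isna().any():
        raise ValueError("trial table has trials without choices")
    bad = set(table["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_trial_table(table)
    return table


def write_trial_table(table: pd.DataFrame, path) -> None:
    validate_trial_table(table)
    table.to_csv(path, index=False)


@dataclass
class EpochArray:
    """Epoched multichannel EEG: trials x channels x time.

    ``times`` is in seconds with 0 = stimulus onset. ``ch_names``
    label the rows of the channel axis; EOG channels are recognised by
    a name starting with ``EOG``.  ``ch_pos`` (optional) holds 2-D
    sensor coordinates used for neighbour-based interpolation.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    ch_names: list[str]
    ch_pos: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis does not match times")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def eeg_picks(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.ch_names)
                         if not n.upper().startswith("EOG")], dtype=int)

    @property
    def eog_picks(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.ch_names)
                         if n.upper().startswith("EOG")], dtype=int)

    def copy(self) -> "EpochArray":
        return EpochArray(self.data.copy(), self.times.copy(), self.fs,
                          list(self.ch_names),
                          None if self.ch_pos is None else self.ch_pos.copy())

    def select_trials(self, idx) -> "EpochArray":
        return EpochArray(self.data[np.asarray(idx)], self.times, self.fs,
                          list(self.ch_names), self.ch_pos)

    # ------------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time", data=self.times)
            f.attrs["fs"] = self.fs
            f.create_dataset("channel_names",
                             data=np.array(self.ch_names, dtype="S"))
            if self.ch_pos is not None:
                f.create_dataset("channel_pos", data=self.ch_pos)

    @classmethod
    def from_hdf5(cls, path) -> "EpochArray":
        with h5py.File(path, "r") as f:
            names = [n.decode() for n in f["channel_names"][()]]
            pos = f["channel_pos"][()] if "channel_pos" in f else None
            return cls(f["data"][()], f["time"][()], float(f.attrs["fs"]),
                       names, pos)


@dataclass
class LDAComponent:
    """A trained linear-discriminant projection of the EEG.

    ``w`` maps channels to a one-dimensional discriminant score
    ``y = w @ x + bias`` computed on window-averaged activity;
    ``pattern`` is the forward-model topography (per-channel
    correlation between y and the data), the interpretable scalp map of
    the decoded source.
    """

    w: np.ndarray
    bias: float
    window_start: float
    window_len: float
    gamma: float
    pattern: np.ndarray | None = None

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if not np.any(self.w):
            raise ValueError("discriminant weights are all zero")


@dataclass
class TFPower:
    """Trial-wise time-frequency power, z-scored across trials per bin."""

    power_z: np.ndarray        # (trials, freqs, times)
    freqs: np.ndarray
    times: np.ndarray
    cycles: np.ndarray = field(default=None)

    def __post_init__(self):
        self.power_z = np.asarray(self.power_z, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power_z.shape[1:] != (len(self.freqs), len(self.times)):
            raise ValueError("power_z shape does not match freq/time axes")

    def band_mask(self, fmin: float, fmax: float,
                  tmin: float, tmax: float) -> np.ndarray:
        fm = (self.freqs >= fmin) & (self.freqs <= fmax)
        tm = (self.times >= tmin) & (self.times <= tmax)
        return np.outer(fm, tm)
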