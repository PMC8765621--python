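"""Epoched EEG container and its on-disk layout.

An :class:`EpochSet` holds a trials x channels x time voltage array (in
microvolts) together with per-trial labels (condition, participant,
group), the time axis in milliseconds relative to stimulus onset, and
bookkeeping for bad channels and rejected trials.

On disk, one participant's epochs are a ``<pid>_data.npy`` array next to
a ``<pid>_meta.json`` sidecar carrying every label and the sampling
metadata, so a directory of participants is self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CONDITIONS = ("AA", "HH", "AH", "HA")
GROUPS = ("pTD", "pASD")

__all__ = ["EpochSet", "CONDITIONS", "GROUPS"]


@dataclass
class EpochSet:
    """Trials x channels x time voltages with labels and sampling metadata.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Voltages in microvolts.
    times : ndarray, shape (n_times,)
        Milliseconds relative to stimulus onset, strictly increasing.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels matching the sensor layout.
    condition : ndarray of str, shape (n_trials,)
        Per-trial condition labels from ``CONDITIONS``.
    participant : str
        Participant identifier.
    group : str
        ``"pTD"`` or ``"pASD"``.
    bad_channels : set of str
        Channels excluded from referencing/averaging (interpolation targets).
    rejected_trials : dict of int -> str
        Trial index -> reason code; rejected trials are kept in ``data`` but
        excluded by :meth:`clean_mask`.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list[str]
    condition: np.ndarray
    participant: str
    group: str
    bad_channels: set[str] = field(default_factory=set)
    rejected_trials: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_tr, n_ch, n_t = self.data.shape
        if len(self.ch_names) != n_ch:
            raise ValueError("ch_names length must match channel axis")
        if self.times.shape != (n_t,):
            raise ValueError("times length must match time axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.condition.shape != (n_tr,):
            raise ValueError("one condition label per trial required")
        unknown = set(self.condition) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels {unknown}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    # -- selection -----------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def clean_mask(self) -> np.ndarray:
        """Boolean mask of trials not flagged by artifact rejection."""
        mask = np.ones(self.n_trials, dtype=bool)
        if self.rejected_trials:
            mask[list(self.rejected_trials)] = False
        return mask

    def good_channel_indices(self) -> np.ndarray:
        return np.array(
            [i for i, nm in enumerate(self.ch_names) if nm not in self.bad_channels],
            dtype=int,
        )

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        if lo < self.times[0] or hi > self.times[-1]:
            raise ValueError(f"window {window_ms} outside epoch "
                             f"[{self.times[0]}, {self.times[-1]}] ms")
        return (self.times >= lo) & (self.times <= hi)

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            condition=self.condition.copy(),
            participant=self.participant,
            group=self.group,
            bad_channels=set(self.bad_channels),
            rejected_trials=dict(self.rejected_trials),
        )

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{self.participant}_data.npy", self.data)
        meta = {
            "participant": self.participant,
            "group": self.group,
            "sfreq": self.sfreq,
            "times_ms": self.times.tolist(),
            "ch_names": self.ch_names,
            "condition": list(map(str, self.condition)),
            "bad_channels": sorted(self.bad_channels),
            "rejected_trials": {str(k): v for k, v in self.rejected_trials.items()},
        }
        with open(directory / f"{self.participant}_meta.json", "w") as fh:
            json.dump(meta, fh)
        return directory

    @classmethod
    def load(cls, directory: str | Path, participant: str) -> "EpochSet":
        directory = Path(directory)
        data = np.load(directory / f"{participant}_data.npy")
        with open(directory / f"{participant}_meta.json") as fh:
            meta = json.load(fh)
        return cls(
            data=data,
            times=np.asarray(meta["times_ms"]),
            sfreq=meta["sfreq"],
            ch_names=meta["ch_names"],
            condition=np.asarray(meta["condition"], dtype=object),
            participant=meta["participant"],
            group=meta["group"],
            bad_channels=set(meta["bad_channels"]),
            rejected_trials={int(k): v for k, v in meta["rejected_trials"].items()},
        )
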