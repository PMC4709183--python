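"""Core data containers shared across the pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError
from .paradigm import FlashSchedule

__all__ = ["EEGRecording", "EpochSet", "CHANNELS_1020_19"]

#: The 19 scalp electrodes of the revised international 10/20 montage, in the
#: order used by the reference acquisition setup.
CHANNELS_1020_19 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4", "P3", "P4",
    "O1", "O2", "T3", "T4", "T5", "T6", "Fz", "Pz", "Cz",
)


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with its stimulus event stream.

    Attributes
    ----------
    data
        ``(n_channels, n_samples)`` signal in microvolts.
    fs
        Sampling frequency in Hz.
    channel_labels
        One 10/20-style label per channel.
    events
        The flash schedule aligned to this recording's time axis.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    events: FlashSchedule | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DomainError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise DomainError("sampling frequency must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise DomainError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if self.events is not None and len(self.events) and (
            self.events.onsets[-1] >= self.duration
        ):
            raise DomainError("event onsets extend past the end of the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data, self.fs, self.channel_labels, self.events)


@dataclass
class EpochSet:
    """Stimulus-locked trials cut from a continuous recording.

    ``data`` is ``(n_trials, n_channels, n_samples)`` with a shared time axis
    in milliseconds relative to flash onset (half-open window, e.g.
    ``[-200, 800)`` ms giving exactly ``round(fs * 1 s)`` samples).
    """

    data: np.ndarray
    time_ms: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    is_target: np.ndarray  # (n_trials,) bool
    stimulus_ids: np.ndarray  # (n_trials,) int
    character_indices: np.ndarray  # (n_trials,) int
    n_dropped: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DomainError("epoch data must be 3-D (trials x channels x samples)")
        n_trials = self.data.shape[0]
        for name, arr in (
            ("is_target", self.is_target),
            ("stimulus_ids", self.stimulus_ids),
            ("character_indices", self.character_indices),
        ):
            if len(arr) != n_trials:
                raise DomainError(f"{name} length does not match trial count")
        if len(self.time_ms) != self.data.shape[2]:
            raise DomainError("time axis length does not match sample count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset of trials (boolean mask or integer indices)."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            time_ms=self.time_ms,
            fs=self.fs,
            channel_labels=self.channel_labels,
            is_target=np.asarray(self.is_target)[mask],
            stimulus_ids=np.asarray(self.stimulus_ids)[mask],
            character_indices=np.asarray(self.character_indices)[mask],
        )

    def sample_window(self, start_ms: float, stop_ms: float,
                      inclusive_stop: bool = True) -> np.ndarray:
        """Boolean sample mask for ``start_ms <= t <= stop_ms`` (or ``< stop``)."""
        if inclusive_stop:
            mask = (self.time_ms >= start_ms) & (self.time_ms <= stop_ms)
        else:
            mask = (self.time_ms >= start_ms) & (self.time_ms < stop_ms)
        if not mask.any():
            raise DomainError(f"window [{start_ms}, {stop_ms}] ms contains no samples")
        return mask

    # -- lightweight on-disk form: one .npy per array + JSON metadata sidecar --

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "epochs.npy", self.data)
        meta = {
            "fs": self.fs,
            "time_ms": self.time_ms.tolist(),
            "channel_labels": list(self.channel_labels),
            "is_target": np.asarray(self.is_target).astype(int).tolist(),
            "stimulus_ids": np.asarray(self.stimulus_ids).astype(int).tolist(),
            "character_indices": np.asarray(self.character_indices).astype(int).tolist(),
            "n_dropped": self.n_dropped,
        }
        (d / "epochs.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "EpochSet":
        d = Path(directory)
        meta = json.loads((d / "epochs.json").read_text())
        return cls(
            data=np.load(d / "epochs.npy"),
            time_ms=np.asarray(meta["time_ms"], float),
            fs=float(meta["fs"]),
            channel_labels=tuple(meta["channel_labels"]),
            is_target=np.asarray(meta["is_target"], int).astype(bool),
            stimulus_ids=np.asarray(meta["stimulus_ids"], int),
            character_indices=np.asarray(meta["character_indices"], int),
            n_dropped=int(meta["n_dropped"]),
        )
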