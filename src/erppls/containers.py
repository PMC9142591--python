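"""In-memory containers shared across the pipeline.

The study paradigm is a three-condition audiovisual congruency task recorded
from six scalp electrodes (F7, Fz, F8, Cz, CP5, Pz) plus two peri-ocular EOG
channels at 500 Hz.  Continuous recordings are epoched to a fixed
[-200, 800) ms grid (500 samples) around each stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EEG_CHANNELS: tuple[str, ...] = ("F7", "Fz", "F8", "Cz", "CP5", "Pz")
EOG_CHANNELS: tuple[str, ...] = ("EOG1", "EOG2")
CONDITIONS: tuple[str, ...] = (
    "congruent",
    "incongruent-semantic",
    "incongruent-pragmatic",
)
GROUPS: tuple[str, ...] = ("ASD", "TD")

#: Epoch window in ms relative to stimulus onset, half-open [start, stop).
EPOCH_WINDOW_MS: tuple[float, float] = (-200.0, 800.0)
BASELINE_WINDOW_MS: tuple[float, float] = (-200.0, 0.0)
SAMPLING_RATE: float = 500.0

EVENT_COLUMNS = ("onset_sample", "condition", "rt_seconds", "response")


def epoch_time_grid(
    rate: float = SAMPLING_RATE, window_ms: tuple[float, float] = EPOCH_WINDOW_MS
) -> np.ndarray:
    """Time axis in ms for the half-open epoch window at the given rate."""
    step = 1000.0 / rate
    n = int(round((window_ms[1] - window_ms[0]) / step))
    return window_ms[0] + step * np.arange(n)


@dataclass
class Recording:
    """Continuous multichannel recording in microvolts.

    ``data`` is channels x time; ``roles`` marks each channel as ``"EEG"``
    or ``"EOG"`` so that artifact regression knows its regressors.
    """

    data: np.ndarray
    rate: float
    channels: tuple[str, ...]
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        self.channels = tuple(self.channels)
        self.roles = tuple(self.roles)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x time")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch")
        if len(self.roles) != len(self.channels):
            raise ValueError("one role per channel required")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def pick(self, role: str) -> np.ndarray:
        """View of the rows whose role matches (``"EEG"`` or ``"EOG"``)."""
        idx = [i for i, r in enumerate(self.roles) if r == role]
        return self.data[idx]

    def role_indices(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    def drop_channels(self, labels: list[str] | tuple[str, ...]) -> "Recording":
        keep = [i for i, c in enumerate(self.channels) if c not in set(labels)]
        return Recording(
            data=self.data[keep].copy(),
            rate=self.rate,
            channels=tuple(self.channels[i] for i in keep),
            roles=tuple(self.roles[i] for i in keep),
        )

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data))


@dataclass
class Epochs:
    """Stimulus-locked trials on the fixed epoch grid.

    ``data`` is trials x channels x time.  ``trial_index`` links each epoch
    back to its row in the event table.  Rejection masks are additive: a
    trial is retained iff it is flagged by neither mask.
    """

    data: np.ndarray
    times_ms: np.ndarray
    rate: float
    channels: tuple[str, ...]
    roles: tuple[str, ...]
    trial_index: np.ndarray
    amplitude_rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    response_rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_dropped_edge: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        n = self.data.shape[0]
        if self.amplitude_rejected is None:
            self.amplitude_rejected = np.zeros(n, dtype=bool)
        if self.response_rejected is None:
            self.response_rejected = np.zeros(n, dtype=bool)
        self.amplitude_rejected = np.asarray(self.amplitude_rejected, dtype=bool)
        self.response_rejected = np.asarray(self.response_rejected, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time grid mismatch")
        for mask in (self.amplitude_rejected, self.response_rejected):
            if mask.shape != (n,):
                raise ValueError("masks must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def retained(self) -> np.ndarray:
        return ~(self.amplitude_rejected | self.response_rejected)

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table schema used across the pipeline."""
    missing = [c for c in ("onset_sample", "condition", "response") if c not in events]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    bad = set(events["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    return events
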