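"""In-memory container for multichannel electrode recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SensorRecording"]


@dataclass
class SensorRecording:
    """Multichannel potential recording.

    ``data`` is channels x samples (volts); ``events`` holds stimulus
    markers as an integer array of shape (n_events, 2) with columns
    (sample index, event code).
    """

    data: np.ndarray            # (N, T) volts
    fs: float                   # Hz
    labels: list[str] = field(default_factory=list)
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match channel count")
        if len(self.events) and np.any(np.diff(self.events[:, 0]) < 0):
            raise ValueError("event samples must be non-decreasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "SensorRecording":
        return SensorRecording(data=self.data.copy(), fs=self.fs,
                               labels=list(self.labels),
                               events=self.events.copy())
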