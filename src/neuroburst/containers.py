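"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ElectrodeGeometry


@dataclass
class RawRecording:
    """Multichannel extracellular voltage recording.

    ``samples`` is a (n_channels, n_samples) float array in microvolts,
    all channels sampled synchronously at ``rate`` Hz (20 kHz by default
    for the MEA rigs this package models).
    """

    samples: np.ndarray
    rate: float
    geometry: ElectrodeGeometry

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] != self.geometry.n_electrodes:
            raise ValueError(
                f"{self.samples.shape[0]} channels but geometry has "
                f"{self.geometry.n_electrodes} electrodes"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate


@dataclass
class SpikeRaster:
    """Timestamped spike events across an electrode array.

    Events are stored as two parallel arrays sorted by time (ties by
    electrode index).  This is the lingua franca between the spike
    detector, the synthetic generators, burst segmentation and the
    functional-graph stage.
    """

    electrodes: np.ndarray
    times: np.ndarray
    n_electrodes: int
    duration: float

    def __post_init__(self) -> None:
        self.electrodes = np.asarray(self.electrodes, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.electrodes.shape != self.times.shape or self.electrodes.ndim != 1:
            raise ValueError("electrodes and times must be 1-D arrays of equal length")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_spikes:
            if self.times.min() < 0 or self.times.max() >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")
            if self.electrodes.min() < 0 or self.electrodes.max() >= self.n_electrodes:
                raise ValueError("electrode index out of range")
            order = np.lexsort((self.electrodes, self.times))
            self.electrodes = self.electrodes[order]
            self.times = self.times[order]

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def times_on(self, electrode: int) -> np.ndarray:
        """Sorted spike times of one electrode."""
        return np.sort(self.times[self.electrodes == electrode])

    def times_by_electrode(self) -> list[np.ndarray]:
        """Per-electrode sorted spike-time arrays (length n_electrodes)."""
        out: list[np.ndarray] = [np.empty(0)] * self.n_electrodes
        order = np.argsort(self.electrodes, kind="stable")
        el = self.electrodes[order]
        ts = self.times[order]
        bounds = np.searchsorted(el, np.arange(self.n_electrodes + 1))
        for e in range(self.n_electrodes):
            out[e] = np.sort(ts[bounds[e] : bounds[e + 1]])
        return out

    def spike_counts(self) -> np.ndarray:
        """Number of spikes per electrode."""
        return np.bincount(self.electrodes, minlength=self.n_electrodes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"electrode": self.electrodes, "time_s": self.times})

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_electrodes: int, duration: float
    ) -> "SpikeRaster":
        return cls(
            electrodes=df["electrode"].to_numpy(),
            times=df["time_s"].to_numpy(),
            n_electrodes=n_electrodes,
            duration=duration,
        )

    @classmethod
    def empty(cls, n_electrodes: int, duration: float) -> "SpikeRaster":
        return cls(np.empty(0, dtype=np.int64), np.empty(0), n_electrodes, duration)


@dataclass
class CaTraceSet:
    """Per-cell calcium fluorescence traces.

    ``traces`` is (n_cells, n_frames) in the camera's relative units
    (0-255), sampled at ``frame_rate`` Hz (4 Hz in the imaging protocol
    this mirrors).
    """

    traces: np.ndarray
    frame_rate: float = 4.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (cells x frames)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.traces.size and (self.traces.min() < 0 or self.traces.max() > 255):
            raise ValueError("fluorescence values must lie in [0, 255]")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate
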