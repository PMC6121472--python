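"""Extracellular spike detection with a median-normalized threshold.

The detection threshold on each channel is

    T = N_s * sigma,    sigma = median(|x|) / 0.6745,

where ``x`` is the band-pass-filtered (0.3-8 kHz) voltage.  Dividing the
median absolute signal by 0.6745 — the 0.75 quantile of the standard
normal — turns it into an estimate of the noise standard deviation that
is far less inflated by the spikes themselves than a plain SD, so the
threshold barely moves as firing rates change.  ``N_s = 4`` is the
working default; crossings of ``|x| > T`` are reduced to the extremum
sample of each suprathreshold run, and a 1 ms minimal interspike
interval discards immediate re-crossings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .containers import RawRecording, SpikeRaster

logger = logging.getLogger(__name__)

#: median(|X|) of a standard Gaussian; used to normalize the median
#: absolute signal to the noise SD.
GAUSSIAN_MAD_CONSTANT = 0.6745


def gaussian_mad_constant() -> float:
    """0.75 quantile of the standard normal, computed from first principles.

    This is the exact value of the 0.6745 normalization constant: for
    zero-mean Gaussian noise, median(|X|) = sigma * Phi^-1(0.75).
    """
    return float(stats.norm.ppf(0.75))


@dataclass
class SpikeDetectionParams:
    """Knobs of the threshold detector.

    ns
        Detection coefficient N_s multiplying the noise estimate.
    band_low_hz, band_high_hz
        Corners of the zero-phase Butterworth band-pass.
    min_isi_ms
        Dead time after an accepted spike.
    norm_const
        Gaussian median-to-SD normalization (0.6745).
    """

    ns: float = 4.0
    band_low_hz: float = 300.0
    band_high_hz: float = 8000.0
    min_isi_ms: float = 1.0
    norm_const: float = GAUSSIAN_MAD_CONSTANT

    def __post_init__(self) -> None:
        if self.ns <= 0:
            raise ValueError("ns must be positive")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("band corners must satisfy 0 < low < high")
        if self.min_isi_ms <= 0:
            raise ValueError("min_isi_ms must be positive")


@dataclass
class NoiseEstimate:
    """Per-channel noise SD and detection threshold (T = ns * sigma)."""

    sigma: np.ndarray      # uV per channel
    threshold: np.ndarray  # uV per channel

    def __post_init__(self) -> None:
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.threshold = np.atleast_1d(np.asarray(self.threshold, dtype=float))
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


def bandpass(
    recording: RawRecording,
    band_low_hz: float = 300.0,
    band_high_hz: float = 8000.0,
    order: int = 4,
) -> RawRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward filtering (``sosfiltfilt``) keeps spike times
    unshifted; output length equals input length.
    """
    nyquist = recording.rate / 2.0
    if not 0 < band_low_hz < band_high_hz:
        raise ValueError("band corners must satisfy 0 < low < high")
    if band_high_hz >= nyquist:
        raise ValueError(
            f"band_high_hz={band_high_hz} must be below the Nyquist "
            f"frequency {nyquist}"
        )
    sos = signal.butter(
        order, [band_low_hz, band_high_hz], btype="bandpass",
        fs=recording.rate, output="sos",
    )
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return RawRecording(samples=filtered, rate=recording.rate, geometry=recording.geometry)


def estimate_sigma(
    channel: np.ndarray,
    norm_const: float = GAUSSIAN_MAD_CONSTANT,
    ns: float = 4.0,
) -> NoiseEstimate:
    """Median-based noise SD and threshold of one channel.

    sigma = median(|x|) / norm_const; threshold = ns * sigma.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("cannot estimate noise of an empty channel")
    sigma = float(np.median(np.abs(channel))) / norm_const
    return NoiseEstimate(sigma=np.array([sigma]), threshold=np.array([ns * sigma]))


def _detect_channel(
    x: np.ndarray, threshold: float, rate: float, min_isi_s: float
) -> np.ndarray:
    """Spike times of one filtered channel: extremum of each |x|>T run,
    then a causal min-ISI sweep keeping the earliest spike of each volley."""
    above = np.abs(x) > threshold
    if not above.any():
        return np.empty(0)
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    peaks = np.fromiter(
        (s + int(np.argmax(np.abs(x[s:e]))) for s, e in zip(starts, ends)),
        dtype=np.int64,
        count=starts.size,
    )
    times = peaks / rate
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= min_isi_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def detect_spikes(
    recording: RawRecording,
    params: SpikeDetectionParams | None = None,
    apply_bandpass: bool = True,
) -> tuple[SpikeRaster, NoiseEstimate]:
    """Threshold detection on every channel of a recording.

    Parameters
    ----------
    apply_bandpass
        Apply the 0.3-8 kHz zero-phase band-pass first.  Set False if
        the recording is already filtered.

    Returns
    -------
    raster, noise
        The detected raster (sorted by time) and the per-channel noise
        estimate actually used.
    """
    params = params or SpikeDetectionParams()
    rec = bandpass(recording, params.band_low_hz, params.band_high_hz) if apply_bandpass \
        else recording

    min_isi_s = params.min_isi_ms / 1000.0
    two_samples = 2.0 / rec.rate
    if min_isi_s < two_samples:
        warnings.warn(
            f"min_isi {params.min_isi_ms} ms is shorter than two samples; clamping",
            stacklevel=2,
        )
        min_isi_s = two_samples

    sigmas = np.empty(rec.n_channels)
    thresholds = np.empty(rec.n_channels)
    electrodes: list[np.ndarray] = []
    times: list[np.ndarray] = []
    for ch in range(rec.n_channels):
        x = rec.samples[ch]
        est = estimate_sigma(x, params.norm_const, params.ns)
        sigmas[ch] = est.sigma[0]
        thresholds[ch] = est.threshold[0]
        if thresholds[ch] <= 0:
            continue  # silent channel: sigma 0 would fire on everything
        ts = _detect_channel(x, thresholds[ch], rec.rate, min_isi_s)
        if ts.size:
            electrodes.append(np.full(ts.size, ch, dtype=np.int64))
            times.append(ts)

    noise = NoiseEstimate(sigma=sigmas, threshold=thresholds)
    if electrodes:
        raster = SpikeRaster(
            electrodes=np.concatenate(electrodes),
            times=np.concatenate(times),
            n_electrodes=rec.n_channels,
            duration=rec.duration,
        )
    else:
        raster = SpikeRaster.empty(rec.n_channels, rec.duration)
    logger.info("detected %d spikes on %d channels", raster.n_spikes, rec.n_channels)
    return raster, noise
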