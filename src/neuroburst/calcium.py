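"""Calcium transient detection from fluorescence traces.

Traces (relative units 0-255, 4 Hz) are lightly smoothed by averaging
neighbouring frames, differentiated by first differences, and events
are cut where the derivative exceeds +/- a threshold set to the
detection accuracy coefficient times the SD of the derivative: a pulse
begins at the first frame whose derivative crosses +threshold and ends
at the last frame of the following run below -threshold (the decay).
Population metrics mirror the standard readouts: percentage of active
cells, oscillation frequency (events/min averaged over active cells)
and mean event duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import CaTraceSet

logger = logging.getLogger(__name__)


@dataclass
class CaDetectionParams:
    """Detection accuracy coefficient (threshold = coef * SD(derivative))."""

    accuracy_coef: float = 2.0
    merge_gap_frames: int = 2  # events closer than this are one event

    def __post_init__(self) -> None:
        if self.accuracy_coef <= 0:
            raise ValueError("accuracy_coef must be positive")


@dataclass
class CaEvent:
    """One detected calcium transient on one cell."""

    cell: int
    begin: float  # s
    end: float    # s

    def __post_init__(self) -> None:
        if self.end <= self.begin:
            raise ValueError("event end must exceed begin")

    @property
    def duration(self) -> float:
        return self.end - self.begin


@dataclass
class CaMetrics:
    """Population summary of calcium activity."""

    pct_active_cells: float
    freq_per_min: float | None      # None when no cell is active
    mean_duration_s: float | None   # None when there are no events
    n_active_cells: int
    n_events: int


def smooth_trace(trace: np.ndarray) -> np.ndarray:
    """Average each pair of neighbouring frames; length shrinks by one."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("smoothing needs at least two frames")
    return 0.5 * (trace[:-1] + trace[1:])


def derivative_trace(trace: np.ndarray) -> np.ndarray:
    """First differences between consecutive frames."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("derivative needs at least two frames")
    return np.diff(trace)


def detect_ca_events(
    trace: np.ndarray,
    params: CaDetectionParams | None = None,
    frame_rate: float = 4.0,
    cell: int = 0,
    threshold: float | None = None,
) -> list[CaEvent]:
    """Threshold detection of transients on a single trace.

    The trace is smoothed, differentiated, and thresholded at
    ``accuracy_coef * SD(derivative)`` of this trace (pass ``threshold``
    to use an externally derived value, e.g. a population-pooled one).
    A pulse begins at the first frame whose derivative exceeds
    +threshold; it ends at the last frame of the next run below
    -threshold, or at the trace end if the decay never crosses.  Events
    separated by fewer than ``merge_gap_frames`` frames are merged — a
    debounce against noise at the 4 Hz frame rate.  A zero-variance
    derivative yields no events.
    """
    params = params or CaDetectionParams()
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        raise ValueError("detection needs at least three frames")
    d = derivative_trace(smooth_trace(trace))
    if threshold is None:
        sd = float(d.std())
        if sd == 0.0:
            return []
        thr = params.accuracy_coef * sd
    else:
        if threshold <= 0.0:
            return []
        thr = threshold

    raw: list[tuple[int, int]] = []  # (begin_frame, end_frame) inclusive
    k = 0
    n = d.size
    while k < n:
        if d[k] > thr:
            begin = k
            # find the next run below -thr
            m = k + 1
            while m < n and d[m] >= -thr:
                m += 1
            if m == n:
                end = n - 1  # unterminated pulse closes at trace end
                k = n
            else:
                while m < n and d[m] < -thr:
                    m += 1
                end = m - 1
                k = m
            raw.append((begin, end))
        else:
            k += 1

    merged: list[list[int]] = []
    for begin, end in raw:
        if merged and begin - merged[-1][1] < params.merge_gap_frames:
            merged[-1][1] = end
        else:
            merged.append([begin, end])

    # an event that runs into the final derivative frame was closed at the
    # trace end, so report the trace end as its end time
    return [
        CaEvent(
            cell=cell,
            begin=b / frame_rate,
            end=(trace.size if e == n - 1 else e + 1) / frame_rate,
        )
        for b, e in merged
    ]


def pooled_derivative_sd(traces: CaTraceSet) -> float:
    """SD of the derivative pooled over every cell of a recording."""
    d = np.diff(0.5 * (traces.traces[:, :-1] + traces.traces[:, 1:]), axis=1)
    return float(d.std())


def detect_ca_events_set(
    traces: CaTraceSet, params: CaDetectionParams | None = None
) -> list[list[CaEvent]]:
    """Per-cell event lists for a whole trace set.

    The detection threshold is ``accuracy_coef`` times the derivative SD
    pooled across all cells of the recording, not per trace.  A
    per-trace threshold is scale-free: a silent cell's threshold shrinks
    to its own noise and chases it, flagging every quiet cell as active.
    The pooled threshold ties quiet cells to the population's signal
    scale, which is what makes the percentage-of-active-cells readout
    meaningful.
    """
    params = params or CaDetectionParams()
    thr = params.accuracy_coef * pooled_derivative_sd(traces)
    return [
        detect_ca_events(
            traces.traces[c], params, traces.frame_rate, cell=c, threshold=thr
        )
        for c in range(traces.n_cells)
    ]


def ca_metrics(
    events_per_cell: list[list[CaEvent]], n_cells: int, duration_s: float
) -> CaMetrics:
    """Active-cell percentage, oscillation frequency and mean duration.

    A cell is active when it has at least one event.  Frequency is the
    mean over active cells of events per minute; duration averages over
    all events.  With no active cells both are reported absent (None).
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    active = [ev for ev in events_per_cell if ev]
    n_active = len(active)
    pct = 100.0 * n_active / n_cells
    if n_active:
        freq = float(np.mean([60.0 * len(ev) / duration_s for ev in active]))
        durations = [e.duration for ev in active for e in ev]
        mean_dur = float(np.mean(durations))
    else:
        freq = None
        mean_dur = None
    n_events = sum(len(ev) for ev in events_per_cell)
    return CaMetrics(
        pct_active_cells=pct, freq_per_min=freq, mean_duration_s=mean_dur,
        n_active_cells=n_active, n_events=n_events,
    )
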