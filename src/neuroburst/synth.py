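"""Synthetic MEA and calcium-imaging data with known ground truth.

Every downstream stage of the pipeline (spike detection, burst
segmentation, delayed-synchrony graphs, calcium transient detection) is
validated by recovery of structure planted here:

* raw 20 kHz voltage traces: Gaussian background noise plus biphasic
  extracellular spike waveforms at scheduled times;
* spike rasters with network bursts — brief (~50-500 ms) episodes in
  which an origin electrode fires first and activity propagates to the
  other participants with distance-proportional delays;
* rasters with planted directed connectivity, where presynaptic spikes
  are copied to their targets with a transmission probability at an
  axonal conduction delay — "delayed synchronous" pairs by construction;
* calcium fluorescence traces carrying transient events at a configured
  rate and duration (presets follow the sham-culture statistics:
  ~97% active cells, ~6.9 oscillations/min, ~6.23 s duration).

All generators take a single integer seed; per-stream child generators
are derived deterministically, so identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import CaTraceSet, RawRecording, SpikeRaster
from .geometry import ElectrodeGeometry

logger = logging.getLogger(__name__)

#: default conduction velocity, m/s (unmyelinated cortical axon scale)
DEFAULT_VELOCITY_M_S = 0.4

#: propagation jitter of burst/transmission delays, ms
DEFAULT_JITTER_MS = 0.5


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthBurst:
    """True extent and per-electrode first-spike latencies of a planted burst."""

    start: float                       # s
    end: float                         # s
    participating_electrodes: frozenset[int]
    per_electrode_first_spike: dict[int, float]  # electrode -> latency, ms

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("burst end must exceed start")
        if not self.participating_electrodes:
            raise ValueError("a burst needs at least one electrode")
        if any(v < 0 for v in self.per_electrode_first_spike.values()):
            raise ValueError("latencies must be non-negative")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class PlantedConnectivity:
    """Directed functional connections to embed in a raster.

    Each edge (i, j) copies presynaptic spikes from electrode i to j
    with probability ``transmission_prob`` at delay distance(i, j) /
    ``velocity_m_s`` — the simulated counterpart of spikes transferred
    from one neuron to another along an axon.
    """

    edges: frozenset[tuple[int, int]]
    transmission_prob: float = 1.0
    velocity_m_s: float = DEFAULT_VELOCITY_M_S

    def __post_init__(self) -> None:
        self.edges = frozenset(tuple(e) for e in self.edges)
        if any(i == j for i, j in self.edges):
            raise ValueError("self-edges are not allowed")
        if not 0.0 <= self.transmission_prob <= 1.0:
            raise ValueError("transmission_prob must lie in [0, 1]")
        if self.velocity_m_s <= 0:
            raise ValueError("velocity must be positive")


@dataclass
class CaGroundTruth:
    """Planted calcium events: per-cell (begin, end) pairs in seconds."""

    events_per_cell: list[list[tuple[float, float]]]
    active_fraction: float
    rate_per_min: float        # realized events/min averaged over active cells
    mean_duration_s: float     # realized mean event duration

    def __post_init__(self) -> None:
        for cell_events in self.events_per_cell:
            last_end = -np.inf
            for begin, end in cell_events:
                if end <= begin:
                    raise ValueError("event end must exceed begin")
                if begin < last_end:
                    raise ValueError("events within a cell must not overlap")
                last_end = end

    @property
    def n_events(self) -> int:
        return sum(len(ev) for ev in self.events_per_cell)

    @property
    def n_active_cells(self) -> int:
        return sum(1 for ev in self.events_per_cell if ev)


# ---------------------------------------------------------------------------
# raw voltage
# ---------------------------------------------------------------------------

def biphasic_waveform(amplitude_uv: float, rate: float, width_ms: float = 1.0) -> np.ndarray:
    """Biphasic extracellular spike template.

    Negative half-sine trough followed by a positive overshoot at half
    amplitude, ``width_ms`` total.  ``amplitude_uv`` is the peak absolute
    value (the trough depth).
    """
    n_half = max(1, int(round(width_ms / 2000.0 * rate)))
    phase = np.sin(np.pi * np.arange(n_half) / n_half)
    return np.concatenate([-amplitude_uv * phase, 0.5 * amplitude_uv * phase])


def generate_raw_recording(
    geometry: ElectrodeGeometry,
    duration_s: float,
    noise_sd_uv: float,
    spike_schedule: list[tuple[int, float, float]],
    seed: int,
    rate: float = 20000.0,
) -> RawRecording:
    """Gaussian noise with biphasic spikes inserted at scheduled times.

    Parameters
    ----------
    spike_schedule
        Iterable of ``(electrode, time_s, amplitude_uv)``; the waveform
        trough lands on the sample nearest ``time_s``.  Amplitudes are
        peak absolute values and must be positive.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if noise_sd_uv < 0:
        raise ValueError("noise SD must be non-negative")
    n = int(round(rate * duration_s))
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd_uv, size=(geometry.n_electrodes, n)) if noise_sd_uv > 0 \
        else np.zeros((geometry.n_electrodes, n))

    for electrode, t, amp in spike_schedule:
        if not 0 <= electrode < geometry.n_electrodes:
            raise ValueError(f"electrode {electrode} out of range")
        if not 0 <= t < duration_s:
            raise ValueError(f"scheduled spike time {t} outside [0, {duration_s})")
        if amp <= 0:
            raise ValueError("spike amplitude must be a positive peak magnitude")
        w = biphasic_waveform(amp, rate)
        # place the trough sample at round(t * rate)
        trough_in_w = int(np.argmax(np.abs(w)))
        start = int(round(t * rate)) - trough_in_w
        lo = max(start, 0)
        hi = min(start + w.size, n)
        if hi > lo:
            x[electrode, lo:hi] += w[lo - start : hi - start]
    return RawRecording(samples=x, rate=rate, geometry=geometry)


# ---------------------------------------------------------------------------
# burst rasters
# ---------------------------------------------------------------------------

def _draw_duration(duration_ms, rng) -> float:
    """Burst duration in seconds from a scalar (ms) or a (lo, hi) ms range."""
    if np.isscalar(duration_ms):
        return float(duration_ms) / 1000.0
    lo, hi = duration_ms
    return float(rng.uniform(lo, hi)) / 1000.0


def generate_burst_raster(
    geometry: ElectrodeGeometry,
    duration_s: float,
    burst_rate_per_min: float,
    burst_duration_ms,
    n_electrodes_per_burst: int,
    background_rate_hz: float,
    velocity_m_s: float = DEFAULT_VELOCITY_M_S,
    origin_policy="random",
    seed: int = 0,
    jitter_ms: float = DEFAULT_JITTER_MS,
    in_burst_rate_hz: float = 100.0,
    min_gap_s: float = 0.1,
) -> tuple[SpikeRaster, list[GroundTruthBurst]]:
    """Raster with planted network bursts over homogeneous Poisson background.

    Bursts are placed by a stationary renewal process: successive starts
    are separated by the burst duration plus a refractory gap of at
    least ``min_gap_s`` plus an exponential waiting time whose mean is
    chosen to approach the requested ``burst_rate_per_min`` (rates are
    capped by non-overlap once the requested rate nears 1 / cycle).

    Within a burst the origin electrode fires first; every other
    participant fires its first spike after distance/velocity plus a
    zero-truncated Gaussian jitter (sd ``jitter_ms``), then continues as
    a Poisson train at ``in_burst_rate_hz`` until the burst end.

    ``burst_duration_ms`` may be a scalar or a ``(lo, hi)`` range in ms
    sampled uniformly per burst.

    ``origin_policy``: "random", "corner" (electrode 0), or a fixed
    electrode index.

    Returns the raster and the list of planted bursts (ground truth).
    """
    if np.isscalar(burst_duration_ms):
        if burst_duration_ms <= 0:
            raise ValueError("burst duration must be positive")
        mean_dur_s = burst_duration_ms / 1000.0
    else:
        lo, hi = burst_duration_ms
        if lo <= 0 or hi < lo:
            raise ValueError("invalid burst duration range")
        mean_dur_s = (lo + hi) / 2000.0
    if burst_rate_per_min < 0:
        raise ValueError("burst rate must be non-negative")
    if not 1 <= n_electrodes_per_burst <= geometry.n_electrodes:
        raise ValueError("n_electrodes_per_burst out of range")

    rng = np.random.default_rng(seed)
    burst_rng, bg_rng = rng.spawn(2)
    dist = geometry.distance_matrix_um()

    electrodes: list[np.ndarray] = []
    times: list[np.ndarray] = []
    ground_truth: list[GroundTruthBurst] = []

    if burst_rate_per_min > 0:
        rate_hz = burst_rate_per_min / 60.0
        mean_extra = max(1.0 / rate_hz - mean_dur_s - min_gap_s, 1e-3)
        t = float(burst_rng.exponential(mean_extra))
        while True:
            dur = _draw_duration(burst_duration_ms, burst_rng)
            if t + dur >= duration_s:
                break
            start, end = t, t + dur
            if origin_policy == "random":
                origin = int(burst_rng.integers(geometry.n_electrodes))
            elif origin_policy == "corner":
                origin = 0
            else:
                origin = int(origin_policy)
            others = np.delete(np.arange(geometry.n_electrodes), origin)
            participants = np.concatenate(
                [[origin],
                 burst_rng.choice(others, size=n_electrodes_per_burst - 1, replace=False)]
            ) if n_electrodes_per_burst > 1 else np.array([origin])

            first_spike_ms: dict[int, float] = {}
            for e in participants:
                base_ms = dist[origin, e] / velocity_m_s / 1000.0  # um / (m/s) -> ms
                jit = burst_rng.normal(0.0, jitter_ms) if jitter_ms > 0 and e != origin else 0.0
                lat_ms = max(base_ms + jit, 0.0)
                lat_ms = min(lat_ms, dur * 1000.0)  # keep the first spike inside the burst
                first_spike_ms[int(e)] = lat_ms
                first_t = start + lat_ms / 1000.0
                n_extra = burst_rng.poisson(in_burst_rate_hz * max(end - first_t, 0.0))
                extra = burst_rng.uniform(first_t, end, size=n_extra) if n_extra else np.empty(0)
                ts = np.concatenate([[first_t], extra])
                ts = ts[ts < duration_s]
                electrodes.append(np.full(ts.size, e, dtype=np.int64))
                times.append(ts)

            ground_truth.append(
                GroundTruthBurst(
                    start=start,
                    end=end,
                    participating_electrodes=frozenset(int(e) for e in participants),
                    per_electrode_first_spike=first_spike_ms,
                )
            )
            t = end + min_gap_s + float(burst_rng.exponential(mean_extra))

    if background_rate_hz > 0:
        for e in range(geometry.n_electrodes):
            n_bg = bg_rng.poisson(background_rate_hz * duration_s)
            if n_bg:
                electrodes.append(np.full(n_bg, e, dtype=np.int64))
                times.append(bg_rng.uniform(0.0, duration_s, size=n_bg))

    if electrodes:
        raster = SpikeRaster(
            electrodes=np.concatenate(electrodes),
            times=np.concatenate(times),
            n_electrodes=geometry.n_electrodes,
            duration=duration_s,
        )
    else:
        raster = SpikeRaster.empty(geometry.n_electrodes, duration_s)
    logger.info(
        "generated burst raster: %d bursts, %d spikes over %.1f s",
        len(ground_truth), raster.n_spikes, duration_s,
    )
    return raster, ground_truth


# ---------------------------------------------------------------------------
# planted connectivity
# ---------------------------------------------------------------------------

def generate_connected_raster(
    connectivity: PlantedConnectivity,
    geometry: ElectrodeGeometry,
    duration_s: float,
    source_rate_hz: float,
    seed: int = 0,
    background_rate_hz: float = 0.0,
    jitter_ms: float = 0.0,
) -> SpikeRaster:
    """Raster realizing a planted directed functional graph.

    Every electrode with outgoing edges fires a homogeneous Poisson
    train at ``source_rate_hz``; each of its spikes is copied to each
    target with probability ``transmission_prob`` at a delay
    distance/velocity (plus optional Gaussian jitter, truncated so the
    delay stays non-negative).  Optional independent Poisson background
    is added on every electrode.
    """
    if source_rate_hz <= 0:
        raise ValueError("source_rate_hz must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    src_rng, edge_rng, bg_rng = rng.spawn(3)
    dist = geometry.distance_matrix_um()

    sources = sorted({i for i, _ in connectivity.edges})
    source_trains: dict[int, np.ndarray] = {}
    for i in sources:
        n_i = src_rng.poisson(source_rate_hz * duration_s)
        source_trains[i] = np.sort(src_rng.uniform(0.0, duration_s, size=n_i))

    electrodes: list[np.ndarray] = []
    times: list[np.ndarray] = []
    for i in sources:
        ts = source_trains[i]
        electrodes.append(np.full(ts.size, i, dtype=np.int64))
        times.append(ts)

    for i, j in sorted(connectivity.edges):
        ts = source_trains[i]
        if ts.size == 0:
            continue
        keep = edge_rng.random(ts.size) < connectivity.transmission_prob
        delay_s = dist[i, j] * 1e-6 / connectivity.velocity_m_s
        copied = ts[keep] + delay_s
        if jitter_ms > 0 and copied.size:
            jit = edge_rng.normal(0.0, jitter_ms / 1000.0, size=copied.size)
            copied = np.maximum(copied + jit, ts[keep])  # delay stays >= 0
        copied = copied[copied < duration_s]
        if copied.size:
            electrodes.append(np.full(copied.size, j, dtype=np.int64))
            times.append(copied)

    if background_rate_hz > 0:
        for e in range(geometry.n_electrodes):
            n_bg = bg_rng.poisson(background_rate_hz * duration_s)
            if n_bg:
                electrodes.append(np.full(n_bg, e, dtype=np.int64))
                times.append(bg_rng.uniform(0.0, duration_s, size=n_bg))

    if not electrodes:
        return SpikeRaster.empty(geometry.n_electrodes, duration_s)
    return SpikeRaster(
        electrodes=np.concatenate(electrodes),
        times=np.concatenate(times),
        n_electrodes=geometry.n_electrodes,
        duration=duration_s,
    )


def basal_spike_schedule(
    geometry: ElectrodeGeometry,
    duration_s: float,
    rate_range_hz: tuple[float, float] = (10.0, 100.0),
    amplitude_range_uv: tuple[float, float] = (30.0, 60.0),
    refractory_s: float = 0.002,
    seed: int = 0,
) -> list[tuple[int, float, float]]:
    """Spike schedule emulating basal culture activity.

    Each electrode fires a Poisson train with a 2 ms refractory gap at
    its own rate, drawn uniformly from ``rate_range_hz`` — the one spike
    per 10-100 ms regime typical of spontaneously active cultures.
    Amplitudes are uniform in ``amplitude_range_uv``.  Heterogeneous
    rates are deliberate: the median-based noise estimate must hold its
    threshold across electrodes that fire at very different rates.
    """
    rng = np.random.default_rng(seed)
    rates = rng.uniform(*rate_range_hz, size=geometry.n_electrodes)
    schedule: list[tuple[int, float, float]] = []
    margin = 0.002  # keep whole waveforms inside the recording
    for e in range(geometry.n_electrodes):
        t = margin
        while True:
            t += float(rng.exponential(1.0 / rates[e])) + refractory_s
            if t >= duration_s - margin:
                break
            schedule.append((e, t, float(rng.uniform(*amplitude_range_uv))))
    return schedule


def planted_hub_connectivity(
    geometry: ElectrodeGeometry,
    n_hubs: int = 16,
    in_degree: int = 4,
    transmission_prob: float = 0.8,
    velocity_m_s: float = 0.1,
    max_shared_inputs: int = 2,
    seed: int = 0,
) -> tuple[list[int], PlantedConnectivity]:
    """Hub-structured directed connectivity that is identifiable by the
    delayed-synchrony method.

    ``n_hubs`` source electrodes each project to the non-hub electrodes
    so that every target receives exactly ``in_degree`` connections and
    no two targets share more than ``max_shared_inputs`` source hubs.
    The overlap cap matters: targets with near-identical input sets
    receive so many coincident copies that the pairwise synchrony
    between them rivals the true input connections (a common-input
    confound inherent to correlation methods), which would make
    ground-truth recovery impossible by construction rather than by
    failure of the inference.

    Returns the hub list and the connectivity object.
    """
    n = geometry.n_electrodes
    if n_hubs * 2 > n:
        raise ValueError("too many hubs for the array")
    rng = np.random.default_rng(seed)
    hubs = sorted(int(h) for h in rng.choice(n, n_hubs, replace=False))
    targets = [e for e in range(n) if e not in hubs]
    capacity = np.full(n_hubs, in_degree * len(targets) / n_hubs)
    blocks: list[frozenset[int]] = []
    for _j in targets:
        blk = frozenset()
        for _attempt in range(200):
            w = np.maximum(capacity, 0.01)
            blk = frozenset(
                int(h) for h in rng.choice(n_hubs, in_degree, replace=False, p=w / w.sum())
            )
            if all(len(blk & b) <= max_shared_inputs for b in blocks):
                break
        blocks.append(blk)
        for h in blk:
            capacity[h] -= 1
    edges = frozenset(
        (hubs[h], int(j)) for j, blk in zip(targets, blocks) for h in blk
    )
    return hubs, PlantedConnectivity(
        edges=edges, transmission_prob=transmission_prob, velocity_m_s=velocity_m_s
    )


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

#: edge length of the transient, in frames: fluorescence rises linearly to
#: the plateau over this many frames and falls back over the same number.
#: Two frames at 4 Hz = 0.5 s, the fast-onset regime of somatic dye signals.
CA_EDGE_FRAMES = 2


def _render_pulse(trace: np.ndarray, i0: int, i1: int, amplitude: float) -> None:
    """Add a trapezoidal transient to frames [i0, i1)."""
    n_f = i1 - i0
    edge = min(CA_EDGE_FRAMES, max(1, n_f // 2))
    profile = np.full(n_f, amplitude)
    ramp = amplitude * np.arange(1, edge + 1) / edge
    profile[:edge] = ramp
    profile[n_f - edge:] = ramp[::-1]
    trace[i0:i1] += profile


def generate_ca_traces(
    n_cells: int,
    active_fraction: float,
    rate_per_min: float,
    mean_duration_s: float,
    amplitude: float = 50.0,
    noise_sd: float = 1.5,
    frame_rate: float = 4.0,
    duration_s: float = 120.0,
    seed: int = 0,
    baseline: float = 20.0,
    duration_jitter: float = 0.1,
) -> tuple[CaTraceSet, CaGroundTruth]:
    """Fluorescence traces with planted calcium transients.

    ``round(n_cells * active_fraction)`` cells carry events; the rest are
    baseline plus noise.  Events are placed by a renewal process whose
    mean cycle approaches ``60 / rate_per_min`` s; durations are Gaussian
    around ``mean_duration_s`` (cv ``duration_jitter``).  Each event is a
    trapezoidal pulse: linear rise over ~0.5 s, plateau at ``amplitude``,
    linear decay over ~0.5 s.  Values are clipped to the camera range
    [0, 255]; systematic clipping at 255 triggers a logged warning.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if n_cells < 1:
        raise ValueError("need at least one cell")

    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    n_active = int(round(n_cells * active_fraction))
    active_cells = set(rng.choice(n_cells, size=n_active, replace=False).tolist())

    min_gap_s = 3.0 / frame_rate  # keep events resolvable (and unmergeable) at 4 Hz
    traces = np.full((n_cells, n_frames), baseline)
    events_per_cell: list[list[tuple[float, float]]] = [[] for _ in range(n_cells)]

    for cell in range(n_cells):
        if cell not in active_cells or rate_per_min <= 0:
            continue
        cycle = 60.0 / rate_per_min
        mean_extra = max(cycle - mean_duration_s - min_gap_s, 0.05)
        t = float(rng.exponential(mean_extra))
        while True:
            dur = float(rng.normal(mean_duration_s, duration_jitter * mean_duration_s))
            dur = max(dur, 3.0 / frame_rate)
            i0 = int(round(t * frame_rate))
            i1 = int(round((t + dur) * frame_rate))
            if i1 >= n_frames - 1:
                break
            _render_pulse(traces[cell], i0, i1, amplitude)
            events_per_cell[cell].append((i0 / frame_rate, i1 / frame_rate))
            t = i1 / frame_rate + min_gap_s + float(rng.exponential(mean_extra))

    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, size=traces.shape)

    clipped_high = np.mean(traces > 255.0)
    if clipped_high > 0.01:
        warnings.warn(
            f"{clipped_high:.1%} of samples clipped at 255; "
            "amplitude + baseline likely too large",
            stacklevel=2,
        )
    np.clip(traces, 0.0, 255.0, out=traces)

    all_events = [ev for cell_ev in events_per_cell for ev in cell_ev]
    n_active_realized = sum(1 for ev in events_per_cell if ev)
    if n_active_realized:
        realized_rate = 60.0 * len(all_events) / duration_s / n_active_realized
        realized_dur = float(np.mean([e - b for b, e in all_events]))
    else:
        realized_rate = 0.0
        realized_dur = float("nan")

    gt = CaGroundTruth(
        events_per_cell=events_per_cell,
        active_fraction=n_active / n_cells,
        rate_per_min=realized_rate,
        mean_duration_s=realized_dur,
    )
    return CaTraceSet(traces=traces, frame_rate=frame_rate), gt
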