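"""File formats for every pipeline stage.

Raw recordings travel as HDF5 (dataset ``/signal``, channels x samples,
float32 microvolts; attributes ``rate`` plus the electrode geometry).
Rasters are CSV with header ``electrode,time_s``; calcium traces are CSV
with one column per cell plus a JSON metadata sidecar; ground truth,
metrics and reports are JSON; graphs export as GraphML and edge-list
CSV.  All writers are deterministic (sorted keys, no timestamps) so a
re-run with the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .bursts import NetworkBurst
from .calcium import CaEvent
from .containers import CaTraceSet, RawRecording, SpikeRaster
from .geometry import ElectrodeGeometry
from .netgraph import Hub, SynchronyGraph, SynchronyMatrix


# --- raw recordings --------------------------------------------------------

def save_recording_h5(path, recording: RawRecording) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signal", data=recording.samples.astype(np.float32))
        ds.attrs["units"] = "uV"
        f.attrs["rate"] = recording.rate
        f.attrs["geometry"] = json.dumps(recording.geometry.to_dict(), sort_keys=True)


def load_recording_h5(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        samples = f["signal"][...].astype(np.float64)
        rate = float(f.attrs["rate"])
        geometry = ElectrodeGeometry.from_dict(json.loads(f.attrs["geometry"]))
    return RawRecording(samples=samples, rate=rate, geometry=geometry)


# --- rasters ---------------------------------------------------------------

def save_raster_csv(path, raster: SpikeRaster) -> None:
    raster.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def load_raster_csv(path, n_electrodes: int = 64, duration: float | None = None) -> SpikeRaster:
    df = pd.read_csv(path)
    if duration is None:
        duration = float(df["time_s"].max()) + 1e-6 if len(df) else 1.0
    return SpikeRaster.from_dataframe(df, n_electrodes=n_electrodes, duration=duration)


# --- calcium ---------------------------------------------------------------

def save_ca_traces_csv(path, traces: CaTraceSet) -> None:
    """One column per cell, one row per frame, plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        traces.traces.T, columns=[f"cell_{c}" for c in range(traces.n_cells)]
    )
    df.to_csv(path, index=False, float_format="%.4f")
    meta = {"frame_rate": traces.frame_rate, "n_cells": traces.n_cells}
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True, indent=1))


def load_ca_traces_csv(path, frame_rate: float | None = None) -> CaTraceSet:
    path = Path(path)
    df = pd.read_csv(path)
    if frame_rate is None:
        meta = json.loads(path.with_suffix(".json").read_text())
        frame_rate = float(meta["frame_rate"])
    return CaTraceSet(traces=df.to_numpy().T, frame_rate=frame_rate)


def save_ca_events_csv(path, events_per_cell: list[list[CaEvent]]) -> None:
    rows = [
        {"cell": e.cell, "begin_s": e.begin, "end_s": e.end, "duration_s": e.duration}
        for ev in events_per_cell
        for e in ev
    ]
    pd.DataFrame(rows, columns=["cell", "begin_s", "end_s", "duration_s"]).to_csv(
        path, index=False, float_format="%.4f"
    )


# --- bursts ----------------------------------------------------------------

def save_bursts_csv(path, bursts: list[NetworkBurst]) -> None:
    rows = [
        {
            "start_s": b.start,
            "end_s": b.end,
            "duration_s": b.duration,
            "n_spikes": b.n_spikes,
        }
        for b in bursts
    ]
    pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s", "n_spikes"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def save_activation_map_csv(path, pattern: np.ndarray) -> None:
    pd.DataFrame(pattern).to_csv(path, index=False, header=False, float_format="%.4f")


# --- graphs ----------------------------------------------------------------

def save_matrix_csv(path, matrix: SynchronyMatrix) -> None:
    pd.DataFrame(matrix.C).to_csv(path, index=False, header=False, float_format="%.6f")


def save_graph(path_graphml, path_edges_csv, graph: SynchronyGraph) -> None:
    nx.write_graphml(graph.to_networkx(), path_graphml)
    pd.DataFrame(graph.edges, columns=["src", "dst", "weight"]).to_csv(
        path_edges_csv, index=False, float_format="%.6f"
    )


def save_hubs_csv(path, hubs: list[Hub]) -> None:
    rows = [
        {"electrode": h.electrode, "degree": h.degree, "hub_coefficient": h.hub_coefficient}
        for h in hubs
    ]
    pd.DataFrame(rows, columns=["electrode", "degree", "hub_coefficient"]).to_csv(
        path, index=False, float_format="%.6f"
    )


# --- generic JSON ----------------------------------------------------------

def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, allow_nan=True))


def load_json(path):
    return json.loads(Path(path).read_text())
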