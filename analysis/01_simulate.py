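#!/usr/bin/env python
"""Generate the synthetic study datasets and summarize their ground truth.

Three datasets mirror the recording modalities of a cultured-network
experiment: (a) a spike raster with planted network bursts over a
Poisson background, (b) a raster realizing a hub-structured directed
functional graph, and (c) calcium traces at the sham-culture presets
(97% active cells, 6.9 oscillations/min, 6.23 s duration).  Downstream
scripts re-generate the same data from the same seeds; this one records
what was planted.
"""

import json
from pathlib import Path

from neuroburst import (
    ElectrodeGeometry,
    generate_burst_raster,
    generate_ca_traces,
    generate_connected_raster,
    planted_hub_connectivity,
)

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    geometry = ElectrodeGeometry()

    raster, bursts = generate_burst_raster(
        geometry, duration_s=60.0, burst_rate_per_min=120.0,
        burst_duration_ms=(100.0, 400.0), n_electrodes_per_burst=8,
        background_rate_hz=0.2, seed=SEED,
    )
    hubs, connectivity = planted_hub_connectivity(geometry, seed=SEED)
    net_raster = generate_connected_raster(
        connectivity, geometry, 300.0, 2.0, seed=SEED + 1,
        background_rate_hz=0.5, jitter_ms=0.1,
    )
    traces, ca_truth = generate_ca_traces(
        100, 0.97, 6.9, 6.23, noise_sd=1.5, duration_s=120.0, seed=SEED,
    )

    summary = {
        "burst_raster": {
            "n_spikes": raster.n_spikes,
            "n_planted_bursts": len(bursts),
            "mean_duration_s": sum(b.duration for b in bursts) / len(bursts),
        },
        "connected_raster": {
            "n_spikes": net_raster.n_spikes,
            "n_planted_edges": len(connectivity.edges),
            "n_planted_hubs": len(hubs),
        },
        "calcium": {
            "n_cells": traces.n_cells,
            "planted_active_cells": ca_truth.n_active_cells,
            "planted_rate_per_min": ca_truth.rate_per_min,
            "planted_mean_duration_s": ca_truth.mean_duration_s,
        },
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "simulation_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    print(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
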