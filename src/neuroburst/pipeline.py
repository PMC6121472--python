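"""End-to-end orchestration: synth -> spikes -> bursts -> netgraph -> calcium.

A run is driven by a config mapping (usually loaded from YAML).  Each
replicate derives a child seed from the top-level seed, runs every
configured stage, and writes its outputs under one directory; metrics
are aggregated across replicates as mean +/- SEM.  All outputs are pure
functions of config + seed, so a re-run is byte-identical.

Config layout (all sections optional except one activity source)::

    seed: 1
    replicates: 3
    group: sham
    synth:
      raster:  {...kwargs of synth.generate_burst_raster...}
      raw:     {...kwargs of synth.generate_raw_recording...}
      calcium: {...kwargs of synth.generate_ca_traces...}
    inputs:
      raster: path.csv        # alternatively: raw: rec.h5, traces: ca.csv
    params:
      spikes:  {ns: 4.0, ...}
      bursts:  {threshold_coef: 0.1, min_electrodes: 4}
      netgraph: {velocity_m_s: 0.4, delta_ms: 2.0, quantile: 0.95}
      calcium: {accuracy_coef: 2.0}
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import bursts as bursts_mod
from . import calcium as ca_mod
from . import io as io_mod
from . import netgraph as net_mod
from . import spikes as spikes_mod
from . import synth as synth_mod
from .geometry import ElectrodeGeometry

logger = logging.getLogger(__name__)

PIPELINE_VERSION = "0.1.0"


@dataclass
class GroupSummary:
    """mean +/- SEM of one metric over replicates."""

    metric: str
    mean: float
    sem: float
    n: int


def summarize(values, metric: str = "") -> GroupSummary:
    """Mean and standard error of the mean of replicate values.

    SEM = sample SD / sqrt(n); a single replicate reports SEM = 0 (the
    n field flags it).
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        raise ValueError(f"empty replicate group for metric {metric!r}")
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return GroupSummary(metric=metric, mean=float(vals.mean()), sem=sem, n=int(vals.size))


def summarize_groups(values_per_group: dict[str, dict[str, list[float]]]) -> dict:
    """Nested {group: {metric: [values]}} -> {group: {metric: summary}}."""
    out: dict = {}
    for group, metrics in values_per_group.items():
        out[group] = {}
        for metric, vals in metrics.items():
            s = summarize(vals, metric)
            out[group][metric] = {"mean": s.mean, "sem": s.sem, "n": s.n}
    return out


def _child_seed(seed: int, replicate: int) -> int:
    # stable, collision-free for practical replicate counts, < 2**31
    return (seed * 1_000_003 + replicate) % (2**31)


def _run_replicate(config: dict, seed: int, outdir: Path, geometry: ElectrodeGeometry) -> dict:
    """Run every configured stage once; returns the replicate's metrics."""
    synth_cfg = config.get("synth", {})
    inputs = config.get("inputs", {})
    params = config.get("params", {})
    metrics: dict[str, float] = {}
    outdir.mkdir(parents=True, exist_ok=True)

    # --- activity source: synthetic or file inputs -------------------------
    raster = None
    if "raw" in synth_cfg:
        rec = synth_mod.generate_raw_recording(
            geometry=geometry, seed=seed, **synth_cfg["raw"]
        )
        io_mod.save_recording_h5(outdir / "recording.h5", rec)
    elif "raw" in inputs:
        rec = io_mod.load_recording_h5(inputs["raw"])
    else:
        rec = None

    if rec is not None:
        sp = spikes_mod.SpikeDetectionParams(**params.get("spikes", {}))
        raster, noise = spikes_mod.detect_spikes(rec, sp)
        io_mod.save_json(
            outdir / "noise.json",
            {
                "sigma_uv": noise.sigma.tolist(),
                "threshold_uv": noise.threshold.tolist(),
            },
        )
        metrics["n_spikes"] = float(raster.n_spikes)

    if raster is None:
        if "raster" in synth_cfg:
            raster, gt = synth_mod.generate_burst_raster(
                geometry=geometry, seed=seed, **synth_cfg["raster"]
            )
            io_mod.save_json(
                outdir / "ground_truth_bursts.json",
                [
                    {
                        "start": b.start,
                        "end": b.end,
                        "electrodes": sorted(b.participating_electrodes),
                    }
                    for b in gt
                ],
            )
        elif "raster" in inputs:
            raster = io_mod.load_raster_csv(
                inputs["raster"], n_electrodes=geometry.n_electrodes
            )

    if raster is not None:
        io_mod.save_raster_csv(outdir / "raster.csv", raster)

        # --- bursts --------------------------------------------------------
        bp = bursts_mod.BurstDetectionParams(**params.get("bursts", {}))
        tsr = bursts_mod.compute_tsr(raster, bp.bin_width_ms)
        detected = bursts_mod.detect_bursts(tsr, raster, bp)
        io_mod.save_bursts_csv(outdir / "bursts.csv", detected)
        bm = bursts_mod.burst_metrics(detected, raster.duration)
        metrics["bursts_per_10min"] = bm.bursts_per_10min
        if bm.mean_spikes_per_burst is not None:
            metrics["mean_spikes_per_burst"] = bm.mean_spikes_per_burst
        if detected:
            pattern = bursts_mod.activation_pattern(detected, geometry)
            io_mod.save_activation_map_csv(outdir / "activation_map.csv", pattern)

        # --- functional graph ---------------------------------------------
        np_cfg = dict(params.get("netgraph", {}))
        quantile = np_cfg.pop("quantile", 0.95)
        sp_params = net_mod.SynchronyParams(quantile=quantile, **np_cfg)
        if np.count_nonzero(raster.spike_counts()) >= 2:
            matrix = net_mod.synchrony_matrix(raster, geometry, sp_params)
            graph = net_mod.select_edges(matrix, quantile)
            hubs = net_mod.identify_hubs(graph)
            io_mod.save_matrix_csv(outdir / "synchrony_matrix.csv", matrix)
            io_mod.save_graph(outdir / "graph.graphml", outdir / "edges.csv", graph)
            io_mod.save_hubs_csv(outdir / "hubs.csv", hubs)
            metrics["n_edges"] = float(graph.n_edges)
            metrics["n_hubs"] = float(len(hubs))
            if hubs:
                metrics["connections_per_hub"] = float(np.mean([h.degree for h in hubs]))

    # --- calcium -----------------------------------------------------------
    traces = None
    if "calcium" in synth_cfg:
        traces, ca_gt = synth_mod.generate_ca_traces(seed=seed, **synth_cfg["calcium"])
        io_mod.save_ca_traces_csv(outdir / "ca_traces.csv", traces)
        io_mod.save_json(
            outdir / "ground_truth_ca.json",
            {
                "active_fraction": ca_gt.active_fraction,
                "rate_per_min": ca_gt.rate_per_min,
                "mean_duration_s": ca_gt.mean_duration_s,
                "n_events": ca_gt.n_events,
            },
        )
    elif "traces" in inputs:
        traces = io_mod.load_ca_traces_csv(inputs["traces"])

    if traces is not None:
        cp = ca_mod.CaDetectionParams(**params.get("calcium", {}))
        events = ca_mod.detect_ca_events_set(traces, cp)
        io_mod.save_ca_events_csv(outdir / "ca_events.csv", events)
        cm = ca_mod.ca_metrics(events, traces.n_cells, traces.duration)
        metrics["pct_active_cells"] = cm.pct_active_cells
        if cm.freq_per_min is not None:
            metrics["ca_freq_per_min"] = cm.freq_per_min
        if cm.mean_duration_s is not None:
            metrics["ca_mean_duration_s"] = cm.mean_duration_s

    io_mod.save_json(outdir / "metrics.json", metrics)
    return metrics


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages for every replicate and summarize.

    Returns the run report (also written to ``report.json``): pipeline
    version, config echo, per-replicate metrics and mean +/- SEM
    summaries.  Stage timing goes to the log stream only, never into
    the outputs, so identical config + seed reproduce identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    replicates = int(config.get("replicates", 1))
    if replicates < 1:
        raise ValueError("need at least one replicate")
    group = str(config.get("group", "default"))
    geometry = ElectrodeGeometry.from_dict(config.get("geometry", {}))

    t0 = time.perf_counter()
    per_replicate: list[dict] = []
    for r in range(replicates):
        rep_seed = _child_seed(seed, r)
        rep_dir = out_dir / f"replicate_{r:02d}"
        logger.info("replicate %d (seed %d) -> %s", r, rep_seed, rep_dir)
        try:
            per_replicate.append(_run_replicate(config, rep_seed, rep_dir, geometry))
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc

    metric_names = sorted({k for m in per_replicate for k in m})
    summaries = summarize_groups(
        {group: {name: [m.get(name) for m in per_replicate] for name in metric_names}}
    )
    report = {
        "pipeline_version": PIPELINE_VERSION,
        "seed": seed,
        "replicates": replicates,
        "group": group,
        "config": {k: v for k, v in config.items() if k != "inputs" or v},
        "per_replicate": per_replicate,
        "summary": summaries,
    }
    io_mod.save_json(out_dir / "report.json", report)
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return report
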