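# neuroburst

Analysis pipeline for spontaneous neural-network activity recorded from
cultured neurons: 64-electrode multielectrode-array (MEA) voltage
recordings and 4 Hz calcium-imaging traces.  It implements the full
chain from raw signal to network-level readouts —

1. **Spike detection** — each channel is band-pass filtered (0.3–8 kHz,
   zero-phase Butterworth) and thresholded at

   *T = N*<sub>s</sub> · *σ*,  *σ* = median(|*x*|) / 0.6745,

   where 0.6745 is the 0.75 quantile of the standard normal: the median
   absolute signal normalized to the noise SD.  Unlike an SD-based
   estimate, the median barely moves with firing rate, so the threshold
   stays put whether an electrode fires at 10 Hz or 100 Hz.
   *N*<sub>s</sub> = 4 by default, minimal interspike interval 1 ms.

2. **Network bursts** — the total spiking rate TSR(*t*) counts spikes
   from all electrodes in 50 ms bins.  A small network burst is a
   maximal run of bins with TSR > 0.1 · σ<sub>TSR</sub> involving ≥ 4
   distinct electrodes, refined to the first/last spike inside the run.
   Per-burst first-spike latencies give the 8×8 **activation pattern**
   (where bursts start and how fast they propagate).

3. **Functional graph** — for every ordered electrode pair (*i*, *j*)
   the fraction of "delayed synchronous" spikes
   *C*<sub>ij</sub> = *n*<sub>synchr</sub> / *n*<sub>j</sub> counts
   spikes on *j* preceded by a spike on *i* at the axonal delay
   τ<sub>ij</sub> = distance/velocity within a tolerance δ.  The largest
   5% of entries form the graph; electrodes with exceptionally many
   incident connections are **hubs**, each with a hub coefficient
   (incident connections / total connections) and a Jaccard-based
   percentage overlap between sessions.

4. **Calcium transients** — traces (relative units 0–255) are smoothed
   by neighbour averaging, differentiated, and thresholded at an
   accuracy coefficient times the derivative SD pooled across cells;
   pulses run from the positive crossing to the end of the following
   negative excursion.  Population metrics: % active cells,
   oscillations/min, mean duration.

Because raw culture recordings are not distributable, the package ships
a first-class **synthetic generator** (`neuroburst.synth`) that plants
ground truth for every stage — scheduled biphasic spikes in Gaussian
noise, network bursts with distance-proportional propagation delays,
directed connectivity realized by probabilistic spike transmission, and
calcium events at configurable rate/duration — so every claim the
pipeline makes is verified by recovery of known structure.

## Worked example

```python
import neuroburst as nb

geometry = nb.ElectrodeGeometry()          # 8x8, 150 um pitch

# plant ~2 bursts/s of 100-400 ms over sparse background, then detect
raster, truth = nb.generate_burst_raster(
    geometry, duration_s=60.0, burst_rate_per_min=120.0,
    burst_duration_ms=(100.0, 400.0), n_electrodes_per_burst=8,
    background_rate_hz=0.2, seed=1,
)
tsr = nb.compute_tsr(raster)               # 50 ms bins
bursts = nb.detect_bursts(tsr, raster)
m = nb.burst_metrics(bursts, raster.duration)
print(len(truth), len(bursts), round(m.bursts_per_10min, 1), round(m.mean_spikes_per_burst))
```

prints `116 116 1160.0 206`: all 116 planted bursts are detected, a
rate of 1160 bursts per 10 min and a mean of 206 spikes per burst.
Matching each planted burst to its detected counterpart gives a median
duration error of about 4% (see `analysis/03_burst_recovery.py`).

The numbered scripts under `analysis/` walk through every stage the
same way — simulation, spike-detection calibration (sensitivity 1.00,
false positives ≈ 0.38/s/electrode at *N*<sub>s</sub> = 4 under basal
activity), burst-duration recovery, functional-graph recovery (edge
Jaccard 0.95, all 16 planted hubs found), and calcium metrics (97/100
active cells, 6.6 osc/min, 6.24 s vs planted 6.68 osc/min, 6.22 s) —
writing their tables to `results/`.

A `neuroburst` CLI mirrors the stages (`synth`, `spikes detect`,
`bursts detect`, `netgraph build`, `calcium detect`, `run`); `run`
drives the whole pipeline from a YAML config with per-replicate child
seeds and writes a mean ± SEM summary report.

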