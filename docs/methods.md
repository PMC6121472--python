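# Methods

This note documents the models, parameters and numerical choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the known limitations.

## Array geometry

A planar 8×8 grid of 64 electrodes, 50×50 µm sites on a 150 µm pitch,
row-major indexing.  Inter-electrode distance enters twice: activation
patterns are read against it, and the synchrony stage converts it to an
axonal conduction delay τ = distance / velocity.

## Spike detection

The detection threshold per channel is T = N_s·σ with
σ = median(|x|)/0.6745, x the 0.3–8 kHz band-passed signal.  0.6745 is
the 0.75 quantile of the standard normal: for zero-mean Gaussian noise,
median(|X|) = 0.6745·σ, so the estimator reads the noise SD off the
median.  Its virtue is robustness: spikes occupy few samples, so even
vigorous firing moves the median only a few percent where it would
inflate an SD estimate severalfold.

Choices and defaults:

- N_s = 4, band 300–8000 Hz, minimal ISI 1 ms.
- Filter: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase, so spike times are not shifted.
- Detection is on |x| (both polarities); the spike time is the sample
  of maximum |x| within each suprathreshold run; later crossings within
  the minimal ISI of an accepted spike are discarded (causal sweep).
- σ is estimated on the whole channel.  A channel whose σ is exactly 0
  (an all-zero synthetic channel) is treated as silent rather than
  detected on everything.

False-positive budget.  For Gaussian noise the |x| > 4σ crossing rate
at 20 kHz is ≈ 0.8–1.2 events/s — irreducible at N_s = 4 on a truly
silent channel, since the threshold then sits at exactly 4 noise SDs.
In the operating regime this pipeline targets, electrodes carry basal
activity (one spike per 10–100 ms); the spike samples nudge the median
estimate up a few percent, and because the crossing rate falls as
exp(−T²/2σ²), that small inflation cuts false positives to
≈ 0.4/s/electrode while leaving sensitivity at 1.0 for ≥ 30 µV spikes
on 5 µV noise.  The calibration scripts and tests therefore score the
detector under basal-activity schedules (heterogeneous 10–100 Hz
per-electrode rates, 2 ms refractory, amplitudes 30–60 µV), which is
the regime the median normalization exists for.

## Network bursts

TSR(t) = total spikes across all electrodes per 50 ms bin (half-open
bins).  Burst threshold T_burst = 0.1 × SD(TSR) over the full series,
silent bins included.  A burst is a maximal run of bins above T_burst
containing at least one bin with ≥ 4 distinct active electrodes; the
run's edges are refined to the first/last spike inside it, which is
what makes sub-bin duration estimates possible at 50 ms resolution.
Runs separated by even one subthreshold bin are not merged.

- "≥ 4 electrodes" is the default reading of the multi-electrode
  criterion; the count is configurable.
- The null behaviour is rate-dependent: for quiet recordings T_burst is
  below a single spike, so chance bursts are rejected only by the
  4-electrode bin criterion.  With Poisson background at rate r per
  electrode the false-burst rate is ≈ P(Poisson(64·r·0.05) ≥ 4) per
  bin: < 1/min for r ≲ 0.1 Hz, but ~20/min by 0.3 Hz.  Burst detection
  presumes genuinely sparse background between bursts.
- Duration recovery: across burst rates 0.5–5 Hz (durations 100–1000 ms
  where they fit between cycles) the median relative duration error is
  ≈ 4%, within the 10% figure the TSR method is known for.  At 5 Hz the
  inter-burst gap is held ≥ 100 ms so consecutive bursts keep at least
  one empty bin between them regardless of bin alignment.

Activation pattern: per electrode, the median over bursts of its
first-spike latency (ms from burst start), arranged 8×8; electrodes
never firing in a burst are NaN.  The median is used because single
bursts are noisy realizations; with zero jitter the map equals
distance/velocity from the origin exactly.

## Delayed-synchrony graph and hubs

C[i,j] = n_synchr/n_j, where n_synchr counts spikes on j with at least
one spike on i inside the closed window
[t_j − τ_ij − δ/2, t_j − τ_ij + δ/2].  Each postsynaptic spike counts
at most once, so C ≤ 1; electrodes with n_j = 0 are flagged undefined
and reported as 0.  The implementation uses sorted per-electrode trains
and binary search; tests pin it, exactly, to a naive all-pairs scan.

- δ defaults to 2 ms and the conduction velocity to 0.4 m/s
  (unmyelinated-axon scale); both are exposed because neither is
  universal.
- Edge selection: threshold at the empirical 95% quantile of all
  defined off-diagonal entries, keep entries strictly above it.  Strict
  inequality is deterministic and order-independent; for continuous
  weights the boundary carries no mass.  An all-equal matrix is
  degenerate and yields no edges (warning).
- Hubs: by default, electrodes whose incident degree (in + out) exceeds
  the 90th percentile of nonzero degrees; an explicit minimum degree
  can be given instead.  Hub coefficient = degree / total edges; the
  coefficients sum to 2 whenever edges exist.
- Hub overlap between sessions = 100 · |A∩B| / |A∪B| (Jaccard).

Identifiability limitation.  Delay-window correlation cannot tell a
direct connection from common input when the geometry makes their
delays compatible: two targets of one source receive coincident copies,
and if |d(h,j) − d(h,j′) − d(j′,j)| / v < δ/2 (near-collinear triples,
short pairs) the co-target pair scores as highly as a true edge.
Equally, at v = 0.4 m/s the whole array spans < 4 ms of delay, so a
2 ms window blurs most of the delay structure.  The planted-network
recovery scenario (`planted_hub_connectivity`) therefore uses a slower
propagation speed (0.1 m/s, the scale of activity propagation in
cultured networks), δ = 0.5 ms with 0.1 ms transmission jitter, and
caps the shared-input overlap of any two targets at 2 of their 4
sources; 16 hubs × 12 targets ≈ 192 planted edges, comparable to the
~202-edge top-5% budget, since Jaccard against a fixed-size selection
is only meaningful when truth and selection have comparable cardinality.
Under those conditions edge recovery reaches Jaccard ≈ 0.95 and all
planted hubs are found (explicit min-degree 8; with a quarter of the
electrodes being hubs, a 90th-percentile rule cannot flag them all by
construction).  On real data the confounds remain; selected edges are
functional, not anatomical.

## Calcium transients

Each trace (relative units 0–255, 4 Hz) is smoothed by averaging
neighbouring frames, differentiated by first differences, and
thresholded at accuracy_coef × SD(derivative).  A pulse begins at the
first frame whose derivative exceeds +threshold and ends at the last
frame of the following run below −threshold; a pulse still open at the
trace end closes there.  Events separated by < 2 frames are merged.

- accuracy_coef defaults to 2.0.
- Threshold scope: the population detector pools the derivative SD
  across all cells of a recording.  A per-trace threshold is
  scale-free — on a silent cell it shrinks to that cell's own noise and
  fires at ~3 events/min regardless of how small the noise is, so every
  quiet cell would read as active.  Pooling ties quiet cells to the
  population's signal scale, which is what makes "% active cells" a
  meaningful readout.  The single-trace function keeps the per-trace
  threshold (and accepts an explicit override).
- Null calibration: on an all-noise population the pooled and per-trace
  thresholds coincide, and the false-event rate at coef 2 is ≈ 3/min —
  an inherent property of single-frame derivative thresholding of
  Gaussian noise (≈ 2.3% exceedance per frame).  It drops below
  0.5/min at coef 3, which is the documented operating point for
  recordings that may contain no activity at all.

Generator: active cells receive trapezoidal pulses — linear rise over 2
frames (0.5 s), plateau at the configured amplitude (default 50 RU over
a baseline of 20), linear decay over 2 frames — placed by a renewal
process whose mean cycle matches the requested rate, with duration
jitter (cv 0.1) and a ≥ 3-frame gap so events stay resolvable at 4 Hz.
The fast edges reflect the onset kinetics of somatic dye signals at
this frame rate and concentrate the derivative where the detector looks
for it; a decay stretched over seconds would smear the event end below
any threshold the rise can clear, because at the preset duty cycle
(6.9/min × 6.23 s ≈ 72% of the trace inside events) the derivative SD
is dominated by the pulses themselves.  Traces are clipped to [0, 255];
systematic clipping warns.  Not emulated: photobleaching, motion, ROI
segmentation, ΔF/F variants — traces are taken as given, so passing
tests validate the event detector and metrics, not image processing.

At the sham presets (97/100 active cells, 6.9 osc/min, 6.23 s, noise
sd 1.5 RU) detection recovers the active-cell count exactly and the
frequency and duration within a few percent; duration is quantized by
the 0.25 s frame period.

## Synthetic raw voltage

Gaussian noise of configurable SD plus a biphasic template per
scheduled spike: a 0.5 ms negative half-sine trough (peak = the stated
amplitude) followed by a 0.5 ms positive overshoot at half amplitude,
the trough landing on the sample nearest the scheduled time.  The 1 ms
biphasic shape puts its energy near 1 kHz, inside the detection band.
Not emulated: spatial spread across neighbouring electrodes, electrode
drift, non-Gaussian noise.

## Bursts and connectivity generators

Burst placement is a stationary renewal process: each cycle is the
burst duration plus a refractory gap (≥ 100 ms) plus an exponential
wait calibrated to the requested rate; rates are capped by non-overlap.
Within a burst the origin electrode (random, fixed, or corner) fires
first and every participant's first spike follows at
distance/velocity + zero-truncated Gaussian jitter (sd 0.5 ms), then
continues as a 100 Hz Poisson train to the burst end.  Background is
homogeneous Poisson per electrode.

Connectivity rasters: electrodes with outgoing edges fire Poisson
trains; each spike is copied to each target with the transmission
probability at delay distance/velocity (+ optional jitter, truncated so
the delay stays non-negative) — delayed-synchronous pairs by
construction.

Seeding: every generator takes one integer seed; independent child
streams are spawned deterministically, so identical inputs give
bit-identical outputs (the pipeline's reports are byte-identical across
re-runs; timing information goes to the log stream, never into files).

## Pipeline and summaries

`run_pipeline` executes synth (optional) → spikes → bursts → netgraph →
calcium per replicate, with child seeds derived from the top-level
seed, and aggregates each metric as mean ± SEM (sample SD/√n; a single
replicate reports SEM 0 with n = 1).  Formal between-group hypothesis
testing is out of scope; per-replicate values are exposed for external
statistics.

## Problem sizes

Default validation sizes are chosen so the whole suite runs in well
under a minute of CPU: 6 s of 64-channel 20 kHz voltage for detector
calibration, 4 × 60 s rasters for the burst sweep (~470 planted
bursts), one 300 s connectivity raster, 100 calcium cells × 120 s.
All scale linearly with duration if tighter confidence intervals are
wanted.
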