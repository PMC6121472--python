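"""TSR computation, burst segmentation, metrics and activation patterns."""

import numpy as np
import pytest

from neuroburst import (
    BurstDetectionParams,
    SpikeRaster,
    activation_pattern,
    burst_metrics,
    compute_tsr,
    detect_bursts,
    generate_burst_raster,
)
from tests.conftest import random_raster


class TestComputeTSR:
    def test_empty_raster_gives_all_zero_bins(self):
        raster = SpikeRaster.empty(64, 600.0)
        tsr = compute_tsr(raster, 50.0)
        assert tsr.n_bins == 12000
        assert not tsr.counts.any()

    def test_spikes_in_one_bin(self):
        raster = SpikeRaster(
            electrodes=np.arange(10) % 64,
            times=np.full(10, 0.01),
            n_electrodes=64,
            duration=1.0,
        )
        tsr = compute_tsr(raster, 50.0)
        assert tsr.counts[0] == 10
        assert tsr.counts[1:].sum() == 0
        assert tsr.active_electrodes[0] == 10

    def test_total_count_conserved(self):
        raster = random_raster(10_000, 64, 120.0, seed=1)
        tsr = compute_tsr(raster, 50.0)
        assert tsr.counts.sum() == 10_000

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ValueError):
            compute_tsr(SpikeRaster.empty(64, 1.0), 0.0)


class TestDetectBursts:
    def test_silent_raster_has_no_bursts(self):
        raster = SpikeRaster.empty(64, 60.0)
        assert detect_bursts(compute_tsr(raster), raster) == []

    def test_three_electrode_run_fails_four_electrode_criterion(self):
        # dense volley confined to 3 electrodes must not qualify
        times = np.sort(np.random.default_rng(0).uniform(1.0, 1.1, 60))
        electrodes = np.tile([0, 1, 2], 20)
        raster = SpikeRaster(electrodes, times, 64, 60.0)
        bursts = detect_bursts(compute_tsr(raster), raster)
        assert bursts == []

    def test_four_electrode_run_qualifies(self):
        times = np.sort(np.random.default_rng(0).uniform(1.0, 1.1, 60))
        electrodes = np.tile([0, 1, 2, 3], 15)
        raster = SpikeRaster(electrodes, times, 64, 60.0)
        bursts = detect_bursts(compute_tsr(raster), raster)
        assert len(bursts) == 1
        assert bursts[0].start == pytest.approx(times[0])
        assert bursts[0].end == pytest.approx(times[-1])
        assert bursts[0].n_spikes == 60

    def test_planted_duration_recovery_within_ten_percent(self, geometry):
        errs = []
        for rate_hz, dur_rng, seed in [(0.5, (100, 1000), 1), (5.0, (100, 150), 2)]:
            raster, gt = generate_burst_raster(
                geometry, 60.0, rate_hz * 60.0, dur_rng, 8, 0.2, seed=seed
            )
            bursts = detect_bursts(compute_tsr(raster), raster)
            for b in gt:
                overlaps = [
                    (min(b.end, d.end) - max(b.start, d.start), d) for d in bursts
                ]
                ov, best = max(overlaps, key=lambda x: x[0], default=(0, None))
                errs.append(
                    abs(best.duration - b.duration) / b.duration if ov > 0 else 1.0
                )
        assert np.median(errs) <= 0.10

    def test_lower_threshold_expands_suprathreshold_coverage(self):
        # lowering the coefficient grows the suprathreshold bin set, so
        # every burst found at a high threshold lies inside one found at
        # a lower threshold (run counts themselves are not monotone:
        # neighbouring runs merge as the gap bins rise above threshold)
        raster = random_raster(3000, 64, 60.0, seed=3)
        tsr = compute_tsr(raster)
        by_coef = {
            c: detect_bursts(tsr, raster, BurstDetectionParams(threshold_coef=c,
                                                               min_electrodes=1))
            for c in (2.0, 1.0, 0.5, 0.1)
        }
        coefs = sorted(by_coef, reverse=True)
        for hi_c, lo_c in zip(coefs, coefs[1:]):
            for b in by_coef[hi_c]:
                assert any(
                    lo.start <= b.start and lo.end >= b.end for lo in by_coef[lo_c]
                )

    def test_low_rate_poisson_background_rarely_bursts(self, geometry):
        # pure background at 0.1 Hz/electrode: false bursts < 1/min.
        # for quiet recordings the TSR threshold 0.1*SD sits below one
        # spike, so the >=4-distinct-electrodes criterion is what rejects
        # chance pile-ups; it bounds the false rate only when the
        # expected bin occupancy 64*r*50ms stays well under 4
        raster, _ = generate_burst_raster(geometry, 300.0, 0.0, 100.0, 8, 0.1, seed=4)
        bursts = detect_bursts(compute_tsr(raster), raster)
        assert len(bursts) / (300.0 / 60.0) < 1.0


class TestBurstMetrics:
    def test_no_bursts(self):
        m = burst_metrics([], 600.0)
        assert m.n_bursts == 0
        assert m.bursts_per_10min == 0.0
        assert m.mean_spikes_per_burst is None

    def test_rate_scaling_to_ten_minutes(self):
        from neuroburst.bursts import NetworkBurst

        bursts = [
            NetworkBurst(start=i * 2.0, end=i * 2.0 + 0.2, n_spikes=100 + 100 * (i % 2),
                         first_spike_latency_ms={0: 0.0})
            for i in range(93)
        ]
        m = burst_metrics(bursts, 300.0)
        assert m.bursts_per_10min == pytest.approx(186.0)
        assert m.mean_spikes_per_burst == pytest.approx(150.0, abs=1.0)


class TestActivationPattern:
    def test_empty_burst_list_rejected(self, geometry):
        with pytest.raises(ValueError):
            activation_pattern([], geometry)

    def test_single_burst_latency_passthrough(self, geometry):
        from neuroburst.bursts import NetworkBurst

        b = NetworkBurst(start=0.0, end=0.1, n_spikes=5,
                         first_spike_latency_ms={5: 7.0})
        pattern = activation_pattern([b], geometry)
        assert pattern[0, 5] == pytest.approx(7.0)
        assert np.isnan(pattern).sum() == 63

    def test_zero_jitter_pattern_equals_distance_over_velocity(self, geometry):
        v = 0.4
        raster, gt = generate_burst_raster(
            geometry, 60.0, 60.0, 300.0, 64, 0.0,
            velocity_m_s=v, origin_policy="corner", seed=6, jitter_ms=0.0,
        )
        bursts = detect_bursts(compute_tsr(raster), raster)
        pattern = activation_pattern(bursts, geometry).ravel()
        dist = geometry.distance_matrix_um()
        expected = dist[0] * 1e-6 / v * 1000.0  # ms
        assert np.allclose(pattern, expected, atol=1e-6)

    def test_jittered_pattern_within_one_ms_of_planted(self, geometry):
        v = 0.4
        raster, gt = generate_burst_raster(
            geometry, 120.0, 60.0, 300.0, 64, 0.0,
            velocity_m_s=v, origin_policy="corner", seed=7, jitter_ms=0.5,
        )
        bursts = detect_bursts(compute_tsr(raster), raster)
        pattern = activation_pattern(bursts, geometry).ravel()
        dist = geometry.distance_matrix_um()
        expected = dist[0] * 1e-6 / v * 1000.0
        assert np.nanmean(np.abs(pattern - expected)) < 1.0
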