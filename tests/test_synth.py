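"""Ground-truth generators: determinism, conservation, rate calibration."""

import numpy as np
import pytest
from scipy import stats

from neuroburst import (
    PlantedConnectivity,
    generate_burst_raster,
    generate_ca_traces,
    generate_connected_raster,
    generate_raw_recording,
)


class TestRawRecording:
    def test_silent_recording_is_all_zero(self, geometry):
        rec = generate_raw_recording(geometry, 1.0, 0.0, [], seed=0)
        assert rec.samples.shape == (64, 20000)
        assert np.all(rec.samples == 0.0)

    def test_single_spike_peak_amplitude_and_channel_isolation(self, geometry):
        rec = generate_raw_recording(
            geometry, 1.0, 0.0, [(0, 0.5, 30.0)], seed=0
        )
        assert np.abs(rec.samples[0]).max() == pytest.approx(30.0)
        assert np.argmax(np.abs(rec.samples[0])) == 10000  # trough at 0.5 s
        assert np.all(rec.samples[1:] == 0.0)

    def test_noise_sd_matches_request(self, geometry):
        rec = generate_raw_recording(geometry, 10.0, 5.0, [], seed=1)
        sds = rec.samples.std(axis=1)
        assert np.all(np.abs(sds - 5.0) / 5.0 < 0.02)

    def test_identical_seed_is_bit_identical(self, geometry):
        a = generate_raw_recording(geometry, 0.5, 5.0, [(3, 0.1, 40.0)], seed=7)
        b = generate_raw_recording(geometry, 0.5, 5.0, [(3, 0.1, 40.0)], seed=7)
        assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize(
        "schedule", [[(0, 2.0, 30.0)], [(0, 0.5, -30.0)], [(99, 0.5, 30.0)]]
    )
    def test_invalid_schedule_rejected(self, geometry, schedule):
        with pytest.raises(ValueError):
            generate_raw_recording(geometry, 1.0, 0.0, schedule, seed=0)


class TestBurstRaster:
    def test_no_bursts_no_background_is_empty(self, geometry):
        raster, gt = generate_burst_raster(geometry, 10.0, 0.0, 100.0, 8, 0.0, seed=0)
        assert raster.n_spikes == 0
        assert gt == []

    def test_burst_count_near_requested_rate(self, geometry):
        # 60 bursts/min for 60 s; renewal count within the Poisson 99% band
        _, gt = generate_burst_raster(geometry, 60.0, 60.0, 200.0, 8, 0.0, seed=42)
        lo = stats.poisson.ppf(0.005, 60)
        hi = stats.poisson.ppf(0.995, 60)
        assert lo <= len(gt) <= hi

    def test_zero_jitter_latency_is_distance_over_velocity(self, geometry):
        v = 0.4
        raster, gt = generate_burst_raster(
            geometry, 30.0, 30.0, 200.0, 8, 0.0,
            velocity_m_s=v, origin_policy="corner", seed=3, jitter_ms=0.0,
        )
        dist = geometry.distance_matrix_um()
        for b in gt:
            for e, lat_ms in b.per_electrode_first_spike.items():
                assert lat_ms == pytest.approx(dist[0, e] * 1e-6 / v * 1000.0)

    def test_ground_truth_spikes_present_and_conserved(self, geometry):
        raster, gt = generate_burst_raster(geometry, 30.0, 60.0, 150.0, 6, 0.0, seed=5)
        assert gt
        # with no background, every raster spike lies inside a planted burst
        inside = np.zeros(raster.n_spikes, dtype=bool)
        for b in gt:
            inside |= (raster.times >= b.start) & (raster.times <= b.end)
        assert inside.all()
        # and every first spike is present on its electrode
        for b in gt:
            for e, lat_ms in b.per_electrode_first_spike.items():
                t = b.start + lat_ms / 1000.0
                assert np.isclose(raster.times[raster.electrodes == e], t).any()

    def test_background_rate_calibration(self, geometry):
        raster, _ = generate_burst_raster(geometry, 600.0, 0.0, 100.0, 8, 2.0, seed=9)
        per_electrode = raster.n_spikes / 64 / 600.0
        assert per_electrode == pytest.approx(2.0, rel=0.05)

    def test_determinism(self, geometry):
        a, _ = generate_burst_raster(geometry, 20.0, 60.0, 150.0, 8, 1.0, seed=11)
        b, _ = generate_burst_raster(geometry, 20.0, 60.0, 150.0, 8, 1.0, seed=11)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.electrodes, b.electrodes)

    def test_invalid_duration_rejected(self, geometry):
        with pytest.raises(ValueError):
            generate_burst_raster(geometry, 10.0, 60.0, -5.0, 8, 0.0, seed=0)


class TestConnectedRaster:
    def test_full_transmission_copies_every_spike_at_exact_delay(self, geometry):
        pc = PlantedConnectivity(frozenset({(0, 7)}), 1.0, 0.4)
        raster = generate_connected_raster(pc, geometry, 100.0, 2.0, seed=1)
        src = raster.times_on(0)
        dst = raster.times_on(7)
        delay = geometry.distance_um(0, 7) * 1e-6 / 0.4
        expected = src + delay
        expected = expected[expected < 100.0]
        assert dst.size == expected.size
        assert np.allclose(np.sort(dst), np.sort(expected))

    def test_zero_transmission_leaves_target_silent(self, geometry):
        pc = PlantedConnectivity(frozenset({(0, 7)}), 0.0, 0.4)
        raster = generate_connected_raster(pc, geometry, 50.0, 5.0, seed=2)
        assert raster.times_on(7).size == 0

    def test_half_transmission_count_in_binomial_band(self, geometry):
        pc = PlantedConnectivity(frozenset({(0, 7)}), 0.5, 0.4)
        # ~10^4 source spikes
        raster = generate_connected_raster(pc, geometry, 1000.0, 10.0, seed=3)
        n_src = raster.times_on(0).size
        n_dst = raster.times_on(7).size
        band = stats.binom.interval(0.99, n_src, 0.5)
        assert band[0] <= n_dst <= band[1]

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError):
            PlantedConnectivity(frozenset({(3, 3)}), 1.0, 0.4)


class TestCaTraces:
    def test_inactive_population_has_no_events(self):
        traces, gt = generate_ca_traces(10, 0.0, 6.9, 6.23, duration_s=60.0, seed=0)
        assert gt.n_events == 0
        assert gt.n_active_cells == 0
        assert traces.n_cells == 10

    def test_event_spans_requested_frames(self):
        traces, gt = generate_ca_traces(
            1, 1.0, 6.0, 6.0, noise_sd=0.0, duration_s=60.0, seed=1
        )
        begin, end = gt.events_per_cell[0][0]
        n_frames = int(round((end - begin) * traces.frame_rate))
        assert n_frames == pytest.approx(24, abs=3)  # 6 s at 4 Hz, duration jitter
        above = traces.traces[0] > 20.0 + 1e-9
        # frames above baseline within the event window
        i0, i1 = int(begin * 4), int(end * 4)
        assert above[i0:i1].all()

    def test_active_cell_count_follows_rounding(self):
        _, gt = generate_ca_traces(100, 0.97, 6.9, 6.23, duration_s=30.0, seed=2)
        assert gt.n_active_cells == 97

    def test_event_rate_and_duration_calibration(self):
        _, gt = generate_ca_traces(50, 1.0, 6.9, 6.23, duration_s=300.0, seed=3)
        # mean over ~50*34 events: sampling error a few percent
        assert gt.rate_per_min == pytest.approx(6.9, rel=0.10)
        assert gt.mean_duration_s == pytest.approx(6.23, rel=0.10)

    def test_events_never_overlap_within_cell(self):
        _, gt = generate_ca_traces(20, 1.0, 10.0, 5.0, duration_s=120.0, seed=4)
        for events in gt.events_per_cell:
            for (b1, e1), (b2, e2) in zip(events, events[1:]):
                assert b2 >= e1

    def test_clipping_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            generate_ca_traces(
                5, 1.0, 6.9, 6.23, amplitude=300.0, baseline=100.0,
                duration_s=60.0, seed=5,
            )

    def test_determinism(self):
        a, _ = generate_ca_traces(5, 0.8, 6.9, 6.23, duration_s=30.0, seed=6)
        b, _ = generate_ca_traces(5, 0.8, 6.9, 6.23, duration_s=30.0, seed=6)
        assert np.array_equal(a.traces, b.traces)
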