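"""Median-threshold spike detection: noise estimate, filter, detector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroburst import (
    GAUSSIAN_MAD_CONSTANT,
    RawRecording,
    SpikeDetectionParams,
    bandpass,
    detect_spikes,
    estimate_sigma,
    gaussian_mad_constant,
    generate_raw_recording,
)
from neuroburst.geometry import ElectrodeGeometry


def single_channel_recording(x, rate=20000.0):
    geom = ElectrodeGeometry(n_rows=1, n_cols=1)
    return RawRecording(samples=np.asarray(x)[None, :], rate=rate, geometry=geom)


class TestNormalizationConstant:
    def test_gaussian_median_to_sd_constant(self):
        # median(|X|)/sigma of a Gaussian is the 0.75 normal quantile
        assert round(gaussian_mad_constant(), 4) == 0.6745
        assert GAUSSIAN_MAD_CONSTANT == pytest.approx(gaussian_mad_constant(), abs=5e-5)


class TestEstimateSigma:
    def test_zero_channel_gives_zero_sigma(self):
        est = estimate_sigma(np.zeros(100))
        assert est.sigma[0] == 0.0
        assert est.threshold[0] == 0.0

    def test_constant_abs_at_norm_const_gives_unit_sigma(self):
        est = estimate_sigma(np.full(1000, 0.6745), norm_const=0.6745)
        assert est.sigma[0] == pytest.approx(1.0)
        assert est.threshold[0] == pytest.approx(4.0)

    def test_gaussian_noise_sigma_within_one_percent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5.0, 200000)  # 10 s at 20 kHz
        est = estimate_sigma(x)
        assert est.sigma[0] == pytest.approx(5.0, rel=0.01)

    def test_robust_to_one_percent_spike_contamination(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5.0, 200000)
        clean = estimate_sigma(x).sigma[0]
        xc = x.copy()
        idx = rng.choice(x.size, size=x.size // 100, replace=False)
        xc[idx] += 100.0  # large-amplitude spikes on 1% of samples
        contaminated = estimate_sigma(xc).sigma[0]
        assert abs(contaminated - clean) / clean < 0.02

    def test_empty_channel_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.empty(0))

    @given(scale=st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1.0, 5000)
        base = estimate_sigma(x)
        scaled = estimate_sigma(scale * x)
        assert scaled.sigma[0] == pytest.approx(scale * base.sigma[0], rel=1e-9)
        assert scaled.threshold[0] == pytest.approx(scale * base.threshold[0], rel=1e-9)


class TestBandpass:
    def test_zero_in_zero_out(self):
        rec = single_channel_recording(np.zeros(20000))
        out = bandpass(rec)
        assert out.n_samples == rec.n_samples
        assert np.allclose(out.samples, 0.0)

    @pytest.mark.parametrize(
        "freq,passes", [(1000.0, True), (10.0, False)]
    )
    def test_in_band_preserved_out_of_band_rejected(self, freq, passes):
        t = np.arange(0, 2.0, 1 / 20000.0)
        x = np.sin(2 * np.pi * freq * t)
        out = bandpass(single_channel_recording(x)).samples[0]
        rms_ratio = np.sqrt(np.mean(out**2)) / np.sqrt(np.mean(x**2))
        if passes:
            assert rms_ratio > 0.95
        else:
            assert rms_ratio < 0.05

    def test_band_above_nyquist_rejected(self):
        rec = single_channel_recording(np.zeros(1000), rate=10000.0)
        with pytest.raises(ValueError):
            bandpass(rec, 300.0, 8000.0)


class TestDetectSpikes:
    def test_clean_spike_above_threshold_detected_once(self):
        # noise-free except a tiny dither to give sigma ~ 5/0.6745 scale
        rng = np.random.default_rng(3)
        x = rng.normal(0, 5.0, 20000)
        rec = single_channel_recording(x)
        filtered = bandpass(rec)
        sigma = estimate_sigma(filtered.samples[0]).sigma[0]
        # plant one spike well above 4 sigma
        rec2 = generate_raw_recording(
            ElectrodeGeometry(n_rows=1, n_cols=1), 1.0, 5.0,
            [(0, 0.5, 8 * sigma)], seed=3,
        )
        raster, noise = detect_spikes(rec2)
        near = np.abs(raster.times - 0.5) < 0.002
        assert near.sum() == 1

    def test_two_crossings_within_min_isi_collapse_to_one(self):
        # controlled signal: +/-1 dither sets sigma = 1/0.6745, T ~ 5.9;
        # two clean 30 uV impulses 0.5 ms apart must yield one spike
        x = np.tile([1.0, -1.0], 10000).astype(float)
        x[10000] = 30.0
        x[10010] = 30.0  # 0.5 ms later at 20 kHz
        raster, _ = detect_spikes(
            single_channel_recording(x),
            SpikeDetectionParams(ns=4.0, min_isi_ms=1.0),
            apply_bandpass=False,
        )
        on0 = raster.times_on(0)
        assert np.sum(np.abs(on0 - 0.5) < 0.002) == 1

    def test_all_zero_recording_yields_empty_raster(self, geometry):
        rec = generate_raw_recording(geometry, 0.5, 0.0, [], seed=0)
        raster, noise = detect_spikes(rec)
        assert raster.n_spikes == 0
        assert np.all(noise.sigma == 0.0)

    def test_scale_invariance_of_detected_set(self):
        geom = ElectrodeGeometry(n_rows=1, n_cols=1)
        rec = generate_raw_recording(
            geom, 2.0, 5.0, [(0, 0.5, 40.0), (0, 1.2, 35.0)], seed=4
        )
        r1, _ = detect_spikes(rec)
        rec_scaled = RawRecording(rec.samples * 3.0, rec.rate, rec.geometry)
        r2, n2 = detect_spikes(rec_scaled)
        assert np.array_equal(r1.times, r2.times)

    def test_detection_calibration_sensitivity_and_false_rate(self, geometry):
        # basal-activity regime: heterogeneous rates, spikes >= 30 uV on 5 uV noise
        from neuroburst import basal_spike_schedule

        duration = 5.0
        schedule = basal_spike_schedule(geometry, duration, seed=10)
        rec = generate_raw_recording(geometry, duration, 5.0, schedule, seed=11)
        raster, _ = detect_spikes(rec)
        true_by_e = {}
        for e, t, _a in schedule:
            true_by_e.setdefault(e, []).append(t)
        hits = 0
        n_true = 0
        n_fp = 0
        for e in range(64):
            det = raster.times_on(e)
            tt = np.asarray(true_by_e.get(e, []))
            n_true += tt.size
            for t in tt:
                if det.size and np.abs(det - t).min() < 0.001:
                    hits += 1
            for d in det:
                if tt.size == 0 or np.abs(tt - d).min() >= 0.001:
                    n_fp += 1
        assert hits / n_true >= 0.95
        assert n_fp / (64 * duration) < 0.5
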