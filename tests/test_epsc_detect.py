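"""EPSC detection pipeline: detrend, deconvolve, detect, cluster, fit."""

import numpy as np
import pandas as pd
import pytest

from synaptomap import epsc_detect as ed
from synaptomap import synthgen


def make_trace(events, duration_s=2.0, rate=5000.0, noise_sd=0.0, seed=0):
    """Render an event list (onset_ms, amplitude_pa) into a SweepTrace."""
    rows = [dict(onset_ms=o, amplitude_pa=a, source="spontaneous",
                 target_id=-1, tau_rise_ms=0.7, tau_decay_ms=3.5)
            for o, a in events]
    ev = pd.DataFrame(rows, columns=["onset_ms", "amplitude_pa", "source",
                                     "target_id", "tau_rise_ms",
                                     "tau_decay_ms"])
    n = int(duration_s * rate)
    trace = synthgen.render_events(ev, n, rate)
    if noise_sd > 0:
        trace = trace + np.random.default_rng(seed).normal(0, noise_sd, n)
    return ed.SweepTrace(current_pa=trace, rate=rate)


class TestKernel:
    def test_zero_at_origin_and_for_negative_times(self):
        assert ed.synaptic_kernel(0.0, 0.7, 3.5) == 0.0
        assert ed.synaptic_kernel(-1.0, 0.7, 3.5) == 0.0

    def test_peak_time_closed_form_matches_numeric_maximum(self):
        t = np.linspace(0, 20, 200_001)
        k = ed.synaptic_kernel(t, 0.7, 3.5)
        t_star = t[np.argmax(k)]
        assert ed.kernel_peak_time(0.7, 3.5) == pytest.approx(
            0.7 * np.log(1 + 3.5 / 0.7), rel=1e-12)
        assert abs(t_star - ed.kernel_peak_time(0.7, 3.5)) < 1e-3

    def test_reduces_to_pure_decay_as_rise_vanishes(self):
        t = np.array([1.0, 5.0, 10.0])
        k = ed.synaptic_kernel(t, 1e-9, 3.5)
        np.testing.assert_allclose(k, np.exp(-t / 3.5), rtol=1e-6)

    def test_invalid_time_constant_ordering_rejected(self):
        with pytest.raises(ValueError):
            ed.synaptic_kernel(1.0, 3.5, 0.7)

    def test_normalized_kernel_has_unit_peak(self):
        t = np.linspace(0, 30, 30_001)
        k = ed.synaptic_kernel(t, 0.7, 3.5, normalized=True)
        assert k.max() == pytest.approx(1.0, abs=1e-6)


class TestDetrend:
    def test_white_noise_noise_sd_close_to_unity(self):
        rng = np.random.default_rng(0)
        raw = ed.SweepTrace(current_pa=rng.standard_normal(200_000),
                            rate=5000.0)
        z = ed.detrend_and_noise(raw)
        assert z.noise_sd == pytest.approx(1.0, rel=0.02)
        assert abs(np.median(z.samples)) < 1e-6 * max(z.noise_sd, 1.0)

    def test_constant_trace_maps_to_zero(self):
        raw = ed.SweepTrace(current_pa=np.full(10_000, -63.2), rate=5000.0)
        z = ed.detrend_and_noise(raw)
        assert np.max(np.abs(z.samples)) < 1e-9
        assert z.noise_sd == 0.0

    def test_slow_sinusoidal_drift_suppressed(self):
        rng = np.random.default_rng(1)
        n, rate = 100_000, 5000.0
        t = np.arange(n) / rate
        drift = 30.0 * np.sin(2 * np.pi * 0.5 * t)
        raw = ed.SweepTrace(current_pa=rng.normal(0, 2, n) + drift,
                            rate=rate)
        z = ed.detrend_and_noise(raw)
        # residual amplitude at the drift frequency
        spec = np.fft.rfft(z.samples)
        freqs = np.fft.rfftfreq(n, 1 / rate)
        bin_drift = np.argmin(np.abs(freqs - 0.5))
        resid_amp = 2 * np.abs(spec[bin_drift]) / n
        assert resid_amp < 0.1 * 30.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ed.detrend_and_noise(ed.SweepTrace(np.zeros(100), 5000.0))

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            ed.detrend_and_noise(ed.SweepTrace(np.zeros(10_000), 1000.0))


class TestDeconvolve:
    def test_single_event_mass_concentrates_at_onset(self):
        sweep = make_trace([(500.0, 20.0)])
        z = ed.detrend_and_noise(sweep)
        d = ed.deconvolve(z)
        assert np.all(d.deconvolved >= 0)
        i_peak = np.argmax(d.deconvolved)
        assert abs(i_peak * ed.MS_PER_SAMPLE - 500.0) <= 2 * ed.MS_PER_SAMPLE
        rms = np.sqrt(np.mean((d.denoised - z.samples) ** 2))
        assert rms < 0.05 * 20.0

    def test_all_zero_trace_maps_to_zero(self):
        z = ed.ZeroBaselineTrace(samples=np.zeros(5000), noise_sd=0.0)
        d = ed.deconvolve(z)
        assert not np.any(d.deconvolved) and not np.any(d.denoised)

    def test_two_events_15ms_apart_give_two_mass_peaks(self):
        from scipy.signal import find_peaks
        sweep = make_trace([(500.0, 20.0), (515.0, 20.0)])
        z = ed.detrend_and_noise(sweep)
        d = ed.deconvolve(z)
        peaks, _ = find_peaks(d.deconvolved, height=0.2 * d.deconvolved.max(),
                              distance=int(5 / ed.MS_PER_SAMPLE))
        assert len(peaks) == 2

    def test_denoised_is_exact_convolution_of_deconvolved(self):
        from scipy.signal import fftconvolve
        sweep = make_trace([(300.0, 15.0), (700.0, 10.0)], noise_sd=1.0)
        params = ed.DetectionParams()
        z = ed.detrend_and_noise(sweep, params)
        d = ed.deconvolve(z, params)
        k = ed.discretized_kernel(params)
        redo = fftconvolve(d.deconvolved, k)[: len(d.denoised)]
        assert np.max(np.abs(redo - d.denoised)) < 1e-9


class TestDetect:
    def test_pure_noise_yields_no_detections(self):
        rng = np.random.default_rng(3)
        raw = ed.SweepTrace(rng.normal(0, 2, 25_000), 5000.0)
        z = ed.detrend_and_noise(raw)
        d = ed.deconvolve(z)
        events = ed.detect_putative_events(d, z)
        assert len(events) <= 2  # rare noise crossings only

    def test_events_closer_than_minimum_distance_merge(self):
        sweep = make_trace([(500.0, 20.0), (501.0, 20.0)],
                           noise_sd=1.0, seed=9)
        z = ed.detrend_and_noise(sweep)
        d = ed.deconvolve(z)
        events = ed.detect_putative_events(d, z)
        assert len(events) == 1

    def test_recall_and_precision_on_synthetic_benchmark(self):
        rng = np.random.default_rng(7)
        onsets = np.sort(rng.uniform(100, 24_000, 50))
        onsets = onsets[np.r_[True, np.diff(onsets) > 10]]
        sweep = make_trace([(o, 20.0) for o in onsets], duration_s=25.0,
                           noise_sd=2.0, seed=7)
        z = ed.detrend_and_noise(sweep)
        d = ed.deconvolve(z)
        det = np.array([o for o, _ in ed.detect_putative_events(d, z)])
        tp = sum(np.min(np.abs(det - o)) <= 1.0 for o in onsets)
        recall = tp / len(onsets)
        precision = tp / len(det)
        assert recall >= 0.9 and precision >= 0.9


class TestCluster:
    def _pipeline(self, events, **kw):
        kw.setdefault("noise_sd", 1.0)
        kw.setdefault("seed", 0)
        sweep = make_trace(events, **kw)
        z = ed.detrend_and_noise(sweep)
        d = ed.deconvolve(z)
        ev = ed.detect_putative_events(d, z)
        return ed.cluster_events(d, ev, z), ev

    def test_well_separated_events_get_separate_clusters(self):
        clusters, ev = self._pipeline([(300.0, 20.0), (400.0, 20.0)])
        assert len(ev) == 2 and len(clusters) == 2

    def test_close_events_share_a_cluster(self):
        clusters, ev = self._pipeline([(300.0, 20.0), (305.0, 20.0)])
        assert len(ev) == 2
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_cluster_bounds_sorted_and_disjoint(self):
        clusters, _ = self._pipeline(
            [(200.0, 20.0), (208.0, 15.0), (600.0, 25.0), (900.0, 10.0)])
        bounds = [(c.start, c.stop) for c in clusters]
        assert bounds == sorted(bounds)
        assert all(b1[0] >= b0[1] for b0, b1 in zip(bounds, bounds[1:]))

    def test_every_event_assigned_exactly_once(self):
        clusters, ev = self._pipeline(
            [(200.0, 20.0), (208.0, 15.0), (600.0, 25.0)])
        members = sorted(m for c in clusters for m in c.members)
        assert members == list(range(len(ev)))


class TestFitCluster:
    def test_single_noiseless_event_recovered(self):
        sweep = make_trace([(500.0, 20.0)])
        z = ed.detrend_and_noise(sweep)
        d = ed.deconvolve(z)
        ev = ed.detect_putative_events(d, z)
        clusters = ed.cluster_events(d, ev, z)
        fit = ed.fit_cluster(z, clusters[0], ev)
        assert len(fit) == 1
        row = fit.iloc[0]
        assert row.height_pa == pytest.approx(20.0, rel=0.05)
        assert abs(row.onset_ms - 500.0) < 0.2
        assert row.tau_decay_ms == pytest.approx(3.5, rel=0.25)

    def test_overlapping_pair_decomposed(self):
        sweep = make_trace([(500.0, 15.0), (504.0, 25.0)], noise_sd=2.0,
                           seed=11)
        z = ed.detrend_and_noise(sweep)
        d = ed.deconvolve(z)
        ev = ed.detect_putative_events(d, z)
        clusters = ed.cluster_events(d, ev, z)
        fit = pd.concat([ed.fit_cluster(z, c, ev) for c in clusters])
        assert len(fit) == 2
        heights = np.sort(fit.height_pa.to_numpy())
        assert heights[0] == pytest.approx(15.0, rel=0.2)
        assert heights[1] == pytest.approx(25.0, rel=0.2)

    def test_fitted_decay_always_exceeds_rise(self):
        sweep = make_trace([(300.0, 8.0), (600.0, 30.0)], noise_sd=2.0,
                           seed=5)
        table = ed.detect_epscs(sweep)
        assert np.all(table.tau_decay_ms > table.tau_rise_ms)


class TestFullPipeline:
    def test_large_event_survives_threshold(self):
        sweep = make_trace([(500.0, 20.0)], noise_sd=1.5, seed=1)
        table = ed.detect_epscs(sweep)
        assert len(table) == 1

    def test_small_event_discarded_by_threshold(self):
        # 2 pA < 2.5 x 1.5 pA: fitted but dropped
        sweep = make_trace([(500.0, 2.0)], noise_sd=1.5, seed=2)
        table = ed.detect_epscs(sweep)
        assert len(table) == 0

    def test_offset_invariance(self):
        sweep = make_trace([(400.0, 18.0), (900.0, 12.0)], noise_sd=1.5,
                           seed=3)
        shifted = ed.SweepTrace(sweep.current_pa - 37.5, sweep.rate)
        a = ed.detect_epscs(sweep)
        b = ed.detect_epscs(shifted)
        assert len(a) == len(b)
        for col in ("onset_ms", "height_pa", "tau_rise_ms", "tau_decay_ms"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-6)

    def test_threshold_monotonicity(self):
        sweep = make_trace([(300.0, 5.0), (600.0, 10.0), (900.0, 25.0)],
                           noise_sd=1.5, seed=4)
        counts = []
        for mult in (1.0, 2.5, 5.0, 10.0):
            params = ed.DetectionParams(height_threshold_sd=mult)
            counts.append(len(ed.detect_epscs(sweep, params)))
        assert counts == sorted(counts, reverse=True)

    def test_noiseless_events_match_ground_truth(self):
        # oracle equivalence on well-separated noiseless events
        truth = [(300.0, 20.0), (600.0, 12.0), (900.0, 30.0)]
        sweep = make_trace(truth)
        table = ed.detect_epscs(sweep)
        assert len(table) == 3
        for (o, h), row in zip(truth, table.itertuples()):
            assert abs(row.onset_ms - o) < 0.4
            assert row.height_pa == pytest.approx(h, rel=0.05)
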