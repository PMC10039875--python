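"""Synthetic-data generator: schedules, traces, volumes, pair tables."""

import numpy as np
import pandas as pd
import pytest

from synaptomap import synthgen
from synaptomap.epsc_detect import SweepTrace


class TestStimSchedule:
    def test_total_stimulations_is_pulses_times_reps(self):
        sched = synthgen.make_stim_schedule(
            1, synthgen.TrainSpec(n_pulses=10, repetitions=2), seed=0)
        assert sched.stimulations_per_target()[0] == 20

    def test_mean_stimulations_across_targets(self):
        sched = synthgen.make_stim_schedule(
            100, synthgen.TrainSpec(n_pulses=15, repetitions=2), seed=1)
        assert sched.stimulations_per_target().mean() == 30

    def test_deterministic_given_seed(self):
        a = synthgen.make_stim_schedule(5, seed=42)
        b = synthgen.make_stim_schedule(5, seed=42)
        pd.testing.assert_frame_equal(a.pulses, b.pulses)
        np.testing.assert_array_equal(a.positions_um, b.positions_um)

    def test_pulse_times_strictly_increasing_and_trains_disjoint(self):
        sched = synthgen.make_stim_schedule(
            7, synthgen.TrainSpec(n_pulses=10, repetitions=3), seed=3)
        times = sched.pulses.time_s.to_numpy()
        assert np.all(np.diff(times) > 0)

    @pytest.mark.parametrize("kwargs", [dict(n_targets=0),
                                        dict(n_targets=3, n_pulses=0)])
    def test_nonpositive_counts_rejected(self, kwargs):
        n = kwargs.pop("n_targets")
        trains = synthgen.TrainSpec(**kwargs) if kwargs else None
        with pytest.raises(ValueError):
            synthgen.make_stim_schedule(n, trains, seed=0)


class TestSimulateTrace:
    def test_spontaneous_only_event_count_matches_rate(self):
        sched = synthgen.make_stim_schedule(
            1, synthgen.TrainSpec(n_pulses=1, repetitions=1), seed=0)
        truth = synthgen.GroundTruth(
            connected=[False], e_p=[0.0], bump_center_ms=[13],
            bump_sd_ms=[5], spont_rate_hz=2.0, noise_sd_pa=0.0,
            drift_sd_pa=0.0)
        _, events = synthgen.simulate_trace(sched, truth, seed=0,
                                            duration_s=60.0)
        n = len(events)
        assert events.source.eq("spontaneous").all()
        # Poisson(120): 5 sigma band
        assert abs(n - 120) < 5 * np.sqrt(120)

    def test_noiseless_single_event_peak_equals_amplitude(self):
        ev = pd.DataFrame([dict(onset_ms=100.0, amplitude_pa=20.0,
                                source="spontaneous", target_id=-1,
                                tau_rise_ms=0.7, tau_decay_ms=3.5)])
        trace = synthgen.render_events(ev, 5000, 5000.0)
        assert trace.min() == pytest.approx(-20.0, abs=0.05)

    def test_evoked_latency_moments_match_gamma_bump(self):
        # mean 12.96 ms, sd 6.33 ms from the PSTH gamma fit (k*theta etc.)
        sched = synthgen.make_stim_schedule(
            1, synthgen.TrainSpec(n_pulses=10, repetitions=3), seed=0)
        lats = []
        seed = 0
        while len(lats) < 10_000:
            truth = synthgen.GroundTruth(
                connected=[True], e_p=[40.0], bump_center_ms=[12.96],
                bump_sd_ms=[6.33], spont_rate_hz=0.0, noise_sd_pa=0.0,
                drift_sd_pa=0.0)
            _, events = synthgen.simulate_trace(sched, truth, seed=seed)
            pulse_t = sched.pulses.time_s.to_numpy() * 1000.0
            ev = events[events.source == "evoked"]
            rel = ev.onset_ms.to_numpy()[:, None] - pulse_t[None, :]
            rel = np.where(rel >= 0, rel, np.inf).min(axis=1)
            lats.extend(rel.tolist())
            seed += 1
        lats = np.array(lats[:10_000])
        se = 6.33 / np.sqrt(len(lats))
        assert abs(lats.mean() - 12.96) < 3 * se

    def test_rendering_is_linear(self):
        rng = np.random.default_rng(0)
        rows = [dict(onset_ms=o, amplitude_pa=a, source="spontaneous",
                     target_id=-1, tau_rise_ms=0.7, tau_decay_ms=3.5)
                for o, a in zip(rng.uniform(0, 900, 20),
                                rng.uniform(5, 30, 20))]
        ev = pd.DataFrame(rows)
        full = synthgen.render_events(ev, 5000, 5000.0)
        parts = (synthgen.render_events(ev.iloc[:10], 5000, 5000.0)
                 + synthgen.render_events(ev.iloc[10:], 5000, 5000.0))
        assert np.max(np.abs(full - parts)) < 1e-9

    def test_ground_truth_table_re_renders_noiseless_trace(self):
        sched = synthgen.make_stim_schedule(
            2, synthgen.TrainSpec(n_pulses=5, repetitions=1), seed=1)
        truth = synthgen.GroundTruth(
            connected=[True, False], e_p=[1.0, 0.0],
            bump_center_ms=[13, 13], bump_sd_ms=[5, 5],
            spont_rate_hz=2.0, noise_sd_pa=0.0, drift_sd_pa=0.0)
        sweep, events = synthgen.simulate_trace(sched, truth, seed=2)
        redo = synthgen.render_events(events, len(sweep.current_pa),
                                      sweep.rate)
        assert np.max(np.abs(sweep.current_pa - redo)) < 1e-9

    def test_schedule_longer_than_trace_rejected(self):
        sched = synthgen.make_stim_schedule(2, seed=0)
        truth = synthgen.make_ground_truth(2, seed=0)
        with pytest.raises(ValueError):
            synthgen.simulate_trace(sched, truth, duration_s=0.5)

    def test_disjoint_window_counts_are_poisson(self):
        # chi-square GOF of per-window counts against Poisson
        from scipy import stats as st
        sched = synthgen.make_stim_schedule(
            1, synthgen.TrainSpec(n_pulses=1, repetitions=1), seed=0)
        truth = synthgen.GroundTruth(
            connected=[False], e_p=[0.0], bump_center_ms=[13],
            bump_sd_ms=[5], spont_rate_hz=50.0, noise_sd_pa=0.0,
            drift_sd_pa=0.0)
        _, events = synthgen.simulate_trace(sched, truth, seed=3,
                                            duration_s=2000.0)
        counts = np.histogram(events.onset_ms, bins=np.arange(0, 2000e3,
                                                              1000.0))[0]
        lam = counts.mean()
        kmax = int(st.poisson.ppf(0.999, lam))
        obs = np.bincount(counts, minlength=kmax + 1)[: kmax + 1].astype(float)
        exp = st.poisson.pmf(np.arange(kmax + 1), lam) * counts.size
        keep = exp > 5
        chi2 = np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep])
        p = 1 - st.chi2.cdf(chi2, keep.sum() - 2)
        assert p > 0.01


class TestCellVolume:
    def test_count_is_poisson_around_expectation(self):
        box = (420.0, 420.0, 300.0)
        vol_mm3 = np.prod(box) * 1e-9
        density = 200.0 / vol_mm3
        counts = [len(synthgen.simulate_cell_volume(density, box, seed=s))
                  for s in range(50)]
        assert abs(np.mean(counts) - 200) < 5 * np.sqrt(200 / 50)

    def test_two_seeds_differ_but_fill_the_box(self):
        a = synthgen.simulate_cell_volume(2e5, seed=0)
        b = synthgen.simulate_cell_volume(2e5, seed=1)
        assert not np.array_equal(a.to_numpy()[: min(len(a), len(b))],
                                  b.to_numpy()[: min(len(a), len(b))])
        assert a.x_um.max() <= 420 and a.z_um.max() <= 300

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            synthgen.simulate_cell_volume(0.0)


class TestPairFeatures:
    def test_intercept_only_prevalence(self):
        from scipy.special import logit
        beta = np.zeros(21)
        beta[0] = logit(0.025)
        df = synthgen.simulate_pair_features(100_000, beta, seed=0)
        se = np.sqrt(0.025 * 0.975 / 100_000)
        assert abs(df.attrs["prevalence"] - 0.025) < 3 * se

    def test_null_coefficients_leave_label_independent(self):
        beta = np.zeros(6)
        beta[0] = -1.0
        df = synthgen.simulate_pair_features(50_000, beta, seed=1)
        y = df.connected.to_numpy()
        for col in df.columns[:-1]:
            r = np.corrcoef(df[col], y)[0, 1]
            assert abs(r) < 0.02

    def test_unregularized_fit_recovers_coefficient_signs(self):
        from sklearn.linear_model import LogisticRegression
        beta = np.array([0.0, 1.0, -1.0, 0, 0, 0])
        df = synthgen.simulate_pair_features(5000, beta, seed=2)
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        clf.fit(df[df.columns[:-1]], df.connected)
        assert clf.coef_[0][0] > 0.5 and clf.coef_[0][1] < -0.5

    def test_singular_correlation_rejected(self):
        corr = np.ones((3, 3))
        with pytest.raises(ValueError):
            synthgen.simulate_pair_features(100, np.zeros(4), seed=0,
                                            correlation=corr)


class TestTraceIO:
    def test_h5_roundtrip(self, tmp_path):
        sched = synthgen.make_stim_schedule(
            1, synthgen.TrainSpec(n_pulses=2, repetitions=1), seed=0)
        truth = synthgen.make_ground_truth(1, seed=0)
        sweep, _ = synthgen.simulate_trace(sched, truth, seed=0)
        path = tmp_path / "trace.h5"
        synthgen.write_trace_h5(path, sweep)
        back = synthgen.read_trace_h5(path)
        np.testing.assert_allclose(back.current_pa, sweep.current_pa)
        assert back.rate == sweep.rate

    def test_schedule_roundtrip(self, tmp_path):
        sched = synthgen.make_stim_schedule(3, seed=5)
        synthgen.write_schedule(sched, tmp_path / "s.csv", tmp_path / "s.json")
        back = synthgen.read_schedule(tmp_path / "s.csv", tmp_path / "s.json")
        pd.testing.assert_frame_equal(back.pulses, sched.pulses)
        np.testing.assert_allclose(back.positions_um, sched.positions_um)
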