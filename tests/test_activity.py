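"""ΔF/F, event detection, peri-event motility, Δspeed, correlations."""

import numpy as np
import pytest
from scipy import stats

from dendromito.activity import (ActivityTrace, classify_event_extent,
                                 compute_dff, delta_speed, detect_events,
                                 event_frequency, pairwise_correlation,
                                 peri_event_motility)
from dendromito.synthetic import (CalciumParams, MotilityParams,
                                  simulate_calcium, simulate_spike_trains,
                                  simulate_tracks)
from dendromito.tracks import TrackSet

DT = 1.0 / 0.9


class TestDff:
    def test_constant_trace_all_zero(self):
        out = compute_dff(ActivityTrace(np.full(100, 7.0), DT))
        np.testing.assert_allclose(out.values, 0.0)

    def test_doubling_gives_unity(self):
        f = np.full(100, 3.0)
        f[50] = 6.0
        out = compute_dff(ActivityTrace(f, DT))
        assert out.values[50] == pytest.approx(1.0)

    def test_recovers_generator_amplitude(self):
        tr, _ = simulate_tracks(50.0, MotilityParams(seed=1, duration=400.0),
                                n_organelles=3)
        traces, _, truth = simulate_calcium(CalciumParams(
            global_rate=0.01, local_rate=0.0, amplitude_dff=1.0,
            decay_tau=10.0, noise_sd=0.0, seed=2), tr)
        onsets = [e.onset_s for e in truth.calcium_events]
        assert onsets  # at least one event in 400 s at 0.01/s (seeded)
        dff = compute_dff(traces[0])
        t = traces[0].times
        for t0 in onsets:
            f = int(np.searchsorted(t, t0))
            if f < len(t):
                # the first sampled frame holds the step amplitude up to at
                # most one frame interval of decay
                assert dff.values[f] >= np.exp(-DT / 10.0) * 0.99

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(ActivityTrace(np.zeros(10), DT))


class TestDetectEvents:
    def test_constant_trace_no_events(self):
        ev = detect_events(ActivityTrace(np.full(200, 5.0), DT))
        assert ev.n_events == 0
        assert ev.percent_time_above == 0.0

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(3)
        ev = detect_events(ActivityTrace(rng.normal(0, 1, 10_000), DT), k_sd=2)
        assert ev.percent_time_above == pytest.approx(2.275, abs=0.5)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.normal(5, 2, 500)
        e1 = detect_events(ActivityTrace(v, DT))
        e2 = detect_events(ActivityTrace(3.0 * v + 10.0, DT))
        np.testing.assert_array_equal(e1.onsets, e2.onsets)
        assert e1.percent_time_above == e2.percent_time_above

    def test_generator_events_recovered_with_onset_accuracy(self):
        tr, _ = simulate_tracks(50.0, MotilityParams(seed=5, duration=600.0),
                                n_organelles=3)
        traces, _, truth = simulate_calcium(CalciumParams(
            global_rate=0.01, local_rate=0.0, amplitude_dff=2.0,
            noise_sd=0.02, seed=6), tr)
        true_onsets = np.array([e.onset_s for e in truth.calcium_events])
        dff = compute_dff(traces[0])
        ev = detect_events(dff)
        # every true event matched by a detected onset within 1 frame
        for t0 in true_onsets:
            assert np.min(np.abs(ev.onset_times - t0)) <= 2 * DT

    def test_percent_above_is_exact_accounting(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0, 1, 1000)
        ev = detect_events(ActivityTrace(v, DT))
        assert ev.percent_time_above == pytest.approx(
            100.0 * np.mean(v > ev.threshold))


class TestEventExtent:
    def _traces(self, active_windows, n_windows=10, T=300):
        rng = np.random.default_rng(8)
        out = []
        for w in range(n_windows):
            v = rng.normal(1.0, 0.02, T)
            if w in active_windows:
                v[100:110] += 1.0
            out.append(ActivityTrace(v, DT, roi=f"w{w}"))
        return out

    def test_all_windows_active_is_global(self):
        df = classify_event_extent(self._traces(set(range(10))))
        assert (df["label"] == "global").all()
        assert len(df) >= 1

    def test_single_window_active_is_local(self):
        df = classify_event_extent(self._traces({4}))
        assert (df["label"] == "local").all()

    def test_simulated_local_events_labelled_local(self):
        hits = trials = 0
        for seed in range(10):
            tr, _ = simulate_tracks(100.0, MotilityParams(seed=seed,
                                                          duration=400.0),
                                    n_organelles=3)
            traces, _, truth = simulate_calcium(CalciumParams(
                global_rate=0.0, local_rate=0.01, local_extent=10.0,
                noise_sd=0.02, amplitude_dff=2.0, seed=seed + 50), tr)
            df = classify_event_extent(traces)
            hits += (df["label"] == "local").sum()
            trials += len(df)
        assert trials > 10
        assert hits / trials >= 0.95

    def test_frequency_is_count_over_duration(self):
        tr = ActivityTrace(np.zeros(300), 1.0)
        ev = detect_events(tr)
        assert event_frequency(ev, 300.0) == 0.0
        ev.onsets = np.array([10, 50, 90])
        ev.offsets = np.array([11, 51, 91])
        assert event_frequency(ev, 300.0) == pytest.approx(0.01)


class TestPeriEvent:
    def test_no_events_error(self):
        tr, _ = simulate_tracks(50.0, MotilityParams(seed=9), n_organelles=3)
        with pytest.raises(ValueError, match="no events"):
            peri_event_motility(tr, np.array([]))

    def test_null_coupling_flat_profile(self):
        tr, _ = simulate_tracks(200.0, MotilityParams(seed=10, duration=900.0),
                                n_organelles=60)
        _, out, truth = simulate_calcium(CalciumParams(
            global_rate=0.01, local_rate=0.0, motility_coupling=0.0,
            noise_sd=0.0, seed=11), tr)
        onsets = np.array([e.onset_s for e in truth.calcium_events])
        prof = peri_event_motility(out, onsets, half_window=8.0)
        diff, (lo, hi) = prof.pre_post_difference()
        assert lo <= 0.0 <= hi

    def test_full_coupling_arrests_post_onset(self):
        tr, _ = simulate_tracks(200.0, MotilityParams(motile_prob=1.0,
                                                      pause_duration_mean=0.5,
                                                      seed=12, duration=900.0),
                                n_organelles=40)
        _, out, truth = simulate_calcium(CalciumParams(
            global_rate=0.008, local_rate=0.0, motility_coupling=1.0,
            event_duration_s=6.0, noise_sd=0.0, seed=13), tr)
        onsets = np.array([e.onset_s for e in truth.calcium_events])
        prof = peri_event_motility(out, onsets, half_window=5.0)
        pre = np.nanmean(prof.mean[prof.lag_centers < 0])
        # skip the frame pair straddling the onset (pre-onset motion)
        post = np.nanmean(prof.mean[prof.lag_centers > DT])
        assert post < 0.1 * pre

    def test_shuffled_onsets_are_flat(self):
        tr, _ = simulate_tracks(200.0, MotilityParams(seed=14, duration=900.0),
                                n_organelles=60)
        rng = np.random.default_rng(15)
        onsets = rng.uniform(50, 850, size=12)
        prof = peri_event_motility(tr, onsets, half_window=8.0)
        diff, (lo, hi) = prof.pre_post_difference()
        assert lo <= 0.0 <= hi


class TestDeltaSpeed:
    def _track_halving_speed(self, t_event=50.0, v=0.5):
        t = np.arange(0, 100, DT)
        x = np.where(t < t_event, v * t,
                     v * t_event + 0.5 * v * (t - t_event))
        return TrackSet(positions=x[None, :], frame_interval=DT)

    def test_unchanged_speed_gives_zero(self):
        t = np.arange(0, 100, DT)
        tr = TrackSet(positions=(0.5 * t)[None, :], frame_interval=DT)
        res = delta_speed(tr, np.array([50.0]))
        assert res.deltas[0] == pytest.approx(0.0, abs=1e-9)

    def test_halved_speed_gives_minus_half_v(self):
        tr = self._track_halving_speed()
        res = delta_speed(tr, np.array([50.0]), window=5.0)
        assert res.deltas[0] == pytest.approx(-0.25, abs=0.05)

    def test_stationary_pre_excluded(self):
        tr = TrackSet(positions=np.zeros((1, 90)), frame_interval=DT)
        res = delta_speed(tr, np.array([50.0]))
        assert res.n_included == 0
        assert res.n_excluded == 1


class TestCorrelation:
    def test_self_correlation_peaks_at_one(self):
        rng = np.random.default_rng(16)
        spikes = np.sort(rng.uniform(0, 600, 400))
        cg = pairwise_correlation(spikes, spikes, duration=600.0, correction=None)
        assert cg.zero_lag == pytest.approx(1.0)
        assert cg.peak == pytest.approx(1.0)

    def test_independent_poisson_flat(self):
        rng = np.random.default_rng(17)
        a = np.sort(rng.uniform(0, 2000, 2000))
        b = np.sort(rng.uniform(0, 2000, 2000))
        cg = pairwise_correlation(a, b, duration=2000.0, correction=None)
        assert np.max(np.abs(cg.values)) < 3.0 / np.sqrt(20_000)

    def test_shared_envelope_removed_by_correction(self):
        # rate-matched but independent nonstationary trains
        rng = np.random.default_rng(18)
        t = np.arange(0, 2000, 0.1)
        envelope = 1.0 + np.sin(2 * np.pi * t / 40.0)
        def draw():
            lam = envelope * 0.1 * 2.0
            return t[rng.uniform(size=len(t)) < lam]
        a, b = draw(), draw()
        raw = pairwise_correlation(a, b, duration=2000.0, correction=None)
        cor = pairwise_correlation(a, b, duration=2000.0, correction="jitter")
        assert raw.peak > 0.05
        assert abs(cor.zero_lag) < 0.02
        assert cor.peak < raw.peak / 3

    def test_wave_trains_peak_at_zero_lag(self):
        trains, _ = simulate_spike_trains(2, 2000.0, burst_rate=0.02,
                                          within_burst_rate=40.0,
                                          burst_duration=1.0,
                                          participation_prob=1.0,
                                          baseline_rate=0.5, seed=19)
        cg = pairwise_correlation(trains.trains[0], trains.trains[1],
                                  duration=2000.0, correction="jitter",
                                  jitter_window=4.0)
        far = np.abs(cg.lags) > 1.0
        assert cg.zero_lag > np.max(np.abs(cg.values[far]))
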