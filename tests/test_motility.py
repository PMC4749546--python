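"""Kymographs, track linking, motile fractions, runs/pauses, displacement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendromito.images import TimeLapse
from dendromito.motility import (LinkParams, build_kymograph, classify_motility,
                                 displacement_fraction, link_tracks,
                                 segment_runs_pauses)
from dendromito.synthetic import MotilityParams, RenderParams, render_movie, \
    simulate_tracks
from dendromito.tracks import TrackSet

DT = 1.0 / 0.9


def straight_movie(tracks, seed=0, **render_kw):
    L = tracks.path_length
    return render_movie(tracks, np.array([[0.0, 0.0], [L, 0.0]]),
                        RenderParams(seed=seed, **render_kw))


class TestKymograph:
    def test_static_organelle_horizontal_band(self):
        tr, _ = simulate_tracks(30.0, MotilityParams(motile_prob=0.0, seed=1,
                                                     duration=30.0), n_organelles=1)
        movie, rel = straight_movie(tr, gaussian_read_noise_sd=0.0, background=0.0)
        kymo = build_kymograph(movie, rel)
        rows = np.argmax(kymo.data, axis=0)
        assert rows.max() - rows.min() <= 1  # constant spatial position

    def test_constant_speed_band_slope(self):
        p = MotilityParams(motile_prob=1.0, run_duration_mean=1e9,
                           pause_duration_mean=1e-9, run_speed_mean=0.5,
                           run_speed_sd=0.0, direction_switch_prob=0.0,
                           duration=30.0, seed=5)
        tr, _ = simulate_tracks(60.0, p, n_organelles=1)
        movie, rel = straight_movie(tr)
        kymo = build_kymograph(movie, rel)
        pos = np.argmax(kymo.data, axis=0) * kymo.bin_length
        # per-frame band shift is robust to reflections at the path ends
        speed = np.abs(np.diff(pos)).mean() / kymo.frame_interval
        assert abs(speed - 0.5) / 0.5 < 0.1

    def test_empty_movie_background_only(self):
        frames = np.full((5, 20, 40), 3.0)
        movie = TimeLapse(frames=frames, frame_interval=DT, voxel_size=[0.2, 0.2])
        kymo = build_kymograph(movie, np.array([[0.0, 2.0], [7.0, 2.0]]))
        assert np.all(kymo.data == 3.0)


class TestLinker:
    def test_single_organelle_recovered(self):
        tr, _ = simulate_tracks(30.0, MotilityParams(motile_prob=1.0, seed=2,
                                                     duration=60.0), n_organelles=1)
        movie, rel = straight_movie(tr)
        linked = link_tracks(movie, rel)
        assert linked.n_organelles >= 1
        # best track matches the truth within half a micron on shared frames
        errs = []
        for j in range(linked.n_organelles):
            both = np.isfinite(linked.positions[j])
            errs.append(np.median(np.abs(linked.positions[j][both]
                                         - tr.positions[0][both])))
        assert min(errs) < 0.5

    def test_recall_on_noisy_benchmark(self):
        # frame-level recall: true (organelle, frame) points matched by a
        # linked detection within 0.5 µm
        hits, total = 0, 0
        for seed in range(3):
            tr, _ = simulate_tracks(50.0, MotilityParams(seed=seed, duration=90.0),
                                    n_organelles=10)
            movie, rel = straight_movie(tr, seed=seed + 50)
            linked = link_tracks(movie, rel)
            for i in range(tr.n_organelles):
                d = np.abs(linked.positions - tr.positions[i][None, :])
                d = np.where(np.isfinite(d), d, np.inf)
                hit = d.min(axis=0) <= 0.5 if linked.n_organelles else \
                    np.zeros(tr.n_frames, bool)
                hits += hit.sum()
                total += tr.n_frames
        assert hits / total >= 0.9


class TestClassifyMotility:
    def test_fraction_counts_movers(self):
        pos = np.zeros((10, 61))
        for i in range(3):
            pos[i, 30] = 1.0  # one 1 µm jump within the first minute
            pos[i, 31:] = 1.0
        tr = TrackSet(positions=pos, frame_interval=1.0)
        stats = classify_motility(tr, window=60.0, move_threshold=0.4)
        assert stats.motile_fraction == pytest.approx(0.3)

    def test_all_static_zero_everywhere(self):
        tr = TrackSet(positions=np.ones((5, 70)), frame_interval=1.0)
        stats = classify_motility(tr)
        assert stats.motile_fraction == 0.0
        assert np.nanmax(stats.instantaneous) == 0.0

    def test_motile_prob_recovery_within_binomial_ci(self):
        p = MotilityParams(motile_prob=0.3, duration=90.0, seed=21)
        tr, _ = simulate_tracks(300.0, p, n_organelles=1000)
        stats = classify_motility(tr)
        se = np.sqrt(0.3 * 0.7 / 1000)
        assert abs(stats.motile_fraction - 0.3) < 2.58 * se

    def test_per_minute_dominates_instantaneous(self):
        for seed in range(5):
            tr, _ = simulate_tracks(100.0, MotilityParams(seed=seed, duration=80.0),
                                    n_organelles=50)
            stats = classify_motility(tr)
            assert stats.motile_fraction >= np.nanmax(stats.instantaneous) - 1e-12

    def test_empty_tracks_error(self):
        tr = TrackSet(positions=np.ones((1, 70)), frame_interval=1.0)
        tr.positions = tr.positions[:0]
        with pytest.raises(ValueError):
            classify_motility(tr)

    @pytest.mark.parametrize("motile_prob", [0.0, 1.0])
    def test_pipeline_consistency_truth_vs_linker(self, motile_prob):
        # clean movies with unambiguous identities: ground-truth tracks and
        # linker-recovered tracks classify identically
        tr, _ = simulate_tracks(60.0, MotilityParams(motile_prob=motile_prob,
                                                     seed=33, duration=80.0),
                                n_organelles=3)
        movie, rel = straight_movie(tr, seed=34, gaussian_read_noise_sd=0.0,
                                    background=0.0, photon_scale=2000.0)
        linked = link_tracks(movie, rel)
        s_true = classify_motility(tr)
        s_link = classify_motility(linked)
        assert s_link.motile_fraction == s_true.motile_fraction


class TestRunsPauses:
    def test_constant_speed_single_run(self):
        x = np.arange(40) * DT * 0.5
        rp = segment_runs_pauses(x, DT)
        assert len(rp.run_durations) == 1
        assert len(rp.pause_durations) == 0
        assert rp.run_durations[0] == pytest.approx(39 * DT)
        assert rp.run_speeds[0] == pytest.approx(0.5)

    def test_all_pause_track(self):
        rp = segment_runs_pauses(np.full(30, 2.0), DT)
        assert len(rp.run_durations) == 0
        assert len(rp.pause_durations) == 1

    def test_alternating_bouts_recovered(self):
        # deterministic 5 s runs / 3 s pauses at 0.5 µm/s
        xs = [(f * DT // 8.0) * 2.5 + min(f * DT % 8.0, 5.0) * 0.5
              for f in range(400)]
        rp = segment_runs_pauses(np.array(xs), DT)
        assert abs(rp.run_durations.mean() - 5.0) < DT
        assert abs(rp.pause_durations.mean() - 3.0) < DT
        assert abs(rp.run_speeds.mean() - 0.5) / 0.5 < 0.05

    def test_partition_sums_to_track_duration(self):
        tr, _ = simulate_tracks(100.0, MotilityParams(motile_prob=1.0, seed=40,
                                                      duration=200.0),
                                n_organelles=5)
        for i in range(5):
            rp = segment_runs_pauses(tr.positions[i], DT)
            assert rp.total_time == pytest.approx((tr.n_frames - 1) * DT, rel=1e-9)


class TestDisplacement:
    def test_identical_images_zero_percent(self):
        img = np.zeros((30, 30), bool)
        img[5:10, 5:10] = True
        img[20:24, 20:24] = True
        res = displacement_fraction(img, img)
        assert res.percent_displaced == 0.0

    def test_full_translation_hundred_percent(self):
        t0 = np.zeros((20, 40), bool)
        t0[5:8, 2:8] = True
        t1 = np.roll(t0, 20, axis=1)
        res = displacement_fraction(t0, t1)
        assert res.percent_displaced == 100.0

    def test_twenty_percent_boundary_inclusive(self):
        t0 = np.zeros((10, 120), bool)
        t0[4:5, 0:100] = True            # one 100-pixel organelle
        keep20 = np.zeros_like(t0)
        keep20[4:5, 0:20] = True         # exactly 20 pixels retained
        assert displacement_fraction(t0, keep20).n_displaced == 0
        keep19 = np.zeros_like(t0)
        keep19[4:5, 0:19] = True
        assert displacement_fraction(t0, keep19).n_displaced == 1

    def test_empty_baseline_error(self):
        with pytest.raises(ValueError, match="baseline"):
            displacement_fraction(np.zeros((5, 5)), np.ones((5, 5)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_to_background_and_labels(self, seed):
        rng = np.random.default_rng(seed)
        t0 = rng.random((20, 20)) > 0.8
        t1 = rng.random((20, 20)) > 0.8
        if not t0.any():
            t0[0, 0] = True
        base = displacement_fraction(t0, t1)
        # flipping background-only pixels of t1's complement leaves result
        flipped = displacement_fraction(t0[::-1, ::-1], t1[::-1, ::-1])
        assert base.percent_displaced == flipped.percent_displaced
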