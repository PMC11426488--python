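"""The synthetic-trial generator: determinism, forward models, injected effects."""

import dataclasses

import numpy as np
import pytest

from plumekin import kinematics as kin
from plumekin import plume
from plumekin.config import AnalysisConfig
from plumekin.synthetic import (
    GroundTruth,
    SyntheticConfig,
    gen_accel_trace,
    gen_cohort,
    gen_events,
    gen_sensor_trace,
    gen_trajectory,
    gen_trial,
    read_ground_truth_csv,
    write_ground_truth_csv,
)


class TestGroundTruth:
    def test_null_factory(self):
        t = GroundTruth.null()
        assert t.null_mode
        assert t.amp_boost_pre == t.amp_drop_post == t.heading_var_drop_post == 1.0
        assert t.freq_shift_post == t.head_drop_post == 0.0

    def test_null_mode_rejects_modulations(self):
        with pytest.raises(ValueError, match="null_mode"):
            GroundTruth(null_mode=True)  # defaults carry modulations

    def test_factors_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            GroundTruth(amp_drop_post=0.0)


class TestEvents:
    def test_events_respect_refractory_and_edges(self, cfg):
        synth = SyntheticConfig(duration=300.0)
        on = gen_events(cfg, synth, seed=5)
        assert np.all(on >= cfg.window_half)
        assert np.all(on <= synth.duration - cfg.window_half)
        if len(on) > 1:
            assert np.min(np.diff(on)) > 2 * cfg.min_event_separation

    def test_exact_event_count(self, cfg):
        synth = SyntheticConfig(duration=120.0, events_per_trial=3)
        on = gen_events(cfg, synth, seed=1)
        assert len(on) == 3


class TestSensorTrace:
    def test_silent_world_is_flat(self, cfg):
        synth = SyntheticConfig(duration=20.0, sensor_noise_sd=0.0,
                                drift_amplitude=0.0)
        ts = gen_sensor_trace([], cfg, seed=0, synth=synth)
        np.testing.assert_allclose(ts.values, synth.sensor_baseline, atol=1e-12)

    def test_single_impulse_matches_convolution_oracle(self, cfg):
        # one-sample pulse: the trace must equal the kernel shifted to the
        # onset (oracle: direct convolution)
        synth = SyntheticConfig(duration=30.0, sensor_noise_sd=0.0,
                                drift_amplitude=0.0, pulse_width=1 / cfg.fs_sensor,
                                pulse_area=1.0)
        ts = gen_sensor_trace([10.0], cfg, seed=0, synth=synth)
        k = plume.response_kernel(cfg.tau_rise, cfg.tau_decay, cfg.fs_sensor,
                                  support=cfg.kernel_support)
        n = int(30.0 * cfg.fs_sensor)
        expected = np.zeros(n)
        i0 = int(10.0 * cfg.fs_sensor)
        expected[i0:] = k[: n - i0]
        np.testing.assert_allclose(
            ts.values - synth.sensor_baseline, expected, atol=1e-9
        )

    def test_superposition_of_two_onsets(self, cfg):
        synth = SyntheticConfig(duration=30.0, sensor_noise_sd=0.0,
                                drift_amplitude=0.0)
        both = gen_sensor_trace([10.0, 11.0], cfg, seed=0, synth=synth)
        a = gen_sensor_trace([10.0], cfg, seed=0, synth=synth)
        b = gen_sensor_trace([11.0], cfg, seed=0, synth=synth)
        np.testing.assert_allclose(
            both.values - synth.sensor_baseline,
            (a.values - synth.sensor_baseline) + (b.values - synth.sensor_baseline),
            atol=1e-9,
        )

    def test_onset_outside_duration_rejected(self, cfg):
        with pytest.raises(ValueError, match="duration"):
            gen_sensor_trace([50.0], cfg, seed=0,
                             synth=SyntheticConfig(duration=30.0))


class TestAccelTrace:
    def test_pure_raised_schedule_constant_head_height(self, cfg):
        synth = SyntheticConfig(duration=20.0, accel_noise_sd=0.0,
                                pitch_amp=0.0, pitch_freq_wander_sd=0.0)
        ts = gen_accel_trace([], [(0.0, 20.0, "raised")], cfg, seed=0,
                            truth=GroundTruth.null(), synth=synth)
        d = ts.values[:, 2] - ts.values[:, 0]
        np.testing.assert_allclose(d, synth.z_raised - synth.x_raised, atol=1e-9)

    def test_schedule_gap_rejected(self, cfg):
        with pytest.raises(ValueError, match="schedule"):
            gen_accel_trace([], [(0.0, 5.0, "raised")], cfg, seed=0,
                           synth=SyntheticConfig(duration=20.0))

    def test_amplitude_modulation_windows(self, cfg):
        # generator-side analytic check: oscillation envelope scales by the
        # boost factor in [-1, 0) and the drop factor in [0, 1)
        synth = SyntheticConfig(duration=40.0, accel_noise_sd=0.0,
                                pitch_freq_wander_sd=0.0,
                                pitch_freq_raised_offset=0.0)
        truth = GroundTruth(amp_boost_pre=1.5, amp_drop_post=0.6,
                            freq_shift_post=0.0, head_drop_post=0.0)
        onset = 20.0
        ts = gen_accel_trace([onset], [(0.0, 40.0, "raised")], cfg, seed=3,
                            truth=truth, synth=synth)
        x = ts.values[:, 0] - np.median(ts.values[:, 0])
        fs = cfg.fs_accel
        rms = lambda lo, hi: np.sqrt(np.mean(
            x[int((onset + lo) * fs):int((onset + hi) * fs)] ** 2))
        base = rms(-5.0, -1.5)
        assert rms(-0.9, -0.1) / base == pytest.approx(1.5, rel=0.1)
        assert rms(0.1, 0.9) / base == pytest.approx(0.6, rel=0.1)

    def test_null_mode_band_power_stationary(self, cfg):
        synth = SyntheticConfig(duration=60.0)
        ts = gen_accel_trace([20.0, 40.0], [(0.0, 60.0, "raised")], cfg, seed=4,
                            truth=GroundTruth.null(), synth=synth)
        from plumekin import headmotion as hm
        j = hm.jerk(ts, cfg)
        bp = hm.cwt_band_power(j.channel(0), cfg)
        fs = cfg.fs_accel
        pre = np.concatenate([bp.power[int((o - 1) * fs):int(o * fs)] for o in (20, 40)])
        post = np.concatenate([bp.power[int(o * fs):int((o + 1) * fs)] for o in (20, 40)])
        assert 0.5 < pre.mean() / post.mean() < 2.0


class TestTrajectory:
    def test_noiseless_walk_aims_at_port(self, cfg):
        synth = SyntheticConfig(duration=10.0, heading_noise_sd=0.0,
                                yaw_amp=0.0, yaw_noise_sd=0.0,
                                dropout_fraction=0.0)
        track, port = gen_trajectory(cfg, GroundTruth.null(), seed=2, synth=synth)
        angles = kin.body_angle(track, port)
        # ignore frames right after a capture reset (positions jump)
        ok = angles.valid & np.isfinite(angles.angle)
        assert np.nanmax(np.abs(angles.angle[ok])) < 1e-6

    def test_heading_variance_drop_after_onsets(self, cfg):
        synth = SyntheticConfig(duration=120.0, events_per_trial=6,
                                dropout_fraction=0.0)
        truth = GroundTruth(heading_var_drop_post=0.3)
        lower = 0
        n_seeds = 8
        for seed in range(n_seeds):
            onsets = gen_events(cfg, synth, seed=1000 + seed)
            track, port = gen_trajectory(cfg, truth, seed=seed, synth=synth,
                                         true_onsets=onsets)
            ang = kin.body_angle(track, port).angle
            fps = cfg.fps_video
            pre, post = [], []
            for o in onsets:
                pre.extend(ang[int((o - 3) * fps):int(o * fps)])
                post.extend(ang[int(o * fps):int((o + 3) * fps)])
            csd = lambda a: np.sqrt(-2 * np.log(np.abs(
                np.nanmean(np.exp(1j * np.radians(np.asarray(a)))))))
            lower += csd(post) < csd(pre)
        assert lower >= n_seeds - 1

    def test_port_inside_arena(self, cfg):
        synth = SyntheticConfig(duration=5.0)
        _, port = gen_trajectory(cfg, GroundTruth.null(), seed=9, synth=synth)
        x0, y0, x1, y1 = synth.arena
        assert x0 < port[0] < x1 and y0 < port[1] < y1

    def test_seed_required(self, cfg):
        with pytest.raises(ValueError, match="seed"):
            gen_trajectory(cfg, GroundTruth.null(), seed=None)


class TestTrialAndCohort:
    def test_same_seed_bit_identical(self, cfg, short_synth):
        a = gen_trial(cfg, GroundTruth.null(), 11, short_synth)
        b = gen_trial(cfg, GroundTruth.null(), 11, short_synth)
        np.testing.assert_array_equal(a.trial.sensor.values, b.trial.sensor.values)
        np.testing.assert_array_equal(a.trial.accel.values, b.trial.accel.values)
        np.testing.assert_array_equal(a.trial.keypoints.nose, b.trial.keypoints.nose)
        np.testing.assert_array_equal(a.truth.true_onsets, b.truth.true_onsets)

    def test_cohort_has_distinct_onset_sets(self, cfg, short_synth):
        cohort = gen_cohort(cfg, GroundTruth.null(), 8, 3, short_synth)
        assert len(cohort) == 8
        keys = {tuple(np.round(st.truth.true_onsets, 6)) for st in cohort
                if len(st.truth.true_onsets)}
        assert len(keys) > 1

    def test_event_count_bookkeeping(self, cfg):
        synth = SyntheticConfig(duration=60.0, events_per_trial=2)
        cohort = gen_cohort(cfg, GroundTruth.null(), 30, 7, synth)
        total = sum(len(st.truth.true_onsets) for st in cohort)
        assert total == 60

    def test_onsets_inside_windowable_range(self, cfg, short_synth):
        for st in gen_cohort(cfg, GroundTruth.null(), 5, 21, short_synth):
            on = st.truth.true_onsets
            a, b = st.trial.in_arena[0]
            assert np.all(on >= a + cfg.window_half)
            assert np.all(on <= b - cfg.window_half)

    def test_ground_truth_csv_round_trip(self, cfg, short_synth, tmp_path):
        cohort = gen_cohort(cfg, GroundTruth(), 3, 5, short_synth)
        write_ground_truth_csv(cohort, tmp_path / "gt.csv")
        df, meta = read_ground_truth_csv(tmp_path / "gt.csv")
        assert meta["amp_boost_pre"] == 1.5
        assert len(df) == sum(len(st.truth.true_onsets) for st in cohort)
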