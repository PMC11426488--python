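"""Peri-event windows, surrogate sampling, and the statistical comparisons."""

import numpy as np
import pytest
from scipy import stats as sstats

from plumekin import perievent as pe
from plumekin.config import AnalysisConfig
from plumekin.kinematics import AngleSeries
from plumekin.plume import PlumeEventList
from plumekin.timeseries import TimeSeries

FS = 100.0


def events(onsets, retained=None):
    onsets = np.asarray(onsets, float)
    return PlumeEventList(
        onsets=onsets, ratio_at_onset=np.full(len(onsets), 2.0),
        retained=np.ones(len(onsets), bool) if retained is None
        else np.asarray(retained, bool),
    )


def identity_series(duration=60.0):
    n = int(duration * FS)
    return TimeSeries(0.0, FS, np.arange(n) / FS)


class TestExtractRealWindows:
    def test_identity_series_rows_are_onset_plus_axis(self, cfg):
        s = identity_series()
        out = pe.extract_real_windows(s, events([30.0]), cfg)
        np.testing.assert_allclose(out.real[0], 30.0 + out.time_axis, atol=1e-9)

    def test_one_row_per_retained_event(self, cfg):
        out = pe.extract_real_windows(identity_series(),
                                      events([10.0, 20.0, 30.0],
                                             retained=[True, False, True]), cfg)
        assert out.real.shape[0] == 2

    def test_edge_event_is_hard_error(self, cfg):
        with pytest.raises(ValueError, match="edge"):
            pe.extract_real_windows(identity_series(), events([3.0]), cfg)


class TestSampleRandomWindows:
    def test_count_matches_real_events(self, cfg):
        out = pe.sample_random_windows(identity_series(), events([10.0, 20.0, 30.0]),
                                       [(0.0, 60.0)], cfg, seed=0)
        assert out.random.shape[0] == 3

    def test_exclusion_zone_never_hit(self, cfg):
        ev = events([20.0, 40.0])
        hits = []
        for seed in range(250):
            out = pe.sample_random_windows(identity_series(), ev, [(0.0, 60.0)],
                                           cfg, seed=seed)
            hits.extend(out.random_t0)
        hits = np.asarray(hits)  # 500 draws
        for onset in ev.onsets:
            assert np.all(np.abs(hits - onset) >= cfg.random_exclusion)

    def test_surrogates_uniform_over_admissible_times(self, cfg):
        ev = events([20.0])
        draws = []
        for seed in range(400):
            out = pe.sample_random_windows(identity_series(), ev, [(0.0, 60.0)],
                                           cfg, seed=seed)
            draws.extend(out.random_t0)
        draws = np.sort(np.asarray(draws))
        # admissible support: [5, 19] u [21, 55]; map to a uniform cdf
        lens = np.array([14.0, 34.0])
        u = np.where(draws < 20.0, draws - 5.0, 14.0 + draws - 21.0) / lens.sum()
        assert sstats.kstest(u, "uniform").pvalue > 0.01

    def test_short_arena_interval_rejected(self, cfg):
        with pytest.raises(ValueError, match="admissible"):
            pe.sample_random_windows(identity_series(12.0), events([6.0]),
                                     [(0.0, 8.0)], cfg, seed=0)


class TestBinMeans:
    def test_constant_rows(self, cfg):
        out = pe.extract_real_windows(
            TimeSeries(0, FS, np.full(6000, 7.0)), events([30.0]), cfg)
        means, labels = pe.bin_means(out.real, out.time_axis, 1.0, 5.0)
        assert means.shape == (1, 10)
        np.testing.assert_allclose(means, 7.0, atol=1e-12)
        assert labels[0] == "-5 to -4" and labels[-1] == "4 to 5"

    def test_identity_rows_give_bin_midpoints(self, cfg):
        out = pe.extract_real_windows(identity_series(), events([30.0]), cfg)
        means, _ = pe.bin_means(out.real - 30.0, out.time_axis, 1.0, 5.0)
        expected = np.arange(-4.5, 5.0, 1.0)
        np.testing.assert_allclose(means[0], expected, atol=0.01)

    def test_all_missing_bin_stays_missing(self, cfg):
        rows = np.full((1, 11), np.nan)
        rows[0, 6:] = 1.0
        axis = np.linspace(-5, 5, 11)
        means, _ = pe.bin_means(rows, axis, 1.0, 5.0)
        assert np.isnan(means[0, 0])
        assert np.isfinite(means[0, -1])

    def test_bin_width_must_divide_window(self):
        with pytest.raises(ValueError, match="divide"):
            pe.bin_means(np.zeros((1, 10)), np.linspace(-5, 5, 10), 0.7, 5.0)


class TestKsPerBin:
    def test_identical_samples_no_difference(self):
        x = np.tile(np.arange(10.0), (10, 1))
        bc = pe.ks_per_bin(x, x.copy(), [str(i) for i in range(10)])
        np.testing.assert_allclose(bc.ks_stat, 0.0)
        np.testing.assert_allclose(bc.p_value, 1.0)

    def test_insufficient_data_flagged_not_fatal(self):
        a = np.random.default_rng(0).normal(size=(3, 2))
        bc = pe.ks_per_bin(a, a + 1.0, ["a", "b"], min_n=5)
        assert np.all(np.isnan(bc.p_value))
        assert np.all(bc.n_real == 3)

    def test_power_against_shifted_alternative(self, rng):
        # real ~ N(1,1), random ~ N(0,1), n=100/side: asymptotic p below
        # 0.01 nearly always, and the permutation oracle agrees
        hits = 0
        for rep in range(40):
            r = rng.normal(1.0, 1.0, (100, 1))
            s = rng.normal(0.0, 1.0, (100, 1))
            bc = pe.ks_per_bin(r, s, ["0"])
            hits += bc.p_value[0] < 0.01
        assert hits >= 38

    def test_asymptotic_agrees_with_permutation_oracle(self, rng):
        r = rng.normal(0.3, 1.0, (40, 1))
        s = rng.normal(0.0, 1.0, (40, 1))
        bc = pe.ks_per_bin(r, s, ["0"])
        oracle = pe.ks_per_bin_permutation(r, s, ["0"], n_perm=2000, seed=1)
        assert bc.ks_stat[0] == pytest.approx(oracle.ks_stat[0])
        # permutation p and asymptotic p agree within Monte-Carlo slack
        assert abs(bc.p_value[0] - oracle.p_value[0]) < 0.05

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        n_rep = 150
        for rep in range(n_rep):
            r = rng.normal(0.0, 1.0, (60, 1))
            s = rng.normal(0.0, 1.0, (60, 1))
            rejections += pe.ks_per_bin(r, s, ["0"]).p_value[0] < 0.05
        assert 0.015 <= rejections / n_rep <= 0.09


class TestResultsCsv:
    def test_round_trip(self, rng, tmp_path):
        a = rng.normal(size=(30, 10))
        b = rng.normal(size=(30, 10))
        labels = [f"{i - 5} to {i - 4}" for i in range(10)]
        tables = {"band_power": pe.ks_per_bin(a, b, labels),
                  "head_height": pe.ks_per_bin(a + 1, b, labels)}
        pe.write_results_csv(tables, tmp_path / "res.csv")
        back = pe.read_results_csv(tmp_path / "res.csv")
        assert set(back) == set(tables)
        np.testing.assert_allclose(back["band_power"].p_value,
                                   tables["band_power"].p_value, rtol=1e-5)
        assert back["head_height"].labels == labels

    def test_missing_column_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("parameter,bin\nx,a\n")
        with pytest.raises(ValueError, match="missing column"):
            pe.read_results_csv(tmp_path / "bad.csv")


class TestCircular:
    def test_identical_angles(self):
        mean, R = pe.circular_mean_R([37.0] * 20)
        assert mean == pytest.approx(37.0)
        assert R == pytest.approx(1.0)

    def test_antipodal_pair_cancels(self):
        _, R = pe.circular_mean_R([0.0, 180.0])
        assert R == pytest.approx(0.0, abs=1e-12)

    def test_uniform_angles_near_zero(self, rng):
        _, R = pe.circular_mean_R(rng.uniform(-180, 180, 10_000))
        assert R < 0.03

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            pe.circular_mean_R([])

    def test_R_invariant_to_rotation(self, rng):
        a = rng.normal(20.0, 30.0, 500)
        _, r1 = pe.circular_mean_R(a)
        _, r2 = pe.circular_mean_R(a + 111.0)
        assert r1 == pytest.approx(r2, abs=1e-12)


def angle_windows(cfg, rows):
    """Wrap raw angle rows (deg) into a PeriEventSet on the standard axis."""
    m = int(round(cfg.window_half * FS))
    axis = np.arange(-m, m + 1) / FS
    assert rows.shape[1] == len(axis)
    return pe.PeriEventSet(time_axis=axis, real=rows, random=rows.copy())


class TestAngleDeviations:
    def test_constant_angle_zero_deviation(self, cfg):
        rows = np.full((3, 1001), 25.0)
        win = angle_windows(cfg, rows)
        before, after = pe.angle_deviation_distributions(win, cfg)
        np.testing.assert_allclose(before, 0.0, atol=1e-9)
        np.testing.assert_allclose(after, 0.0, atol=1e-9)

    def test_wrapping_at_180(self, cfg):
        rows = np.full((1, 1001), np.nan)
        sel = np.arange(1001)
        rows[0, sel % 2 == 0] = 179.0
        rows[0, sel % 2 == 1] = -179.0
        win = angle_windows(cfg, rows)
        before, after = pe.angle_deviation_distributions(win, cfg)
        assert set(np.round(np.unique(np.abs(np.concatenate([before, after]))), 6)) == {1.0}

    def test_variance_drop_direction(self, cfg, rng):
        n_rows, m = 40, 1001
        axis_post = np.arange(m) >= 500
        rows = np.where(axis_post, rng.normal(0, 10, (n_rows, m)),
                        rng.normal(0, 20, (n_rows, m)))
        win = angle_windows(cfg, rows)
        before, after = pe.angle_deviation_distributions(win, cfg)
        assert np.std(after) < np.std(before)


class TestPairedRTest:
    def test_no_change_reports_no_effect(self, cfg):
        rows = np.tile(np.linspace(-30, 30, 1001), (8, 1))
        res = pe.paired_R_test(angle_windows(cfg, rows), cfg)
        assert res.p_value == 1.0

    def test_power_under_known_variance_drop(self, cfg, rng):
        hits = 0
        for rep in range(20):
            rows = np.concatenate([
                rng.normal(0, 60, (30, 501)), rng.normal(0, 18, (30, 500))
            ], axis=1)
            res = pe.paired_R_test(angle_windows(cfg, rows), cfg)
            hits += (res.p_value < 0.05) and (np.mean(res.r_after) > np.mean(res.r_before))
        assert hits >= 18

    def test_type_one_error_calibrated(self, cfg, rng):
        rejections = 0
        n_rep = 150
        for rep in range(n_rep):
            rows = rng.normal(0, 40, (30, 1001))
            res = pe.paired_R_test(angle_windows(cfg, rows), cfg)
            rejections += res.p_value < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_too_few_rows_rejected(self, cfg):
        rows = np.tile(np.linspace(-30, 30, 1001), (4, 1))
        with pytest.raises(ValueError, match="6 rows"):
            pe.paired_R_test(angle_windows(cfg, rows), cfg)


class TestCrossingRate:
    def test_single_constant_rate_row_is_flat_zero(self, cfg):
        # crossings every 0.25 s with a generic offset: every full 0.5 s
        # window holds exactly two, so the rate is exactly constant
        crossings = [np.arange(-5.0, 5.0, 0.25) + 0.013]
        axis, mean, sem, n_used, n_exc, _ = pe.zscored_crossing_rate(crossings, cfg)
        assert n_used == 1 and n_exc == 0
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)

    def test_empty_rows_excluded(self, cfg):
        crossings = [np.array([]), np.arange(-5.0, 5.0, 0.5)]
        _, _, _, n_used, n_exc, _ = pe.zscored_crossing_rate(crossings, cfg)
        assert n_used == 1 and n_exc == 1

    def test_homogeneous_poisson_flat(self, cfg, rng):
        rows = []
        for _ in range(200):
            n = rng.poisson(40)
            rows.append(np.sort(rng.uniform(-5, 5, n)))
        axis, mean, _, n_used, _, _ = pe.zscored_crossing_rate(rows, cfg)
        # pointwise max over ~600 correlated grid points: allow ~3.5 SE
        assert np.abs(mean).max() < 0.25
        assert np.abs(mean).mean() < 0.08

    def test_rate_boost_appears_post_onset(self, cfg, rng):
        rows = []
        for _ in range(200):
            base = np.sort(rng.uniform(-5, 5, rng.poisson(30)))
            boost = np.sort(rng.uniform(0.0, 0.5, rng.poisson(6)))
            rows.append(np.sort(np.concatenate([base, boost])))
        axis, mean, _, _, _, _ = pe.zscored_crossing_rate(rows, cfg)
        sel = (axis >= 0.0) & (axis < 0.5)
        rest = (axis < -0.5) | (axis > 1.0)
        assert mean[sel].mean() > mean[rest].mean() + 0.3
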