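import numpy as np
import pandas as pd
import pytest

from envtrace.traj import (INDIVIDUAL_FEATURES, WINDOW_SUBSET, acf_lag1,
                           brownian_scaling, circular_rho, first_passage_times,
                           fpt_features, individual_feature_vector,
                           individual_features_batch, msd, msd_fit,
                           net_gross_ratio, step_speeds, tangential_velocity,
                           turning_angles)


def straight_path(n, v=1.0):
    t = np.arange(n, dtype=float)
    return t, np.column_stack([v * t, np.zeros(n)])


class TestStepSpeeds:
    def test_unit_steps(self):
        t, xy = straight_path(10)
        assert np.allclose(step_speeds(t, xy), 1.0)

    def test_stationary(self):
        t = np.arange(5, dtype=float)
        assert np.allclose(step_speeds(t, np.zeros((5, 2))), 0.0)

    def test_rayleigh_mean_speed(self, rng):
        """2-D Gaussian steps: mean speed = sigma*sqrt(pi/2)."""
        sigma = 0.7
        xy = np.cumsum(rng.normal(0, sigma, (200_000, 2)), axis=0)
        sp = step_speeds(np.arange(len(xy), dtype=float), xy)
        assert sp.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)


class TestTurningAndRho:
    def test_straight_line_angles_zero_rho_one(self):
        _, xy = straight_path(20)
        ta = turning_angles(xy)
        assert np.allclose(ta, 0.0)
        assert circular_rho(ta) == pytest.approx(1.0)

    def test_alternating_right_angles(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [2, 1], [2, 2]], float)
        assert np.allclose(np.abs(turning_angles(xy)), np.pi / 2)

    def test_uniform_headings_rho_vanishes(self, rng):
        angles = rng.uniform(-np.pi, np.pi, 100_000)
        assert circular_rho(angles) < 0.02

    @pytest.mark.parametrize("angles,expect", [
        ([0.3] * 8, 1.0),
        ([0, np.pi / 2, np.pi, 3 * np.pi / 2], 0.0),
        ([0, np.pi / 2], np.sqrt(2) / 2),
    ])
    def test_rho_values(self, angles, expect):
        assert circular_rho(np.array(angles)) == pytest.approx(expect, abs=1e-12)


class TestAcf:
    def test_linear_trend_tends_to_one(self):
        assert acf_lag1(np.arange(10_000.0)) == pytest.approx(1.0, abs=1e-3)

    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 50)  # n = 100
        assert acf_lag1(x) == pytest.approx(-99 / 100)

    def test_white_noise_near_zero(self, rng):
        assert abs(acf_lag1(rng.normal(size=10_000))) < 0.05

    def test_zero_variance_missing(self):
        assert np.isnan(acf_lag1(np.ones(10)))


class TestTangentialVelocity:
    def test_uniform_circular_motion(self):
        r, omega = 10.0, 0.1
        t = np.arange(40, dtype=float)
        xy = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t)])
        tv = tangential_velocity(t, xy)
        assert np.allclose(tv, r * omega, rtol=1e-9)

    def test_stationary_missing(self):
        t = np.arange(5, dtype=float)
        assert np.all(np.isnan(tangential_velocity(t, np.zeros((5, 2)))))

    def test_straight_line_missing(self):
        t, xy = straight_path(10)
        assert np.all(np.isnan(tangential_velocity(t, xy)))


class TestNetGrossRatio:
    def test_straight(self):
        assert net_gross_ratio(straight_path(10)[1]) == pytest.approx(1.0)

    def test_closed_loop(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        assert net_gross_ratio(xy) == pytest.approx(0.0)

    def test_right_angle_equal_legs(self):
        xy = np.array([[0, 0], [1, 0], [1, 1]], float)
        assert net_gross_ratio(xy) == pytest.approx(np.sqrt(2) / 2)


class TestBrownianScaling:
    def test_constant_velocity_is_zero(self):
        t, xy = straight_path(50, v=2.0)
        assert brownian_scaling(t, xy) == pytest.approx(0.0, abs=1e-12)

    def test_recovers_increment_sigma(self, rng):
        sigma = 2.0
        xy = np.cumsum(rng.normal(0, sigma, (100_000, 2)), axis=0)
        t = np.arange(len(xy), dtype=float)
        assert brownian_scaling(t, xy) == pytest.approx(sigma, rel=0.02)

    def test_homogeneity(self, rng):
        xy = np.cumsum(rng.normal(0, 1, (500, 2)), axis=0)
        t = np.arange(len(xy), dtype=float)
        assert brownian_scaling(t, 2 * xy) == pytest.approx(
            2 * brownian_scaling(t, xy), rel=1e-12)


class TestMsd:
    def test_ballistic_closed_form(self):
        t, xy = straight_path(100)
        a, b = msd_fit(t, xy)
        assert a == pytest.approx(1.0, rel=1e-9)
        assert b == pytest.approx(2.0, rel=1e-9)

    def test_brownian_exponent_near_one(self, rng):
        xy = np.cumsum(rng.normal(0, 1, (10_000, 2)), axis=0)
        t = np.arange(len(xy), dtype=float)
        _, b = msd_fit(t, xy)
        assert b == pytest.approx(1.0, abs=0.1)

    def test_stationary_missing(self):
        t = np.arange(20, dtype=float)
        a, b = msd_fit(t, np.zeros((20, 2)))
        assert np.isnan(a) and np.isnan(b)

    def test_matches_bruteforce_on_random_path(self, rng):
        xy = np.cumsum(rng.normal(0, 1, (50, 2)), axis=0)
        t = np.arange(50, dtype=float)
        got = msd(t, xy)
        for i, tau in enumerate(range(1, 7)):
            pairs = [np.sum((xy[j + tau] - xy[j]) ** 2)
                     for j in range(50 - tau)]
            assert got[i] == pytest.approx(np.mean(pairs), rel=1e-12)


def bruteforce_fpt(t, xy, radius):
    """Independent per-fix both-directions FPT with interpolated crossings."""
    n = len(t)
    out = np.full(n, np.nan)
    for i in range(n):
        d = np.linalg.norm(xy - xy[i], axis=1)
        fwd = bwd = np.nan
        for j in range(i + 1, n):
            if d[j] >= radius:
                tc = t[j - 1] + (radius - d[j - 1]) / (d[j] - d[j - 1]) * (
                    t[j] - t[j - 1])
                fwd = tc - t[i]
                break
        for j in range(i - 1, -1, -1):
            if d[j] >= radius:
                tc = t[j + 1] - (radius - d[j + 1]) / (d[j] - d[j + 1]) * (
                    t[j + 1] - t[j])
                bwd = t[i] - tc
                break
        out[i] = fwd + bwd
    return out


class TestFpt:
    def test_straight_line_fpt_is_2r_over_v(self):
        t, xy = straight_path(60)
        fpt = first_passage_times(t, xy, 5.0)
        interior = fpt[6:-6]
        assert np.allclose(interior, 10.0)
        feats = fpt_features(t, xy)
        assert feats["fpt__mean_5m"] == pytest.approx(10.0, rel=1e-6)
        assert feats["fpt__var_log_5m"] == pytest.approx(0.0, abs=1e-12)
        assert feats["fpt__loglog_slope"] == pytest.approx(1.0, rel=1e-6)

    def test_tight_cluster_fully_censored(self, rng):
        xy = rng.uniform(0, 0.5, (30, 2))
        t = np.arange(30, dtype=float)
        fpt = first_passage_times(t, xy, 5.0)
        assert np.all(np.isnan(fpt))
        assert np.isnan(fpt_features(t, xy)["fpt__mean_5m"])

    def test_matches_bruteforce_on_random_path(self, rng):
        xy = np.cumsum(rng.normal(0, 1.5, (50, 2)), axis=0)
        t = np.arange(50, dtype=float)
        for r in (1.0, 3.0, 5.0):
            got = first_passage_times(t, xy, r)
            want = bruteforce_fpt(t, xy, r)
            np.testing.assert_allclose(got, want, rtol=1e-9, equal_nan=True)

    def test_forward_only_mode(self):
        t, xy = straight_path(30)
        fpt = first_passage_times(t, xy, 5.0, mode="forward")
        assert np.allclose(fpt[:-6], 5.0)


class TestFeatureVector:
    def test_straight_hour(self):
        t, xy = straight_path(3600)
        v = individual_feature_vector(t, xy, fpt_center_stride=5)
        assert v["speed__mean"] == pytest.approx(1.0)
        assert v["speed__sd"] == pytest.approx(0.0, abs=1e-9)
        assert v["net_gross_ratio"] == pytest.approx(1.0)
        assert v["turn__rho"] == pytest.approx(1.0)
        assert v["msd__power_b"] == pytest.approx(2.0, rel=1e-6)
        assert v["fpt__loglog_slope"] == pytest.approx(1.0, rel=1e-4)

    def test_has_27_features(self):
        assert len(INDIVIDUAL_FEATURES) == 27
        t, xy = straight_path(100)
        assert individual_feature_vector(t, xy).size == 27

    def test_deterministic(self, rng):
        xy = np.cumsum(rng.normal(0, 1, (60, 2)), axis=0)
        t = np.arange(60, dtype=float)
        a = individual_feature_vector(t, xy)
        b = individual_feature_vector(t, xy)
        pd.testing.assert_series_equal(a, b)

    def test_rigid_motion_invariance(self, rng):
        xy = np.cumsum(rng.normal(0, 0.5, (60, 2)), axis=0)
        t = np.arange(60, dtype=float)
        base = individual_feature_vector(t, xy)
        ang = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        moved = xy @ rot.T + rng.uniform(-100, 100, 2)
        got = individual_feature_vector(t, moved)
        np.testing.assert_allclose(got.to_numpy(), base.to_numpy(),
                                   rtol=1e-7, atol=1e-9, equal_nan=True)


class TestBatchEquivalence:
    def test_batch_matches_scalar_on_random_windows(self, rng):
        """The vectorised per-window path reproduces the scalar feature
        vector (on the 24-feature subset) exactly."""
        k = 3
        xy = np.cumsum(rng.normal(0, 0.4, (200, k, 2)), axis=1)
        batch = individual_features_batch(xy)
        assert list(batch.columns) == list(WINDOW_SUBSET)
        for i in range(0, 200, 17):
            t = np.arange(k, dtype=float)
            want = individual_feature_vector(t, xy[i])[list(WINDOW_SUBSET)]
            np.testing.assert_allclose(batch.iloc[i].to_numpy(),
                                       want.to_numpy(), rtol=1e-9,
                                       atol=1e-12, equal_nan=True)

    def test_batch_matches_scalar_on_longer_windows(self, rng):
        k = 10
        xy = np.cumsum(rng.normal(0, 1.0, (40, k, 2)), axis=1)
        batch = individual_features_batch(xy)
        for i in range(0, 40, 7):
            t = np.arange(k, dtype=float)
            want = individual_feature_vector(t, xy[i])[list(WINDOW_SUBSET)]
            np.testing.assert_allclose(batch.iloc[i].to_numpy(),
                                       want.to_numpy(), rtol=1e-9,
                                       atol=1e-12, equal_nan=True)

    def test_subset_has_24_features(self):
        assert len(WINDOW_SUBSET) == 24
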