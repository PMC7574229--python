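import numpy as np
import pandas as pd
import pytest

from envtrace.accel import (CHANNELS, STATS, accel_feature_matrix,
                            feature_names, geometric_transform,
                            window_statistics)


def oracle_transform(x, y, z):
    """Independent evaluation of the 21 geometric channel formulas."""
    import math
    r_xy = math.hypot(x, y)
    r_xz = math.hypot(x, z)
    r_yz = math.hypot(y, z)
    r_xyz = math.sqrt(x * x + y * y + z * z)

    def ang(num, den):
        return math.atan2(num, den) if (num, den) != (0.0, 0.0) else np.nan

    def solid(num, den):
        if den == 0:
            return 0.0 if num == 0 else np.nan
        return math.asin(max(-1.0, min(1.0, num / den)))

    cross = np.cross([x, y, 0.0], [x, 0.0, z])
    return {
        "x": x, "y": y, "z": z,
        "r_xyz": r_xyz, "r_xy": r_xy, "r_xz": r_xz, "r_yz": r_yz,
        "theta_xy": ang(y, x), "theta_xz": ang(z, x), "theta_yz": ang(z, y),
        "theta_z": ang(z, r_xy), "theta_y": ang(y, r_xz),
        "theta_x": ang(x, r_yz),
        "omega_x": solid(y * z, r_xy * r_xz),
        "omega_y": solid(x * z, r_xy * r_yz),
        "omega_z": solid(x * y, r_xz * r_yz),
        "v_xyz": x * y * z,
        "a_x": y * z, "a_y": x * z, "a_z": x * y,
        "a_xyz": 0.5 * float(np.linalg.norm(cross)),
    }


class TestGeometricTransform:
    def test_unit_diagonal_sample(self):
        g = dict(zip(CHANNELS, geometric_transform([1.0, 1.0, 1.0])))
        assert g["r_xyz"] == pytest.approx(np.sqrt(3))
        assert g["theta_xy"] == pytest.approx(np.pi / 4)
        assert g["omega_z"] == pytest.approx(np.pi / 6)
        assert g["v_xyz"] == pytest.approx(1.0)
        assert g["a_xyz"] == pytest.approx(np.sqrt(3) / 2)

    def test_3_4_0_sample(self):
        g = dict(zip(CHANNELS, geometric_transform([3.0, 4.0, 0.0])))
        assert g["r_xy"] == 5.0
        assert g["r_xyz"] == 5.0
        assert g["v_xyz"] == 0.0
        assert g["a_z"] == 12.0

    def test_axis_aligned_sample(self):
        g = dict(zip(CHANNELS, geometric_transform([1.0, 0.0, 0.0])))
        assert g["theta_xy"] == 0.0
        assert g["omega_z"] == 0.0
        assert g["v_xyz"] == g["a_x"] == g["a_y"] == g["a_z"] == 0.0
        assert g["a_xyz"] == 0.0

    def test_matches_independent_oracle_on_random_samples(self, rng):
        xyz = rng.normal(0, 5, (1000, 3))
        got = geometric_transform(xyz)
        for i in range(1000):
            want = oracle_transform(*xyz[i])
            for c, ch in enumerate(CHANNELS):
                assert got[i, c] == pytest.approx(want[ch], abs=1e-9), ch

    def test_scaling_property(self, rng):
        xyz = rng.normal(0, 2, (50, 3))
        c = 3.7
        base = geometric_transform(xyz)
        scaled = geometric_transform(c * xyz)
        names = list(CHANNELS)
        for ch in ("x", "y", "z", "r_xyz", "r_xy", "r_xz", "r_yz"):
            np.testing.assert_allclose(scaled[:, names.index(ch)],
                                       c * base[:, names.index(ch)], rtol=1e-9)
        np.testing.assert_allclose(scaled[:, names.index("v_xyz")],
                                   c**3 * base[:, names.index("v_xyz")],
                                   rtol=1e-9)
        for ch in ("a_x", "a_y", "a_z", "a_xyz"):
            np.testing.assert_allclose(scaled[:, names.index(ch)],
                                       c**2 * base[:, names.index(ch)],
                                       rtol=1e-9)
        for ch in names:
            if ch.startswith(("theta", "omega")):
                np.testing.assert_allclose(scaled[:, names.index(ch)],
                                           base[:, names.index(ch)],
                                           rtol=0, atol=1e-9)


class TestWindowStatistics:
    def test_constant_series(self):
        s = dict(zip(STATS, window_statistics(np.full(96, 2.0), 3.0)))
        assert s["mean"] == 2.0 and s["sd"] == 0.0
        assert s["median"] == s["q1"] == s["q3"] == s["min"] == s["max"] == 2.0
        assert s["dominant_amplitude"] == 0.0
        assert np.isnan(s["dominant_period_s"])
        assert s["spectral_energy"] == pytest.approx((96 * 2.0) ** 2)

    def test_pure_tone_dominant_period(self):
        t = np.arange(96) / 32.0
        s = dict(zip(STATS, window_statistics(np.sin(2 * np.pi * 4 * t), 3.0)))
        assert s["dominant_period_s"] == pytest.approx(0.25)

    def test_all_zero_series(self):
        s = dict(zip(STATS, window_statistics(np.zeros(96), 3.0)))
        assert np.isnan(s["dominant_period_s"])
        vals = [v for k, v in s.items() if k != "dominant_period_s"]
        assert vals == [0.0] * 9

    def test_all_nan_channel_is_all_missing(self):
        assert np.all(np.isnan(window_statistics(np.full(96, np.nan), 3.0)))

    def test_parseval_energy_identity(self, rng):
        x = rng.normal(size=(40, 96))
        stats = window_statistics(x, 3.0)
        energy = stats[:, list(STATS).index("spectral_energy")]
        np.testing.assert_allclose(energy, 96 * np.sum(x * x, axis=1),
                                   rtol=1e-6)

    def test_include_dc_option(self):
        x = np.full(96, 3.0)
        s = window_statistics(x, 3.0, include_dc=True)
        assert s[list(STATS).index("dominant_amplitude")] == pytest.approx(288.0)
        # DC peak means an undefined (infinite) period
        assert np.isnan(s[list(STATS).index("dominant_period_s")])


class TestFeatureMatrix:
    def _frame(self, n_s, rng, animal="a", t0=0.0):
        t = t0 + np.arange(n_s * 32) / 32.0
        xyz = rng.normal(0, 2, (t.size, 3))
        return pd.DataFrame({"animal_id": animal, "t": t, "ax": xyz[:, 0],
                             "ay": xyz[:, 1], "az": xyz[:, 2]})

    def test_feature_count_is_210(self, rng):
        out = accel_feature_matrix(self._frame(3, rng))
        assert len(feature_names()) == len(CHANNELS) * len(STATS) == 210
        assert out[feature_names()].shape == (1, 210)

    def test_one_hour_gives_1200_rows(self, rng):
        out = accel_feature_matrix(self._frame(3600, rng))
        assert out.shape[0] == 1200

    def test_identical_windows_give_identical_rows(self, rng):
        df = self._frame(3, rng)
        df2 = df.copy()
        df2["t"] += 3.0
        out = accel_feature_matrix(pd.concat([df, df2], ignore_index=True))
        np.testing.assert_array_equal(out.iloc[0][feature_names()].to_numpy(),
                                      out.iloc[1][feature_names()].to_numpy())

    def test_stacked_path_matches_per_channel_stats(self, rng):
        """The one-pass stacked implementation equals direct per-channel
        window statistics."""
        from envtrace.accel import geometric_transform as gt
        df = self._frame(9, rng)
        out = accel_feature_matrix(df)
        xyz = df[["ax", "ay", "az"]].to_numpy().reshape(3, 96, 3)
        chans = gt(xyz)
        for c, ch in enumerate(CHANNELS):
            direct = window_statistics(chans[:, :, c], 3.0)
            got = out[[f"{ch}__{st}" for st in STATS]].to_numpy()
            np.testing.assert_allclose(got, direct, rtol=1e-12, equal_nan=True)
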