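import numpy as np
import pandas as pd
import pytest

from envtrace.hourly import (MOVEMENT_COLUMNS, attach_env_targets,
                             column_manifest, fit_family_projection,
                             standardize_day_night)


class TestManifest:
    def test_total_is_548(self):
        m = column_manifest()
        assert len(m) == len(MOVEMENT_COLUMNS) == 548
        assert m["column"].is_unique

    def test_per_set_counts(self):
        counts = column_manifest().groupby("set").size().to_dict()
        assert counts == {
            "individual_gps_hour": 27,
            "activity_proportion": 5,
            "grazing_log_params": 4,
            "group_median": 11, "group_sd": 11,
            "grazing_individual_median": 24, "grazing_individual_sd": 24,
            "grazing_group_median": 11, "grazing_group_sd": 11,
            "grazing_accel_median": 210, "grazing_accel_sd": 210,
        }

    def test_families_cover_all_columns(self):
        m = column_manifest()
        assert set(m["family"]) == {"gps", "acc"}
        assert m.groupby("family").size().sum() == 548


class TestBuild:
    def test_small_herd_hour_records(self, small_records):
        assert all(c in small_records.columns for c in MOVEMENT_COLUMNS)
        props = small_records[[f"prop__{c}" for c in
                               ("grazing", "walking", "standing", "lying")]]
        np.testing.assert_allclose(props.sum(axis=1), 1.0)
        assert {"biomass", "time_since_milking", "wind",
                "session_id"} <= set(small_records.columns)

    def test_one_row_per_animal_hour(self, small_records, sim_small):
        n_hours = sim_small.config.total_s // 3600
        assert len(small_records) == sim_small.config.n_cows * n_hours
        assert not small_records.duplicated(["animal_id", "hour_key"]).any()


def _records_frame(rng, n=40):
    rec = pd.DataFrame(
        rng.normal(size=(n, len(MOVEMENT_COLUMNS))),
        columns=list(MOVEMENT_COLUMNS))
    rec.insert(0, "animal_id", np.repeat(["c1", "c2"], n // 2))
    rec.insert(1, "hour_key", np.arange(n))
    rec.insert(2, "day", np.tile([True, False], n // 2))
    return rec


class TestStandardization:
    def test_training_cells_have_zero_mean_unit_variance(self, rng):
        rec = _records_frame(rng)
        z, _ = standardize_day_night(rec, np.ones(len(rec), bool))
        for (_, _), grp in z.groupby(["animal_id", "day"]):
            block = grp[list(MOVEMENT_COLUMNS)].to_numpy()
            np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-9)
            np.testing.assert_allclose(block.std(axis=0, ddof=1), 1.0,
                                       atol=1e-9)

    def test_test_rows_use_training_parameters(self, rng):
        """Held-out rows are scaled with training means/scales, so mutating
        them cannot change the transform (no leakage)."""
        rec = _records_frame(rng)
        train = np.arange(len(rec)) < 30
        z1, params1 = standardize_day_night(rec, train)
        mutated = rec.copy()
        mutated.loc[~train, list(MOVEMENT_COLUMNS)] += 500.0
        z2, params2 = standardize_day_night(mutated, train)
        np.testing.assert_array_equal(params1.global_mean, params2.global_mean)
        pd.testing.assert_frame_equal(z1[train], z2[train])
        # and the mutated rows moved by 500/scale, i.e. they did not refit
        col = list(MOVEMENT_COLUMNS)[0]
        assert (z2.loc[~train, col] > z1.loc[~train, col]).all()

    def test_constant_column_standardizes_to_zero(self, rng):
        rec = _records_frame(rng)
        rec[list(MOVEMENT_COLUMNS)[5]] = 7.0
        z, _ = standardize_day_night(rec, np.ones(len(rec), bool))
        assert (z[list(MOVEMENT_COLUMNS)[5]] == 0.0).all()

    def test_missing_values_imputed_as_cell_mean(self, rng):
        rec = _records_frame(rng)
        col = list(MOVEMENT_COLUMNS)[3]
        rec.loc[4, col] = np.nan
        z, _ = standardize_day_night(rec, np.ones(len(rec), bool))
        assert z.loc[4, col] == 0.0


class TestFamilyProjection:
    def test_rank3_data_fully_explained_by_3_components(self, rng):
        rec = _records_frame(rng)
        manifest = column_manifest()
        gps_cols = manifest.loc[manifest["family"] == "gps", "column"]
        latent = rng.normal(size=(len(rec), 3))
        mix = rng.normal(size=(3, len(gps_cols)))
        rec[list(gps_cols)] = latent @ mix
        proj = fit_family_projection(rec, "gps", 3)
        assert proj.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_projected_training_columns_uncorrelated(self, rng):
        rec = _records_frame(rng)
        proj = fit_family_projection(rec, "acc", 5)
        scores = proj.transform(rec)
        corr = np.corrcoef(scores.T)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 1e-6)

    def test_transform_deterministic(self, rng):
        rec = _records_frame(rng)
        proj = fit_family_projection(rec, "gps", 4)
        np.testing.assert_array_equal(proj.transform(rec),
                                      proj.transform(rec))

    def test_excess_components_truncated(self, rng):
        rec = _records_frame(rng).head(10)
        proj = fit_family_projection(rec, "gps", 500)
        assert proj.n_components <= 10


class TestEnvTargets:
    def _records(self):
        return pd.DataFrame({"animal_id": ["c1"], "hour_key": [10],
                             "day": [True]})

    def test_linear_biomass_decline_averages_to_midpoint(self):
        t = 10 * 3600.0 - 2 * 3600 + np.arange(0, 3600, 60.0)  # hour_key 10 local (+2h)
        env = pd.DataFrame({"t": t, "biomass": np.linspace(1000, 990, 60),
                            "time_since_milking": 1.0, "wind": 3.0,
                            "session_id": 1})
        out = attach_env_targets(self._records(), env)
        assert out["biomass"].iloc[0] == pytest.approx(995.0)
        assert out["wind"].iloc[0] == pytest.approx(3.0)

    def test_sawtooth_mean_is_piecewise_average(self):
        # time since milking ramps 0.5 -> 1.0 then resets 0 -> 0.5 mid-hour
        t = 10 * 3600.0 - 2 * 3600 + np.arange(0, 3600, 60.0)
        tsm = np.concatenate([0.5 + np.arange(30) / 60.0,
                              np.arange(30) / 60.0])
        env = pd.DataFrame({"t": t, "biomass": 1.0,
                            "time_since_milking": tsm, "wind": 0.0,
                            "session_id": 1})
        out = attach_env_targets(self._records(), env)
        assert out["time_since_milking"].iloc[0] == pytest.approx(
            tsm.mean())

    def test_uncovered_hour_dropped(self):
        env = pd.DataFrame({"t": [0.0], "biomass": [1.0],
                            "time_since_milking": [1.0], "wind": [1.0],
                            "session_id": [1]})
        assert len(attach_env_targets(self._records(), env)) == 0
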