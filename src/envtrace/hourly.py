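"""Per-animal, per-hour variable assembly (548 movement variables).

Variable sets, per animal-hour:

==============================  =====  =======================================
set                             count  contents
==============================  =====  =======================================
individual_gps_hour                27  trajectory features on the full hour of
                                       1 Hz positions
activity_proportion                 5  proportions of the 4 main activities
                                       plus rumination, over 3 s windows
grazing_log_params                  4  mean/sd of log median speed and log
                                       median |tangential velocity| over
                                       grazing windows
group_median / group_sd         11+11  median/sd over windows of the 11 group
                                       features
grazing_individual_median/sd    24+24  median/sd over grazing windows of the
                                       24-feature per-window individual subset
grazing_group_median/sd         11+11  median/sd over grazing windows of the
                                       group features
grazing_accel_median/sd       210+210  median/sd over grazing windows of the
                                       210 accelerometer features
==============================  =====  =======================================

Total 548.  The per-window individual subset excludes the MSD fit pair and
the Brownian scaling parameter, which are not estimable from a handful of
fixes; the exclusion is recorded in the column manifest.

Grazing-conditional columns of an hour without grazing windows are missing
and are imputed (as the cell mean, i.e. zero) after standardization.
Variables are z-scored per combination of day/night and animal using
training-hour parameters only, then projected to principal components
separately per sensor family (GPS-derived vs accelerometer-derived sets;
the activity proportions ride with the accelerometer family whose signal
dominates the classifier that produces them).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import accel as accel_mod
from .group import GROUP_FEATURES
from .io import is_day, local_hour_key
from .traj import INDIVIDUAL_FEATURES, WINDOW_SUBSET, individual_feature_vector

logger = logging.getLogger("envtrace")

SUMMARY = ("mean", "sd", "median", "min", "max", "q1", "q3")


def _cols(prefix, names, suffix=""):
    return [f"{prefix}{n}{suffix}" for n in names]


def column_manifest() -> pd.DataFrame:
    """All 548 movement columns with their variable set and sensor family."""
    acc_names = accel_mod.feature_names()
    rows = []

    def add(names, set_name, family):
        rows.extend({"column": c, "set": set_name, "family": family}
                    for c in names)

    add(_cols("h__", INDIVIDUAL_FEATURES), "individual_gps_hour", "gps")
    add([f"prop__{c}" for c in
         ("grazing", "walking", "standing", "lying", "ruminating")],
        "activity_proportion", "acc")
    add(["logmedspeed__mean", "logmedspeed__sd",
         "logmedtangv__mean", "logmedtangv__sd"],
        "grazing_log_params", "gps")
    add(_cols("grp__", GROUP_FEATURES, "__med"), "group_median", "gps")
    add(_cols("grp__", GROUP_FEATURES, "__sd"), "group_sd", "gps")
    add(_cols("g_igps__", WINDOW_SUBSET, "__med"),
        "grazing_individual_median", "gps")
    add(_cols("g_igps__", WINDOW_SUBSET, "__sd"), "grazing_individual_sd", "gps")
    add(_cols("g_grp__", GROUP_FEATURES, "__med"), "grazing_group_median", "gps")
    add(_cols("g_grp__", GROUP_FEATURES, "__sd"), "grazing_group_sd", "gps")
    add(_cols("g_acc__", acc_names, "__med"), "grazing_accel_median", "acc")
    add(_cols("g_acc__", acc_names, "__sd"), "grazing_accel_sd", "acc")
    return pd.DataFrame(rows)


MOVEMENT_COLUMNS = tuple(column_manifest()["column"])


def _med_sd(block: np.ndarray):
    """Column-wise (median, sd) over rows, NaN-aware, NaN when empty."""
    if block.shape[0] == 0:
        return (np.full(block.shape[1], np.nan),) * 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if np.isnan(block).any():
            med = np.nanmedian(block, axis=0)
            n = np.isfinite(block).sum(axis=0)
            sd = np.where(n >= 2, np.nanstd(block, axis=0, ddof=1), np.nan)
        else:
            med = np.median(block, axis=0)
            sd = (block.std(axis=0, ddof=1) if block.shape[0] >= 2
                  else np.full(block.shape[1], np.nan))
    return med, sd


def build_hourly_variables(positions: pd.DataFrame, windows: pd.DataFrame,
                           duration_s: float = 3.0, utc_offset_h: float = 2.0,
                           min_window_frac: float = 0.5,
                           fpt_center_stride: int = 5,
                           day_start: float = 7.0, day_end: float = 19.0
                           ) -> pd.DataFrame:
    """Assemble the 548 movement variables per animal-hour.

    ``positions``: animal_id, t, x, y at 1 Hz.
    ``windows``: one row per (animal, 3 s window) with columns animal_id,
    window_start, main_class, ruminating, the 210 accelerometer feature
    columns, the 24 individual-subset columns prefixed ``igps__`` and the
    11 group columns prefixed ``grp__``.

    Hours with fewer than ``min_window_frac`` of the nominal window count
    are dropped (logged).  Returns a frame keyed by (animal_id, hour_key)
    with a ``day`` flag and exactly the 548 movement columns.
    """
    acc_cols = accel_mod.feature_names()
    igps_cols = [f"igps__{f}" for f in WINDOW_SUBSET]
    grp_cols = [f"grp__{f}" for f in GROUP_FEATURES]

    win = windows.copy()
    win["hour_key"] = local_hour_key(win["window_start"].to_numpy(), utc_offset_h)
    pos = positions.copy()
    pos["hour_key"] = local_hour_key(pos["t"].to_numpy(), utc_offset_h)

    quorum = min_window_frac * 3600.0 / duration_s
    pos_groups = {k: g for k, g in pos.groupby(["animal_id", "hour_key"],
                                               sort=False)}
    rows, keys, dropped = [], [], 0
    for (animal, hour), grp in win.groupby(["animal_id", "hour_key"], sort=False):
        if len(grp) < quorum:
            dropped += 1
            continue
        rec = {}

        pg = pos_groups.get((animal, hour))
        if pg is not None and len(pg) >= 2:
            vec = individual_feature_vector(pg["t"].to_numpy(),
                                            pg[["x", "y"]].to_numpy(),
                                            fpt_center_stride=fpt_center_stride)
            for f in INDIVIDUAL_FEATURES:
                rec[f"h__{f}"] = vec[f]
        else:
            for f in INDIVIDUAL_FEATURES:
                rec[f"h__{f}"] = np.nan

        labels = grp["main_class"]
        labelled = labels.notna()
        n_lab = int(labelled.sum())
        for c in ("grazing", "walking", "standing", "lying"):
            rec[f"prop__{c}"] = ((labels == c).sum() / n_lab if n_lab else np.nan)
        rec["prop__ruminating"] = (grp.loc[labelled, "ruminating"].astype(bool)
                                   .mean() if n_lab else np.nan)

        grazing = (labels == "grazing").to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for src, tag in (("igps__speed__median", "logmedspeed"),
                             ("igps__tangv__median", "logmedtangv")):
                vals = grp.loc[grazing, src].to_numpy(float)
                vals = vals[np.isfinite(vals) & (vals > 0)]
                logs = np.log(vals)
                rec[f"{tag}__mean"] = logs.mean() if logs.size else np.nan
                rec[f"{tag}__sd"] = (logs.std(ddof=1) if logs.size >= 2
                                     else np.nan)

        med, sd = _med_sd(grp[grp_cols].to_numpy(float))
        for f, m, s in zip(GROUP_FEATURES, med, sd):
            rec[f"grp__{f}__med"], rec[f"grp__{f}__sd"] = m, s

        for block_cols, prefix, names in (
                (igps_cols, "g_igps__", WINDOW_SUBSET),
                (grp_cols, "g_grp__", GROUP_FEATURES),
                (acc_cols, "g_acc__", acc_cols)):
            med, sd = _med_sd(grp.loc[grazing, block_cols].to_numpy(float))
            for f, m, s in zip(names, med, sd):
                key = f if prefix != "g_acc__" else f
                rec[f"{prefix}{key}__med"], rec[f"{prefix}{key}__sd"] = m, s

        rows.append(rec)
        keys.append((animal, hour))
    if dropped:
        logger.info("dropped %d animal-hours below the %d%%-window quorum",
                    dropped, int(100 * min_window_frac))

    out = pd.DataFrame(rows)
    out.insert(0, "animal_id", [k[0] for k in keys])
    out.insert(1, "hour_key", [k[1] for k in keys])
    out.insert(2, "day", is_day(np.array([k[1] * 3600.0 for k in keys]),
                                utc_offset_h=0.0,  # hour_key is already local
                                day_start=day_start, day_end=day_end))
    missing = [c for c in MOVEMENT_COLUMNS if c not in out.columns]
    if missing:
        raise AssertionError(f"hourly build lost columns: {missing[:5]}...")
    return out[["animal_id", "hour_key", "day"] + list(MOVEMENT_COLUMNS)]


@dataclass
class StandardizationParams:
    """Per-(animal, day/night) means and scales fitted on training hours."""

    cell_means: dict
    cell_scales: dict
    global_mean: np.ndarray
    global_scale: np.ndarray
    columns: tuple


def standardize_day_night(records: pd.DataFrame, train_mask: np.ndarray,
                          params: StandardizationParams | None = None):
    """Z-score the movement columns per (animal, day/night) cell.

    Parameters are estimated from training rows only (pass the returned
    ``params`` to standardize further data with the same transforms).
    Missing values become 0 (the cell mean) after standardization;
    zero-variance columns standardize to 0.
    """
    cols = list(MOVEMENT_COLUMNS)
    x = records[cols].to_numpy(float)
    train_mask = np.asarray(train_mask, bool)

    def _fit(block):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(block, axis=0)
            sd = np.nanstd(block, axis=0, ddof=1)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        sd = np.where(np.isfinite(sd) & (sd > 0), sd, np.nan)
        return mean, sd

    def _cell_keys(df):
        return (df["animal_id"].astype(str) + "|"
                + df["day"].astype(bool).astype(str)).to_numpy()

    if params is None:
        if not train_mask.any():
            raise ValueError("no training rows to fit standardization")
        gmean, gscale = _fit(x[train_mask])
        cell_means, cell_scales = {}, {}
        cells = _cell_keys(records)
        for cell in pd.unique(cells):
            m = (cells == cell) & train_mask
            if m.sum() >= 2:
                cell_means[cell], cell_scales[cell] = _fit(x[m])
            else:
                logger.warning("cell %r has <2 training hours; using global "
                               "standardization parameters", cell)
        params = StandardizationParams(cell_means, cell_scales, gmean, gscale,
                                       tuple(cols))

    cells = _cell_keys(records)
    z = np.empty_like(x)
    for cell in pd.unique(cells):
        m = cells == cell
        mean = params.cell_means.get(cell, params.global_mean)
        scale = params.cell_scales.get(cell, params.global_scale)
        with np.errstate(invalid="ignore"):
            z[m] = (x[m] - mean) / scale
    n_imputed = int(np.sum(~np.isfinite(z)))
    if n_imputed:
        logger.info("imputed %d standardized values as 0", n_imputed)
    z[~np.isfinite(z)] = 0.0

    out = records.copy()
    out[cols] = z
    return out, params


@dataclass
class SensorFamilyProjection:
    """Principal axes for one sensor family, fitted on training hours."""

    family: str
    columns: list
    pca: PCA

    @property
    def n_components(self) -> int:
        return self.pca.n_components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, records: pd.DataFrame) -> np.ndarray:
        return self.pca.transform(records[self.columns].to_numpy(float))


def fit_family_projection(train_records: pd.DataFrame, family: str,
                          n_components: int) -> SensorFamilyProjection:
    """Fit a per-family PCA on (already standardized) training hours."""
    manifest = column_manifest()
    cols = manifest.loc[manifest["family"] == family, "column"].tolist()
    if not cols:
        raise ValueError(f"unknown sensor family {family!r}")
    x = train_records[cols].to_numpy(float)
    rank = min(x.shape[0], x.shape[1])
    if n_components > rank:
        logger.warning("n_components=%d exceeds rank %d; truncating",
                       n_components, rank)
        n_components = rank
    pca = PCA(n_components=n_components, random_state=0).fit(x)
    return SensorFamilyProjection(family, cols, pca)


def attach_env_targets(records: pd.DataFrame, env: pd.DataFrame,
                       utc_offset_h: float = 2.0) -> pd.DataFrame:
    """Join hourly environmental means (biomass, time since milking, wind)
    and the session id onto the hourly records; uncovered hours drop."""
    e = env.copy()
    e["hour_key"] = local_hour_key(e["t"].to_numpy(), utc_offset_h)
    agg = e.groupby("hour_key").agg(
        biomass=("biomass", "mean"),
        time_since_milking=("time_since_milking", "mean"),
        wind=("wind", "mean"),
        session_id=("session_id", "first"),
    ).reset_index()
    merged = records.merge(agg, on="hour_key", how="inner")
    n_drop = len(records) - len(merged)
    if n_drop:
        logger.info("dropped %d animal-hours without environment coverage",
                    n_drop)
    return merged
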