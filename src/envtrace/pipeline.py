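"""End-to-end assembly: sensors -> per-window features -> hourly records.

The per-window table has one row per (animal, 3 s window) carrying the
main-activity label (observed from the ethogram or predicted by a fitted
activity model), the 210 accelerometer features, the 24-feature individual
GPS subset (prefixed ``igps__``) and the 11 group features (prefixed
``grp__``).  The hourly builder then condenses it to the 548-variable
animal-hour records.

Two entry paths share all feature code: a fast in-memory path over a
:class:`~envtrace.simulate.SimOutput` (accelerometer hours synthesized
lazily) and a generic path over the CSV frames the readers produce.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import accel as accel_mod
from .activity import ActivityModel
from .geo import UtmZone
from .group import GROUP_FEATURES, group_feature_vector, group_features_batch
from .hourly import attach_env_targets, build_hourly_variables
from .preprocess import filter_hdop, project_to_metric, segment_ids
from .simulate import ACTIVITIES, SimOutput
from .traj import WINDOW_SUBSET, individual_features_batch

logger = logging.getLogger("envtrace")

IGPS_COLS = [f"igps__{f}" for f in WINDOW_SUBSET]
GRP_COLS = [f"grp__{f}" for f in GROUP_FEATURES]


def gps_to_grid(gps: pd.DataFrame, zone: UtmZone = UtmZone(),
                hdop_max: float = 5.0, rate: float = 1.0) -> pd.DataFrame:
    """HDOP-filter, project and linearly regrid fixes to a uniform grid.

    Occasional dropped fixes leave sub-segment holes that are interpolated;
    genuine recording gaps (> 2x nominal spacing) split segments and stay
    uncovered.  Returns animal_id, t, x, y rows.
    """
    fixes = project_to_metric(filter_hdop(gps, hdop_max), zone)
    frames = []
    for animal, grp in fixes.groupby("animal_id", sort=False, observed=True):
        t = grp["t"].to_numpy(float)
        seg = segment_ids(t, 1.0 / rate)
        for s in np.unique(seg):
            m = seg == s
            ts = t[m]
            if ts.size < 2:
                continue
            n_out = int(np.floor((ts[-1] - ts[0]) * rate + 1e-9)) + 1
            grid = ts[0] + np.arange(n_out) / rate
            frames.append(pd.DataFrame({
                "animal_id": animal, "t": grid,
                "x": np.interp(grid, ts, grp.loc[m, "x"].to_numpy(float)),
                "y": np.interp(grid, ts, grp.loc[m, "y"].to_numpy(float)),
            }))
    return pd.concat(frames, ignore_index=True)


def group_window_features(mean_positions: np.ndarray) -> np.ndarray:
    """(W, n, 11) group features; snapshots with missing animals fall back
    to the scalar path over the animals present."""
    pts = np.asarray(mean_positions, float)
    w, n, _ = pts.shape
    complete = np.isfinite(pts).all(axis=(1, 2))
    out = np.full((w, n, len(GROUP_FEATURES)), np.nan)
    if complete.any():
        out[complete] = group_features_batch(pts[complete])
    for wi in np.flatnonzero(~complete):
        present = np.flatnonzero(np.isfinite(pts[wi]).all(axis=1))
        if present.size < 2:
            continue
        sub = pts[wi, present]
        for j, focal in enumerate(present):
            out[wi, focal] = group_feature_vector(sub, j).to_numpy()
    return out


def _labels_from_intervals(eth: pd.DataFrame, animal, mid_times: np.ndarray):
    """Main class + rumination at given times from ethogram intervals."""
    sub = eth[eth["animal_id"] == animal]
    starts = sub["start"].to_numpy(float)
    ends = sub["end"].to_numpy(float)
    mains = sub["main_class"].to_numpy()
    rums = sub["ruminating"].to_numpy(bool)
    idx = np.searchsorted(starts, mid_times, side="right") - 1
    ok = (idx >= 0) & (mid_times < ends[np.clip(idx, 0, None)])
    main = np.where(ok, mains[np.clip(idx, 0, None)], None)
    rum = np.where(ok, rums[np.clip(idx, 0, None)], False)
    return main, rum


def _accel_features_df(animal, t, xyz, duration_s, rate):
    df = pd.DataFrame({"animal_id": animal, "t": t, "ax": xyz[:, 0],
                       "ay": xyz[:, 1], "az": xyz[:, 2]})
    return accel_mod.accel_feature_matrix(df, duration_s=duration_s, rate=rate)


# ---------------------------------------------------------------------------
# fast path over a simulation
# ---------------------------------------------------------------------------

def sim_gps_grids(sim: SimOutput, zone: UtmZone = UtmZone(),
                  hdop_max: float = 5.0) -> np.ndarray:
    """Per-cow noisy GPS passed through the real preprocessing (HDOP filter,
    UTM projection, regridding); (n_cows, total_s, 2) plot-local metres."""
    cfg = sim.config
    grids = np.full((cfg.n_cows, cfg.total_s, 2), np.nan)
    for ci in range(cfg.n_cows):  # one animal at a time: bounded memory
        grid_df = gps_to_grid(sim.gps([ci]), zone, hdop_max)
        idx = np.round(grid_df["t"].to_numpy(float) - cfg.t0).astype(int)
        keep = (idx >= 0) & (idx < cfg.total_s)
        grids[ci, idx[keep], 0] = grid_df["x"].to_numpy(float)[keep]
        grids[ci, idx[keep], 1] = grid_df["y"].to_numpy(float)[keep]
    # drop the global UTM offset; features are translation-invariant
    finite = np.isfinite(grids[..., 0])
    for d in range(2):
        grids[..., d] -= np.nanmin(grids[..., d])
    logger.info("GPS grids cover %.1f%% of cow-seconds", 100 * finite.mean())
    return grids


def window_table_for_hours(sim: SimOutput, grids: np.ndarray, hours,
                           duration_s: float = 3.0,
                           label_mode: str = "observed",
                           model: ActivityModel | None = None) -> pd.DataFrame:
    """Per-window feature table for the given hour indices."""
    cfg = sim.config
    n_win = int(3600 // duration_s)
    k = int(duration_s)  # fixes per window at 1 Hz
    acc_names = accel_mod.feature_names()
    frames = []
    for h in hours:
        s0 = h * 3600
        xy = grids[:, s0: s0 + 3600]
        win_xy = xy[:, : n_win * k].reshape(cfg.n_cows, n_win, k, 2)
        win_ok = np.isfinite(win_xy).all(axis=(2, 3))  # (n_cows, W)
        mean_pos = np.transpose(np.where(win_ok[:, :, None],
                                         win_xy.mean(axis=2), np.nan),
                                (1, 0, 2))  # (W, n, 2)
        grp_feats = group_window_features(mean_pos)  # (W, n, 11)

        starts = cfg.t0 + s0 + duration_s * np.arange(n_win)
        mid_s = (s0 + duration_s * np.arange(n_win) + duration_s / 2).astype(int)
        for ci in range(cfg.n_cows):
            t_acc, xyz = sim.accel_hour(ci, h)
            acc = _accel_features_df(cfg.cow_ids[ci], t_acc, xyz, duration_s,
                                     cfg.accel_rate)
            good = win_ok[ci]
            igps = pd.DataFrame(np.nan, index=range(n_win),
                                columns=list(WINDOW_SUBSET))
            if good.all():
                igps.iloc[:] = individual_features_batch(win_xy[ci]).to_numpy()
            elif good.any():
                igps.iloc[np.flatnonzero(good)] = individual_features_batch(
                    win_xy[ci, good]).to_numpy()
            row = pd.DataFrame({"animal_id": cfg.cow_ids[ci],
                                "window_start": starts})
            row["main_class"] = pd.array(
                [ACTIVITIES[a] for a in sim.activities[ci, mid_s]])
            row["ruminating"] = sim.ruminating[ci, mid_s]
            for j, c in enumerate(IGPS_COLS):
                row[c] = igps.iloc[:, j].to_numpy()
            for j, c in enumerate(GRP_COLS):
                row[c] = grp_feats[:, ci, j]
            acc_block = acc[acc_names].reset_index(drop=True)
            acc_block = acc_block.reindex(range(n_win))
            row = pd.concat([row, acc_block], axis=1)
            frames.append(row)
    table = pd.concat(frames, ignore_index=True)
    if label_mode == "predicted":
        if model is None:
            raise ValueError("label_mode='predicted' requires a fitted model")
        feats = table[acc_names + IGPS_COLS].to_numpy(float)
        feats = np.nan_to_num(feats, nan=0.0)
        pred = model.predict(feats)
        table["main_class"] = pred["main_class"].to_numpy()
        table["ruminating"] = pred["ruminating"].to_numpy()
    elif label_mode != "observed":
        raise ValueError("label_mode must be 'observed' or 'predicted'")
    return table


def hourly_records_from_sim(sim: SimOutput, hours=None,
                            duration_s: float = 3.0,
                            label_mode: str = "observed",
                            model: ActivityModel | None = None,
                            fpt_center_stride: int = 5,
                            grids: np.ndarray | None = None,
                            return_windows=False):
    """Full hourly 548-variable records with environment targets attached.

    Processes one clock hour at a time so multi-day herds never hold the
    whole per-window table in memory.  ``return_windows`` may be True
    (keep every window row) or a collection of hour indices to keep only
    those — enough to train/evaluate an activity classifier afterwards.
    """
    cfg = sim.config
    if grids is None:
        grids = sim_gps_grids(sim)
    if hours is None:
        hours = range(cfg.total_s // 3600)
    keep_hours = (set(hours) if return_windows is True
                  else set(return_windows) if return_windows else set())
    t_all = cfg.t0 + np.arange(cfg.total_s, dtype=float)
    rec_frames, kept_windows = [], []
    for h in hours:
        win_h = window_table_for_hours(sim, grids, [h], duration_s,
                                       label_mode, model)
        if h in keep_hours:
            kept_windows.append(win_h)
        s0 = h * 3600
        pos_frames = []
        for ci, cow in enumerate(cfg.cow_ids):
            ok = np.isfinite(grids[ci, s0: s0 + 3600]).all(axis=1)
            pos_frames.append(pd.DataFrame({
                "animal_id": cow, "t": t_all[s0: s0 + 3600][ok],
                "x": grids[ci, s0: s0 + 3600, 0][ok],
                "y": grids[ci, s0: s0 + 3600, 1][ok]}))
        rec_frames.append(build_hourly_variables(
            pd.concat(pos_frames, ignore_index=True), win_h, duration_s,
            cfg.utc_offset_h, fpt_center_stride=fpt_center_stride))
    records = pd.concat(rec_frames, ignore_index=True)
    records = attach_env_targets(records, sim.env, cfg.utc_offset_h)
    if keep_hours:
        return records, pd.concat(kept_windows, ignore_index=True)
    return records


# ---------------------------------------------------------------------------
# generic path over CSV frames
# ---------------------------------------------------------------------------

def window_table_from_frames(gps: pd.DataFrame, accel: pd.DataFrame,
                             ethogram: pd.DataFrame | None = None,
                             zone: UtmZone = UtmZone(), hdop_max: float = 5.0,
                             duration_s: float = 3.0, accel_rate: float = 32.0
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window features (and the regridded positions) from raw frames.

    Windows are aligned to whole duration_s multiples of the epoch so the
    GPS and accelerometer streams key together.
    """
    grid_df = gps_to_grid(gps, zone, hdop_max)
    acc_table = accel_mod.accel_feature_matrix(accel, duration_s=duration_s,
                                               rate=accel_rate)

    animals = sorted(set(grid_df["animal_id"]))
    t_min = grid_df["t"].min()
    t_max = grid_df["t"].max()
    t0 = np.floor(t_min / duration_s) * duration_s
    n_win = int((t_max - t0) // duration_s)
    k = int(round(duration_s))  # 1 Hz fixes per window
    starts = t0 + duration_s * np.arange(n_win)

    xy = np.full((len(animals), n_win * k, 2), np.nan)
    for ci, cow in enumerate(animals):
        sub = grid_df[grid_df["animal_id"] == cow]
        idx = np.round(sub["t"].to_numpy(float) - t0).astype(int)
        keep = (idx >= 0) & (idx < n_win * k)
        xy[ci, idx[keep], 0] = sub["x"].to_numpy(float)[keep]
        xy[ci, idx[keep], 1] = sub["y"].to_numpy(float)[keep]
    win_xy = xy.reshape(len(animals), n_win, k, 2)
    usable = np.isfinite(win_xy).all(axis=(2, 3))  # (n, W)
    mean_pos = np.transpose(np.where(usable[:, :, None],
                                     win_xy.mean(axis=2),
                                     np.nan), (1, 0, 2))
    grp = group_window_features(mean_pos)

    frames = []
    for ci, cow in enumerate(animals):
        row = pd.DataFrame({"animal_id": cow, "window_start": starts})
        good = usable[ci]
        igps = pd.DataFrame(np.nan, index=range(n_win),
                            columns=list(WINDOW_SUBSET))
        if good.any():
            igps.loc[good] = individual_features_batch(
                win_xy[ci, good]).to_numpy()
        for j, c in enumerate(IGPS_COLS):
            row[c] = igps.iloc[:, j].to_numpy()
        for j, c in enumerate(GRP_COLS):
            row[c] = grp[:, ci, j]
        if ethogram is not None:
            main, rum = _labels_from_intervals(
                ethogram, cow, starts + duration_s / 2)
            row["main_class"] = main
            row["ruminating"] = rum
        else:
            row["main_class"] = None
            row["ruminating"] = False
        frames.append(row)
    gps_windows = pd.concat(frames, ignore_index=True)

    table = gps_windows.merge(acc_table.drop(columns=["window_end"]),
                              on=["animal_id", "window_start"], how="left")
    return table, grid_df
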