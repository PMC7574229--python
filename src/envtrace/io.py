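"""CSV readers/writers and tabular schemas shared by the whole pipeline.

All streams are plain comma-separated text with a header row and ISO-8601
timestamps.  Internally time is carried as float seconds since the Unix
epoch (UTC); local clock logic (day/night, milking) applies a configured
UTC offset on top.

Schemas
-------
GPS        : animal_id, t, lat, lon, hdop
Accelerometer : animal_id, t, ax, ay, az                  (m s^-2)
Ethogram   : animal_id, start, end, activity
             activity is one of the six mutually exclusive observed types
             (grazing, walking, standing, lying, ruminating_standing,
             ruminating_lying); readers derive the 4-class main activity
             plus a rumination flag.
Environment: t, biomass, time_since_milking, wind, session_id
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("envtrace")

MAIN_CLASSES = ("grazing", "walking", "standing", "lying")

#: six observed ethogram types -> (main class, ruminating flag)
ETHOGRAM_TYPES = {
    "grazing": ("grazing", False),
    "walking": ("walking", False),
    "standing": ("standing", False),
    "lying": ("lying", False),
    "ruminating_standing": ("standing", True),
    "ruminating_lying": ("lying", True),
}

GPS_COLUMNS = ["animal_id", "t", "lat", "lon", "hdop"]
ACCEL_COLUMNS = ["animal_id", "t", "ax", "ay", "az"]
ETHOGRAM_COLUMNS = ["animal_id", "start", "end", "activity"]
ENV_COLUMNS = ["t", "biomass", "time_since_milking", "wind", "session_id"]


def to_epoch(s) -> np.ndarray:
    """ISO-8601 strings/Timestamps -> float seconds since the epoch (UTC)."""
    ts = pd.to_datetime(s, utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def to_iso(t: np.ndarray) -> pd.Series:
    """Float epoch seconds -> millisecond ISO-8601 UTC strings."""
    ts = pd.to_datetime(np.asarray(t, float) * 1e3, unit="ms", utc=True)
    return pd.Series(ts).dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3] + "Z"


def local_hour_key(t: np.ndarray, utc_offset_h: float = 2.0) -> np.ndarray:
    """Integer calendar-hour identifier in local clock time."""
    return np.floor((np.asarray(t, float) + utc_offset_h * 3600.0) / 3600.0).astype(
        np.int64
    )


def is_day(t: np.ndarray, utc_offset_h: float = 2.0, day_start: float = 7.0,
           day_end: float = 19.0) -> np.ndarray:
    """True for local clock hours in [day_start, day_end)."""
    hod = (np.asarray(t, float) / 3600.0 + utc_offset_h) % 24.0
    return (hod >= day_start) & (hod < day_end)


def _read(path, time_cols, required):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in time_cols:
        df[c] = to_epoch(df[c])
    return df


def read_gps(path) -> pd.DataFrame:
    df = _read(path, ["t"], GPS_COLUMNS)
    return df.sort_values(["animal_id", "t"], kind="stable").reset_index(drop=True)


def read_accel(path) -> pd.DataFrame:
    df = _read(path, ["t"], ACCEL_COLUMNS)
    return df.sort_values(["animal_id", "t"], kind="stable").reset_index(drop=True)


def read_ethogram(path) -> pd.DataFrame:
    """Read activity observations; adds main_class and ruminating columns."""
    df = _read(path, ["start", "end"], ETHOGRAM_COLUMNS)
    unknown = set(df["activity"]) - set(ETHOGRAM_TYPES)
    if unknown:
        raise ValueError(f"unknown ethogram activity types: {sorted(unknown)}")
    df["main_class"] = [ETHOGRAM_TYPES[a][0] for a in df["activity"]]
    df["ruminating"] = [ETHOGRAM_TYPES[a][1] for a in df["activity"]]
    return df.sort_values(["animal_id", "start"], kind="stable").reset_index(drop=True)


def read_env(path) -> pd.DataFrame:
    df = _read(path, ["t"], ENV_COLUMNS)
    if (df["biomass"] < 0).any() or (df["time_since_milking"] < 0).any():
        raise ValueError("environment series must have biomass >= 0 and "
                         "time_since_milking >= 0")
    return df.sort_values("t", kind="stable").reset_index(drop=True)


def _write(df: pd.DataFrame, path, time_cols, columns):
    out = df[columns].copy() if all(c in df.columns for c in columns) else df.copy()
    for c in time_cols:
        out[c] = to_iso(out[c].to_numpy())
    out.to_csv(path, index=False)
    logger.info("wrote %d rows to %s", len(out), path)


def write_gps(df, path):
    _write(df, path, ["t"], GPS_COLUMNS)


def write_accel(df, path):
    _write(df, path, ["t"], ACCEL_COLUMNS)


def write_ethogram(df, path):
    _write(df, path, ["start", "end"], ETHOGRAM_COLUMNS)


def write_env(df, path):
    _write(df, path, ["t"], ENV_COLUMNS)
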