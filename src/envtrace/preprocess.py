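"""GPS quality filtering, metric projection, accelerometer resampling and
window bookkeeping.

Segments: sensors in the field pause recording for multi-hour stretches, so
any inter-sample gap larger than twice the nominal spacing splits a stream
into contiguous segments.  Windows are non-overlapping, start at each
segment's first timestamp, and never span segments; a trailing partial
window is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import UtmZone, geodetic_to_utm

logger = logging.getLogger("envtrace")


@dataclass(frozen=True)
class Window:
    """One non-overlapping analysis window within a recording segment."""

    animal_id: object
    start: float
    end: float
    index: int

    @property
    def duration_s(self) -> float:
        return self.end - self.start


def filter_hdop(fixes: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Drop GPS fixes whose HDOP exceeds ``threshold`` (strictly more than).

    A fix with hdop exactly equal to the threshold is retained.
    """
    if threshold <= 0:
        raise ValueError("HDOP threshold must be > 0")
    kept = fixes[fixes["hdop"] <= threshold].reset_index(drop=True)
    logger.info("HDOP filter: retained %d/%d fixes (threshold %.2f)",
                len(kept), len(fixes), threshold)
    return kept


def project_to_metric(fixes: pd.DataFrame, zone: UtmZone = UtmZone()) -> pd.DataFrame:
    """Project WGS84 fixes to UTM metric coordinates (columns x, y).

    Fixes outside the zone's validity region (central meridian +/- 6 deg,
    latitude within +/- 84 deg) are rejected with a diagnostic naming the
    offending fix.
    """
    lat = fixes["lat"].to_numpy(float)
    lon = fixes["lon"].to_numpy(float)
    dlon = (lon - zone.central_meridian_deg + 180.0) % 360.0 - 180.0
    bad = (~np.isfinite(lat) | ~np.isfinite(lon)
           | (np.abs(lat) > 84.0) | (np.abs(dlon) > 6.0))
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"fix out of range for UTM zone {zone.number}: animal "
            f"{fixes['animal_id'].iloc[i]!r} at t={fixes['t'].iloc[i]} "
            f"(lat={lat[i]}, lon={lon[i]})"
        )
    x, y = geodetic_to_utm(lat, lon, zone)
    out = fixes.copy()
    out["x"] = x
    out["y"] = y
    return out


def segment_ids(t: np.ndarray, nominal_dt: float, gap_factor: float = 2.0) -> np.ndarray:
    """Label contiguous segments: a gap > gap_factor * nominal_dt splits."""
    t = np.asarray(t, float)
    if t.size == 0:
        return np.zeros(0, dtype=np.int64)
    breaks = np.diff(t) > gap_factor * nominal_dt
    return np.concatenate([[0], np.cumsum(breaks)]).astype(np.int64)


def resample_accel(samples: pd.DataFrame, rate: float = 32.0,
                   nominal_dt: float | None = None,
                   gap_factor: float = 2.0) -> pd.DataFrame:
    """Resample accelerometer streams to a uniform grid by linear interpolation.

    Works per animal and per contiguous segment; the grid runs from each
    segment's first to last timestamp inclusive (no extrapolation).
    Single-sample segments are dropped with a warning.  ``nominal_dt``
    defaults to the per-animal median spacing (the raw rate is variable).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    out = []
    for animal, grp in samples.groupby("animal_id", sort=False):
        t = grp["t"].to_numpy(float)
        if t.size < 2:
            logger.warning("dropping single-sample segment for animal %r", animal)
            continue
        dt = nominal_dt if nominal_dt is not None else float(np.median(np.diff(t)))
        seg = segment_ids(t, dt, gap_factor)
        for s in np.unique(seg):
            m = seg == s
            ts = t[m]
            if ts.size < 2:
                logger.warning("dropping single-sample segment for animal %r at t=%s",
                               animal, ts[0] if ts.size else "?")
                continue
            n_out = int(np.floor((ts[-1] - ts[0]) * rate + 1e-9)) + 1
            grid = ts[0] + np.arange(n_out) / rate
            cols = {"animal_id": animal, "t": grid}
            for ax in ("ax", "ay", "az"):
                cols[ax] = np.interp(grid, ts, grp.loc[m, ax].to_numpy(float))
            out.append(pd.DataFrame(cols))
    if not out:
        return pd.DataFrame(columns=["animal_id", "t", "ax", "ay", "az"])
    return pd.concat(out, ignore_index=True)


def window_starts(seg_start: float, seg_end: float, duration_s: float) -> np.ndarray:
    """Start times of consecutive windows fully inside [seg_start, seg_end]."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = int(np.floor((seg_end - seg_start) / duration_s + 1e-9))
    return seg_start + duration_s * np.arange(max(n, 0))


def make_windows(animal_id, seg_start: float, seg_end: float,
                 duration_s: float = 3.0) -> list[Window]:
    """Non-overlapping windows covering a segment; trailing remainder dropped."""
    starts = window_starts(seg_start, seg_end, duration_s)
    return [Window(animal_id, float(s), float(s) + duration_s, i)
            for i, s in enumerate(starts)]
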