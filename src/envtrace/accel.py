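"""Accelerometer feature engineering.

Each 32 Hz tri-axial sample (x, y, z) is expanded into 21 geometric
channels — the raw axes, resultant-vector magnitudes in 1/2/3 dimensions,
plane and elevation angles, solid angles of the resultant pyramid, the
cuboid volume, and projected/triangle areas.  Per non-overlapping window
(default 3 s = 96 samples) ten statistics summarise every channel: mean,
standard deviation, median, min, max, first and third quartile, and three
discrete-Fourier-transform descriptors (dominant amplitude, dominant
period, spectral energy), giving 21 x 10 = 210 features per window.

Conventions
-----------
* Angles use the two-argument arctangent so the full circle is resolved;
  an angle whose defining pair is exactly (0, 0) is missing (NaN).
* Solid angles are ``arcsin`` of an axis-pair product over the product of
  two projected resultant norms, exactly as defined; arcsin arguments are
  clamped to [-1, 1] and clamping events are counted in the module logger.
* Volume and area channels are signed products (orientation carries
  information); only the triangle area ``a_xyz`` is a norm and hence >= 0.
* The DFT is the unnormalized transform of the raw (mean-retained) window:
  dominant amplitude is the maximum magnitude over bins 1..n/2 (DC excluded
  by default, configurable), the dominant period is the window duration
  divided by the winning bin index, and the spectral energy is the sum of
  squared magnitudes over *all* n bins (so it equals n * sum(sample^2)).
* Standard deviations and variances use the n-1 denominator and quantiles
  linear interpolation, matching the common statistical-environment
  defaults.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import row_summary7
from .preprocess import segment_ids

logger = logging.getLogger("envtrace")

CHANNELS = (
    "x", "y", "z",
    "r_xyz", "r_xy", "r_xz", "r_yz",
    "theta_xy", "theta_xz", "theta_yz", "theta_z", "theta_y", "theta_x",
    "omega_x", "omega_y", "omega_z",
    "v_xyz",
    "a_x", "a_y", "a_z", "a_xyz",
)

STATS = (
    "mean", "sd", "median", "min", "max", "q1", "q3",
    "dominant_amplitude", "dominant_period_s", "spectral_energy",
)


def feature_names() -> list[str]:
    """The 210 feature column names, channel-major."""
    return [f"{ch}__{st}" for ch in CHANNELS for st in STATS]


def _atan2_or_nan(num, den):
    out = np.arctan2(num, den)
    both_zero = (num == 0) & (den == 0)
    return np.where(both_zero, np.nan, out)


def _arcsin_clamped(num, den):
    # a vanishing numerator pins the angle at 0 even when the projected
    # resultants degenerate; only 0-denominator with nonzero numerator is
    # genuinely undefined
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio = np.where(den == 0, np.where(num == 0, 0.0, np.nan), ratio)
    n_clamp = int(np.sum(np.abs(ratio) > 1))
    if n_clamp:
        logger.debug("clamped %d arcsin arguments outside [-1, 1]", n_clamp)
    return np.arcsin(np.clip(ratio, -1.0, 1.0))


def geometric_transform(xyz: np.ndarray) -> np.ndarray:
    """Map raw samples (..., 3) to the 21 geometric channels (..., 21)."""
    xyz = np.asarray(xyz, dtype=float)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]

    r_xy = np.hypot(x, y)
    r_xz = np.hypot(x, z)
    r_yz = np.hypot(y, z)
    r_xyz = np.sqrt(x * x + y * y + z * z)

    out = np.empty(xyz.shape[:-1] + (len(CHANNELS),), dtype=float)
    out[..., 0] = x
    out[..., 1] = y
    out[..., 2] = z
    out[..., 3] = r_xyz
    out[..., 4] = r_xy
    out[..., 5] = r_xz
    out[..., 6] = r_yz
    out[..., 7] = _atan2_or_nan(y, x)
    out[..., 8] = _atan2_or_nan(z, x)
    out[..., 9] = _atan2_or_nan(z, y)
    out[..., 10] = _atan2_or_nan(z, r_xy)
    out[..., 11] = _atan2_or_nan(y, r_xz)
    out[..., 12] = _atan2_or_nan(x, r_yz)
    out[..., 13] = _arcsin_clamped(y * z, r_xy * r_xz)
    out[..., 14] = _arcsin_clamped(x * z, r_xy * r_yz)
    out[..., 15] = _arcsin_clamped(x * y, r_xz * r_yz)
    out[..., 16] = x * y * z
    out[..., 17] = y * z
    out[..., 18] = x * z
    out[..., 19] = x * y
    # area of the triangle spanned by (x, y, 0) and (x, 0, z):
    # half the norm of their cross product (y z, -x z, -x y)
    out[..., 20] = 0.5 * np.sqrt((y * z) ** 2 + (x * z) ** 2 + (x * y) ** 2)
    return out


def _fft_stats(block: np.ndarray, duration_s: float, include_dc: bool):
    """Dominant amplitude/period and spectral energy for rows of a 2-D block."""
    n = block.shape[1]
    mag = np.abs(np.fft.rfft(block, axis=1))  # bins 0..n//2
    sq = mag * mag
    # full-spectrum energy: DC and (even-n) Nyquist bins appear once,
    # every other bin twice (conjugate symmetry)
    energy = 2.0 * sq.sum(axis=1) - sq[:, 0]
    if n % 2 == 0:
        energy -= sq[:, -1]
    lo = 0 if include_dc else 1
    half = mag[:, lo: n // 2 + 1]
    k = np.argmax(half, axis=1) + lo
    amp = np.max(half, axis=1)
    with np.errstate(divide="ignore"):
        period = np.where(k > 0, duration_s / np.maximum(k, 1), np.nan)
    period = np.where(amp > 0, period, np.nan)
    return amp, period, energy


def window_statistics(series: np.ndarray, duration_s: float = 3.0,
                      include_dc: bool = False) -> np.ndarray:
    """The 10 per-window statistics for one channel.

    ``series`` is (n,) for one window or (W, n) for a stack of windows;
    returns (10,) or (W, 10).  Rows with fewer than two finite samples are
    entirely missing; rows with some NaNs are summarised over the finite
    samples only and their DFT runs on the NaN-stripped series.
    """
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    w, _ = arr.shape
    out = np.full((w, len(STATS)), np.nan)
    finite = np.isfinite(arr)
    ok = finite.sum(axis=1) >= 2

    summary = row_summary7(arr)
    out[ok, :7] = summary[ok]
    clean = finite.all(axis=1) & ok
    if clean.any():
        out[np.ix_(clean, [7, 8, 9])] = np.column_stack(
            _fft_stats(arr[clean], duration_s, include_dc))
    for i in np.flatnonzero(ok & ~clean):
        row = arr[i, finite[i]]
        amp, per, en = _fft_stats(row[None, :], duration_s, include_dc)
        out[i, 7], out[i, 8], out[i, 9] = amp[0], per[0], en[0]
    if np.asarray(series).ndim == 1:
        return out[0]
    return out


def accel_feature_matrix(samples: pd.DataFrame, duration_s: float = 3.0,
                         rate: float = 32.0, include_dc: bool = False,
                         min_valid_frac: float = 0.5) -> pd.DataFrame:
    """One row of 210 features per (animal, window) from resampled samples.

    Windows with fewer than ``min_valid_frac`` of the expected samples are
    emitted with all features missing (and a warning logged) so downstream
    bookkeeping stays aligned.
    """
    n_per = int(round(duration_s * rate))
    names = feature_names()
    rows, meta = [], []
    for animal, grp in samples.groupby("animal_id", sort=False):
        t = grp["t"].to_numpy(float)
        xyz = grp[["ax", "ay", "az"]].to_numpy(float)
        seg = segment_ids(t, 1.0 / rate)
        for s in np.unique(seg):
            m = seg == s
            ts, block = t[m], xyz[m]
            n_win = block.shape[0] // n_per
            if n_win == 0:
                continue
            trimmed = block[: n_win * n_per].reshape(n_win, n_per, 3)
            valid_frac = np.isfinite(trimmed).all(axis=2).mean(axis=1)
            chans = geometric_transform(trimmed)  # (W, n, 21)
            chans[valid_frac < min_valid_frac] = np.nan
            # stack channels into one row block: one sort/FFT pass for all
            big = np.ascontiguousarray(
                chans.transpose(2, 0, 1)).reshape(-1, n_per)
            stats = window_statistics(big, duration_s, include_dc)
            feats = (stats.reshape(len(CHANNELS), n_win, len(STATS))
                     .transpose(1, 0, 2).reshape(n_win, len(names)))
            meta.append(pd.DataFrame({
                "animal_id": animal,
                "window_start": ts[0] + duration_s * np.arange(n_win),
            }))
            rows.append(feats)
    if not rows:
        return pd.DataFrame(columns=["animal_id", "window_start", "window_end"] + names)
    meta_df = pd.concat(meta, ignore_index=True)
    meta_df["window_end"] = meta_df["window_start"] + duration_s
    feat_df = pd.DataFrame(np.vstack(rows), columns=names)
    low = feat_df.isna().all(axis=1)
    if low.any():
        logger.warning("%d windows emitted with all-missing accelerometer features",
                       int(low.sum()))
    return pd.concat([meta_df, feat_df], axis=1)
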