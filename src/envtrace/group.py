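"""Group-geometry features per window and focal animal.

A group snapshot is the set of per-animal mean positions over one window.
Per focal animal the 11 features are: mean/median/minimum distance to the
other animals, neighbour counts within 2/4/8/16 m (boundary inclusive),
the group elongation index phi (first-principal-component explained
variance share of the mean positions, rescaled from [0.5, 1] to [0, 1]),
the group area proxy pi * sigma^2 * (1 - phi) with sigma the standard
deviation of the first-PC scores, the mean resultant length of the
directions from the focal to the others, and a periphery index
(max circular gap between consecutive directions, minus 2*pi/(n-1),
divided by 2*pi).

Animals without GPS coverage in a window are excluded from the snapshot;
all counts and the periphery normalisation use the number present.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

GROUP_FEATURES = (
    "nbr_dist__mean", "nbr_dist__median", "nbr_dist__min",
    "nbr_count__2m", "nbr_count__4m", "nbr_count__8m", "nbr_count__16m",
    "elongation_phi", "area_proxy", "direction_rho", "periphery_index",
)

COUNT_RADII = (2.0, 4.0, 8.0, 16.0)


def _elongation(points: np.ndarray):
    """(phi, sigma) of one snapshot; NaN when degenerate (n < 3 or zero
    total variance)."""
    pts = np.asarray(points, float)
    if len(pts) < 3:
        return np.nan, np.nan
    c = np.cov(pts.T, ddof=1)
    ev = np.linalg.eigvalsh(c)[::-1]
    total = ev.sum()
    if total <= 0:
        return np.nan, np.nan
    share = ev[0] / total
    return float(2.0 * (share - 0.5)), float(np.sqrt(ev[0]))


def elongation_index(points: np.ndarray) -> float:
    """Group elongation phi in [0, 1]."""
    return _elongation(points)[0]


def group_area_proxy(points: np.ndarray) -> float:
    """pi * sigma^2 * (1 - phi): zero when fully elongated, pi*sigma^2 when
    circular."""
    phi, sigma = _elongation(points)
    if not np.isfinite(phi):
        return np.nan
    return float(np.pi * sigma**2 * (1.0 - phi))


def neighbour_distance_stats(points: np.ndarray, focal: int) -> dict:
    """Distance statistics and radius counts from the focal animal."""
    pts = np.asarray(points, float)
    out = dict.fromkeys(GROUP_FEATURES[:7], np.nan)
    if len(pts) < 2:
        return out
    d = np.linalg.norm(np.delete(pts, focal, axis=0) - pts[focal], axis=1)
    out["nbr_dist__mean"] = float(d.mean())
    out["nbr_dist__median"] = float(np.median(d))
    out["nbr_dist__min"] = float(d.min())
    for r in COUNT_RADII:
        out[f"nbr_count__{int(r)}m"] = float(np.sum(d <= r))
    return out


def periphery_index(points: np.ndarray, focal: int) -> float:
    """(max gap between consecutive focal-to-other directions - 2pi/(n-1)) / 2pi."""
    pts = np.asarray(points, float)
    n = len(pts)
    if n < 3:
        return np.nan
    rel = np.delete(pts, focal, axis=0) - pts[focal]
    nz = (rel != 0).any(axis=1)
    dirs = np.arctan2(rel[nz, 1], rel[nz, 0])
    if dirs.size < 2:
        return np.nan
    s = np.sort(dirs)
    gaps = np.diff(np.concatenate([s, [s[0] + 2 * np.pi]]))
    return float((gaps.max() - 2 * np.pi / (n - 1)) / (2 * np.pi))


def direction_rho(points: np.ndarray, focal: int) -> float:
    """Mean resultant length of directions from focal to the other animals."""
    pts = np.asarray(points, float)
    if len(pts) < 2:
        return np.nan
    rel = np.delete(pts, focal, axis=0) - pts[focal]
    nz = (rel != 0).any(axis=1)
    if not nz.any():
        return np.nan
    dirs = np.arctan2(rel[nz, 1], rel[nz, 0])
    return float(np.hypot(np.mean(np.cos(dirs)), np.mean(np.sin(dirs))))


def group_feature_vector(points: np.ndarray, focal: int) -> pd.Series:
    """All 11 group features for one focal animal in one snapshot."""
    out = neighbour_distance_stats(points, focal)
    out["elongation_phi"], sigma = _elongation(points)
    out["area_proxy"] = (np.pi * sigma**2 * (1.0 - out["elongation_phi"])
                         if np.isfinite(out["elongation_phi"]) else np.nan)
    out["direction_rho"] = direction_rho(points, focal)
    out["periphery_index"] = periphery_index(points, focal)
    return pd.Series(out, index=list(GROUP_FEATURES), dtype=float)


def group_features_batch(points: np.ndarray) -> np.ndarray:
    """All features for every focal animal over a stack of snapshots.

    ``points`` is (W, n, 2) window-mean positions; returns (W, n, 11) in
    :data:`GROUP_FEATURES` order.  Vectorised across windows and focals;
    matches :func:`group_feature_vector` per snapshot.
    """
    pts = np.asarray(points, float)
    w, n, _ = pts.shape
    out = np.full((w, n, len(GROUP_FEATURES)), np.nan)
    if n < 2:
        return out

    rel = pts[:, None, :, :] - pts[:, :, None, :]  # focal f -> other o: rel[w,f,o]
    d = np.linalg.norm(rel, axis=3)  # (W, n, n)
    off = ~np.eye(n, dtype=bool)
    d_off = d[:, off].reshape(w, n, n - 1)
    out[:, :, 0] = d_off.mean(axis=2)
    out[:, :, 1] = np.median(d_off, axis=2)
    out[:, :, 2] = d_off.min(axis=2)
    for j, r in enumerate(COUNT_RADII):
        out[:, :, 3 + j] = (d_off <= r).sum(axis=2)

    if n >= 3:
        centred = pts - pts.mean(axis=1, keepdims=True)
        sxx = np.einsum("wni,wnj->wij", centred, centred) / (n - 1)
        tr = sxx[:, 0, 0] + sxx[:, 1, 1]
        det = sxx[:, 0, 0] * sxx[:, 1, 1] - sxx[:, 0, 1] ** 2
        disc = np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))
        lam1 = tr / 2 + disc
        with np.errstate(divide="ignore", invalid="ignore"):
            share = lam1 / tr
        phi = np.where(tr > 0, 2.0 * (share - 0.5), np.nan)
        area = np.pi * lam1 * (1.0 - phi)
        out[:, :, 7] = phi[:, None]
        out[:, :, 8] = area[:, None]

    ang = np.arctan2(rel[..., 1], rel[..., 0])
    zero = d == 0
    ang_off = np.where(zero, np.nan, ang)[:, off].reshape(w, n, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.hypot(np.nanmean(np.cos(ang_off), axis=2),
                       np.nanmean(np.sin(ang_off), axis=2))
        out[:, :, 9] = np.where(np.isfinite(ang_off).any(axis=2), rho, np.nan)

    # periphery: sort directions (NaNs pushed to the end), wrap-around gap
    s = np.sort(ang_off, axis=2)
    m = np.isfinite(ang_off).sum(axis=2)  # valid directions per (w, focal)
    if n >= 3:
        peri = np.full((w, n), np.nan)
        for k in np.unique(m):
            if k < 2:
                continue
            sel = m == k
            sk = s[sel][:, :k]
            gaps = np.diff(np.concatenate([sk, sk[:, :1] + 2 * np.pi], axis=1),
                           axis=1)
            peri[sel] = (gaps.max(axis=1) - 2 * np.pi / (n - 1)) / (2 * np.pi)
        out[:, :, 10] = peri
    return out
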