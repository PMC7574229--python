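"""Individual-trajectory features from 1 Hz projected GPS positions.

Per analysis window the 27 features cover: path straightness (net/gross
ratio), step-speed distribution and persistence, a Brownian-motion scaling
parameter of the displacement increments, turning-angle concentration,
absolute tangential velocity along the local circular arc, a power-law fit
MSD = a * tau^b of the mean squared displacement over lags 1..6 s, and
first-passage-time (FPT) statistics over circles of radius 1..10 m.

Missing-value policy: a feature whose defining quantities are undefined
(zero-length displacements, collinear triples, censored passage times,
zero variance) is NaN and simply excluded from downstream summaries.

First passage time uses the both-directions convention (backward plus
forward time to first exit of the circle centred on a fix); crossing times
are linearly interpolated between the last fix inside and the first fix at
or beyond the radius, so a straight path at 1 m/s yields exactly 2r.
Fixes whose circle is never exited within the available path (in either
required direction) are censored and excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import row_summary7 as _summary7_rows

INDIVIDUAL_FEATURES = (
    "net_gross_ratio",
    "speed__mean", "speed__sd", "speed__median", "speed__min", "speed__max",
    "speed__q1", "speed__q3", "speed__acf1", "speed__brownian_scaling",
    "turn__rho", "turn__abs_acf1",
    "tangv__mean", "tangv__sd", "tangv__median", "tangv__min", "tangv__max",
    "tangv__q1", "tangv__q3", "tangv__acf1",
    "msd__diffusion_a", "msd__power_b",
    "fpt__mean_5m", "fpt__var_log_5m", "fpt__acf1_5m",
    "fpt__argmax_var_radius", "fpt__loglog_slope",
)

#: per-3-s-window subset: Table-length paths of a few fixes cannot support
#: the MSD fit or the increment-scaling parameter, so those three are
#: excluded from the windowed block (24 features).
WINDOW_SUBSET = tuple(f for f in INDIVIDUAL_FEATURES
                      if f not in ("speed__brownian_scaling",
                                   "msd__diffusion_a", "msd__power_b"))

DEFAULT_FPT_RADII = tuple(range(1, 11))
DEFAULT_MSD_TAUS = tuple(range(1, 7))


def _wrap(a):
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a, float), 2 * np.pi)


def step_speeds(t: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Per-step speeds ||p_{i+1} - p_i|| / dt; length n-1."""
    t, xy = np.asarray(t, float), np.asarray(xy, float)
    if len(t) < 2:
        return np.zeros(0)
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return d / np.diff(t)


def headings(xy: np.ndarray) -> np.ndarray:
    """Per-step movement directions; NaN for zero-length displacements."""
    d = np.diff(np.asarray(xy, float), axis=0)
    h = np.arctan2(d[:, 1], d[:, 0])
    return np.where((d == 0).all(axis=1), np.nan, h)


def turning_angles(xy: np.ndarray) -> np.ndarray:
    """Wrapped differences of successive headings; length n-2."""
    h = headings(xy)
    if h.size < 2:
        return np.zeros(0)
    return _wrap(h[1:] - h[:-1])


def circular_rho(angles: np.ndarray) -> float:
    """Mean resultant length of a circular sample, in [0, 1]."""
    a = np.asarray(angles, float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return np.nan
    return float(np.hypot(np.mean(np.cos(a)), np.mean(np.sin(a))))


def acf_lag1(series: np.ndarray) -> float:
    """Biased sample autocorrelation at lag 1 (NaNs dropped, order kept)."""
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        return np.nan
    xc = x - x.mean()
    denom = np.sum(xc * xc)
    if denom == 0:
        return np.nan
    return float(np.sum(xc[:-1] * xc[1:]) / denom)


def tangential_velocity(t: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """|v_t| per interior fix: |d(heading)/dt| times the circumradius of the
    three consecutive fixes.  Collinear triples (infinite radius) and
    stationary steps (undefined heading) are NaN.  Length n-2."""
    t, xy = np.asarray(t, float), np.asarray(xy, float)
    n = len(t)
    if n < 3:
        return np.zeros(0)
    p0, p1, p2 = xy[:-2], xy[1:-1], xy[2:]
    u, v = p1 - p0, p2 - p1
    a = np.linalg.norm(u, axis=1)
    b = np.linalg.norm(v, axis=1)
    c = np.linalg.norm(p2 - p0, axis=1)
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    area2 = np.abs(cross)  # twice the triangle area
    h = np.arctan2(u[:, 1], u[:, 0]), np.arctan2(v[:, 1], v[:, 0])
    dhead = np.abs(_wrap(h[1] - h[0]))
    dt = (t[2:] - t[:-2]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r_curv = a * b * c / (2.0 * area2)
        out = dhead * r_curv / dt
    bad = (area2 == 0) | (a == 0) | (b == 0)
    return np.where(bad, np.nan, out)


def net_gross_ratio(xy: np.ndarray) -> float:
    """Straight-line distance over path length, in [0, 1]."""
    xy = np.asarray(xy, float)
    if len(xy) < 2:
        return np.nan
    gross = np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1))
    if gross == 0:
        return np.nan
    return float(np.linalg.norm(xy[-1] - xy[0]) / gross)


def brownian_scaling(t: np.ndarray, xy: np.ndarray) -> float:
    """Scale of sqrt(dt)-normalised displacement increments.

    Per axis the increments d/sqrt(dt) are centred by (sum of d/dt)/n (the
    two normalisations coincide at 1 s spacing); the parameter is the
    square root of half the trace of the mean outer-product matrix of the
    centred increment rows.
    """
    t, xy = np.asarray(t, float), np.asarray(xy, float)
    if len(t) < 2:
        return np.nan
    dt = np.diff(t)
    d = np.diff(xy, axis=0)
    n = d.shape[0]
    scaled = d / np.sqrt(dt)[:, None]
    centre = np.sum(d / dt[:, None], axis=0) / n
    c = scaled - centre
    return float(np.sqrt(np.sum(c * c) / n / 2.0))


def msd(t: np.ndarray, xy: np.ndarray, taus=DEFAULT_MSD_TAUS) -> np.ndarray:
    """Mean squared displacement over integer lags (overlapping pairs),
    assuming a uniform 1 s grid."""
    xy = np.asarray(xy, float)
    n = len(xy)
    out = np.full(len(taus), np.nan)
    for i, tau in enumerate(taus):
        if n > tau:
            d = xy[tau:] - xy[:-tau]
            out[i] = np.mean(np.sum(d * d, axis=1))
    return out


def msd_fit(t: np.ndarray, xy: np.ndarray, taus=DEFAULT_MSD_TAUS):
    """Least-squares fit of log MSD on log tau; returns (a, b) of a*tau^b."""
    m = msd(t, xy, taus)
    if not np.isfinite(m).all() or (m <= 0).any():
        return np.nan, np.nan
    lx = np.log(np.asarray(taus, float))
    ly = np.log(m)
    b, b0 = np.polyfit(lx, ly, 1)
    return float(np.exp(b0)), float(b)


def _center_distances(xy: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Distances centre -> every fix; float32 when the matrix is large
    (centimetre-scale rounding, immaterial for passage times)."""
    dtype = np.float32 if centers.size * len(xy) > 1_000_000 else np.float64
    diff = xy[centers, None, :].astype(dtype) - xy[None, :, :].astype(dtype)
    return np.sqrt((diff * diff).sum(axis=2))


def _fpt_from_distances(d: np.ndarray, t: np.ndarray, centers: np.ndarray,
                        radius: float, mode: str) -> np.ndarray:
    """Vectorised FPT for centre rows of a (m, n) distance matrix."""
    m, n = d.shape
    rows = np.arange(m)
    cols = np.arange(n)[None, :]
    ge = d >= radius
    with np.errstate(divide="ignore", invalid="ignore"):
        mask_f = ge & (cols > centers[:, None])
        has_f = mask_f.any(axis=1)
        jf = np.argmax(mask_f, axis=1)
        jf_safe = np.where(has_f, jf, 1)
        dj, djm = d[rows, jf_safe], d[rows, jf_safe - 1]
        tc = t[jf_safe - 1] + (radius - djm) / (dj - djm) * (
            t[jf_safe] - t[jf_safe - 1])
        fwd = np.where(has_f, tc - t[centers], np.nan)
        if mode == "forward":
            return fwd
        mask_b = ge & (cols < centers[:, None])
        has_b = mask_b.any(axis=1)
        jb = n - 1 - np.argmax(mask_b[:, ::-1], axis=1)
        jb_safe = np.where(has_b, jb, 0)
        dj, djp = d[rows, jb_safe], d[rows, np.minimum(jb_safe + 1, n - 1)]
        jb1 = np.minimum(jb_safe + 1, n - 1)
        tc = t[jb1] - (radius - djp) / (dj - djp) * (t[jb1] - t[jb_safe])
        bwd = np.where(has_b, t[centers] - tc, np.nan)
    return fwd + bwd  # NaN if either side censored


def first_passage_times(t: np.ndarray, xy: np.ndarray, radius: float,
                        mode: str = "both", center_stride: int = 1) -> np.ndarray:
    """FPT per evaluated centre fix (NaN when censored).

    ``center_stride`` evaluates every k-th fix as a centre — the literal
    per-fix definition at stride 1, a decimated grid for long tracks.
    """
    t, xy = np.asarray(t, float), np.asarray(xy, float)
    n = len(t)
    centers = np.arange(0, n, center_stride)
    if n < 2:
        return np.full(centers.size, np.nan)
    d = _center_distances(xy, centers)
    return _fpt_from_distances(d, t, centers, radius, mode)


def fpt_features(t: np.ndarray, xy: np.ndarray, radii=DEFAULT_FPT_RADII,
                 mode: str = "both", center_stride: int = 1) -> dict:
    """The five FPT summary features over the configured radii."""
    t, xy = np.asarray(t, float), np.asarray(xy, float)
    n = len(t)
    centers = np.arange(0, n, center_stride)
    if n >= 2:
        d = _center_distances(xy, centers)
        series = {r: _fpt_from_distances(d, t, centers, r, mode)
                  for r in radii}
    else:
        series = {r: np.full(centers.size, np.nan) for r in radii}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = {r: np.nanmean(s) if np.isfinite(s).any() else np.nan
                 for r, s in series.items()}
        var_logs = {}
        for r, s in series.items():
            v = s[np.isfinite(s) & (s > 0)]
            var_logs[r] = np.var(np.log(v), ddof=1) if v.size >= 2 else np.nan

    out = {
        "fpt__mean_5m": means.get(5, np.nan),
        "fpt__var_log_5m": var_logs.get(5, np.nan),
        "fpt__acf1_5m": acf_lag1(series.get(5, np.zeros(0))),
    }
    vl = np.array([var_logs[r] for r in radii])
    out["fpt__argmax_var_radius"] = (
        float(radii[int(np.nanargmax(vl))]) if np.isfinite(vl).any() else np.nan)
    lr, lm = [], []
    for r in radii:
        if np.isfinite(means[r]) and means[r] > 0:
            lr.append(np.log(r))
            lm.append(np.log(means[r]))
    if len(lr) >= 2:
        out["fpt__loglog_slope"] = float(np.polyfit(lr, lm, 1)[0])
    else:
        out["fpt__loglog_slope"] = np.nan
    return out


def _summary7(x: np.ndarray) -> dict:
    """mean, sd, median, min, max, q1, q3 over finite values."""
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return dict.fromkeys(("mean", "sd", "median", "min", "max", "q1", "q3"),
                             np.nan)
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size >= 2 else np.nan,
        "median": float(np.median(x)),
        "min": float(x.min()),
        "max": float(x.max()),
        "q1": float(np.quantile(x, 0.25)),
        "q3": float(np.quantile(x, 0.75)),
    }


def individual_feature_vector(t: np.ndarray, xy: np.ndarray,
                              fpt_radii=DEFAULT_FPT_RADII, fpt_mode: str = "both",
                              fpt_center_stride: int = 1,
                              msd_taus=DEFAULT_MSD_TAUS) -> pd.Series:
    """All 27 individual features for one trajectory window."""
    t, xy = np.asarray(t, float), np.asarray(xy, float)
    out = {}
    out["net_gross_ratio"] = net_gross_ratio(xy)

    sp = step_speeds(t, xy)
    for k, v in _summary7(sp).items():
        out[f"speed__{k}"] = v
    out["speed__acf1"] = acf_lag1(sp)
    out["speed__brownian_scaling"] = brownian_scaling(t, xy)

    ta = turning_angles(xy)
    out["turn__rho"] = circular_rho(ta)
    out["turn__abs_acf1"] = acf_lag1(np.abs(ta))

    tv = tangential_velocity(t, xy)
    for k, v in _summary7(tv).items():
        out[f"tangv__{k}"] = v
    out["tangv__acf1"] = acf_lag1(tv)

    if len(t) >= max(msd_taus) + 2:
        out["msd__diffusion_a"], out["msd__power_b"] = msd_fit(t, xy, msd_taus)
    else:
        out["msd__diffusion_a"] = out["msd__power_b"] = np.nan

    out.update(fpt_features(t, xy, fpt_radii, fpt_mode, fpt_center_stride))
    return pd.Series(out, index=list(INDIVIDUAL_FEATURES), dtype=float)


# ---------------------------------------------------------------------------
# vectorised per-window batch (the 24-feature subset)
# ---------------------------------------------------------------------------



def _acf1_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise lag-1 autocorrelation; NaN where <3 finite or zero variance.

    Rows containing interior NaNs fall back to the scalar routine (NaNs are
    dropped, order kept) to stay consistent with :func:`acf_lag1`.
    """
    w, m = x.shape
    out = np.full(w, np.nan)
    if m < 3:
        return out
    fin = np.isfinite(x)
    clean = fin.all(axis=1)
    if clean.any():
        xc = x[clean] - x[clean].mean(axis=1, keepdims=True)
        denom = np.sum(xc * xc, axis=1)
        num = np.sum(xc[:, :-1] * xc[:, 1:], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = num / denom
        out[clean] = np.where(denom > 0, v, np.nan)
    mixed = ~clean & (fin.sum(axis=1) >= 3)
    for i in np.flatnonzero(mixed):
        out[i] = acf_lag1(x[i])
    return out


def _tangv_rows(xy: np.ndarray, dt: float) -> np.ndarray:
    """Row-wise |tangential velocity| for (W, k, 2) windows; (W, k-2)."""
    u = xy[:, 1:-1] - xy[:, :-2]
    v = xy[:, 2:] - xy[:, 1:-1]
    a = np.linalg.norm(u, axis=2)
    b = np.linalg.norm(v, axis=2)
    c = np.linalg.norm(xy[:, 2:] - xy[:, :-2], axis=2)
    area2 = np.abs(u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0])
    dhead = np.abs(_wrap(np.arctan2(v[..., 1], v[..., 0])
                         - np.arctan2(u[..., 1], u[..., 0])))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = dhead * (a * b * c / (2.0 * area2)) / dt
    return np.where((area2 == 0) | (a == 0) | (b == 0), np.nan, out)


def _fpt_batch(xy: np.ndarray, dt: float, radii, mode: str):
    """FPT series per radius for (W, k, 2) windows; dict r -> (W, k)."""
    w, k, _ = xy.shape
    t = dt * np.arange(k)
    d = np.sqrt(((xy[:, :, None, :] - xy[:, None, :, :]) ** 2).sum(axis=3))
    out = {}
    for r in radii:
        fpt = np.full((w, k), np.nan)
        ge = d >= r
        for i in range(k):
            # forward
            fwd = np.full(w, np.nan)
            if i + 1 < k:
                blk = ge[:, i, i + 1:]
                hit = blk.any(axis=1)
                j = i + 1 + np.argmax(blk, axis=1)
                jj = np.where(hit, j, i + 1)
                dj = d[np.arange(w), i, jj]
                djm = d[np.arange(w), i, jj - 1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    tc = t[jj - 1] + (r - djm) / (dj - djm) * dt
                fwd = np.where(hit, tc - t[i], np.nan)
            if mode == "forward":
                fpt[:, i] = fwd
                continue
            bwd = np.full(w, np.nan)
            if i > 0:
                blk = ge[:, i, :i]
                hit = blk.any(axis=1)
                j = i - 1 - np.argmax(blk[:, ::-1], axis=1)  # last True < i
                jj = np.where(hit, j, 0)
                dj = d[np.arange(w), i, jj]
                djp = d[np.arange(w), i, jj + 1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    tc = t[jj + 1] - (r - djp) / (dj - djp) * dt
                bwd = np.where(hit, t[i] - tc, np.nan)
            fpt[:, i] = fwd + bwd
        out[r] = fpt
    return out


def individual_features_batch(xy: np.ndarray, dt: float = 1.0,
                              fpt_radii=DEFAULT_FPT_RADII,
                              fpt_mode: str = "both") -> pd.DataFrame:
    """The 24-feature per-window subset for a stack of short windows.

    ``xy`` is (W, k, 2): W windows of k fixes at uniform spacing ``dt``.
    Vectorised across windows; numerically identical to calling
    :func:`individual_feature_vector` per window (minus the three excluded
    long-track features).
    """
    xy = np.asarray(xy, float)
    w, k, _ = xy.shape
    cols = {}

    steps = np.diff(xy, axis=1)
    step_len = np.linalg.norm(steps, axis=2)  # (W, k-1)
    gross = step_len.sum(axis=1)
    net = np.linalg.norm(xy[:, -1] - xy[:, 0], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ngr = net / gross
    cols["net_gross_ratio"] = np.where(gross > 0, ngr, np.nan)

    sp = step_len / dt
    s7 = _summary7_rows(sp)
    for j, name in enumerate(("mean", "sd", "median", "min", "max", "q1", "q3")):
        cols[f"speed__{name}"] = s7[:, j]
    cols["speed__acf1"] = _acf1_rows(sp)

    h = np.arctan2(steps[..., 1], steps[..., 0])
    h = np.where((steps == 0).all(axis=2), np.nan, h)
    ta = _wrap(h[:, 1:] - h[:, :-1]) if k >= 3 else np.zeros((w, 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.hypot(np.nanmean(np.cos(ta), axis=1) if ta.shape[1] else np.nan,
                       np.nanmean(np.sin(ta), axis=1) if ta.shape[1] else np.nan)
    if ta.shape[1]:
        rho = np.where(np.isfinite(ta).any(axis=1), rho, np.nan)
        cols["turn__rho"] = rho
    else:
        cols["turn__rho"] = np.full(w, np.nan)
    cols["turn__abs_acf1"] = _acf1_rows(np.abs(ta)) if ta.shape[1] else np.full(w, np.nan)

    tv = _tangv_rows(xy, dt) if k >= 3 else np.zeros((w, 0))
    s7 = _summary7_rows(tv)
    for j, name in enumerate(("mean", "sd", "median", "min", "max", "q1", "q3")):
        cols[f"tangv__{name}"] = s7[:, j]
    cols["tangv__acf1"] = _acf1_rows(tv) if tv.shape[1] else np.full(w, np.nan)

    fpt = _fpt_batch(xy, dt, fpt_radii, fpt_mode)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means, var_logs = {}, {}
        for r, s in fpt.items():
            means[r] = np.where(np.isfinite(s).any(axis=1), np.nanmean(s, axis=1),
                                np.nan)
            logs = np.where(np.isfinite(s) & (s > 0), np.log(np.where(s > 0, s, 1.0)),
                            np.nan)
            n_fin = np.isfinite(logs).sum(axis=1)
            vl = np.full(w, np.nan)
            two = n_fin >= 2
            if two.any():
                vl[two] = np.nanvar(logs[two], axis=1, ddof=1)
            var_logs[r] = vl
        cols["fpt__mean_5m"] = means.get(5, np.full(w, np.nan))
        cols["fpt__var_log_5m"] = var_logs.get(5, np.full(w, np.nan))
        cols["fpt__acf1_5m"] = (_acf1_rows(fpt[5]) if 5 in fpt
                                else np.full(w, np.nan))
        vl_mat = np.stack([var_logs[r] for r in fpt_radii], axis=1)
        any_vl = np.isfinite(vl_mat).any(axis=1)
        arg = np.full(w, np.nan)
        if any_vl.any():
            arg[any_vl] = np.asarray(fpt_radii, float)[
                np.nanargmax(vl_mat[any_vl], axis=1)]
        cols["fpt__argmax_var_radius"] = arg

        m_mat = np.stack([means[r] for r in fpt_radii], axis=1)
        lr = np.log(np.asarray(fpt_radii, float))
        ok = np.isfinite(m_mat) & (m_mat > 0)
        xm = np.where(ok, lr[None, :], np.nan)
        ym = np.where(ok, np.log(np.where(ok, m_mat, 1.0)), np.nan)
        xbar = np.nanmean(xm, axis=1, keepdims=True)
        ybar = np.nanmean(ym, axis=1, keepdims=True)
        num = np.nansum((xm - xbar) * (ym - ybar), axis=1)
        den = np.nansum((xm - xbar) ** 2, axis=1)
        enough = (ok.sum(axis=1) >= 2) & (den > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(enough, num / den, np.nan)
        cols["fpt__loglog_slope"] = slope

    return pd.DataFrame(cols, columns=list(WINDOW_SUBSET))
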