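"""Row-wise summary statistics shared by the feature modules.

All helpers are NaN-aware (missing values are excluded per row) and use
the n-1 variance denominator and linear-interpolation quantiles.
"""

from __future__ import annotations

import numpy as np

SUMMARY7 = ("mean", "sd", "median", "min", "max", "q1", "q3")


def sorted_row_quantile(sorted_x: np.ndarray, n_valid: np.ndarray,
                        q: float) -> np.ndarray:
    """Quantile per row of a NaN-last sorted (W, m) matrix."""
    w = sorted_x.shape[0]
    out = np.full(w, np.nan)
    rows = np.flatnonzero(n_valid > 0)
    if rows.size == 0:
        return out
    nv = n_valid[rows]
    pos = q * (nv - 1)
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    hi = np.minimum(lo + 1, nv - 1)
    out[rows] = sorted_x[rows, lo] * (1 - frac) + sorted_x[rows, hi] * frac
    return out


def row_summary7(x: np.ndarray, sorted_x: np.ndarray | None = None
                 ) -> np.ndarray:
    """(W, 7): mean, sd, median, min, max, q1, q3 over finite row entries."""
    w, m = x.shape
    out = np.full((w, 7), np.nan)
    if m == 0:
        return out
    fin = np.isfinite(x)
    n = fin.sum(axis=1)
    any_ = n > 0
    xz = np.where(fin, x, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = xz.sum(axis=1) / n
        ssq = (xz * xz).sum(axis=1) - n * mean * mean
        sd = np.sqrt(np.maximum(ssq, 0.0) / (n - 1))
    out[any_, 0] = mean[any_]
    out[n >= 2, 1] = sd[n >= 2]
    xs = np.sort(x, axis=1) if sorted_x is None else sorted_x  # NaNs last
    out[:, 2] = sorted_row_quantile(xs, n, 0.5)
    rows = np.flatnonzero(any_)
    out[rows, 3] = xs[rows, 0]
    out[rows, 4] = xs[rows, n[rows] - 1]
    out[:, 5] = sorted_row_quantile(xs, n, 0.25)
    out[:, 6] = sorted_row_quantile(xs, n, 0.75)
    return out
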