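"""Per-pixel stability metrics: proportional variability and lag-1
autocorrelation, over full series and moving windows, plus the
median-threshold stability-regime classification.

Regime code table: 0 = invalid, 1 = stable (low PV, low AR),
2 = unstable (high PV, high AR), 3 = intermediate high-PV/low-AR,
4 = intermediate low-PV/high-AR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import RasterStack

__all__ = [
    "StabilityMap",
    "WindowSeries",
    "RegimeMap",
    "REGIME_CODES",
    "proportional_variability",
    "lag1_autocorrelation",
    "stability_map",
    "moving_window_metrics",
    "classify_regimes",
]

REGIME_CODES = {
    0: "invalid",
    1: "stable",
    2: "unstable",
    3: "moderate_highPV_lowAR",
    4: "moderate_lowPV_highAR",
}

_VAR_EPS = 1e-30


@dataclass
class StabilityMap:
    pv: np.ndarray  # (rows, cols), NaN where invalid
    ar: np.ndarray  # (rows, cols), NaN where invalid/degenerate
    valid: np.ndarray  # bool (rows, cols)
    degenerate: np.ndarray  # bool; zero-variance series (PV forced to 0)


@dataclass
class WindowSeries:
    """Moving-window PV/AR series per pixel; windows anchored at center year."""

    pv: np.ndarray  # (n_windows, rows, cols)
    ar: np.ndarray  # (n_windows, rows, cols)
    anchor_years: np.ndarray  # (n_windows,)
    window: int
    valid: np.ndarray  # bool (rows, cols): all windows valid


@dataclass
class RegimeMap:
    codes: np.ndarray  # uint8 per REGIME_CODES
    pv_threshold: float
    ar_threshold: float


def proportional_variability(series: np.ndarray) -> float:
    """Mean relative difference over all value pairs, in [0, 1].

    ``PV = 2/(n(n-1)) * sum_{i<j} |x_i - x_j| / (x_i + x_j)``; exactly 0
    for a constant series. Any pair with ``x_i + x_j <= 0`` makes the
    statistic undefined and raises ``ValueError``.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    diff = np.abs(x[:, None] - x[None, :])
    tot = x[:, None] + x[None, :]
    iu = np.triu_indices(x.size, k=1)
    sums = tot[iu]
    if np.any(sums <= 0):
        raise ValueError("pair with non-positive sum reached PV")
    n = x.size
    return float(np.sum(diff[iu] / sums) * 2.0 / (n * (n - 1)))


def lag1_autocorrelation(series: np.ndarray) -> float:
    """Lag-one autocorrelation against the series mean, in [-1, 1].

    ``AR = sum_{t<n} (x_t - xbar)(x_{t+1} - xbar) / sum_t (x_t - xbar)^2``.
    A zero-variance series is undefined (0/0) and raises ``ValueError``
    rather than silently returning 0.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    d = x - x.mean()
    denom = np.sum(d**2)
    if denom <= _VAR_EPS * x.size:
        raise ValueError("zero-variance series: AR undefined")
    return float(np.sum(d[:-1] * d[1:]) / denom)


# ---------------------------------------------------------------------------
# vectorized internals operating on (n_years, n_pixels) matrices


def _detrend_cols(x: np.ndarray, restore_mean: bool = True) -> np.ndarray:
    n = x.shape[0]
    t = np.arange(n, dtype=np.float64)
    tc = t - t.mean()
    mean = x.mean(axis=0)
    slope = (tc[:, None] * (x - mean)).sum(axis=0) / (tc**2).sum()
    resid = x - mean - tc[:, None] * slope
    return resid + mean if restore_mean else resid


def _pv_cols(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PV per column; returns (pv, bad) where bad marks non-positive pair sums."""
    n = x.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diff = np.abs(x[iu] - x[ju])
    tot = x[iu] + x[ju]
    bad = np.any(tot <= 0, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pv = np.sum(diff / tot, axis=0) * 2.0 / (n * (n - 1))
    pv[bad] = np.nan
    return pv, bad


def _ar_cols(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AR per column; returns (ar, degenerate) with NaN where variance is 0."""
    d = x - x.mean(axis=0)
    denom = np.sum(d**2, axis=0)
    degenerate = denom <= _VAR_EPS * x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = np.sum(d[:-1] * d[1:], axis=0) / denom
    ar[degenerate] = np.nan
    return ar, degenerate


def _metrics_cols(x: np.ndarray, detrend: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(pv, ar, degenerate, pv_bad) for a (n_years, n_pixels) block."""
    y = _detrend_cols(x, restore_mean=True) if detrend else x
    ar, degenerate = _ar_cols(y)
    pv, pv_bad = _pv_cols(y)
    # zero-variance after detrend: PV defined as exactly 0, AR stays undefined
    pv[degenerate & ~pv_bad] = 0.0
    return pv, ar, degenerate, pv_bad


def stability_map(stack: RasterStack, detrend: bool = True) -> StabilityMap:
    """Full-series PV and AR per pixel (after per-pixel linear detrending).

    Degenerate pixels (zero variance after detrending) carry PV = 0 and an
    undefined AR and are flagged invalid; masked pixels are invalid with
    NaN in both metrics.
    """
    if stack.n_years < 3:
        raise ValueError("stack must span at least 3 years")
    n_rows, n_cols = stack.shape[1:]
    flat = stack.data.reshape(stack.n_years, -1)
    pixel_ok = stack.mask.ravel() & np.all(np.isfinite(flat), axis=0)

    pv = np.full(n_rows * n_cols, np.nan)
    ar = np.full(n_rows * n_cols, np.nan)
    degen = np.zeros(n_rows * n_cols, dtype=bool)
    if np.any(pixel_ok):
        p, a, d, bad = _metrics_cols(flat[:, pixel_ok], detrend)
        pv[pixel_ok] = p
        ar[pixel_ok] = a
        degen[pixel_ok] = d
    valid = pixel_ok & np.isfinite(ar) & np.isfinite(pv)
    shape = (n_rows, n_cols)
    return StabilityMap(
        pv=pv.reshape(shape),
        ar=ar.reshape(shape),
        valid=valid.reshape(shape),
        degenerate=degen.reshape(shape),
    )


def moving_window_metrics(
    stack: RasterStack, window: int = 15, detrend: bool = True
) -> WindowSeries:
    """PV and AR over every length-``window`` moving window per pixel.

    Each window is re-detrended independently so residual long-term trends
    cannot contaminate the within-window statistics; windows are anchored
    at their center year.
    """
    if window >= stack.n_years:
        raise ValueError("window must be shorter than the series")
    if stack.n_years < window + 2:
        raise ValueError("need at least window + 2 years for a window trend")
    n_win = stack.n_years - window + 1
    n_rows, n_cols = stack.shape[1:]
    flat = stack.data.reshape(stack.n_years, -1)
    pixel_ok = stack.mask.ravel() & np.all(np.isfinite(flat), axis=0)

    pv = np.full((n_win, n_rows * n_cols), np.nan)
    ar = np.full((n_win, n_rows * n_cols), np.nan)
    if np.any(pixel_ok):
        sub = flat[:, pixel_ok]
        for s in range(n_win):
            p, a, _, _ = _metrics_cols(sub[s : s + window], detrend)
            pv[s, pixel_ok] = p
            ar[s, pixel_ok] = a
    anchor_years = stack.years[np.arange(n_win) + window // 2]
    valid = np.all(np.isfinite(pv), axis=0) & np.all(np.isfinite(ar), axis=0)
    return WindowSeries(
        pv=pv.reshape(n_win, n_rows, n_cols),
        ar=ar.reshape(n_win, n_rows, n_cols),
        anchor_years=anchor_years,
        window=window,
        valid=valid.reshape(n_rows, n_cols),
    )


def classify_regimes(smap: StabilityMap, quantile: float = 0.5) -> RegimeMap:
    """Quadrant classification by the PV and AR quantile thresholds.

    Thresholds default to the medians over valid pixels. Ties (a value
    exactly at the threshold) go to the "low" side, making "stable" the
    closed cell of the partition.
    """
    valid = smap.valid
    if not np.any(valid):
        raise ValueError("no valid pixels to classify")
    pv_thr = float(np.quantile(smap.pv[valid], quantile))
    ar_thr = float(np.quantile(smap.ar[valid], quantile))
    low_pv = smap.pv <= pv_thr
    low_ar = smap.ar <= ar_thr
    codes = np.zeros(smap.pv.shape, dtype=np.uint8)
    codes[valid & low_pv & low_ar] = 1
    codes[valid & ~low_pv & ~low_ar] = 2
    codes[valid & ~low_pv & low_ar] = 3
    codes[valid & low_pv & ~low_ar] = 4
    return RegimeMap(codes=codes, pv_threshold=pv_thr, ar_threshold=ar_thr)
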