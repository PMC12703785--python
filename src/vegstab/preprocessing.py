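"""Index transforms and covariate preparation.

Covers the kernel NDVI transform, annual-maximum compositing, vapor
pressure deficit, inverse-distance-weighted station interpolation,
nearest-neighbor grid resampling and per-pixel linear detrending.
"""

from __future__ import annotations

import numpy as np

from .stack import GridSpec, RasterStack

__all__ = [
    "kndvi",
    "annual_max_composite",
    "vpd",
    "idw_interpolate",
    "resample_nearest",
    "detrend_linear",
]


def kndvi(ndvi):
    """Kernel NDVI: ``tanh(ndvi**2)``, element-wise.

    Input must lie in [-1, 1]; values outside signal unscaled input and
    raise ``ValueError``. NaN passes through (masked cells).
    """
    arr = np.asarray(ndvi, dtype=np.float64)
    finite = np.isfinite(arr)
    if np.any(np.abs(arr[finite]) > 1.0):
        raise ValueError("NDVI values outside [-1, 1]; input appears unscaled")
    out = np.tanh(arr**2)
    if np.isscalar(ndvi) or arr.ndim == 0:
        return float(out)
    return out


def annual_max_composite(
    observations: np.ndarray, years: np.ndarray, grid: GridSpec | None = None
) -> RasterStack:
    """Composite per-observation layers into one annual-maximum layer per year.

    Parameters
    ----------
    observations : array (n_obs, n_rows, n_cols)
        Individual observations; NaN marks invalid (cloudy/masked) cells.
    years : array (n_obs,)
        Calendar year of each observation layer.

    Pixel-years with zero valid observations come out masked (NaN), never 0.
    """
    obs = np.asarray(observations, dtype=np.float64)
    yrs = np.asarray(years)
    if obs.ndim != 3:
        raise ValueError("observations must be 3-D (obs, row, col)")
    if yrs.shape != (obs.shape[0],):
        raise ValueError("one timestamp per observation layer required")
    uyears = np.unique(yrs)
    out = np.full((uyears.size,) + obs.shape[1:], np.nan)
    for i, y in enumerate(uyears):
        sel = obs[yrs == y]
        with np.errstate(all="ignore"):
            out[i] = np.nanmax(sel, axis=0)
    mask = np.all(np.isfinite(out), axis=0)
    return RasterStack(out, uyears.astype(np.int64), mask, grid or GridSpec())


def vpd(temperature, relative_humidity):
    """Vapor pressure deficit (kPa) from air temperature (degC) and RH (%).

    Tetens saturation vapor pressure, ``0.611 * exp(17.27*T/(T+237.3))``,
    scaled by the saturation deficit fraction ``(100 - RH)/100``.
    """
    t = np.asarray(temperature, dtype=np.float64)
    rh = np.asarray(relative_humidity, dtype=np.float64)
    finite = np.isfinite(rh)
    if np.any((rh[finite] < 0) | (rh[finite] > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    svp = 0.611 * np.exp(17.27 * t / (t + 237.3))
    out = svp * (1.0 - rh / 100.0)
    if np.isscalar(temperature) and np.isscalar(relative_humidity):
        return float(out)
    return out


def idw_interpolate(
    station_xy: np.ndarray,
    station_values: np.ndarray,
    grid: GridSpec,
    shape: tuple[int, int],
    power: float = 2.0,
    k: int = 10,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of station values onto a grid.

    Each cell is the ``d**-power`` weighted mean of its ``k`` nearest
    stations (all stations when fewer than ``k`` exist). A cell whose center
    coincides with a station returns that station's value exactly. Nearest
    sets are resolved with a stable sort so distance ties break by station
    index, keeping the output deterministic.
    """
    xy = np.asarray(station_xy, dtype=np.float64).reshape(-1, 2)
    vals = np.asarray(station_values, dtype=np.float64).ravel()
    if xy.shape[0] == 0:
        raise ValueError("at least one station required")
    if xy.shape[0] != vals.size:
        raise ValueError("one value per station required")
    if not np.all(np.isfinite(xy)) or not np.all(np.isfinite(vals)):
        raise ValueError("station coordinates and values must be finite")
    # duplicate coordinates with conflicting values are ambiguous
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    sx = xy[order]
    dup = np.all(np.diff(sx, axis=0) == 0, axis=1)
    if np.any(dup):
        v = vals[order]
        if np.any(v[:-1][dup] != v[1:][dup]):
            raise ValueError("duplicate station coordinates with conflicting values")

    n_rows, n_cols = shape
    gx, gy = grid.cell_centers(n_rows, n_cols)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    k_use = min(k, xy.shape[0])
    out = np.empty(pts.shape[0])
    # brute-force distances in row chunks; stable argsort gives index tie-break
    chunk = max(1, 2_000_000 // max(1, xy.shape[0]))
    for start in range(0, pts.shape[0], chunk):
        p = pts[start : start + chunk]
        d = np.sqrt(((p[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
        idx = np.argsort(d, axis=1, kind="stable")[:, :k_use]
        dk = np.take_along_axis(d, idx, axis=1)
        vk = vals[idx]
        exact = dk[:, 0] == 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            w = dk ** (-power)
            est = (w * vk).sum(axis=1) / w.sum(axis=1)
        est[exact] = vk[exact, 0]
        out[start : start + chunk] = est
    return out.reshape(shape)


def resample_nearest(
    layer: np.ndarray,
    source_grid: GridSpec,
    target_grid: GridSpec,
    target_shape: tuple[int, int],
) -> np.ndarray:
    """Nearest-neighbor resampling of ``layer`` onto ``target_grid``.

    Each target cell takes the value of the source cell whose center is
    nearest to the target cell center; NaN (mask) propagates. Raises
    ``ValueError`` when the two extents are disjoint.
    """
    src = np.asarray(layer, dtype=np.float64)
    if src.ndim != 2:
        raise ValueError("layer must be 2-D")
    s_xmin, s_xmax, s_ymin, s_ymax = source_grid.extent(*src.shape)
    t_xmin, t_xmax, t_ymin, t_ymax = target_grid.extent(*target_shape)
    if t_xmax <= s_xmin or t_xmin >= s_xmax or t_ymax <= s_ymin or t_ymin >= s_ymax:
        raise ValueError("source and target extents are disjoint")
    tx, ty = target_grid.cell_centers(*target_shape)
    col = np.clip(np.floor((tx - source_grid.x0) / source_grid.dx).astype(int), 0, src.shape[1] - 1)
    row = np.clip(np.floor((ty - source_grid.y0) / source_grid.dy).astype(int), 0, src.shape[0] - 1)
    return src[row, col]


def detrend_linear(series: np.ndarray, restore_mean: bool = True) -> np.ndarray:
    """Remove the OLS line fit on (year index, value) from a series.

    With ``restore_mean`` the series mean is added back so downstream
    ratio statistics keep strictly positive values; without it the raw OLS
    residuals are returned. An all-identical input yields a constant
    (degenerate) output that downstream stages must flag, not an error.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size < 3:
        raise ValueError("series must have length >= 3")
    t = np.arange(x.size, dtype=np.float64)
    tc = t - t.mean()
    denom = (tc**2).sum()
    slope = (tc * (x - x.mean())).sum() / denom
    fitted = x.mean() + slope * tc
    resid = x - fitted
    return resid + x.mean() if restore_mean else resid
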