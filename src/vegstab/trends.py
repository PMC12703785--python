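"""Trend estimation and hotspot mapping.

Theil-Sen slopes with Mann-Kendall significance, the composite
destabilization index (sum of max-abs-normalized PV and AR trends after
excluding opposing-sign pixels), Moran's I spatial clustering, and the
five-state ecosystem typology coupling functioning and stability.

Code tables:
  composite label: 0 = excluded, 1 = hotspot (both trends up),
                   2 = coldspot (both trends down), 3 = neutral (zero sum)
  ecosystem state: 0 = invalid, 1 = ideal, 2 = acceptable, 3 = poor,
                   4 = abysmal, 5 = unknown
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

from .stability import WindowSeries, _metrics_cols
from .stack import RasterStack

__all__ = [
    "TrendMap",
    "CompositeMap",
    "EcosystemStateMap",
    "COMPOSITE_CODES",
    "STATE_CODES",
    "theil_sen",
    "mann_kendall",
    "mann_kendall_p",
    "trend_map",
    "window_trend_permutation_p",
    "composite_index",
    "rook_weights",
    "morans_i",
    "ecosystem_state",
]

COMPOSITE_CODES = {0: "excluded", 1: "hotspot", 2: "coldspot", 3: "neutral"}
STATE_CODES = {0: "invalid", 1: "ideal", 2: "acceptable", 3: "poor", 4: "abysmal", 5: "unknown"}


@dataclass
class TrendMap:
    slope: np.ndarray  # per pixel, NaN invalid
    p_value: np.ndarray  # per pixel, NaN invalid
    direction: np.ndarray  # int8: +1 increasing, -1 decreasing, 0 zero/invalid
    valid: np.ndarray  # bool


@dataclass
class CompositeMap:
    value: np.ndarray  # normalized dAR + dPV in [-2, 2]; NaN where excluded/invalid
    label: np.ndarray  # uint8 per COMPOSITE_CODES
    excluded: np.ndarray  # bool: opposing trend signs
    valid: np.ndarray  # bool: both inputs valid
    ar_norm: float  # max |dAR| over retained pixels
    pv_norm: float  # max |dPV| over retained pixels


@dataclass
class EcosystemStateMap:
    codes: np.ndarray  # uint8 per STATE_CODES
    alpha: float


def theil_sen(series: np.ndarray, t: np.ndarray | None = None) -> float:
    """Theil-Sen slope: median of all pairwise slopes (x_j - x_i)/(t_j - t_i)."""
    y = np.asarray(series, dtype=np.float64)
    x = np.arange(y.size, dtype=np.float64) if t is None else np.asarray(t, dtype=np.float64)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 2:
        return float("nan")
    i, j = np.triu_indices(y.size, k=1)
    return float(np.median((y[j] - y[i]) / (x[j] - x[i])))


def mann_kendall(series: np.ndarray) -> tuple[float, float, float]:
    """Mann-Kendall trend test: returns (S, z, two-sided p).

    Uses the tie-corrected variance and the +/-1 continuity correction on S
    before the normal approximation.
    """
    y = np.asarray(series, dtype=np.float64)
    y = y[np.isfinite(y)]
    n = y.size
    if n < 4:
        return float("nan"), float("nan"), float("nan")
    s = float(np.sign(y[None, :] - y[:, None])[np.triu_indices(n, k=1)].sum())
    _, counts = np.unique(y, return_counts=True)
    tie_term = np.sum(counts * (counts - 1) * (2 * counts + 5))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_s <= 0:
        return s, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(z), float(p)


def mann_kendall_p(series: np.ndarray) -> float:
    """Two-sided Mann-Kendall p-value (NaN when n < 4)."""
    return mann_kendall(series)[2]


def trend_map(windows: WindowSeries, metric: str) -> TrendMap:
    """Theil-Sen slope and Mann-Kendall p of a windowed metric, per pixel.

    Slopes are per window step, i.e. per year of window advance.
    """
    if metric not in ("pv", "ar"):
        raise ValueError("metric must be 'pv' or 'ar'")
    cube = getattr(windows, metric)
    n_win = cube.shape[0]
    if n_win < 3:
        raise ValueError("need at least 3 windows for a trend")
    shape = cube.shape[1:]
    flat = cube.reshape(n_win, -1)
    slope = np.full(flat.shape[1], np.nan)
    p = np.full(flat.shape[1], np.nan)
    ok = windows.valid.ravel()
    for idx in np.flatnonzero(ok):
        y = flat[:, idx]
        slope[idx] = theil_sen(y)
        p[idx] = mann_kendall_p(y)
    valid = np.isfinite(slope) & np.isfinite(p)
    direction = np.zeros(flat.shape[1], dtype=np.int8)
    direction[valid & (slope > 0)] = 1
    direction[valid & (slope < 0)] = -1
    return TrendMap(
        slope=slope.reshape(shape),
        p_value=p.reshape(shape),
        direction=direction.reshape(shape),
        valid=valid.reshape(shape),
    )


def window_trend_permutation_p(
    stack: RasterStack,
    window: int = 15,
    metric: str = "pv",
    n_permutations: int = 99,
    seed: int = 0,
    detrend: bool = True,
) -> np.ndarray:
    """Calibrated p-values for moving-window metric trends via permutation.

    The Mann-Kendall p of :func:`trend_map` is strongly anti-conservative
    on moving-window series because adjacent windows share most of their
    years; this test instead recomputes the whole window-metric chain on
    year-permuted series, so under exchangeability the two-sided pseudo
    p-value of the observed Theil-Sen slope is calibrated by construction.
    Returns a per-pixel p map (NaN where invalid).
    """
    if metric not in ("pv", "ar"):
        raise ValueError("metric must be 'pv' or 'ar'")
    if window >= stack.n_years:
        raise ValueError("window must be shorter than the series")
    t = stack.n_years
    flat = stack.data.reshape(t, -1)
    ok = stack.mask.ravel() & np.all(np.isfinite(flat), axis=0)
    out = np.full(flat.shape[1], np.nan)
    if not np.any(ok):
        return out.reshape(stack.shape[1:])
    sub = flat[:, ok]
    n_win = t - window + 1
    i, j = np.triu_indices(n_win, 1)
    step = (j - i).astype(np.float64)[:, None]

    def _win_metric(x: np.ndarray) -> np.ndarray:
        m = np.empty((n_win, x.shape[1]))
        for s in range(n_win):
            p, a, _, _ = _metrics_cols(x[s : s + window], detrend)
            m[s] = p if metric == "pv" else a
        return m

    def _slopes(m: np.ndarray) -> np.ndarray:
        return np.median((m[j] - m[i]) / step, axis=0)

    obs = _slopes(_win_metric(sub))
    rng = np.random.default_rng(seed)
    count = np.zeros(obs.size)
    for _ in range(n_permutations):
        perm = rng.permutation(t)
        count += np.abs(_slopes(_win_metric(sub[perm]))) >= np.abs(obs)
    out[ok] = (count + 1) / (n_permutations + 1)
    return out.reshape(stack.shape[1:])


def composite_index(dar: TrendMap, dpv: TrendMap) -> CompositeMap:
    """Composite destabilization index from the two stability-trend maps.

    Steps: (1) exclude pixels whose AR and PV trends have strictly opposing
    signs; (2) divide each retained slope by the maximum absolute slope of
    its variable over retained pixels; (3) sum the two normalized values.
    Positive sums are destabilization hotspots, negative sums coldspots.
    """
    if dar.slope.shape != dpv.slope.shape:
        raise ValueError("trend maps must share a grid")
    valid = dar.valid & dpv.valid
    opposing = valid & (np.sign(dar.slope) * np.sign(dpv.slope) < 0)
    retained = valid & ~opposing

    def _norm(slopes: np.ndarray) -> float:
        if not np.any(retained):
            return 0.0
        return float(np.max(np.abs(slopes[retained])))

    ar_norm = _norm(dar.slope)
    pv_norm = _norm(dpv.slope)
    value = np.full(dar.slope.shape, np.nan)
    if np.any(retained):
        a = np.where(ar_norm > 0, dar.slope / max(ar_norm, np.finfo(float).tiny), 0.0)
        p = np.where(pv_norm > 0, dpv.slope / max(pv_norm, np.finfo(float).tiny), 0.0)
        value[retained] = a[retained] + p[retained]
    label = np.zeros(dar.slope.shape, dtype=np.uint8)
    label[retained & (value > 0)] = 1
    label[retained & (value < 0)] = 2
    label[retained & (value == 0)] = 3
    return CompositeMap(
        value=value,
        label=label,
        excluded=opposing,
        valid=valid,
        ar_norm=ar_norm,
        pv_norm=pv_norm,
    )


def rook_weights(shape: tuple[int, int], row_standardize: bool = True) -> sparse.csr_matrix:
    """Rook-contiguity spatial weights for a full regular grid."""
    n_rows, n_cols = shape
    n = n_rows * n_cols
    rows, cols = [], []
    idx = np.arange(n).reshape(shape)
    for dr, dc in ((0, 1), (1, 0)):
        a = idx[: n_rows - dr, : n_cols - dc].ravel()
        b = idx[dr:, dc:].ravel()
        rows.extend([a, b])
        cols.extend([b, a])
    w = sparse.csr_matrix(
        (np.ones(sum(len(r) for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    if row_standardize:
        inv = 1.0 / np.asarray(w.sum(axis=1)).ravel()
        w = sparse.diags(inv) @ w
    return w.tocsr()


def morans_i(
    layer: np.ndarray,
    weights: sparse.spmatrix | None = None,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Global Moran's I with a permutation pseudo p-value.

    ``I = (N / sum(w)) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with z the
    deviations from the layer mean. The p-value is one-sided in the
    direction of the observed departure from the null expectation
    ``-1/(N-1)``, estimated from ``permutations`` random relabelings.
    """
    z = np.asarray(layer, dtype=np.float64).ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("layer must be finite (subset valid cells first)")
    n = z.size
    if n < 9:
        raise ValueError("need at least 9 cells")
    z = z - z.mean()
    denom = np.sum(z**2)
    if denom == 0:
        raise ValueError("constant layer: Moran's I undefined")
    if weights is None:
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise ValueError("default rook weights need a square layer; pass weights")
        weights = rook_weights((side, side))
    w = sparse.csr_matrix(weights)
    s0 = w.sum()

    def _stat(v: np.ndarray) -> float:
        return float(n / s0 * (v @ (w @ v)) / np.sum(v**2))

    i_obs = _stat(z)
    if permutations <= 0:
        return i_obs, float("nan")
    rng = np.random.default_rng(seed)
    e_i = -1.0 / (n - 1)
    extreme = 0
    for _ in range(permutations):
        i_perm = _stat(rng.permutation(z))
        if (i_obs >= e_i and i_perm >= i_obs) or (i_obs < e_i and i_perm <= i_obs):
            extreme += 1
    p = (extreme + 1) / (permutations + 1)
    return i_obs, float(p)


def ecosystem_state(
    ef: TrendMap, es: CompositeMap, alpha: float = 0.05, state_table: dict | None = None
) -> EcosystemStateMap:
    """Five-state typology from the functioning trend and the stability composite.

    EF is the vegetation-index Theil-Sen trend (significance via
    Mann-Kendall at ``alpha``); ES is the composite index sign (negative =
    stability improving). Default table: EF up & ES improving -> ideal;
    EF up & ES degrading -> acceptable; EF down & ES improving -> poor;
    EF down & ES degrading -> abysmal; ES-excluded, zero-composite or
    non-significant EF -> unknown. A custom ``state_table`` may remap the
    (ef_direction, es_sign) pairs, e.g. ``{(1, -1): "ideal", ...}``.
    """
    if ef.slope.shape != es.value.shape:
        raise ValueError("EF and ES maps must share a grid")
    table = state_table or {
        (1, -1): "ideal",
        (1, 1): "acceptable",
        (-1, -1): "poor",
        (-1, 1): "abysmal",
    }
    name_to_code = {v: k for k, v in STATE_CODES.items()}
    codes = np.zeros(ef.slope.shape, dtype=np.uint8)
    valid = ef.valid & es.valid
    codes[valid] = name_to_code["unknown"]
    ef_sig = valid & (ef.p_value < alpha)
    retained = ~es.excluded & np.isfinite(es.value)
    decidable = ef_sig & retained
    es_sign = np.sign(es.value)
    for (ef_dir, es_dir), name in table.items():
        sel = decidable & (ef.direction == ef_dir) & (es_sign == es_dir)
        codes[sel] = name_to_code[name]
    return EcosystemStateMap(codes=codes, alpha=alpha)
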