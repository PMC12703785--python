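"""Synthetic raster time series and covariate stacks with known structure.

Every generator is bit-reproducible under a fixed seed and independent of
grid traversal order: each pixel derives its own RNG stream from
``(seed, row, col)`` via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stack import GridSpec, RasterStack

__all__ = [
    "SimConfig",
    "DriverSpec",
    "ZoneParams",
    "simulate_pixel_series",
    "simulate_stack",
    "simulate_drivers",
]

_MAX_POSITIVITY_ATTEMPTS = 100


@dataclass(frozen=True)
class ZoneParams:
    """Per-zone overrides of the AR(1) process parameters."""

    phi: float
    sigma_rel: float
    trend: float = 0.0


@dataclass
class SimConfig:
    """Parameters of the simulated annual vegetation-index process.

    Each pixel series is ``baseline + trend*t + e_t`` where ``e_t`` is a
    stationary Gaussian AR(1) process with coefficient ``phi`` and marginal
    standard deviation ``sigma_rel * baseline`` (innovation sd
    ``sigma_rel * baseline * sqrt(1 - phi**2)``).
    """

    n_years: int = 40
    n_rows: int = 10
    n_cols: int = 10
    baseline: float = 0.5
    phi: float = 0.3
    sigma_rel: float = 0.1
    trend: float = 0.0
    seed: int = 0
    zone_map: np.ndarray | None = None
    zones: dict[int, ZoneParams] = field(default_factory=dict)
    first_year: int = 1984
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        for name in ("baseline", "phi", "sigma_rel", "trend"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter {name}={v!r}")
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if not -1.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (-1, 1)")
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be non-negative")
        if self.zone_map is not None:
            zm = np.asarray(self.zone_map)
            if zm.shape != (self.n_rows, self.n_cols):
                raise ValueError(
                    f"zone_map shape {zm.shape} != grid shape {(self.n_rows, self.n_cols)}"
                )
            self.zone_map = zm
            missing = set(np.unique(zm).tolist()) - set(self.zones)
            if missing:
                raise ValueError(f"zone_map labels without ZoneParams: {sorted(missing)}")

    def params_at(self, row: int, col: int) -> ZoneParams:
        if self.zone_map is not None:
            return self.zones[int(self.zone_map[row, col])]
        return ZoneParams(self.phi, self.sigma_rel, self.trend)


@dataclass
class DriverSpec:
    """Covariate effect structure for the driver-recovery experiments."""

    weights: dict[str, float]
    noise_sd: float = 0.0
    smoothness: float = 3.0

    def __post_init__(self) -> None:
        if len(self.weights) < 2:
            raise ValueError("at least two covariates required")
        if all(w == 0 for w in self.weights.values()):
            raise ValueError("all-zero weights are degenerate")
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ValueError("noise_sd must be finite and non-negative")

    @property
    def dominant(self) -> str:
        return max(self.weights, key=lambda k: abs(self.weights[k]))


def _pixel_rng(seed: int, row: int, col: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(row, col)))


def _draw_series(rng: np.random.Generator, n: int, params: ZoneParams, baseline: float) -> np.ndarray:
    sigma = params.sigma_rel * baseline
    t = np.arange(n, dtype=np.float64)
    if sigma == 0.0:
        return baseline + params.trend * t
    phi = params.phi
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    z = rng.standard_normal(n)
    e = np.empty(n)
    e[0] = z[0] * sigma  # stationary start
    for i in range(1, n):
        e[i] = phi * e[i - 1] + innov_sd * z[i]
    return baseline + params.trend * t + e


def simulate_pixel_series(config: SimConfig, pixel: tuple[int, int]) -> np.ndarray:
    """Simulate one strictly positive annual series.

    Positivity is enforced by rejection-resampling the whole innovation
    sequence (up to 100 attempts) rather than clipping, which would distort
    the variance structure. Raises ``RuntimeError`` if all attempts fail;
    :func:`simulate_stack` converts that failure into a masked pixel.
    """
    row, col = pixel
    params = config.params_at(row, col)
    rng = _pixel_rng(config.seed, row, col)
    for _ in range(_MAX_POSITIVITY_ATTEMPTS):
        series = _draw_series(rng, config.n_years, params, config.baseline)
        if np.all(series > 0):
            return series
    raise RuntimeError(f"pixel {pixel}: no strictly positive series in "
                       f"{_MAX_POSITIVITY_ATTEMPTS} attempts")


def simulate_stack(config: SimConfig) -> RasterStack:
    """Simulate every pixel of the grid into a :class:`RasterStack`.

    Pixels whose series cannot be made strictly positive are masked out
    (mask False, NaN data) instead of raising.
    """
    data = np.full((config.n_years, config.n_rows, config.n_cols), np.nan)
    mask = np.zeros((config.n_rows, config.n_cols), dtype=bool)
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            try:
                data[:, r, c] = simulate_pixel_series(config, (r, c))
                mask[r, c] = True
            except RuntimeError:
                pass
    years = config.first_year + np.arange(config.n_years)
    return RasterStack(data=data, years=years, mask=mask, grid=config.grid)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Standardized smooth spatial field (blurred white noise, zero mean, unit sd)."""
    raw = rng.standard_normal(shape)
    if smoothness > 0:
        raw = ndimage.gaussian_filter(raw, sigma=smoothness, mode="reflect")
    sd = raw.std()
    if sd == 0:  # degenerate 1x1 grids
        return raw - raw.mean()
    return (raw - raw.mean()) / sd


def simulate_drivers(
    config: SimConfig, spec: DriverSpec
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Simulate covariate fields and a stability response with known drivers.

    Returns ``(covariates, response, response_noiseless)`` where each
    covariate is a smooth standardized field of shape (n_rows, n_cols) and
    ``response = sum_c weight_c * covariate_c + N(0, noise_sd)``. The
    noiseless response is returned alongside for recovery tests.
    """
    shape = (config.n_rows, config.n_cols)
    covariates: dict[str, np.ndarray] = {}
    # Per-covariate streams keyed by sorted name so insertion order of the
    # weights dict cannot change the fields.
    for name in sorted(spec.weights):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(hash(name) % 2**31,))
        )
        covariates[name] = _smooth_field(rng, shape, spec.smoothness)
    # accumulate in sorted name order so float summation order (and thus the
    # bit pattern) is independent of the weights dict insertion order
    noiseless = np.zeros(shape)
    for name in sorted(spec.weights):
        noiseless = noiseless + spec.weights[name] * covariates[name]
    rng_noise = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2**31 + 1,))
    )
    response = noiseless + spec.noise_sd * rng_noise.standard_normal(shape)
    return covariates, response, noiseless
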