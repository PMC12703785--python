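"""End-to-end pipeline driver.

Stage order: input -> stability metrics -> moving windows -> trend maps ->
composite index -> regimes / ecosystem states -> driver attribution, with a
structured JSON run manifest for reproducibility. All randomness flows from
the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .attribution import (
    build_feature_table,
    dependence_export,
    fit_stability_model,
    shapley_attribution,
)
from .stability import REGIME_CODES, classify_regimes, moving_window_metrics, stability_map
from .stack import RasterStack
from .synthetic import DriverSpec, SimConfig, simulate_drivers, simulate_stack
from .trends import (
    COMPOSITE_CODES,
    STATE_CODES,
    TrendMap,
    composite_index,
    ecosystem_state,
    mann_kendall_p,
    theil_sen,
)

__all__ = ["PipelineConfig", "run_pipeline", "functioning_trend"]

log = logging.getLogger("vegstab")


@dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run.

    Defaults reproduce the reference settings: 15-year moving window,
    alpha 0.05 significance, median (0.5-quantile) regime thresholds and
    composite normalization over retained pixels.
    """

    input_stack: str | None = None
    simulate: dict | None = None  # SimConfig kwargs (seed is injected)
    drivers: dict | None = None  # DriverSpec kwargs for synthetic covariates
    window: int = 15
    alpha: float = 0.05
    regime_quantile: float = 0.5
    detrend: bool = True
    attribution: dict = field(
        default_factory=lambda: {
            "enabled": True,
            "response": "darpv",
            "grid_search": False,
            "params": None,
            "max_samples": 50_000,
            "shap_samples": 1_000,
        }
    )
    outdir: str = "vegstab_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def functioning_trend(stack: RasterStack) -> TrendMap:
    """Theil-Sen slope + Mann-Kendall p of the raw annual series per pixel."""
    t, r, c = stack.shape
    flat = stack.data.reshape(t, -1)
    ok = stack.mask.ravel() & np.all(np.isfinite(flat), axis=0)
    slope = np.full(r * c, np.nan)
    p = np.full(r * c, np.nan)
    for idx in np.flatnonzero(ok):
        slope[idx] = theil_sen(flat[:, idx])
        p[idx] = mann_kendall_p(flat[:, idx])
    valid = np.isfinite(slope) & np.isfinite(p)
    direction = np.zeros(r * c, dtype=np.int8)
    direction[valid & (slope > 0)] = 1
    direction[valid & (slope < 0)] = -1
    return TrendMap(
        slope=slope.reshape(r, c),
        p_value=p.reshape(r, c),
        direction=direction.reshape(r, c),
        valid=valid.reshape(r, c),
    )


def _load_input(config: PipelineConfig) -> RasterStack:
    if config.input_stack:
        return vio.read_stack(config.input_stack)
    if config.simulate is not None:
        kwargs = dict(config.simulate)
        kwargs.setdefault("seed", config.seed)
        return simulate_stack(SimConfig(**kwargs))
    raise ValueError("config must provide input_stack or simulate")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all outputs under ``config.outdir``.

    Returns the result bundle; identical config + seed reruns are
    bit-identical. A stage failure halts with a stage-tagged error while
    earlier outputs remain on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    bundle: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                log.info("stage %s done in %.2fs", name, timings[name])
                return False

        return _Timer()

    with stage("validate"):
        if config.window < 3:
            raise ValueError("window must be >= 3")

    with stage("input"):
        stack = _load_input(config)
        if config.window >= stack.n_years:
            raise ValueError(
                f"window {config.window} must be shorter than the {stack.n_years}-year series"
            )
        bundle["stack"] = stack
        counts["total_pixels"] = int(stack.mask.size)
        counts["masked_pixels"] = int((~stack.mask).sum())
        vio.write_stack(stack, outdir / "stack.tif")

    with stage("stability"):
        smap = stability_map(stack, detrend=config.detrend)
        bundle["stability"] = smap
        counts["valid_stability"] = int(smap.valid.sum())
        counts["degenerate"] = int(smap.degenerate.sum())
        vio.write_layer(smap.pv, outdir / "pv.tif", stack.grid)
        vio.write_layer(smap.ar, outdir / "ar.tif", stack.grid)

    with stage("regimes"):
        regimes = classify_regimes(smap, quantile=config.regime_quantile)
        bundle["regimes"] = regimes
        for code, name in REGIME_CODES.items():
            counts[f"regime_{name}"] = int((regimes.codes == code).sum())
        vio.write_layer(regimes.codes, outdir / "regimes.tif", stack.grid)
        vio.write_code_table(REGIME_CODES, outdir / "regimes.codes.json")

    with stage("windows"):
        windows = moving_window_metrics(stack, window=config.window, detrend=config.detrend)
        bundle["windows"] = windows

    with stage("trends"):
        from .trends import trend_map

        dar = trend_map(windows, "ar")
        dpv = trend_map(windows, "pv")
        bundle["dar"], bundle["dpv"] = dar, dpv
        for name, tm in (("dar", dar), ("dpv", dpv)):
            vio.write_layer(tm.slope, outdir / f"{name}_slope.tif", stack.grid)
            vio.write_layer(tm.p_value, outdir / f"{name}_p.tif", stack.grid)
            counts[f"{name}_significant"] = int((tm.valid & (tm.p_value < config.alpha)).sum())

    with stage("composite"):
        comp = composite_index(dar, dpv)
        bundle["composite"] = comp
        counts["hotspot"] = int((comp.label == 1).sum())
        counts["coldspot"] = int((comp.label == 2).sum())
        counts["neutral"] = int((comp.label == 3).sum())
        counts["excluded"] = int(comp.excluded.sum())
        counts["composite_invalid"] = int((~comp.valid).sum())
        vio.write_layer(comp.value, outdir / "composite_value.tif", stack.grid)
        vio.write_layer(comp.label, outdir / "composite_label.tif", stack.grid)
        vio.write_code_table(COMPOSITE_CODES, outdir / "composite_label.codes.json")

    with stage("states"):
        ef = functioning_trend(stack)
        states = ecosystem_state(ef, comp, alpha=config.alpha)
        bundle["ef"], bundle["states"] = ef, states
        for code, name in STATE_CODES.items():
            counts[f"state_{name}"] = int((states.codes == code).sum())
        vio.write_layer(states.codes, outdir / "states.tif", stack.grid)
        vio.write_code_table(STATE_CODES, outdir / "states.codes.json")

    att_cfg = dict(config.attribution or {})
    if att_cfg.get("enabled", True) and config.drivers is not None:
        with stage("attribution"):
            sim_kwargs = dict(config.simulate or {})
            sim_kwargs.setdefault("seed", config.seed)
            sim_kwargs.setdefault("n_rows", stack.shape[1])
            sim_kwargs.setdefault("n_cols", stack.shape[2])
            sim_cfg = SimConfig(**sim_kwargs)
            covariates, _, _ = simulate_drivers(sim_cfg, DriverSpec(**config.drivers))
            response_key = att_cfg.get("response", "darpv")
            response, valid = _select_response(response_key, dar, dpv, comp)
            table = build_feature_table(
                covariates,
                response,
                valid,
                response_name=response_key,
                max_samples=att_cfg.get("max_samples", 50_000),
                seed=config.seed,
            )
            fit = fit_stability_model(
                table,
                params=att_cfg.get("params"),
                grid_search=att_cfg.get("grid_search", False),
                seed=config.seed,
                min_train_rows=att_cfg.get("min_train_rows", 100),
            )
            result = shapley_attribution(
                fit, table, max_samples=att_cfg.get("shap_samples", 1_000), seed=config.seed
            )
            bundle["attribution"] = result
            payload = {
                "r2_validation": result.r2_validation,
                "base_value": result.base_value,
                "params": result.params,
                "importances_pct": {k: float(v) for k, v in result.importances.items()},
                "category_totals_pct": result.category_totals,
            }
            (outdir / "attribution.json").write_text(json.dumps(payload, indent=2))
            table.X.assign(response=table.y).to_csv(outdir / "feature_table.csv", index=False)
            dep_frames = []
            for feat in result.importances.index:
                dep = dependence_export(result, feat, bins=10).assign(feature=feat)
                dep_frames.append(dep)
            pd.concat(dep_frames, ignore_index=True).to_csv(
                outdir / "dependence.csv", index=False
            )

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "pixel_counts": counts,
        "timings_s": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def _select_response(key: str, dar, dpv, comp) -> tuple[np.ndarray, np.ndarray]:
    if key == "dar":
        return dar.slope, dar.valid
    if key == "dpv":
        return dpv.slope, dpv.valid
    if key == "darpv":
        return comp.value, comp.valid & ~comp.excluded
    raise ValueError("attribution response must be 'dar', 'dpv' or 'darpv'")


def _versions() -> dict[str, str]:
    import sklearn
    import scipy

    from . import __version__

    return {
        "vegstab": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "pandas": pd.__version__,
    }
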