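"""Raster and tabular I/O.

Stacks and layers are stored as (multi-page) TIFF with NaN as NoData and a
JSON sidecar (``<file>.json``) carrying year labels and the affine grid;
the year is additionally written into each page's description tag. Code
tables for categorical rasters are emitted as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stack import GridSpec, RasterStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_layer",
    "read_layer",
    "write_code_table",
    "stack_to_csv",
    "csv_to_stack",
    "read_stations_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: RasterStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF, one page per year."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.data.astype(np.float32).copy()
    data[:, ~stack.mask] = np.nan
    with tifffile.TiffWriter(path) as tw:
        for i, year in enumerate(stack.years):
            tw.write(data[i], description=str(int(year)), contiguous=False)
    meta = {"years": [int(y) for y in stack.years], "grid": stack.grid.to_dict()}
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def _read_tiff_pages(path: Path) -> tuple[np.ndarray, list[int | None]]:
    with tifffile.TiffFile(path) as tf:
        layers = [page.asarray() for page in tf.pages]
        years: list[int | None] = []
        for page in tf.pages:
            desc = page.tags.get("ImageDescription")
            try:
                years.append(int(str(desc.value).strip()))
            except (AttributeError, ValueError, TypeError):
                years.append(None)
    return np.stack(layers).astype(np.float64), years


def read_stack(source: str | Path | list[str | Path]) -> RasterStack:
    """Read a stack from one multi-page TIFF or an (unordered) list of
    single-layer TIFFs; years come from page descriptions or the JSON
    sidecar, and layers are sorted by year."""
    if isinstance(source, (str, Path)):
        paths = [Path(source)]
    else:
        paths = [Path(p) for p in source]

    all_layers, all_years, grid = [], [], None
    for p in paths:
        data, page_years = _read_tiff_pages(p)
        meta = json.loads(_sidecar(p).read_text()) if _sidecar(p).exists() else {}
        if any(y is None for y in page_years):
            side_years = meta.get("years")
            if side_years is None or len(side_years) != len(page_years):
                raise ValueError(f"{p}: missing year metadata (page description or sidecar)")
            page_years = [int(y) for y in side_years]
        g = GridSpec.from_dict(meta["grid"]) if "grid" in meta else GridSpec()
        if grid is None:
            grid = g
            shape = data.shape[1:]
        elif g != grid or data.shape[1:] != shape:
            raise ValueError(f"{p}: grid/resolution inconsistent with other inputs")
        all_layers.append(data)
        all_years.extend(page_years)

    data = np.concatenate(all_layers, axis=0)
    years = np.asarray(all_years, dtype=np.int64)
    order = np.argsort(years, kind="stable")
    data, years = data[order], years[order]
    mask = np.all(np.isfinite(data), axis=0)
    return RasterStack(data=data, years=years, mask=mask, grid=grid)


def write_layer(array: np.ndarray, path: str | Path, grid: GridSpec | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array)
    if arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    meta = {"grid": (grid or GridSpec()).to_dict()}
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_layer(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    grid = GridSpec.from_dict(meta["grid"]) if "grid" in meta else GridSpec()
    return np.asarray(arr), grid


def write_code_table(codes: dict[int, str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({str(k): v for k, v in codes.items()}, indent=2))
    return path


def stack_to_csv(stack: RasterStack, path: str | Path) -> Path:
    """Flat long-format export: pixel_id, row, col, year, value."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t, r, c = stack.shape
    rows, cols = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
    frame = pd.DataFrame(
        {
            "pixel_id": np.tile((rows * c + cols).ravel(), t),
            "row": np.tile(rows.ravel(), t),
            "col": np.tile(cols.ravel(), t),
            "year": np.repeat(stack.years, r * c),
            "value": stack.data.reshape(t, -1).ravel(),
        }
    )
    frame.to_csv(path, index=False)
    return path


def csv_to_stack(path: str | Path, grid: GridSpec | None = None) -> RasterStack:
    frame = pd.read_csv(path)
    years = np.sort(frame["year"].unique())
    n_rows = int(frame["row"].max()) + 1
    n_cols = int(frame["col"].max()) + 1
    data = np.full((years.size, n_rows, n_cols), np.nan)
    year_pos = {int(y): i for i, y in enumerate(years)}
    data[
        frame["year"].map(year_pos).to_numpy(),
        frame["row"].to_numpy(),
        frame["col"].to_numpy(),
    ] = frame["value"].to_numpy()
    mask = np.all(np.isfinite(data), axis=0)
    return RasterStack(data, years.astype(np.int64), mask, grid or GridSpec())


def read_stations_csv(path: str | Path) -> pd.DataFrame:
    """Station table with columns station_id, x, y, time, variable, value."""
    frame = pd.read_csv(path)
    required = {"station_id", "x", "y", "time", "variable", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"station CSV missing columns: {sorted(missing)}")
    return frame
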