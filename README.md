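# vegstab

Vegetation-stability analysis for annual vegetation-index raster time
series. From a per-pixel annual series (e.g. annual-maximum kernel NDVI),
the package computes:

- **Temporal variability (PV)** — the mean relative difference over all
  year pairs, `2/(n(n-1)) * sum_{i<j} |xi-xj|/(xi+xj)`, in [0, 1];
- **Resilience (AR)** — lag-one autocorrelation of the detrended series,
  interpreted under critical-slowing-down theory;
- **Moving-window trends** — Theil–Sen slopes of PV and AR over a 15-year
  moving window, with Mann–Kendall and calibrated permutation significance;
- **Composite destabilization index** — the sum of max-abs-normalized PV and
  AR trends after excluding pixels with opposing trend signs
  (hotspots = both increasing, coldspots = both decreasing);
- **Stability regimes** — quadrant classification by median PV/AR thresholds;
- **Ecosystem states** — a five-class typology (ideal / acceptable / poor /
  abysmal / unknown) coupling the functioning trend with the stability
  composite;
- **Driver attribution** — gradient-boosted regression of the stability
  responses on climatic background and climatic-stability predictors,
  interpreted with exact tree-Shapley values (in-repo engine with a
  numba-compiled fast path), grouped importances and dependence curves;
- **Spatial clustering** — global Moran's I with permutation significance;
- **Synthetic data** — AR(1) raster stacks with controllable persistence,
  relative variability, trends and zones, plus covariate fields with a known
  dominant driver, so every stage has a ground-truth test surface.

Preprocessing helpers cover the kernel NDVI transform `tanh(NDVI^2)`,
annual-maximum compositing, vapor pressure deficit (Tetens, kPa), IDW
station interpolation (power 2, 10 nearest neighbors), nearest-neighbor
resampling and per-pixel linear detrending.

## CLI

```sh
stability simulate  --config cfg.yaml --out outdir     # synthetic stack
stability metrics   --stack stack.tif --out outdir     # PV/AR + regimes
stability trends    --stack stack.tif --out outdir --window 15 --alpha 0.05
stability hotspots  --stack stack.tif --out outdir --window 15
stability states    --stack stack.tif --out outdir --window 15 --alpha 0.05
stability attribute --config cfg.yaml --response darpv
stability run       --config cfg.yaml --seed 1 --out outdir  # full pipeline
stability preprocess kndvi NDVI.tif OUT.tif
stability preprocess vpd T.tif RH.tif OUT.tif
```

A minimal pipeline config:

```yaml
simulate: {n_years: 40, n_rows: 30, n_cols: 30, phi: 0.4, sigma_rel: 0.1}
drivers: {weights: {radiation: 0.8, temperature: 0.2, vpd: 0.1}}
window: 15
alpha: 0.05
seed: 1
outdir: out
```

`stability run` executes input → stability metrics → moving windows →
trend maps → composite index → regimes/states → attribution, writes all
rasters, code tables and a JSON run manifest (config hash, versions,
per-stage pixel counts), and is bit-identical across reruns with the same
config and seed.

## Library notes

Built on numpy/scipy/pandas/scikit-learn; tifffile for raster I/O. The
Mann–Kendall test, Moran's I and the exact tree-Shapley engine are
implemented in-repo and each is validated in the test suite against an
independent brute-force oracle. For moving-window trend significance,
prefer `window_trend_permutation_p` over the Mann–Kendall p of
`trend_map`: adjacent windows share most of their years, which makes the
MK test strongly anti-conservative on window series, while the permutation
test recomputes the whole window chain on year-shuffled series and is
calibrated by construction.
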