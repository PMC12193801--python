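# morphodyn

Quantification of sessile-cell morphodynamics in 2D+T microscopy movies:
segmentation and seeded-watershed labeling of probability-map movies,
31 human-interpretable size/shape/dynamics quantifiers per cell, and
population-level comparison statistics (permutation Welch tests, an
exact cross-match test for multivariate distributions, and a PCA
morphospace). A synthetic-movie generator makes every stage testable
without microscopy data.

## Modules

| module | contents |
| --- | --- |
| `morphodyn.io_config` | calibrated TIFF/CSV I/O, `Calibration`, `PipelineConfig`, `Movie` |
| `morphodyn.labeling` | Li binarization, binary cleanup, time-integrated seeds, two-pass watershed, file-driven curation |
| `morphodyn.features` | per-frame shape features, fixed/mobile split, protrusion length, Sholl-style protrusiveness, dynamic area change |
| `morphodyn.summaries` | the 31-quantifier summary vector and population matrices |
| `morphodyn.stats` | permutation Welch test, standardized-distance cross-match test with exact null, PCA morphospace, KDE densities |
| `morphodyn.simulate` | ground-truthed synthetic cells, tissue movies and Gaussian feature populations |
| `morphodyn.cli` | the `morphodyn` command-line entry point |

## The 31 quantifiers

For each of the nine per-frame time series — area, perimeter, solidity,
convexity, circularity, aspect ratio, angularity, maximum protrusion
length, protrusiveness — the summary keeps the mean (`*_mean`), the
sample SD normalized by the mean (`*_var`; disable normalization with
`--raw-sd`), and the least-squares slope against time in seconds
(`*_trend`). Four more entries complete the vector: `fixed_area`,
`mobile_area` (temporal mean), `ratio_mobile_fixed`, and
`dac_cumsum_slope` (slope of the cumulative dynamic-area-change sum).
Trends are computed on raw (unnormalized) feature values.

## CLI

Pixel size has no default — it must always be supplied.

```bash
# synthetic data with ground truth
morphodyn simulate --preset tissue --seed 3 --out demo/

# segmentation -> labels
morphodyn segment demo/probability.tif demo/labels.tif \
    --pixel-size-um 0.45 --frame-interval-s 14 [--curation curation.json]

# per-frame feature time series and per-cell summaries
morphodyn features demo/labels.tif demo/timeseries.csv \
    --pixel-size-um 0.45 --frame-interval-s 14
morphodyn summarize demo/timeseries.csv demo/summary.csv --condition ctrl

# population statistics
morphodyn compare A_summary.csv B_summary.csv --test welch --n-perm 10000 --seed 0
morphodyn compare A_summary.csv B_summary.csv --test crossmatch
morphodyn morphospace demo/summary.csv --components 2 --out demo/space/

# or everything at once (resumable; writes a JSON run manifest)
morphodyn run demo/probability.tif --pixel-size-um 0.45 \
    --frame-interval-s 14 --condition ctrl --out demo/run/
```

Curation specs are JSON: `{"merge": [[2, 3]], "exclude": [7]}`.

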