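# ctrlits

Monte Carlo evaluation of the ways a control series can be embedded in an
interrupted-time-series (ITS) segmented regression.

A configurable data-generating process simulates two-group panels (one
intervention, one control series) with a mid-series level-change intervention,
a post-period common confounder, group-specific unobserved levels with
time-varying multipliers (parallel, linearly diverging, or irregularly
diverging trends), and iid or AR(1) errors that may be homoscedastic or
level-dependent heteroscedastic. A suite of segmented-regression estimators
embeds the control in four distinct ways — controlled ITS (CITS) panel,
difference-in-differences (DiD) panel, single ITS of the treated-minus-control
difference, and control-as-covariate — plus an uncontrolled reference, with
linear or restricted-cubic-spline time terms and classical, White,
Driscoll-Kraay, panel-FGLS or AR(1)-ML variance machinery. A simulation
engine scores every (scenario x sample size x model) cell by absolute bias,
the ratio of average model SE to empirical SE, and 95%-CI coverage, and a
pre-trend diagnostic estimates the power to detect non-parallel trends.

## Layout

| module                 | contents                                                         |
|------------------------|------------------------------------------------------------------|
| `ctrlits.dgp`          | `DGPParams`, `ScenarioSpec`, `PanelData`, panel simulation       |
| `ctrlits.splines`      | Harrell-percentile knots, restricted cubic spline basis, AIC/BIC knot-count selection |
| `ctrlits.estimators`   | `ModelSpec`, the `TABLE2_MODELS` grid, design building, fitting  |
| `ctrlits.inference`    | White / Driscoll-Kraay / Newey-West sandwiches, panel FGLS, AR(1) regression |
| `ctrlits.pretrend`     | pre-trend slope test, Monte Carlo power, divergence calibration  |
| `ctrlits.metrics`      | per-cell performance summaries, bias meta-regression             |
| `ctrlits.engine`       | cell/grid orchestration, seeding, stability checks               |
| `ctrlits.config` / `report` / `fixtures` / `cli` | YAML config, summary tables, test fixtures, CLI |

## CLI

```sh
ctrlits dump-config --out config.yaml        # full default configuration
ctrlits simulate --n-points 312 --seed 1 --out panel.csv
ctrlits run --config config.yaml --out results.csv --seed 1
ctrlits report --results results.csv --out-dir report/
ctrlits pretrend-power --n-points 24 --trend-regime unparallel_linear
ctrlits stability --n-points 312 --rep-counts 100,300 --model "DiD FE"
```

`run` executes the full factorial (12 scenarios x 10 sample sizes x 21
models x 300 replicates by default — several hours on one core; trim the
config for smaller runs) and writes one tidy CSV row per cell. Exit codes:
0 success, 1 validation error, 2 runtime failure.

Model labels: `CITS FE T`, `CITS DK T`, `CITS splnT`, `CITS FGLS T`,
`DiD FE`, `DiD FE T`, `DiD DK`, `DiD splnT`, `DiD FGLS T`,
`Diff`, `Diff X`, `Diff T`, `Diff X T`, `Diff splnT`, `Diff X splnT`,
`OLS C`, `OLS C T`, `OLS C splnT`, `OLS`, `OLS T`, `OLS splnT`.

In heteroscedastic scenarios the engine switches models without their own
error correction to White standard errors; in autocorrelated scenarios the
single-series control-as-covariate and uncontrolled models are fitted with an
AR(1) error correction.

## Reproducibility

All randomness flows from numpy `SeedSequence`s: a root seed is combined
with cell coordinates, each replicate gets its own spawned stream shared by
every estimator in the cell (paired comparisons), and per-group sub-streams
make panels bit-reproducible in isolation.
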