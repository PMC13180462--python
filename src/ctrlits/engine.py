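"""Monte Carlo orchestration: scenarios x sample sizes x models x replicates.

Within a cell every model consumes the identical replicate panels (paired
comparison), replicate streams are derived deterministically from the root
seed and the cell coordinates, and cells are therefore independently
reproducible and embarrassingly parallel.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dgp import (DGPParams, ScenarioSpec, simulate_panel,
                  ERROR_REGIMES, TREND_REGIMES, VARIANCE_REGIMES)
from .errors import ParameterError
from .estimators import ModelSpec, TABLE2_MODELS, fit, get_model
from .metrics import summarise

logger = logging.getLogger("ctrlits")

DEFAULT_SIZES = (24, 32, 40, 48, 56, 72, 88, 120, 184, 312)
DEFAULT_N_REPS = 300

CELL_KEY = ["variance_regime", "trend_regime", "error_regime", "n_points", "model"]
RESULT_COLUMNS = CELL_KEY + ["n_reps", "n_converged", "bias", "bias_signed",
                             "emp_se", "avg_mod_se", "se_ratio", "coverage",
                             "mcse_bias"]


def scenario_grid(include_irregular: bool = False) -> list[ScenarioSpec]:
    """The 12-cell factorial (3 variance x 2 trend x 2 error regimes)."""
    trends = ["parallel", "unparallel_linear"]
    if include_irregular:
        trends.append("unparallel_irregular")
    return [ScenarioSpec(v, t, e)
            for v in VARIANCE_REGIMES for t in trends for e in ERROR_REGIMES]


@dataclass
class GridConfig:
    scenarios: list = field(default_factory=scenario_grid)
    n_points_list: tuple = DEFAULT_SIZES
    model_labels: tuple = tuple(TABLE2_MODELS)
    n_reps: int = DEFAULT_N_REPS
    root_seed: int = 0
    output: str | None = None

    def __post_init__(self):
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if any(n < 4 for n in self.n_points_list):
            raise ParameterError("all n_points must be >= 4")
        self.model_labels = tuple(self.model_labels)
        for label in self.model_labels:
            get_model(label)


def adjust_for_scenario(spec: ModelSpec, scenario: ScenarioSpec) -> ModelSpec:
    """Scenario-dependent error corrections applied across the grid.

    Heteroscedastic scenarios switch models without their own error
    adjustment from classical to White SEs; the autocorrelated scenarios fit
    the single-series control-as-covariate and uncontrolled models with an
    AR(1) error correction.
    """
    from dataclasses import replace

    if (scenario.error_regime == "ar1"
            and spec.design in ("control_cov", "uncontrolled")):
        return replace(spec, se_method="arma")
    if (scenario.variance_regime != "homoscedastic"
            and spec.se_method == "classical"):
        return replace(spec, se_method="white")
    return spec


def cell_seed_sequence(root_seed: int, scenario: ScenarioSpec,
                       n_points: int) -> np.random.SeedSequence:
    """Counter-based per-cell seed derivation from the root seed."""
    return np.random.SeedSequence([
        int(root_seed),
        VARIANCE_REGIMES.index(scenario.variance_regime),
        TREND_REGIMES.index(scenario.trend_regime),
        ERROR_REGIMES.index(scenario.error_regime),
        int(n_points),
    ])


def _resolve_models(model_specs) -> list[ModelSpec]:
    out = []
    for m in model_specs:
        out.append(get_model(m) if isinstance(m, str) else m)
    return out


def _pin_spline_counts(specs, params, scenario, pilot_stream):
    from dataclasses import replace

    if not any(s.time_term == "spline" and s.spline_k is None for s in specs):
        return specs
    from .estimators import _resolve_spline

    pilot = simulate_panel(params, scenario, pilot_stream)
    pinned = []
    for spec in specs:
        if spec.time_term == "spline" and spec.spline_k is None:
            try:
                _, k = _resolve_spline(spec, pilot)
                spec = replace(spec, spline_k=k)
            except Exception:  # noqa: BLE001 - fall back to per-fit selection
                logger.warning("pilot knot selection failed for %s", spec.label)
        pinned.append(spec)
    return pinned


def run_cell(scenario: ScenarioSpec, n_points: int, model_specs, n_reps: int,
             params: DGPParams | None = None, seed=0,
             return_estimates: bool = False):
    """Simulate one cell and summarise every model on the shared panels."""
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    params = (params or DGPParams()).with_n_points(n_points)
    specs = [adjust_for_scenario(s, scenario) for s in _resolve_models(model_specs)]
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = cell_seed_sequence(seed, scenario, n_points)
    pilot_stream, *streams = root.spawn(n_reps + 1)

    # Pin each spline model's knot count once per cell from a pilot panel
    # (mirroring a one-off analysis choice); re-selecting the count on every
    # replicate would distort coverage through post-selection inference.
    specs = _pin_spline_counts(specs, params, scenario, pilot_stream)

    store = {s.label: {"est": [], "se": [], "ci": []} for s in specs}
    n_failed = {s.label: 0 for s in specs}
    for stream in streams:
        panel = simulate_panel(params, scenario, stream)
        for spec in specs:
            res = fit(spec, panel)
            if res.converged:
                store[spec.label]["est"].append(res.tau_hat)
                store[spec.label]["se"].append(res.se_tau)
                store[spec.label]["ci"].append((res.ci_low, res.ci_high))
            else:
                n_failed[spec.label] += 1

    rows = []
    for spec in specs:
        rec = store[spec.label]
        row = {"variance_regime": scenario.variance_regime,
               "trend_regime": scenario.trend_regime,
               "error_regime": scenario.error_regime,
               "n_points": n_points, "model": spec.label, "n_reps": n_reps}
        if rec["est"]:
            row.update(summarise(rec["est"], rec["se"], rec["ci"],
                                 params.tau).as_dict())
        else:
            row.update({k: np.nan for k in ("bias", "bias_signed", "emp_se",
                                            "avg_mod_se", "se_ratio",
                                            "coverage", "mcse_bias")})
            row["n_converged"] = 0
        if n_failed[spec.label]:
            logger.warning("cell %s n=%d model %s: %d replicates failed",
                           scenario.name, n_points, spec.label,
                           n_failed[spec.label])
        rows.append(row)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if return_estimates:
        return table, store
    return table


def run_grid(config: GridConfig, params: DGPParams | None = None,
             resume: bool = True) -> pd.DataFrame:
    """Full factorial run; resumable per cell when an output path is set."""
    done = None
    results = []
    if config.output and resume:
        try:
            done = pd.read_csv(config.output)
            results.append(done)
            logger.info("resuming: %d rows already computed", len(done))
        except (FileNotFoundError, pd.errors.EmptyDataError):
            done = None

    for scenario in config.scenarios:
        for n_points in config.n_points_list:
            if done is not None:
                mask = ((done["variance_regime"] == scenario.variance_regime)
                        & (done["trend_regime"] == scenario.trend_regime)
                        & (done["error_regime"] == scenario.error_regime)
                        & (done["n_points"] == n_points))
                if mask.any():
                    continue
            t0 = _time.perf_counter()
            table = run_cell(scenario, n_points, config.model_labels,
                             config.n_reps, params=params,
                             seed=cell_seed_sequence(config.root_seed,
                                                     scenario, n_points))
            logger.info("cell %s n=%d: %.2fs", scenario.name, n_points,
                        _time.perf_counter() - t0)
            results.append(table)
            if config.output:
                pd.concat(results, ignore_index=True).sort_values(
                    CELL_KEY, kind="stable").to_csv(config.output, index=False)
    out = pd.concat(results, ignore_index=True)
    return out.sort_values(CELL_KEY, kind="stable").reset_index(drop=True)


def stability_check(scenario: ScenarioSpec, n_points: int, model_specs,
                    rep_counts, params: DGPParams | None = None,
                    seed=0) -> pd.DataFrame:
    """Bias/coverage on nested replicate subsets; flags unstable cells.

    A cell is flagged when the bias at the smallest requested count differs
    from the bias at the largest by more than twice the latter's MCSE.
    """
    rep_counts = [int(r) for r in rep_counts]
    if (any(b <= a for a, b in zip(rep_counts, rep_counts[1:]))
            or rep_counts[0] < 2):
        raise ParameterError("rep_counts must be strictly increasing and >= 2")
    params = (params or DGPParams()).with_n_points(n_points)
    _, store = run_cell(scenario, n_points, model_specs, rep_counts[-1],
                        params=params, seed=seed, return_estimates=True)
    rows = []
    for label, rec in store.items():
        est = np.asarray(rec["est"])
        ses = np.asarray(rec["se"])
        cis = np.asarray(rec["ci"])
        summaries = {}
        for r in rep_counts:
            m = min(r, len(est))
            summaries[r] = summarise(est[:m], ses[:m], cis[:m], params.tau)
        ref = summaries[rep_counts[-1]]
        for r in rep_counts:
            s = summaries[r]
            threshold = 2.0 * ref.mcse_bias if np.isfinite(ref.mcse_bias) else 0.0
            rows.append({"model": label, "n_reps": r, "bias": s.bias,
                         "bias_signed": s.bias_signed, "coverage": s.coverage,
                         "mcse_bias": s.mcse_bias,
                         "unstable": bool(abs(s.bias - ref.bias) > threshold)})
    return pd.DataFrame(rows)
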