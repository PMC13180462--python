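"""Structured-text (YAML) configuration for the simulation grid and DGP."""

from __future__ import annotations

import dataclasses

import yaml

from .dgp import DGPParams, ScenarioSpec
from .engine import GridConfig, scenario_grid
from .errors import ConfigError, ParameterError

_DGP_FIELDS = {f.name for f in dataclasses.fields(DGPParams)}
_GRID_KEYS = {"scenarios", "n_points", "models", "n_reps", "root_seed", "output"}
_SCENARIO_KEYS = {"variance_regime", "trend_regime", "error_regime"}


def _parse_scenarios(raw, problems):
    if raw is None or raw == "default":
        return scenario_grid()
    scenarios = []
    for i, item in enumerate(raw):
        if not isinstance(item, dict) or set(item) - _SCENARIO_KEYS:
            problems.append(f"grid.scenarios[{i}]: expected mapping with keys "
                            f"{sorted(_SCENARIO_KEYS)}")
            continue
        try:
            scenarios.append(ScenarioSpec(**item))
        except ParameterError as err:
            problems.append(f"grid.scenarios[{i}]: {err}")
    return scenarios


def load_config(path) -> tuple[GridConfig, DGPParams]:
    """Parse and validate a config file; an empty file yields full defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    problems = []
    unknown = set(raw) - {"dgp", "grid"}
    if unknown:
        problems.append(f"unknown top-level keys {sorted(unknown)}")

    dgp_raw = raw.get("dgp") or {}
    unknown = set(dgp_raw) - _DGP_FIELDS
    if unknown:
        problems.append(f"unknown dgp keys {sorted(unknown)}")
        dgp_raw = {k: v for k, v in dgp_raw.items() if k in _DGP_FIELDS}
    if "irregular_breaks" in dgp_raw:
        dgp_raw["irregular_breaks"] = tuple(dgp_raw["irregular_breaks"])
    try:
        params = DGPParams(**dgp_raw)
    except ParameterError as err:
        problems.append(f"dgp: {err}")
        params = DGPParams()

    grid_raw = raw.get("grid") or {}
    unknown = set(grid_raw) - _GRID_KEYS
    if unknown:
        problems.append(f"unknown grid keys {sorted(unknown)}")
    kwargs = {}
    if "scenarios" in grid_raw:
        kwargs["scenarios"] = _parse_scenarios(grid_raw["scenarios"], problems)
    if "n_points" in grid_raw:
        kwargs["n_points_list"] = tuple(int(n) for n in grid_raw["n_points"])
    if "models" in grid_raw:
        kwargs["model_labels"] = tuple(grid_raw["models"])
    for key in ("n_reps", "root_seed"):
        if key in grid_raw:
            kwargs[key] = int(grid_raw[key])
    if "output" in grid_raw and grid_raw["output"] is not None:
        kwargs["output"] = str(grid_raw["output"])
    try:
        config = GridConfig(**kwargs)
    except ParameterError as err:
        problems.append(f"grid: {err}")
        config = None

    if problems:
        raise ConfigError(problems)
    return config, params


def dump_config(config: GridConfig, params: DGPParams, path) -> None:
    """Serialise a (grid, dgp) pair; load_config inverts this exactly."""
    doc = {
        "dgp": {f.name: (list(v) if isinstance(v := getattr(params, f.name), tuple) else v)
                for f in dataclasses.fields(DGPParams)},
        "grid": {
            "scenarios": [{"variance_regime": s.variance_regime,
                           "trend_regime": s.trend_regime,
                           "error_regime": s.error_regime}
                          for s in config.scenarios],
            "n_points": list(config.n_points_list),
            "models": list(config.model_labels),
            "n_reps": config.n_reps,
            "root_seed": config.root_seed,
            "output": config.output,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
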