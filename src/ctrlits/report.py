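"""Summary tables derived from a grid results CSV."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParameterError

REPORT_METRICS = ("bias", "coverage", "se_ratio")
FACET_KEYS = ["variance_regime", "trend_regime", "error_regime", "n_points"]
ROUND_DECIMALS = 4


@dataclass
class ReportTable:
    """One metric rendered long (tidy) and wide (models as columns)."""

    metric: str
    long: pd.DataFrame

    @property
    def wide(self) -> pd.DataFrame:
        return self.long.pivot_table(index=FACET_KEYS, columns="model",
                                     values=self.metric, sort=True)


def make_report(results: pd.DataFrame) -> dict[str, ReportTable]:
    missing = set(FACET_KEYS + ["model"]) - set(results.columns)
    if missing:
        raise ParameterError(f"results table missing columns {sorted(missing)}")
    tables = {}
    for metric in REPORT_METRICS:
        if metric not in results.columns:
            continue
        long = results[FACET_KEYS + ["model", metric]].copy()
        long[metric] = long[metric].round(ROUND_DECIMALS)
        tables[metric] = ReportTable(metric=metric, long=long)
    return tables


def write_report(results: pd.DataFrame, out_dir) -> list:
    """One wide CSV per metric, mirroring the facet structure of the grid."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for metric, table in make_report(results).items():
        path = out_dir / f"{metric}.csv"
        table.wide.to_csv(path)
        written.append(path)
    return written
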