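"""Monte Carlo performance measures over a cell's replicate estimates.

bias is reported in absolute value (signed version kept for diagnostics),
emp_se is the SD of the estimator across replicates, avg_mod_se the plain
mean of the model-reported SEs (deliberately the arithmetic mean, not the
root-mean of variances), and coverage the fraction of 95% CIs containing the
true effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ParameterError


@dataclass
class PerfSummary:
    bias: float
    bias_signed: float
    emp_se: float
    avg_mod_se: float
    se_ratio: float
    coverage: float
    mcse_bias: float
    n_converged: int

    def as_dict(self) -> dict:
        return asdict(self)


def summarise(estimates, ses, ci_pairs, true_tau: float) -> PerfSummary:
    """Performance measures for one (scenario, n, model) cell."""
    est = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    cis = np.asarray(ci_pairs, dtype=float).reshape(-1, 2)
    if not (len(est) == len(ses) == len(cis)):
        raise ParameterError("estimates, ses and ci_pairs must have equal length")
    n = len(est)
    if n == 0:
        raise ParameterError("no converged replicates")
    bias_signed = float(np.mean(est) - true_tau)
    if n >= 2:
        emp_se = float(np.std(est, ddof=1))
        mcse = emp_se / np.sqrt(n)
    else:
        emp_se, mcse = np.nan, np.nan  # flagged: undefined with < 2 replicates
    avg_mod_se = float(np.mean(ses))
    ratio = avg_mod_se / emp_se if emp_se and emp_se > 0 else np.nan
    coverage = float(np.mean((cis[:, 0] <= true_tau) & (true_tau <= cis[:, 1])))
    return PerfSummary(bias=abs(bias_signed), bias_signed=bias_signed,
                       emp_se=emp_se, avg_mod_se=avg_mod_se, se_ratio=ratio,
                       coverage=coverage, mcse_bias=mcse, n_converged=n)


#: Scenario-characteristic regressors used by the bias meta-regression.
BIAS_REGRESSION_FACTORS = ("hetero_treat_high", "hetero_ctrl_high",
                           "unparallel", "ar1", "log_n")


def _factor_frame(table: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=table.index)
    out["const"] = 1.0
    out["hetero_treat_high"] = (table["variance_regime"] == "hetero_treat_high").astype(float)
    out["hetero_ctrl_high"] = (table["variance_regime"] == "hetero_ctrl_high").astype(float)
    out["unparallel"] = table["trend_regime"].str.startswith("unparallel").astype(float)
    out["ar1"] = (table["error_regime"] == "ar1").astype(float)
    out["log_n"] = np.log(table["n_points"].astype(float))
    return out


def bias_regression(cell_table: pd.DataFrame, by: str = "model") -> pd.DataFrame:
    """OLS of per-cell |bias| on scenario-characteristic indicators.

    One regression per value of ``by`` (model label or design family),
    pooling all sample sizes with a log(n) covariate.  Collinear factors
    (single-level in the supplied table) are dropped with a warning.
    """
    required = {"variance_regime", "trend_regime", "error_regime", "n_points",
                "bias", by}
    missing = required - set(cell_table.columns)
    if missing:
        raise ParameterError(f"cell table missing columns {sorted(missing)}")
    rows = []
    for key, sub in cell_table.groupby(by, sort=True):
        X = _factor_frame(sub)
        keep = ["const"]
        for col in X.columns.drop("const"):
            if X[col].nunique() > 1:
                keep.append(col)
            else:
                warnings.warn(f"dropping collinear factor {col!r} for {key!r}",
                              stacklevel=2)
        Xk = X[keep].to_numpy()
        y = sub["bias"].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
        resid = y - Xk @ beta
        dof = len(y) - Xk.shape[1]
        if dof > 0:
            sigma2 = float(resid @ resid) / dof
            se = np.sqrt(np.diag(sigma2 * np.linalg.pinv(Xk.T @ Xk)))
        else:
            se = np.full(len(beta), np.nan)
        for name, b, s in zip(keep, beta, se):
            rows.append({by: key, "term": name, "coef": float(b), "se": float(s)})
    return pd.DataFrame(rows)
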