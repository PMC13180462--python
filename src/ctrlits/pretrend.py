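"""Pre-intervention parallel-trend test and its Monte Carlo power."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dgp import DGPParams, ScenarioSpec, PanelData, simulate_panel
from .errors import ParameterError
from .inference import white_vcov

DEFAULT_ALPHA = 0.05


@dataclass
class PretrendResult:
    slope: float
    se: float
    p_value: float
    reject: bool
    alpha: float


def pretrend_test(panel: PanelData, alpha: float = DEFAULT_ALPHA,
                  robust: bool = False) -> PretrendResult:
    """Two-sided t-test of zero slope in pre-period (treated - control) on time."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    pre = panel.post == 0
    if pre.sum() < 3:
        raise ParameterError("need at least 3 pre-intervention points")
    diff = (panel.y_treat - panel.y_ctrl)[pre]
    t = panel.time[pre]
    X = np.column_stack([np.ones(len(t)), t])
    beta, *_ = np.linalg.lstsq(X, diff, rcond=None)
    resid = diff - X @ beta
    dof = len(t) - 2
    if robust:
        se = float(np.sqrt(white_vcov(X, resid).vcov[1, 1]))
    else:
        sigma2 = float(resid @ resid) / dof
        se = float(np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1]))
    slope = float(beta[1])
    if se == 0.0:
        p = 0.0 if slope != 0.0 else 1.0
    else:
        p = float(2.0 * stats.t.sf(abs(slope) / se, dof))
    return PretrendResult(slope=slope, se=se, p_value=p, reject=p < alpha,
                          alpha=alpha)


def pretrend_power(scenario: ScenarioSpec, n_points: int, n_reps: int,
                   alpha: float, seed, params: DGPParams | None = None,
                   robust: bool = False) -> float:
    """Fraction of replicates rejecting the parallel-trend null."""
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    params = (params or DGPParams()).with_n_points(n_points)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(n_reps)
    hits = 0
    for stream in streams:
        panel = simulate_panel(params, scenario, stream)
        if pretrend_test(panel, alpha=alpha, robust=robust).reject:
            hits += 1
    return hits / n_reps


def calibrate_delta(target_power: float = 0.80, n_points: int = 24,
                    n_reps: int = 300, alpha: float = DEFAULT_ALPHA,
                    seed: int = 0, params: DGPParams | None = None,
                    tol: float = 0.01, max_iter: int = 20) -> float:
    """Divergence magnitude giving ~target power at the calibration size.

    Bisection on delta under common random numbers (the same replicate seeds
    at every candidate), exploiting that power is monotone in delta.
    """
    from dataclasses import replace

    params = (params or DGPParams()).with_n_points(n_points)
    scenario = ScenarioSpec("homoscedastic", "unparallel_linear", "iid")

    def power_at(delta: float) -> float:
        p = replace(params, delta=delta)
        return pretrend_power(scenario, n_points, n_reps, alpha, seed, params=p)

    lo, hi = 0.0, 0.02
    while power_at(hi) < target_power:
        hi *= 2.0
        if hi > 100.0:
            raise ParameterError("calibration failed: power never reaches target")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = power_at(mid)
        if abs(p - target_power) <= tol:
            return mid
        if p < target_power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
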