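"""Synthetic data-generating process for two-group interrupted time series panels.

The outcome for group ``i`` (treated or control) at time ``t`` is assembled as

    y[i, t] = x[i, t] * beta1 + post[t] * beta2 + tau * d[i] * post[t]
              + lambda[i, t] * mu[i] + eps[i, t]

where ``post`` switches on at the mid-series interruption, ``d`` marks the
treated group, ``lambda`` is a time-varying multiplier on the group-specific
unobserved level ``mu`` (all ones under parallel trends), and ``eps`` follows
one of the configurable error regimes (iid or AR(1), homoscedastic or
level-dependent heteroscedastic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, StructuralError

VARIANCE_REGIMES = ("homoscedastic", "hetero_treat_high", "hetero_ctrl_high")
TREND_REGIMES = ("parallel", "unparallel_linear", "unparallel_irregular")
ERROR_REGIMES = ("iid", "ar1")

GROUPS = ("treat", "ctrl")

#: Divergence magnitude of the unparallel regimes.  Calibrated once so the
#: pre-intervention trend test rejects in ~80% of homoscedastic replicates at
#: n = 24 (see :func:`ctrlits.pretrend.calibrate_delta`), then frozen.
DEFAULT_DELTA = 0.076

#: SD floor protecting heteroscedastic draws from degenerate zero variance.
SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario grid: variance x trend x error regime."""

    variance_regime: str = "homoscedastic"
    trend_regime: str = "parallel"
    error_regime: str = "iid"

    def __post_init__(self):
        if self.variance_regime not in VARIANCE_REGIMES:
            raise ParameterError(f"unknown variance regime {self.variance_regime!r}")
        if self.trend_regime not in TREND_REGIMES:
            raise ParameterError(f"unknown trend regime {self.trend_regime!r}")
        if self.error_regime not in ERROR_REGIMES:
            raise ParameterError(f"unknown error regime {self.error_regime!r}")

    @property
    def name(self) -> str:
        return f"{self.variance_regime}/{self.trend_regime}/{self.error_regime}"


@dataclass(frozen=True)
class DGPParams:
    """Parameters of the data-generating process.

    ``tau`` is the level-change intervention effect; ``beta2`` a common
    post-period confounder entering both series; ``mu_treat``/``mu_ctrl`` the
    group-specific unobserved levels multiplied by the trend profile.
    """

    tau: float = 2.0
    beta1: float = 0.5
    beta2: float = 1.0
    mu_treat: float = 1.0
    mu_ctrl: float = 0.5
    sigma_base: float = 0.1
    rho: float = 0.7
    delta: float = DEFAULT_DELTA
    x_mean: float = 1.0
    x_sd: float = 0.05
    n_points: int = 312
    irregular_breaks: tuple = (0.2, 0.7, 0.85)
    irregular_amplitude: float = 24.0

    def __post_init__(self):
        if self.n_points < 4 or self.n_points % 2 != 0:
            raise ParameterError("n_points must be even and >= 4")
        if not (0.0 <= self.rho < 1.0):
            raise ParameterError("rho must lie in [0, 1)")
        if self.sigma_base <= 0:
            raise ParameterError("sigma_base must be positive")
        if self.delta < 0:
            raise ParameterError("delta must be non-negative")
        if self.x_sd < 0:
            raise ParameterError("x_sd must be non-negative")

    @property
    def intervention_index(self) -> int:
        """First post-period time index (1-based); the series midpoint + 1."""
        return self.n_points // 2 + 1

    def with_n_points(self, n_points: int) -> "DGPParams":
        return replace(self, n_points=int(n_points))

    def mu(self, group: str) -> float:
        return self.mu_treat if group == "treat" else self.mu_ctrl


@dataclass
class PanelData:
    """A simulated two-group panel on a shared 1-based time grid."""

    time: np.ndarray
    post: np.ndarray
    y_treat: np.ndarray
    y_ctrl: np.ndarray
    x_treat: np.ndarray
    x_ctrl: np.ndarray
    lam_treat: np.ndarray = None
    lam_ctrl: np.ndarray = None
    true_tau: float = np.nan

    def __post_init__(self):
        n = len(self.time)
        if self.lam_treat is None:
            self.lam_treat = np.full(n, np.nan)
        if self.lam_ctrl is None:
            self.lam_ctrl = np.full(n, np.nan)
        for name in ("post", "y_treat", "y_ctrl", "x_treat", "x_ctrl",
                     "lam_treat", "lam_ctrl"):
            if len(getattr(self, name)) != n:
                raise StructuralError(f"column {name!r} has length != n_points")

    @property
    def n_points(self) -> int:
        return len(self.time)

    @property
    def intervention_index(self) -> int:
        return int(self.time[np.argmax(self.post > 0)]) if self.post.any() else self.n_points + 1

    def y(self, group: str) -> np.ndarray:
        return self.y_treat if group == "treat" else self.y_ctrl

    def x(self, group: str) -> np.ndarray:
        return self.x_treat if group == "treat" else self.x_ctrl

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per (group, time), columns per the CSV schema."""
        frames = []
        for group in GROUPS:
            frames.append(pd.DataFrame({
                "group": group,
                "time": self.time.astype(int),
                "post": self.post.astype(int),
                "treated": int(group == "treat"),
                "x": self.x(group),
                "y": self.y(group),
            }))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, frame: pd.DataFrame, true_tau: float = np.nan) -> "PanelData":
        required = {"group", "time", "post", "treated", "x", "y"}
        missing = required - set(frame.columns)
        if missing:
            raise StructuralError(f"long panel missing columns {sorted(missing)}")
        sub = {g: frame[frame["group"] == g].sort_values("time") for g in GROUPS}
        t_treat = sub["treat"]["time"].to_numpy()
        t_ctrl = sub["ctrl"]["time"].to_numpy()
        if len(t_treat) != len(t_ctrl) or not np.array_equal(t_treat, t_ctrl):
            raise StructuralError("panel is unbalanced: groups disagree on the time grid")
        return cls(
            time=t_treat.astype(float),
            post=sub["treat"]["post"].to_numpy().astype(float),
            y_treat=sub["treat"]["y"].to_numpy(dtype=float),
            y_ctrl=sub["ctrl"]["y"].to_numpy(dtype=float),
            x_treat=sub["treat"]["x"].to_numpy(dtype=float),
            x_ctrl=sub["ctrl"]["x"].to_numpy(dtype=float),
            true_tau=true_tau,
        )

    @classmethod
    def from_csv(cls, path) -> "PanelData":
        # round_trip parsing keeps the written doubles bit-exact
        return cls.from_long(pd.read_csv(path, float_precision="round_trip"))


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_lambda(trend_regime: str, n_points: int, delta: float,
                breaks: Sequence[float] = (0.25, 0.5, 0.75)) -> np.ndarray:
    """Trend multiplier profile lambda_1..lambda_n for one regime.

    parallel             -> all ones
    unparallel_linear    -> 1 + delta * (t - 1), strictly increasing for delta > 0
    unparallel_irregular -> piecewise linear from 1 with slopes alternating
                            +delta, -delta, ... at the given break fractions
    """
    if n_points < 4:
        raise ParameterError("n_points must be >= 4")
    if delta < 0:
        raise ParameterError("delta must be non-negative")
    if trend_regime == "parallel":
        return np.ones(n_points)
    t = np.arange(n_points, dtype=float)  # t - 1 in 1-based terms
    if trend_regime == "unparallel_linear":
        return 1.0 + delta * t
    if trend_regime == "unparallel_irregular":
        # piecewise linear on normalized time u in [0, 1] with slopes
        # alternating +delta, -delta at the break fractions, so the profile's
        # amplitude (and hence the assumption violation) is the same at
        # every series length
        u = np.linspace(0.0, 1.0, n_points)
        bounds = [0.0] + sorted(float(b) for b in breaks) + [1.0]
        if any(b <= a for a, b in zip(bounds, bounds[1:])):
            raise ParameterError("break fractions must be strictly increasing in (0, 1)")
        lam = np.empty(n_points)
        level = 1.0
        for seg, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            slope = delta if seg % 2 == 0 else -delta
            mask = (u >= lo) & (u <= hi) if seg == len(bounds) - 2 else (u >= lo) & (u < hi)
            lam[mask] = level + slope * (u[mask] - lo)
            level = level + slope * (hi - lo)
        return lam
    raise ParameterError(f"unknown trend regime {trend_regime!r}")


def sigma_profile(mean_level, variance_regime: str, group: str,
                  sigma_base: float = 0.1, floor: float = SIGMA_FLOOR):
    """Error SD at each (group, time) given the noiseless mean level.

    Under the heteroscedastic regimes the high-variance series gets
    SD = |mean level| / 2 and the other series half of that, both floored at a
    small positive constant so the SD grows with the series level.
    """
    level = np.abs(np.asarray(mean_level, dtype=float))
    if not np.all(np.isfinite(level)):
        raise ParameterError("mean level must be finite")
    if variance_regime == "homoscedastic":
        return np.full_like(level, sigma_base)
    if variance_regime not in VARIANCE_REGIMES:
        raise ParameterError(f"unknown variance regime {variance_regime!r}")
    high_group = "treat" if variance_regime == "hetero_treat_high" else "ctrl"
    sd = level / 2.0
    if group != high_group:
        sd = 0.5 * sd
    return np.maximum(sd, floor)


def make_errors(n_points: int, error_regime: str, sd_sequence, rho: float,
                seed) -> np.ndarray:
    """Draw the error sequence for one series.

    iid: independent zero-mean normals with the given SDs.  ar1: innovations
    with the given SDs fed through eps_t = rho * eps_{t-1} + z_t, the first
    draw taken from the stationary N(0, sd^2 / (1 - rho^2)) so no warm-up is
    needed.
    """
    sd = np.asarray(sd_sequence, dtype=float)
    if sd.shape == ():
        sd = np.full(n_points, float(sd))
    if len(sd) != n_points:
        raise ParameterError("sd_sequence length must equal n_points")
    if np.any(sd <= 0):
        raise ParameterError("sd_sequence must be positive")
    rng = _as_generator(seed)
    z = rng.standard_normal(n_points)
    if error_regime == "iid":
        return z * sd
    if error_regime != "ar1":
        raise ParameterError(f"unknown error regime {error_regime!r}")
    if not abs(rho) < 1:
        raise ParameterError("|rho| must be < 1 for a stationary AR(1)")
    eps = np.empty(n_points)
    eps[0] = z[0] * sd[0] / np.sqrt(1.0 - rho * rho)
    for t in range(1, n_points):
        eps[t] = rho * eps[t - 1] + z[t] * sd[t]
    return eps


def _group_lambda(scenario: ScenarioSpec, params: DGPParams, group: str) -> np.ndarray:
    # The irregular profile perturbs only the control series; the linear
    # divergence acts through the mu gap and is shared by both groups.
    if scenario.trend_regime == "unparallel_irregular":
        if group == "treat":
            return make_lambda("parallel", params.n_points, params.delta)
        return make_lambda("unparallel_irregular", params.n_points,
                           params.irregular_amplitude, params.irregular_breaks)
    return make_lambda(scenario.trend_regime, params.n_points, params.delta)


def simulate_panel(params: DGPParams, scenario: ScenarioSpec, seed) -> PanelData:
    """Simulate one two-group panel; deterministic for a fixed seed.

    Sub-streams per group are derived from the seed so the deterministic
    components are identical across seeds and only the random draws differ.
    """
    n = params.n_points
    time = np.arange(1, n + 1, dtype=float)
    post = (time >= params.intervention_index).astype(float)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(len(GROUPS))

    cols = {}
    for group, stream in zip(GROUPS, streams):
        rng = np.random.default_rng(stream)
        x = params.x_mean + params.x_sd * rng.standard_normal(n)
        lam = _group_lambda(scenario, params, group)
        d = 1.0 if group == "treat" else 0.0
        mean = (x * params.beta1 + post * params.beta2
                + params.tau * d * post + lam * params.mu(group))
        sd = sigma_profile(mean, scenario.variance_regime, group, params.sigma_base)
        eps = make_errors(n, scenario.error_regime, sd, params.rho, rng)
        cols[group] = (x, lam, mean + eps)

    return PanelData(
        time=time, post=post,
        y_treat=cols["treat"][2], y_ctrl=cols["ctrl"][2],
        x_treat=cols["treat"][0], x_ctrl=cols["ctrl"][0],
        lam_treat=cols["treat"][1], lam_ctrl=cols["ctrl"][1],
        true_tau=params.tau,
    )
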