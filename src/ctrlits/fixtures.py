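"""Deterministic test fixtures with analytically known targets."""

from __future__ import annotations

import numpy as np

from .dgp import DGPParams, ScenarioSpec, PanelData, make_errors, simulate_panel
from .errors import ParameterError

FIXTURE_KINDS = ("noiseless_parallel", "noiseless_unparallel", "tiny_2x2",
                 "ar1_long")

_NOISELESS = dict(sigma_base=1e-12, x_mean=0.0, x_sd=0.0)


def make_fixture(kind: str, seed: int = 0):
    """Return (data, expected) for one fixture kind.

    ``data`` is a PanelData for the panel kinds and an error array for
    ``ar1_long``; ``expected`` maps oracle names to their exact or
    asymptotic target values.
    """
    if kind == "tiny_2x2":
        # hand-built 4-point panel: group/period means are
        # treat pre 4, treat post 11, ctrl pre 1.5, ctrl post 4.5
        panel = PanelData(
            time=np.array([1.0, 2.0, 3.0, 4.0]),
            post=np.array([0.0, 0.0, 1.0, 1.0]),
            y_treat=np.array([3.0, 5.0, 10.0, 12.0]),
            y_ctrl=np.array([1.0, 2.0, 4.0, 5.0]),
            x_treat=np.zeros(4), x_ctrl=np.zeros(4), true_tau=4.0)
        # differenced series is (2, 3, 6, 7)
        expected = {"did_of_means": (11.0 - 4.0) - (4.5 - 1.5),
                    "diff_post_minus_pre": (6.0 + 7.0) / 2 - (2.0 + 3.0) / 2}
        return panel, expected

    if kind == "noiseless_parallel":
        params = DGPParams(n_points=24, **_NOISELESS)
        panel = simulate_panel(params, ScenarioSpec(), seed)
        return panel, {"pretrend_slope": 0.0, "did_of_means": params.tau}

    if kind == "noiseless_unparallel":
        params = DGPParams(n_points=24, **_NOISELESS)
        scenario = ScenarioSpec(trend_regime="unparallel_linear")
        panel = simulate_panel(params, scenario, seed)
        slope = params.delta * (params.mu_treat - params.mu_ctrl)
        return panel, {"pretrend_slope": slope}

    if kind == "ar1_long":
        rho, sd, n = 0.7, 0.1, 10_000
        errors = make_errors(n, "ar1", np.full(n, sd), rho, seed)
        return errors, {"lag1_autocorr": rho,
                        "stationary_sd": sd / np.sqrt(1.0 - rho * rho)}

    raise ParameterError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
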