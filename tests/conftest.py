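import numpy as np
import pytest

from ctrlits.dgp import DGPParams, ScenarioSpec, simulate_panel

#: Effectively noiseless DGP settings; x is identically zero, so model specs
#: fitted to these panels must use covariate=False to avoid a zero column.
NOISELESS = dict(sigma_base=1e-12, x_mean=0.0, x_sd=0.0)


@pytest.fixture
def baseline_params():
    return DGPParams()


@pytest.fixture
def baseline_scenario():
    return ScenarioSpec()


@pytest.fixture
def noiseless_panel():
    return simulate_panel(DGPParams(n_points=24, **NOISELESS), ScenarioSpec(), 0)


@pytest.fixture
def noiseless_unparallel_panel():
    params = DGPParams(n_points=24, **NOISELESS)
    return simulate_panel(params, ScenarioSpec(trend_regime="unparallel_linear"), 0)


@pytest.fixture
def baseline_panel():
    return simulate_panel(DGPParams(n_points=312), ScenarioSpec(), 7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
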