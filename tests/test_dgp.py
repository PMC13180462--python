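import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctrlits.dgp import (DGPParams, PanelData, ScenarioSpec, make_errors,
                         make_lambda, sigma_profile, simulate_panel)
from ctrlits.errors import ParameterError, StructuralError

from conftest import NOISELESS


class TestMakeLambda:
    def test_parallel_is_all_ones(self):
        assert np.array_equal(make_lambda("parallel", 6, 0.3), np.ones(6))

    def test_linear_zero_delta_degenerates_to_parallel(self):
        assert np.array_equal(make_lambda("unparallel_linear", 4, 0.0), np.ones(4))

    def test_linear_profile_values(self):
        np.testing.assert_allclose(make_lambda("unparallel_linear", 4, 0.01),
                                   [1.0, 1.01, 1.02, 1.03])

    def test_irregular_alternates_slopes(self):
        lam = make_lambda("unparallel_irregular", 100, 2.0, breaks=(0.2, 0.7, 0.85))
        d = np.diff(lam)
        # strictly rising, then falling, then rising, then falling
        assert d[:19].min() > 0 and d[21:68].max() < 0
        assert d[71:83].min() > 0 and d[86:].max() < 0

    def test_irregular_amplitude_invariant_to_length(self):
        hi = [make_lambda("unparallel_irregular", n, 5.0).max() for n in (24, 312)]
        assert abs(hi[0] - hi[1]) < 0.2

    @pytest.mark.parametrize("n,delta", [(3, 0.1), (-4, 0.1), (10, -0.5)])
    def test_invalid_parameters(self, n, delta):
        with pytest.raises(ParameterError):
            make_lambda("parallel", n, delta)

    def test_unknown_regime(self):
        with pytest.raises(ParameterError):
            make_lambda("wiggly", 10, 0.1)

    @given(n=st.integers(4, 60), delta=st.floats(1e-6, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_strictly_monotone(self, n, delta):
        lam = make_lambda("unparallel_linear", n, delta)
        assert np.all(np.diff(lam) > 0)


class TestSigmaProfile:
    def test_homoscedastic_returns_base(self):
        np.testing.assert_allclose(
            sigma_profile([1.0, -5.0], "homoscedastic", "treat"), [0.1, 0.1])

    def test_hetero_high_and_low_groups(self):
        assert sigma_profile(4.0, "hetero_treat_high", "treat") == pytest.approx(2.0)
        assert sigma_profile(4.0, "hetero_treat_high", "ctrl") == pytest.approx(1.0)
        assert sigma_profile(4.0, "hetero_ctrl_high", "ctrl") == pytest.approx(2.0)
        assert sigma_profile(4.0, "hetero_ctrl_high", "treat") == pytest.approx(1.0)

    def test_zero_level_floored_positive(self):
        sd = sigma_profile(0.0, "hetero_treat_high", "treat")
        assert 0 < sd < 1e-3

    def test_nonfinite_level_rejected(self):
        with pytest.raises(ParameterError):
            sigma_profile(np.inf, "hetero_treat_high", "treat")


class TestMakeErrors:
    N = 10_000

    @staticmethod
    def lag1(e):
        e = e - e.mean()
        return float(e[1:] @ e[:-1] / (e @ e))

    def test_iid_no_autocorrelation(self):
        e = make_errors(self.N, "iid", np.full(self.N, 0.1), 0.0, 11)
        assert abs(self.lag1(e)) < 0.05

    def test_ar1_lag1_near_rho(self):
        e = make_errors(self.N, "ar1", np.full(self.N, 0.1), 0.7, 11)
        assert self.lag1(e) == pytest.approx(0.7, abs=0.03)

    def test_ar1_stationary_sd(self):
        # n = 1e5 so the 2% band is ~5 sigma (sample SD of an AR(1) series
        # has MC noise ~1.2% at n = 1e4)
        n = 100_000
        e = make_errors(n, "ar1", np.full(n, 0.1), 0.7, 11)
        assert e.std() == pytest.approx(0.1 / np.sqrt(1 - 0.49), rel=0.02)

    def test_ar1_initialisation_matches_burn_in(self):
        # exact stationary draw vs a 100-step burn-in: same marginal SD
        rho, sd = 0.7, 0.1
        exact = make_errors(self.N, "ar1", np.full(self.N, sd), rho, 3)
        rng = np.random.default_rng(4)
        z = rng.standard_normal(self.N + 100) * sd
        burn = np.empty(self.N + 100)
        burn[0] = z[0]
        for t in range(1, len(burn)):
            burn[t] = rho * burn[t - 1] + z[t]
        assert exact.std() == pytest.approx(burn[100:].std(), rel=0.05)

    def test_invalid_rho(self):
        with pytest.raises(ParameterError):
            make_errors(10, "ar1", np.full(10, 0.1), 1.0, 0)

    def test_sd_length_mismatch(self):
        with pytest.raises(ParameterError):
            make_errors(10, "iid", np.full(9, 0.1), 0.0, 0)

    def test_nonpositive_sd(self):
        with pytest.raises(ParameterError):
            make_errors(10, "iid", np.zeros(10), 0.0, 0)


class TestDGPParams:
    @pytest.mark.parametrize("kw", [dict(n_points=3), dict(n_points=11),
                                    dict(rho=1.0), dict(rho=-0.1),
                                    dict(sigma_base=0.0), dict(delta=-1.0)])
    def test_invalid(self, kw):
        with pytest.raises(ParameterError):
            DGPParams(**kw)

    def test_intervention_at_midpoint(self):
        assert DGPParams(n_points=312).intervention_index == 157
        assert DGPParams(n_points=24).intervention_index == 13


class TestSimulatePanel:
    def test_did_of_means_recovers_tau(self):
        panel = simulate_panel(DGPParams(n_points=312), ScenarioSpec(), 5)
        pre = panel.post == 0
        did = ((panel.y_treat[~pre].mean() - panel.y_treat[pre].mean())
               - (panel.y_ctrl[~pre].mean() - panel.y_ctrl[pre].mean()))
        assert did == pytest.approx(2.0, abs=0.1)

    def test_noiseless_identity(self):
        p = DGPParams(n_points=24, **NOISELESS)
        panel = simulate_panel(p, ScenarioSpec(), 0)
        np.testing.assert_allclose(
            panel.y_treat, p.beta2 * panel.post + p.tau * panel.post + p.mu_treat,
            atol=1e-9)
        np.testing.assert_allclose(
            panel.y_ctrl, p.beta2 * panel.post + p.mu_ctrl, atol=1e-9)

    def test_uncontrolled_contrast_confounded(self):
        # pre/post contrast on the treated series alone estimates tau + beta2
        panel = simulate_panel(DGPParams(n_points=312), ScenarioSpec(), 5)
        pre = panel.post == 0
        contrast = panel.y_treat[~pre].mean() - panel.y_treat[pre].mean()
        assert contrast == pytest.approx(3.0, abs=0.05)

    def test_parallel_noiseless_difference_flat_with_tau_jump(self, noiseless_panel):
        diff = noiseless_panel.y_treat - noiseless_panel.y_ctrl
        pre = noiseless_panel.post == 0
        assert np.ptp(diff[pre]) < 1e-9 and np.ptp(diff[~pre]) < 1e-9
        assert diff[~pre].mean() - diff[pre].mean() == pytest.approx(2.0, abs=1e-9)

    def test_unparallel_noiseless_pre_difference_linear(self, noiseless_unparallel_panel):
        panel = noiseless_unparallel_panel
        pre = panel.post == 0
        diff = (panel.y_treat - panel.y_ctrl)[pre]
        slopes = np.diff(diff)
        expected = DGPParams().delta * (1.0 - 0.5)  # delta * (mu_treat - mu_ctrl)
        np.testing.assert_allclose(slopes, expected, atol=1e-9)

    def test_hetero_sd_ratio_two(self, rng):
        # level-scaled residual SD of the high-variance group is ~2x the other
        p = DGPParams(n_points=312)
        sc = ScenarioSpec(variance_regime="hetero_treat_high")
        panel = simulate_panel(p, sc, 42)
        scaled = {}
        for g in ("treat", "ctrl"):
            mean = (panel.x(g) * p.beta1 + panel.post * p.beta2
                    + p.tau * (g == "treat") * panel.post
                    + (panel.lam_treat if g == "treat" else panel.lam_ctrl) * p.mu(g))
            scaled[g] = ((panel.y(g) - mean) / np.abs(mean)).std()
        assert scaled["treat"] / scaled["ctrl"] == pytest.approx(2.0, rel=0.25)

    def test_same_seed_byte_stable(self, baseline_params, baseline_scenario):
        a = simulate_panel(baseline_params, baseline_scenario, 9)
        b = simulate_panel(baseline_params, baseline_scenario, 9)
        assert np.array_equal(a.y_treat, b.y_treat)
        assert np.array_equal(a.y_ctrl, b.y_ctrl)
        assert np.array_equal(a.x_treat, b.x_treat)

    def test_different_seed_same_deterministic_components(self, baseline_params,
                                                          baseline_scenario):
        a = simulate_panel(baseline_params, baseline_scenario, 1)
        b = simulate_panel(baseline_params, baseline_scenario, 2)
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.post, b.post)
        assert np.array_equal(a.lam_treat, b.lam_treat)
        assert not np.array_equal(a.y_treat, b.y_treat)

    def test_post_indicator_structure(self, baseline_params, baseline_scenario):
        panel = simulate_panel(baseline_params, baseline_scenario, 0)
        idx = baseline_params.intervention_index
        assert np.all(panel.post[panel.time < idx] == 0)
        assert np.all(panel.post[panel.time >= idx] == 1)

    def test_irregular_affects_control_only(self):
        p = DGPParams(n_points=40)
        sc = ScenarioSpec(trend_regime="unparallel_irregular")
        panel = simulate_panel(p, sc, 0)
        assert np.array_equal(panel.lam_treat, np.ones(40))
        assert np.ptp(panel.lam_ctrl) > 0


class TestPanelIO:
    def test_csv_round_trip(self, tmp_path, baseline_panel):
        path = tmp_path / "panel.csv"
        baseline_panel.to_csv(path)
        back = PanelData.from_csv(path)
        np.testing.assert_array_equal(back.y_treat, baseline_panel.y_treat)
        np.testing.assert_array_equal(back.y_ctrl, baseline_panel.y_ctrl)
        np.testing.assert_array_equal(back.x_ctrl, baseline_panel.x_ctrl)
        np.testing.assert_array_equal(back.post, baseline_panel.post)

    def test_unbalanced_long_frame_rejected(self, baseline_panel):
        frame = baseline_panel.to_long().iloc[:-1]
        with pytest.raises(StructuralError):
            PanelData.from_long(frame)

    def test_missing_columns_rejected(self, baseline_panel):
        frame = baseline_panel.to_long().drop(columns=["x"])
        with pytest.raises(StructuralError):
            PanelData.from_long(frame)
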