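"""Segmented-regression estimators embedding a control series in four ways.

Five design families are supported, each returning the level-change
intervention coefficient with its standard error and 95% CI:

* ``cits``          -- two-group panel with group fixed effect, common trend
                       and a group x time interaction (differing pre-trends).
* ``did``           -- two-group panel without the group x time interaction.
* ``diff_its``      -- single ITS on the treated-minus-control difference.
* ``control_cov``   -- single ITS on the treated series with the control
                       series as a covariate.
* ``uncontrolled``  -- single ITS on the treated series alone.

The public model vocabulary (``TABLE2_MODELS``) enumerates the evaluated
combinations of design, time term (none / linear / restricted cubic spline)
and variance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .dgp import PanelData
from .errors import ParameterError, StructuralError
from .inference import (arma_ols, driscoll_kraay_vcov, panel_fgls, white_vcov)
from .splines import harrell_knots, rcs_basis, select_knot_count

DESIGNS = ("cits", "did", "diff_its", "control_cov", "uncontrolled")
TIME_TERMS = ("none", "linear", "spline")
SE_METHODS = ("classical", "white", "driscoll_kraay", "fgls", "arma")
PANEL_DESIGNS = ("cits", "did")
SINGLE_SERIES_DESIGNS = ("diff_its", "control_cov", "uncontrolled")


@dataclass(frozen=True)
class ModelSpec:
    label: str
    design: str
    time_term: str = "none"
    diff_covariate: bool = False
    covariate: bool = True
    se_method: str = "classical"
    spline_k: int | None = None
    spline_candidates: tuple = (3, 4, 5)
    #: force a knot at the interruption (off by default: risks building the
    #: hypothesised break into the basis)
    knot_at_break: bool = False

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ParameterError(f"unknown design {self.design!r}")
        if self.time_term not in TIME_TERMS:
            raise ParameterError(f"unknown time term {self.time_term!r}")
        if self.se_method not in SE_METHODS:
            raise ParameterError(f"unknown se method {self.se_method!r}")
        if self.se_method in ("fgls", "driscoll_kraay") and self.design not in PANEL_DESIGNS:
            raise ParameterError(f"{self.se_method} requires a panel design")
        if self.se_method == "arma" and self.design not in SINGLE_SERIES_DESIGNS:
            raise ParameterError("arma correction applies to single-series designs only")
        if self.diff_covariate and self.design != "diff_its":
            raise ParameterError("diff_covariate only applies to the differenced-series design")
        if self.design == "cits" and self.time_term == "none":
            raise ParameterError("cits always carries a time component")

    @property
    def is_panel(self) -> bool:
        return self.design in PANEL_DESIGNS


@dataclass
class FitResult:
    tau_hat: float
    se_tau: float
    ci_low: float
    ci_high: float
    converged: bool
    model_label: str
    n_obs: int
    aux: Mapping = field(default_factory=dict)


def _spec(label, design, **kw):
    return ModelSpec(label=label, design=design, **kw)


#: The evaluated model grid, keyed by its stable public label.
TABLE2_MODELS = {m.label: m for m in [
    _spec("CITS FE T", "cits", time_term="linear"),
    _spec("CITS DK T", "cits", time_term="linear", se_method="driscoll_kraay"),
    _spec("CITS splnT", "cits", time_term="spline"),
    _spec("CITS FGLS T", "cits", time_term="linear", se_method="fgls"),
    _spec("DiD FE", "did", time_term="none"),
    _spec("DiD FE T", "did", time_term="linear"),
    _spec("DiD DK", "did", time_term="none", se_method="driscoll_kraay"),
    _spec("DiD splnT", "did", time_term="spline"),
    _spec("DiD FGLS T", "did", time_term="linear", se_method="fgls"),
    _spec("Diff", "diff_its"),
    _spec("Diff X", "diff_its", diff_covariate=True),
    _spec("Diff T", "diff_its", time_term="linear"),
    _spec("Diff X T", "diff_its", time_term="linear", diff_covariate=True),
    _spec("Diff splnT", "diff_its", time_term="spline"),
    _spec("Diff X splnT", "diff_its", time_term="spline", diff_covariate=True),
    _spec("OLS C", "control_cov"),
    _spec("OLS C T", "control_cov", time_term="linear"),
    _spec("OLS C splnT", "control_cov", time_term="spline"),
    _spec("OLS", "uncontrolled"),
    _spec("OLS T", "uncontrolled", time_term="linear"),
    _spec("OLS splnT", "uncontrolled", time_term="spline"),
]}


def get_model(label: str) -> ModelSpec:
    try:
        return TABLE2_MODELS[label]
    except KeyError:
        raise ParameterError(f"unknown model label {label!r}; "
                             f"known: {sorted(TABLE2_MODELS)}") from None


def difference_series(panel: PanelData):
    """Collapse the panel to the treated-minus-control series.

    Returns (diff, diffx, post, time); the sign convention keeps the fitted
    intervention coefficient on the scale and sign of the true effect.
    """
    diff = panel.y_treat - panel.y_ctrl
    diffx = panel.x_treat - panel.x_ctrl
    return diff, diffx, panel.post.copy(), panel.time.copy()


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    names: list
    tau_idx: int
    time_index: np.ndarray = None   # per-observation period, for DK
    group_index: np.ndarray = None  # per-observation group, for FGLS
    time_values: np.ndarray = None  # time variable used for spline placement


def _time_columns(spec: ModelSpec, tvals: np.ndarray, spline_knots):
    """Columns for the time term; spline replaces the plain linear trend."""
    if spec.time_term == "none":
        return [], []
    if spec.time_term == "linear":
        return [tvals], ["time"]
    basis = rcs_basis(tvals, spline_knots)
    cols = [basis[:, j] for j in range(basis.shape[1])]
    names = ["time"] + [f"spline{j}" for j in range(1, basis.shape[1])]
    return cols, names


def build_design(spec: ModelSpec, panel: PanelData, spline_knots=None,
                 _omit_time: bool = False) -> Design:
    """Response vector, regressor matrix and intervention-column index."""
    n = panel.n_points
    if spec.is_panel:
        time = np.concatenate([panel.time, panel.time])
        post = np.concatenate([panel.post, panel.post])
        d = np.concatenate([np.ones(n), np.zeros(n)])
        x = np.concatenate([panel.x_treat, panel.x_ctrl])
        y = np.concatenate([panel.y_treat, panel.y_ctrl])
        cols = [np.ones(2 * n), d]
        names = ["const", "group"]
        if spec.covariate:
            cols.append(x)
            names.append("x")
        cols += [post, d * post]
        names += ["post", "d_post"]
        if not _omit_time:
            tc, tn = _time_columns(spec, time, spline_knots)
            cols += tc
            names += tn
        if spec.design == "cits":
            cols.append(d * time)
            names.append("d_time")
        design = Design(y=y, X=np.column_stack(cols), names=names,
                        tau_idx=names.index("d_post"),
                        time_index=time, group_index=d, time_values=time)
        return design

    if spec.design == "diff_its":
        diff, diffx, post, time = difference_series(panel)
        cols = [np.ones(n), post]
        names = ["const", "post"]
        if spec.diff_covariate:
            cols.append(diffx)
            names.append("diffx")
        y = diff
    elif spec.design == "control_cov":
        time, post = panel.time, panel.post
        cols = [np.ones(n), panel.y_ctrl]
        names = ["const", "control"]
        if spec.covariate:
            cols.append(panel.x_treat)
            names.append("x")
        cols.append(post)
        names.append("post")
        y = panel.y_treat
    else:  # uncontrolled
        time, post = panel.time, panel.post
        cols = [np.ones(n)]
        names = ["const"]
        if spec.covariate:
            cols.append(panel.x_treat)
            names.append("x")
        cols.append(post)
        names.append("post")
        y = panel.y_treat
    if not _omit_time:
        tc, tn = _time_columns(spec, time, spline_knots)
        cols += tc
        names += tn
    return Design(y=y, X=np.column_stack(cols), names=names,
                  tau_idx=names.index("post"), time_values=time)


def _failed(spec: ModelSpec, n_obs: int, reason: str) -> FitResult:
    return FitResult(np.nan, np.nan, np.nan, np.nan, False, spec.label,
                     n_obs, {"reason": reason})


def _resolve_spline(spec: ModelSpec, panel: PanelData):
    """Knot positions for a spline model, selecting the count by AIC if open."""
    base = build_design(spec, panel, _omit_time=True)
    k = spec.spline_k
    if k is None:
        k = select_knot_count(base.y, base.X, base.time_values,
                              candidates=spec.spline_candidates, criterion="aic")
    knots = harrell_knots(base.time_values, k)
    if spec.knot_at_break:
        break_time = float(panel.intervention_index)
        knots = np.unique(np.append(knots, break_time))
    return knots, k


def fit(spec: ModelSpec, panel: PanelData) -> FitResult:
    """Fit one model formulation and return its intervention estimate."""
    knots = None
    aux = {}
    if spec.time_term == "spline":
        try:
            knots, k = _resolve_spline(spec, panel)
        except Exception as err:  # noqa: BLE001
            return _failed(spec, 0, f"spline selection failed: {err}")
        aux["spline_knots"] = tuple(float(v) for v in knots)
        aux["spline_k"] = k
    design = build_design(spec, panel, spline_knots=knots)
    y, X = design.y, design.X
    n, ncol = X.shape
    if np.linalg.matrix_rank(X) < ncol:
        return _failed(spec, n, "rank-deficient design")
    dof = n - ncol

    if spec.se_method in ("classical", "white", "driscoll_kraay"):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        if spec.se_method == "classical":
            if dof <= 0:
                return _failed(spec, n, "no residual degrees of freedom")
            sigma2 = float(resid @ resid) / dof
            vcov = sigma2 * np.linalg.inv(X.T @ X)
        elif spec.se_method == "white":
            vcov = white_vcov(X, resid).vcov
        else:
            vcov = driscoll_kraay_vcov(X, resid, design.time_index).vcov
        crit = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
        converged = True
        params = beta
    elif spec.se_method == "fgls":
        res = panel_fgls(y, X, design.group_index, design.time_index)
        if not res.converged:
            return _failed(spec, n, "fgls covariance not invertible")
        params, vcov, converged = res.params, res.cov.vcov, True
        aux["rho_hat"] = res.rho_hat
        crit = stats.norm.ppf(0.975)
    elif spec.se_method == "arma":
        try:
            res = arma_ols(X, y, ar_order=1)
        except StructuralError as err:
            return _failed(spec, n, str(err))
        if not res.converged:
            return _failed(spec, n, "arma likelihood did not converge")
        params, vcov, converged = res.params, res.cov.vcov, True
        aux["rho_hat"] = res.rho_hat
        crit = stats.norm.ppf(0.975)
    else:  # pragma: no cover - guarded by ModelSpec validation
        raise ParameterError(spec.se_method)

    tau_hat = float(params[design.tau_idx])
    se_tau = float(np.sqrt(vcov[design.tau_idx, design.tau_idx]))
    aux.update({name: float(b) for name, b in zip(design.names, params)})
    return FitResult(tau_hat=tau_hat, se_tau=se_tau,
                     ci_low=tau_hat - crit * se_tau,
                     ci_high=tau_hat + crit * se_tau,
                     converged=converged, model_label=spec.label,
                     n_obs=n, aux=aux)


def _single_series_fit(y, x, post, time, time_term: str,
                       covariate: bool = True) -> FitResult:
    spec = ModelSpec(label=f"single {time_term}", design="uncontrolled",
                     time_term=time_term, covariate=covariate)
    panel = PanelData(time=time, post=post, y_treat=np.asarray(y, dtype=float),
                      y_ctrl=np.zeros_like(time), x_treat=np.asarray(x, dtype=float),
                      x_ctrl=np.zeros_like(time))
    return fit(spec, panel)


def fit_two_single_its(panel: PanelData, time_term: str = "none",
                       covariate: bool = True) -> FitResult:
    """Separate single-series ITS per group; effect = treated minus control.

    The combined SE assumes independence of the two fits (sqrt of the summed
    variances) with a normal 95% CI; the design is reported for the base case
    only, so this convention is documented rather than tuned.
    """
    res_t = _single_series_fit(panel.y_treat, panel.x_treat, panel.post,
                               panel.time, time_term, covariate)
    res_c = _single_series_fit(panel.y_ctrl, panel.x_ctrl, panel.post,
                               panel.time, time_term, covariate)
    label = "2xITS" + (" T" if time_term == "linear" else
                       " splnT" if time_term == "spline" else "")
    if not (res_t.converged and res_c.converged):
        return FitResult(np.nan, np.nan, np.nan, np.nan, False, label,
                         2 * panel.n_points, {})
    tau_hat = res_t.tau_hat - res_c.tau_hat
    se = float(np.hypot(res_t.se_tau, res_c.se_tau))
    crit = stats.norm.ppf(0.975)
    return FitResult(tau_hat=tau_hat, se_tau=se, ci_low=tau_hat - crit * se,
                     ci_high=tau_hat + crit * se, converged=True,
                     model_label=label, n_obs=2 * panel.n_points,
                     aux={"tau_treat": res_t.tau_hat, "tau_ctrl": res_c.tau_hat})
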