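"""Restricted cubic spline bases with percentile-based knot placement.

The basis follows the restricted truncated-power construction: for k knots
the regression receives k - 1 columns (the linear term plus k - 2 restricted
cubic terms), and the represented function is linear beyond the boundary
knots with continuous first and second derivatives everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, ParameterError, SelectionError

#: Recommended knot percentiles by knot count (Harrell's tables).
HARRELL_PERCENTILES = {
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
    6: (5.0, 23.0, 41.0, 59.0, 77.0, 95.0),
    7: (2.5, 18.33, 34.17, 50.0, 65.83, 81.67, 97.5),
}


@dataclass(frozen=True)
class SplineSpec:
    knots: tuple

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        if len(knots) < 3:
            raise ParameterError("need at least 3 knots")
        if np.any(np.diff(knots) <= 0):
            raise DegenerateDataError("knots must be strictly increasing")

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def basis_dim(self) -> int:
        return self.n_knots - 1


def harrell_knots(time_values, k: int) -> np.ndarray:
    """Knot positions at the recommended percentiles of the time variable.

    Quantiles use linear interpolation (numpy's default), which matters only
    for very short series; the convention is fixed here for reproducibility.
    """
    if k not in HARRELL_PERCENTILES:
        raise ParameterError(f"k must be one of {sorted(HARRELL_PERCENTILES)}, got {k}")
    t = np.asarray(time_values, dtype=float)
    if len(np.unique(t)) < k:
        raise DegenerateDataError("too few distinct time values for the requested knots")
    knots = np.quantile(t, np.asarray(HARRELL_PERCENTILES[k]) / 100.0, method="linear")
    if np.any(np.diff(knots) <= 0):
        raise DegenerateDataError("degenerate time distribution: duplicate knots")
    return knots


def rcs_basis(time_values, knots) -> np.ndarray:
    """Basis matrix with k - 1 columns: [t, restricted cubic terms].

    Each nonlinear column j (j = 1..k-2) is

        [(t - kn_j)+^3
         - (t - kn_{k-1})+^3 * (kn_k - kn_j) / (kn_k - kn_{k-1})
         + (t - kn_k)+^3 * (kn_{k-1} - kn_j) / (kn_k - kn_{k-1})]
        / (kn_k - kn_1)^2

    which vanishes below the first knot and is exactly linear above the last.
    """
    spec = SplineSpec(tuple(np.asarray(knots, dtype=float)))
    kn = np.asarray(spec.knots, dtype=float)
    t = np.asarray(time_values, dtype=float)
    k = len(kn)
    scale = (kn[-1] - kn[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [t]
    for j in range(k - 2):
        term = (cube(t - kn[j])
                - cube(t - kn[-2]) * (kn[-1] - kn[j]) / (kn[-1] - kn[-2])
                + cube(t - kn[-1]) * (kn[-2] - kn[j]) / (kn[-1] - kn[-2]))
        cols.append(term / scale)
    return np.column_stack(cols)


def _gaussian_ic(y, X, criterion: str) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        rss = np.finfo(float).tiny
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    n_par = X.shape[1] + 1  # regression coefficients + error variance
    if criterion == "aic":
        return 2.0 * n_par - 2.0 * loglik
    if criterion == "bic":
        return np.log(n) * n_par - 2.0 * loglik
    raise ParameterError(f"criterion must be 'aic' or 'bic', got {criterion!r}")


def select_knot_count(y, design_without_spline, time_values,
                      candidates=(3, 4, 5), criterion: str = "aic") -> int:
    """Pick the knot count minimising an information criterion.

    One fit per candidate; ties break toward the smaller (more parsimonious)
    count because candidates are scanned in increasing order.
    """
    if criterion not in ("aic", "bic"):
        raise ParameterError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    y = np.asarray(y, dtype=float)
    base = np.asarray(design_without_spline, dtype=float)
    if base.ndim == 1:
        base = base[:, None]
    best_k, best_ic = None, np.inf
    failures = {}
    for k in sorted(candidates):
        try:
            basis = rcs_basis(time_values, harrell_knots(time_values, k))
            X = np.column_stack([base, basis])
            ic = _gaussian_ic(y, X, criterion)
        except Exception as err:  # noqa: BLE001 - reported in SelectionError
            failures[k] = err
            continue
        if ic < best_ic:
            best_k, best_ic = k, ic
    if best_k is None:
        raise SelectionError(failures)
    return best_k
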