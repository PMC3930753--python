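"""Regressions linking spatial and regional temporal CV across variables.

Two fits are provided, both ordinary least squares on log10-transformed CVs
(CV clouds are fan-shaped on the raw scale and well described by power
functions):

* :func:`fit_loglog` — simple regression of log10 regional temporal CV on
  log10 mean spatial CV, directly comparable to the independent-dynamics
  line (slope 1, intercept ``-0.5*log10(n_i)``).
* :func:`fit_full_model` — multiple regression of log10 temporal CV on
  log10 spatial CV, phi_t and phi_s, with standardized (beta) coefficients;
  ``beta_ratio`` reports how many times more the temporal CV grows with
  spatial CV than with synchrony.

:func:`predict_space_for_time` implements the out-of-sample check of
space-for-time substitution: the spatial CV measured at a single time point
predicts the temporal CV of the remaining series.

Residual normality is assessed with a one-sample Kolmogorov-Smirnov test
against a normal with moments estimated from the residuals (so p-values are
conservative in the Lilliefors sense).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import SiteTimeMatrix
from .decomposition import Convention, ddof_of
from .indices import VariabilityIndices

__all__ = [
    "RegressionResult",
    "fit_loglog",
    "fit_full_model",
    "predict_space_for_time",
    "residual_diagnostics",
]


@dataclass
class RegressionResult:
    """Fit summary for the CV regressions.

    ``betas`` (standardized coefficients, keyed by predictor) and
    ``beta_ratio`` are populated by :func:`fit_full_model` only.
    """

    kind: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float
    n_used: int
    excluded: list[tuple[str, str]]
    params: dict[str, float] = field(default_factory=dict)
    betas: dict[str, float] = field(default_factory=dict)
    beta_ratio: float = np.nan
    ks_p: float = np.nan
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    fitted: np.ndarray = field(default_factory=lambda: np.array([]))
    variable_ids: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "r2": self.r2,
            "n_used": self.n_used,
            "excluded": [list(e) for e in self.excluded],
            "params": self.params,
            "betas": self.betas,
            "beta_ratio": None if np.isnan(self.beta_ratio) else self.beta_ratio,
            "ks_p": None if np.isnan(self.ks_p) else self.ks_p,
        }


def _usable(ix, fields: Sequence[str]) -> tuple[bool, str]:
    for f in fields:
        v = getattr(ix, f)
        if not np.isfinite(v):
            reason = getattr(ix, "reasons", {}).get(f, "undefined")
            return False, f"{f}: {reason}"
        if f in ("cv_y", "cv_spatial_mean") and v <= 0:
            return False, f"{f}: non-positive (log10 undefined)"
    return True, ""


class _Row:
    """Attribute view of a scatter-table row (duck-types VariabilityIndices)."""

    def __init__(self, d: dict):
        self.variable_id = str(
            d.get("variable_id", d.get("point", "variable"))
        )
        self.reasons = {}
        for f in ("cv_y", "cv_spatial_mean", "phi_t", "phi_s"):
            setattr(self, f, float(d.get(f, np.nan)))


def _iter_indices(indices):
    if isinstance(indices, pd.DataFrame):
        return [_Row(rec) for rec in indices.to_dict("records")]
    return list(indices)


def _screen(indices, fields) -> tuple[list, list[tuple[str, str]]]:
    used, excluded = [], []
    for ix in _iter_indices(indices):
        ok, why = _usable(ix, fields)
        if ok:
            used.append(ix)
        else:
            excluded.append((ix.variable_id, why))
    return used, excluded


def fit_loglog(indices: Sequence[VariabilityIndices]) -> RegressionResult:
    """OLS of log10 cv_y on log10 cv_spatial_mean across variables.

    Variables with undefined or non-positive CVs are excluded with reasons.
    Requires at least 3 usable variables.
    """
    used, excluded = _screen(indices, ("cv_y", "cv_spatial_mean"))
    if len(used) < 3:
        raise ValueError(
            f"fit_loglog needs >= 3 usable variables, got {len(used)} "
            f"(excluded: {excluded})"
        )
    x = np.log10([ix.cv_spatial_mean for ix in used])
    y = np.log10([ix.cv_y for ix in used])
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    res = RegressionResult(
        kind="loglog",
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        r2=float(fit.rsquared),
        n_used=len(used),
        excluded=excluded,
        params={"const": float(fit.params[0]),
                "log10_cv_spatial_mean": float(fit.params[1])},
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        variable_ids=[ix.variable_id for ix in used],
    )
    return residual_diagnostics(res)


PREDICTORS = ("log10_cv_spatial_mean", "phi_t", "phi_s")


def fit_full_model(indices: Sequence[VariabilityIndices]) -> RegressionResult:
    """Multiple OLS of log10 cv_y on log10 spatial CV, phi_t and phi_s.

    Standardized betas come from refitting on z-scored predictors and
    response; ``beta_ratio = |beta_spatial| / |beta_synchrony|``.  Exactly
    collinear (or constant) predictors raise, naming the offenders.
    """
    used, excluded = _screen(
        indices, ("cv_y", "cv_spatial_mean", "phi_t", "phi_s")
    )
    if len(used) < 5:
        raise ValueError(
            f"fit_full_model needs >= 5 usable variables, got {len(used)}"
        )
    y = np.log10([ix.cv_y for ix in used])
    cols = {
        "log10_cv_spatial_mean": np.log10([ix.cv_spatial_mean for ix in used]),
        "phi_t": np.array([ix.phi_t for ix in used]),
        "phi_s": np.array([ix.phi_s for ix in used]),
    }
    Xmat = np.column_stack(list(cols.values()))
    sds = Xmat.std(axis=0, ddof=1)
    degenerate = [name for name, sd in zip(cols, sds) if sd < 1e-12]
    if not degenerate:
        rank = np.linalg.matrix_rank(
            np.column_stack([np.ones(len(y)), Xmat]), tol=1e-10
        )
        if rank < Xmat.shape[1] + 1:
            degenerate = list(cols)
    if degenerate:
        raise ValueError(
            "collinear or constant predictors: " + ", ".join(degenerate)
        )
    X = sm.add_constant(Xmat)
    fit = sm.OLS(y, X).fit()
    zX = (Xmat - Xmat.mean(axis=0)) / sds
    zy = (y - y.mean()) / y.std(ddof=1)
    zfit = sm.OLS(zy, zX).fit()
    betas = dict(zip(cols, (float(b) for b in zfit.params)))
    res = RegressionResult(
        kind="full",
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        r2=float(fit.rsquared),
        n_used=len(used),
        excluded=excluded,
        params={"const": float(fit.params[0]),
                **dict(zip(cols, (float(p) for p in fit.params[1:])))},
        betas=betas,
        beta_ratio=abs(betas["log10_cv_spatial_mean"]) / abs(betas["phi_t"])
        if betas["phi_t"] != 0
        else np.inf,
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        variable_ids=[ix.variable_id for ix in used],
    )
    return residual_diagnostics(res)


def predict_space_for_time(
    m: SiteTimeMatrix,
    t_index: int,
    convention: Convention = "sample",
) -> tuple[float, float]:
    """Space-for-time check: spatial CV at one time point vs the temporal CV
    of the remaining series.

    Parameters
    ----------
    t_index : int
        0-based column index of the predictor time point; at least two later
        time points must remain.

    Returns
    -------
    (cv_spatial_at_k, cv_y_remaining)
    """
    if not m.is_complete:
        raise ValueError("predict_space_for_time requires a complete matrix")
    n_k = m.n_times
    if not 0 <= t_index < n_k:
        raise ValueError(f"t_index {t_index} out of range [0, {n_k})")
    if t_index >= n_k - 2:
        raise ValueError(
            f"need >= 2 time points after index {t_index}, only "
            f"{n_k - 1 - t_index} remain"
        )
    ddof = ddof_of(convention)
    col = m.values[:, t_index]
    if col.mean() <= 0:
        raise ValueError(
            f"time point {t_index} ineligible: spatial mean is not positive "
            "(variable absent everywhere)"
        )
    cv_k = float(col.std(ddof=ddof) / col.mean())
    y_rest = m.values[:, t_index + 1 :].sum(axis=0)
    mu = y_rest.mean()
    if mu == 0:
        raise ValueError("remaining aggregate series has zero mean")
    cv_rest = float(y_rest.std(ddof=ddof) / mu)
    return cv_k, cv_rest


def residual_diagnostics(r: RegressionResult, residuals=None) -> RegressionResult:
    """Populate ``ks_p``: one-sample KS test of the residuals against a
    normal with estimated mean and SD."""
    resid = np.asarray(residuals if residuals is not None else r.residuals)
    if resid.size < 3:
        raise ValueError("residual diagnostics need >= 3 residuals")
    sd = resid.std(ddof=1)
    if sd == 0:
        r.ks_p = 1.0
        return r
    r.ks_p = float(stats.kstest(resid, "norm", args=(resid.mean(), sd)).pvalue)
    if residuals is not None:
        r.residuals = resid
    return r


def regression_frame(result: RegressionResult) -> pd.DataFrame:
    """Per-variable fitted values and residuals as a flat table."""
    return pd.DataFrame(
        {
            "variable_id": result.variable_ids,
            "fitted_log10_cv_y": result.fitted,
            "residual": result.residuals,
        }
    )


__all__.append("regression_frame")
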