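"""Dimensionless variability indices: CVs and the variance-ratio indices.

These are the relative (CV-scale) counterparts of the variance
decomposition:

* ``cv_y`` — regional temporal CV, SD(Y)/mean(Y) of the spatially-aggregated
  series.
* ``cv_spatial_mean`` — mean over *eligible* time points of the among-patch
  CV at time k (a time point is eligible when its spatial mean is positive;
  a species absent everywhere at time k contributes no spatial CV there).
* ``phi_t`` — synchrony variance ratio, Var(Y) / (sum_i SD(X_i))**2.  Grows
  from ~0 (independent or compensating patches) to 1 (perfectly synchronized
  patches); bounded in [0, 1] by Cauchy-Schwarz.
* ``phi_s`` — persistence variance ratio, Var(Z) / (sum_k SD(X_k))**2, the
  spatial mirror image of ``phi_t``: 1 when the same spatial profile is
  retained at every time point.
* ``expected_cv`` — the independence approximation
  ``cv_spatial_mean / sqrt(n_i)``: the regional temporal CV a variable would
  show if its values were uncorrelated between patches and between times.

Quantities that are undefined for a particular matrix (zero means, no
temporal variation, ...) are carried as NaN together with a machine-readable
reason code, never silently dropped.

With missing cells present (skip policy) the aggregate series Y and Z are
restricted to complete columns / rows respectively, and per-time (per-patch)
statistics use the observed cells; the exact [0, 1] bounds and decomposition
identities are then only approximate.  This is documented behaviour, not an
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import SiteTimeMatrix
from .decomposition import Convention, ddof_of

__all__ = [
    "VariabilityIndices",
    "cv_temporal_regional",
    "cv_spatial_mean",
    "phi_t",
    "phi_s",
    "expected_cv_independent",
    "compute_indices",
    "indices_frame",
]

# reason codes for undefined quantities
R_ZERO_MEAN = "zero-mean"
R_NEGATIVE_MEAN = "negative-mean"
R_ABSENT = "absent at all times"
R_NO_TEMPORAL_VARIATION = "no temporal variation"
R_NO_SPATIAL_VARIATION = "no spatial variation"
R_TOO_FEW_COMPLETE = "fewer than 2 complete rows/columns"


@dataclass
class VariabilityIndices:
    """Per-variable CV-scale indices; NaN fields carry a reason code."""

    variable_id: str
    cv_y: float
    cv_spatial_mean: float
    eligible_times: int
    phi_t: float
    phi_s: float
    expected_cv: float
    n_i: int
    n_k: int
    convention: Convention
    reasons: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "variable_id": self.variable_id,
            "cv_y": self.cv_y,
            "cv_spatial_mean": self.cv_spatial_mean,
            "eligible_times": self.eligible_times,
            "phi_t": self.phi_t,
            "phi_s": self.phi_s,
            "expected_cv": self.expected_cv,
            "n_i": self.n_i,
            "n_k": self.n_k,
            "convention": self.convention,
        }
        d["reasons"] = ";".join(f"{k}={v}" for k, v in self.reasons.items())
        return d


def _aggregate_y(m: SiteTimeMatrix) -> np.ndarray:
    """Spatially-aggregated series over columns with no missing cell."""
    complete_cols = ~m.missing.any(axis=0)
    return m.values[:, complete_cols].sum(axis=0)


def _aggregate_z(m: SiteTimeMatrix) -> np.ndarray:
    complete_rows = ~m.missing.any(axis=1)
    return m.values[complete_rows, :].sum(axis=1)


def cv_temporal_regional(
    m: SiteTimeMatrix, convention: Convention = "sample"
) -> tuple[float, str | None]:
    """Regional temporal CV: SD(Y)/mean(Y).

    Returns ``(value, reason)``; the value is NaN (with a reason code) when
    the mean of Y is zero or negative.  For variables with negative raw
    values, rescale with :func:`~varscape.data_model.rescale_min_zero`
    before computing CVs.
    """
    y = _aggregate_y(m)
    if y.size < 2:
        return np.nan, R_TOO_FEW_COMPLETE
    mu = y.mean()
    if mu == 0:
        return np.nan, R_ZERO_MEAN
    if mu < 0:
        return np.nan, R_NEGATIVE_MEAN
    return float(y.std(ddof=ddof_of(convention)) / mu), None


def cv_spatial_mean(
    m: SiteTimeMatrix,
    convention: Convention = "sample",
    eligibility_tol: float = 0.0,
) -> tuple[float, int, str | None]:
    """Mean over eligible time points of the among-patch CV at time k.

    A time point is eligible when the spatial mean of its observed cells is
    > ``eligibility_tol`` and at least two cells are observed.  Returns
    ``(value, eligible_times, reason)``.
    """
    ddof = ddof_of(convention)
    cvs = []
    for k in range(m.n_times):
        obs = ~m.missing[:, k]
        if obs.sum() < 2:
            continue
        col = m.values[obs, k]
        mu = col.mean()
        if mu <= eligibility_tol:
            continue
        cvs.append(col.std(ddof=ddof) / mu)
    if not cvs:
        return np.nan, 0, R_ABSENT
    return float(np.mean(cvs)), len(cvs), None


def _masked_sd_sum(obs: np.ma.MaskedArray, axis: int, ddof: int) -> float:
    """Sum of SDs along ``axis``, skipping slices with < 2 observed cells."""
    counts = (~np.ma.getmaskarray(obs)).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        sds = obs.std(axis=axis, ddof=ddof)
    return float(np.asarray(sds.filled(0.0))[counts >= 2].sum())


def phi_t(
    m: SiteTimeMatrix, convention: Convention = "sample"
) -> tuple[float, str | None]:
    """Synchrony variance ratio Var(Y) / (sum of patch SDs)**2, in [0, 1]."""
    ddof = ddof_of(convention)
    obs = m.observed()
    sd_sum = _masked_sd_sum(obs, 1, ddof)
    if sd_sum == 0:
        return np.nan, R_NO_TEMPORAL_VARIATION
    y = _aggregate_y(m)
    if y.size < 2:
        return np.nan, R_TOO_FEW_COMPLETE
    val = float(np.var(y, ddof=ddof)) / sd_sum**2
    return float(np.clip(val, 0.0, 1.0)) if m.is_complete else val, None


def phi_s(
    m: SiteTimeMatrix, convention: Convention = "sample"
) -> tuple[float, str | None]:
    """Persistence variance ratio Var(Z) / (sum of per-time spatial SDs)**2."""
    ddof = ddof_of(convention)
    obs = m.observed()
    sd_sum = _masked_sd_sum(obs, 0, ddof)
    if sd_sum == 0:
        return np.nan, R_NO_SPATIAL_VARIATION
    z = _aggregate_z(m)
    if z.size < 2:
        return np.nan, R_TOO_FEW_COMPLETE
    val = float(np.var(z, ddof=ddof)) / sd_sum**2
    return float(np.clip(val, 0.0, 1.0)) if m.is_complete else val, None


def expected_cv_independent(cv_spatial: float, n_i: int) -> float:
    """Independence approximation: expected regional temporal CV is roughly
    the mean spatial CV divided by sqrt(number of patches)."""
    if n_i < 1:
        raise ValueError("n_i must be >= 1")
    return cv_spatial / np.sqrt(n_i)


def compute_indices(
    m: SiteTimeMatrix,
    convention: Convention = "sample",
    eligibility_tol: float = 0.0,
) -> VariabilityIndices:
    """All CV-scale indices of one variable, with reason codes for the
    undefined ones."""
    reasons: dict[str, str] = {}
    cvy, r = cv_temporal_regional(m, convention)
    if r:
        reasons["cv_y"] = r
    cvs, eligible, r = cv_spatial_mean(m, convention, eligibility_tol)
    if r:
        reasons["cv_spatial_mean"] = r
    pt, r = phi_t(m, convention)
    if r:
        reasons["phi_t"] = r
    ps, r = phi_s(m, convention)
    if r:
        reasons["phi_s"] = r
    exp_cv = (
        expected_cv_independent(cvs, m.n_patches) if np.isfinite(cvs) else np.nan
    )
    return VariabilityIndices(
        variable_id=m.variable_id,
        cv_y=cvy,
        cv_spatial_mean=cvs,
        eligible_times=eligible,
        phi_t=pt,
        phi_s=ps,
        expected_cv=exp_cv,
        n_i=m.n_patches,
        n_k=m.n_times,
        convention=convention,
        reasons=reasons,
    )


def indices_frame(indices) -> pd.DataFrame:
    """Tabulate a collection of :class:`VariabilityIndices` (or any objects
    exposing the same attributes) as a DataFrame, one row per variable."""
    return pd.DataFrame([ix.as_dict() for ix in indices])
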