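"""Model-object front end: one fitted object per landscape variable.

:class:`LandscapeVariability` wraps a site-by-time matrix the way a
statistical model wraps its data; ``fit()`` runs the variance decomposition,
the CV indices and the signature in one pass and returns a
:class:`LandscapeVariabilityResults` with a ``summary()`` table.  Passing a
:class:`~varscape.null_model.NullEnvelope` (or ``classify=True``) also
assigns the dynamics region.

This is a convenience layer; every quantity is computed by the
corresponding function in :mod:`~varscape.decomposition`,
:mod:`~varscape.indices`, :mod:`~varscape.signature` and
:mod:`~varscape.null_model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    MissingDataPolicy,
    SiteTimeMatrix,
    apply_missing_policy,
    load_long_table,
    rescale_min_zero,
)
from .decomposition import (
    Convention,
    VarianceComponents,
    reconstruct_var_y,
    variance_components,
)
from .indices import VariabilityIndices, compute_indices
from .null_model import (
    DynamicsRegion,
    Marginal,
    NullEnvelope,
    build_null_envelope,
    classify_region,
)
from .signature import (
    MODE_DESCRIPTIONS,
    ModeThresholds,
    SignatureProportions,
    classify_mode,
    normalize_components,
)

__all__ = ["LandscapeVariability", "LandscapeVariabilityResults", "fit_landscape"]


class LandscapeVariability:
    """Spatiotemporal variability model of one landscape variable.

    Parameters
    ----------
    data : SiteTimeMatrix
        Patch x time measurements of one variable.
    convention : {'sample', 'population'}
        Divisor convention for every variance, SD and CV.
    missing_policy : MissingDataPolicy or str, optional
        Applied to ``data`` before analysis.
    rescale : bool
        Shift the minimum observed value to zero first (for variables that
        can be negative).
    """

    def __init__(
        self,
        data: SiteTimeMatrix,
        convention: Convention = "sample",
        missing_policy: MissingDataPolicy | str | None = None,
        rescale: bool = False,
    ):
        m = data
        if missing_policy is not None:
            m = apply_missing_policy(m, missing_policy)
        if rescale:
            m = rescale_min_zero(m)
        self.data = m
        self.convention: Convention = convention

    @classmethod
    def from_long_dataframe(
        cls, df: pd.DataFrame, variable: str, **kwargs
    ) -> "LandscapeVariability":
        """Build the model for one variable of a long-format table."""
        mats = load_long_table(df)
        if variable not in mats:
            raise KeyError(
                f"variable {variable!r} not in table "
                f"(has: {sorted(mats)[:10]}...)"
            )
        return cls(mats[variable], **kwargs)

    def fit(
        self,
        envelope: NullEnvelope | None = None,
        classify: bool = False,
        null_replicates: int = 200,
        seed: int = 0,
        thresholds: ModeThresholds = ModeThresholds(),
    ) -> "LandscapeVariabilityResults":
        """Run decomposition, indices, signature (and optionally region).

        With ``classify=True`` and no envelope given, a null envelope is
        simulated with a lognormal marginal matched to the variable's
        grand mean and mean spatial CV.
        """
        m = self.data
        components = (
            variance_components(m, self.convention) if m.is_complete else None
        )
        indices = compute_indices(m, self.convention)
        sig = mode = None
        if components is not None:
            try:
                sig = normalize_components(components)
                mode = classify_mode(sig, thresholds)
            except ValueError:
                sig = mode = None
        region = None
        if envelope is None and classify:
            grand_mean = float(m.observed().mean())
            cv = (
                indices.cv_spatial_mean
                if np.isfinite(indices.cv_spatial_mean)
                else 0.3
            )
            envelope = build_null_envelope(
                m.n_patches,
                m.n_times,
                Marginal(mean=max(grand_mean, 1e-9), cv=max(cv, 1e-3)),
                replicates=null_replicates,
                seed=seed,
                convention=self.convention,
            )
        if envelope is not None:
            region = classify_region(indices, envelope)
        return LandscapeVariabilityResults(
            model=self,
            components=components,
            indices=indices,
            signature=sig,
            mode=mode,
            region=region,
            envelope=envelope,
        )


@dataclass
class LandscapeVariabilityResults:
    """Fitted decomposition, indices and classification of one variable."""

    model: LandscapeVariability
    components: VarianceComponents | None
    indices: VariabilityIndices
    signature: SignatureProportions | None
    mode: str | None
    region: DynamicsRegion | None
    envelope: NullEnvelope | None

    @property
    def reconstruction_check(self) -> float | None:
        """Relative error of the closed-form Var(Y) reconstruction
        (population convention only; None otherwise)."""
        if self.components is None or self.components.convention != "population":
            return None
        rec = reconstruct_var_y(self.components)
        if self.components.var_y == 0:
            return abs(rec)
        return abs(rec - self.components.var_y) / self.components.var_y

    def scatter_point(self) -> tuple[float, float]:
        """(log10 mean spatial CV, log10 regional temporal CV) plot-ready."""
        return (
            float(np.log10(self.indices.cv_spatial_mean)),
            float(np.log10(self.indices.cv_y)),
        )

    def to_frame(self) -> pd.DataFrame:
        row = self.indices.as_dict()
        if self.components is not None:
            row.update(
                {
                    k: v
                    for k, v in self.components.as_dict().items()
                    if k not in row
                }
            )
        if self.signature is not None:
            row.update(
                {k: v for k, v in self.signature.as_dict().items() if k not in row}
            )
        row["mode"] = self.mode
        row["region"] = self.region.value if self.region else None
        return pd.DataFrame([row])

    def summary(self) -> str:
        ix, c = self.indices, self.components
        lines = []
        w = 66
        lines.append("Landscape Variability Results".center(w))
        lines.append("=" * w)
        lines.append(
            f"Variable: {ix.variable_id:<30s} convention: {ix.convention}"
        )
        lines.append(
            f"Patches (n_i): {ix.n_i:<6d} Time points (n_k): {ix.n_k}"
        )
        lines.append("-" * w)
        def num(v):
            return "      --" if v is None or not np.isfinite(v) else f"{v:10.4f}"
        lines.append(f"Regional temporal CV (cv_y)      {num(ix.cv_y)}")
        lines.append(
            f"Mean spatial CV                  {num(ix.cv_spatial_mean)}"
            f"   (eligible times: {ix.eligible_times})"
        )
        lines.append(f"Expected CV if independent       {num(ix.expected_cv)}")
        lines.append(f"Synchrony index phi_T            {num(ix.phi_t)}")
        lines.append(f"Persistence index phi_S          {num(ix.phi_s)}")
        if c is not None:
            lines.append("-" * w)
            lines.append(f"Var(Y) regional temporal         {num(c.var_y)}")
            lines.append(f"Var(Z) aggregate spatial         {num(c.var_z)}")
            lines.append(f"Sum of spatial variances         {num(c.sum_spatial_var)}")
            lines.append(f"Synchrony covariance sum         {num(c.synchrony_sum)}")
            lines.append(f"Persistence covariance sum       {num(c.persistence_sum)}")
        if self.signature is not None:
            s = self.signature
            lines.append("-" * w)
            lines.append(
                "Signature (spatial/synchrony/persistence): "
                f"{s.p_spatial:.3f}/{s.p_synchrony:.3f}"
                f"({s.sign_synchrony})/{s.p_persistence:.3f}"
                f"({s.sign_persistence})"
            )
            lines.append(
                f"Dynamics mode: {self.mode} ({MODE_DESCRIPTIONS[self.mode]})"
            )
        if self.region is not None:
            lines.append(f"Dynamics region: {self.region.value}")
        if ix.reasons:
            lines.append("-" * w)
            for k, v in ix.reasons.items():
                lines.append(f"undefined {k}: {v}")
        lines.append("=" * w)
        return "\n".join(lines)


def fit_landscape(
    matrices,
    convention: Convention = "sample",
    envelope: NullEnvelope | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every variable of a landscape; one summary row per variable."""
    if isinstance(matrices, dict):
        matrices = matrices.values()
    frames = []
    for m in matrices:
        res = LandscapeVariability(m, convention=convention).fit(
            envelope=envelope, **fit_kwargs
        )
        frames.append(res.to_frame())
    return pd.concat(frames, ignore_index=True)
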