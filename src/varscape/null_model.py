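"""Independent-dynamics null model and region classification.

A variable whose values are uncorrelated between patches and between time
points ("independent dynamics") satisfies, in expectation, the scaling
``cv_y ~ cv_spatial_mean / sqrt(n_i)`` — a line of slope 1 and intercept
``-0.5 * log10(n_i)`` in (log10 mean spatial CV, log10 regional temporal CV)
space.  Simulating matrices of iid cells gives an empirical envelope of
displacements around that line; an observed variable is then classified by
where it falls:

* above the envelope  -> **synchrony** region (inter-patch synchrony boosts
  regional temporal CV),
* below the envelope  -> **persistence** region (spatial gradients retained
  over time depress regional temporal CV),
* inside the envelope -> **independent** region.

The null marginal distribution is configurable (lognormal by default —
positive-valued ecological measurements; gamma and zero-truncated normal are
also provided) and can be matched to a real variable's mean and CV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np
from scipy import stats

from .data_model import SiteTimeMatrix
from .decomposition import Convention
from .indices import VariabilityIndices, compute_indices

__all__ = [
    "Marginal",
    "NullEnvelope",
    "DynamicsRegion",
    "simulate_independent",
    "independent_line",
    "build_null_envelope",
    "classify_region",
]

FAMILIES = ("lognormal", "gamma", "normal_truncated_at_zero")


class DynamicsRegion(str, Enum):
    independent = "independent"
    synchrony = "synchrony"
    persistence = "persistence"


@dataclass(frozen=True)
class Marginal:
    """Cell marginal for null simulations, parameterized by mean and CV.

    For the lognormal and gamma families the requested moments are matched
    exactly; for the zero-truncated normal, mean/CV parameterize the parent
    normal, so realized moments deviate slightly once cv is large enough for
    truncation to bite.
    """

    mean: float = 10.0
    cv: float = 0.3
    family: str = "lognormal"

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("marginal mean must be positive")
        if self.cv < 0:
            raise ValueError("marginal cv must be >= 0")
        if self.family not in FAMILIES:
            raise ValueError(
                f"unsupported marginal family {self.family!r}; "
                f"choose one of {FAMILIES}"
            )

    def sample(self, shape, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.full(shape, self.mean)
        if self.family == "lognormal":
            sigma2 = np.log1p(self.cv**2)
            mu = np.log(self.mean) - sigma2 / 2
            return np.exp(mu + np.sqrt(sigma2) * rng.standard_normal(shape))
        if self.family == "gamma":
            shape_par = 1.0 / self.cv**2
            return rng.gamma(shape_par, self.mean * self.cv**2, shape)
        # zero-truncated normal
        sd = self.mean * self.cv
        a = (0.0 - self.mean) / sd
        return stats.truncnorm.rvs(
            a, np.inf, loc=self.mean, scale=sd, size=shape, random_state=rng
        )


def simulate_independent(
    n_i: int,
    n_k: int,
    marginal: Marginal,
    replicates: int,
    seed: int | np.random.Generator,
) -> list[SiteTimeMatrix]:
    """Simulate matrices of iid cells from ``marginal`` (seeded).

    Synchrony and persistence covariance sums of the result have mean zero
    across replicates by construction.
    """
    rng = np.random.default_rng(seed)
    out = []
    for r in range(replicates):
        out.append(
            SiteTimeMatrix(
                variable_id=f"null_{r:04d}",
                values=marginal.sample((n_i, n_k), rng),
                meta={"family": marginal.family, "mean": marginal.mean,
                      "cv": marginal.cv, "mode": "independent"},
            )
        )
    return out


def independent_line(n_i: int) -> tuple[float, float]:
    """(slope, intercept) of the independent-dynamics line in
    (log10 cv_spatial_mean, log10 cv_y) space: slope 1, intercept
    ``-0.5*log10(n_i)``."""
    if n_i < 1:
        raise ValueError("n_i must be >= 1")
    return 1.0, -0.5 * float(np.log10(n_i))


def displacement(ix: VariabilityIndices) -> float:
    """Vertical log10 distance of a variable from the independent line."""
    if not (np.isfinite(ix.cv_y) and ix.cv_y > 0):
        raise ValueError(
            f"cv_y undefined or non-positive for {ix.variable_id!r}"
            + (f" ({ix.reasons['cv_y']})" if "cv_y" in ix.reasons else "")
        )
    if not (np.isfinite(ix.cv_spatial_mean) and ix.cv_spatial_mean > 0):
        raise ValueError(
            f"cv_spatial_mean undefined or non-positive for {ix.variable_id!r}"
            + (
                f" ({ix.reasons['cv_spatial_mean']})"
                if "cv_spatial_mean" in ix.reasons
                else ""
            )
        )
    _, intercept = independent_line(ix.n_i)
    return float(
        np.log10(ix.cv_y) - (np.log10(ix.cv_spatial_mean) + intercept)
    )


@dataclass
class NullEnvelope:
    """Simulated independent-dynamics band around the analytic null line."""

    n_i: int
    n_k: int
    replicates: int
    marginal: Marginal
    seed: int
    line_slope: float
    line_intercept: float
    band_lower: float
    band_upper: float
    quantiles: tuple[float, float]
    points: np.ndarray = field(repr=False)  # (replicates, 2) log10 cv pairs

    def to_json(self, path=None) -> str:
        d = {
            "n_i": self.n_i, "n_k": self.n_k, "replicates": self.replicates,
            "marginal": asdict(self.marginal), "seed": self.seed,
            "line_slope": self.line_slope, "line_intercept": self.line_intercept,
            "band_lower": self.band_lower, "band_upper": self.band_upper,
            "quantiles": list(self.quantiles),
            "points": self.points.tolist(),
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NullEnvelope":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        d["marginal"] = Marginal(**d["marginal"])
        d["quantiles"] = tuple(d["quantiles"])
        d["points"] = np.asarray(d["points"])
        return cls(**d)


def build_null_envelope(
    n_i: int,
    n_k: int,
    marginal: Marginal = Marginal(),
    replicates: int = 200,
    quantiles: tuple[float, float] = (0.025, 0.975),
    seed: int = 0,
    convention: Convention = "sample",
) -> NullEnvelope:
    """Simulate the null scatter and its displacement band.

    ``replicates`` defaults to 200 for stable quantiles.  The band is the
    (2.5%, 97.5%) quantile pair of null displacements by default, so roughly
    95% of independent variables fall inside it.
    """
    slope, intercept = independent_line(n_i)
    mats = simulate_independent(n_i, n_k, marginal, replicates, seed)
    pts, disps = [], []
    for m in mats:
        ix = compute_indices(m, convention)
        pts.append((np.log10(ix.cv_spatial_mean), np.log10(ix.cv_y)))
        disps.append(displacement(ix))
    lo, hi = np.quantile(disps, quantiles)
    return NullEnvelope(
        n_i=n_i,
        n_k=n_k,
        replicates=replicates,
        marginal=marginal,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        line_slope=slope,
        line_intercept=intercept,
        band_lower=float(lo),
        band_upper=float(hi),
        quantiles=quantiles,
        points=np.asarray(pts),
    )


def classify_region(
    ix: VariabilityIndices, env: NullEnvelope
) -> DynamicsRegion:
    """Assign a variable to the synchrony / independent / persistence region
    by its displacement from the null line.

    Raises ``ValueError`` when the variable's CVs are undefined or
    non-positive (reason code propagated in the message) or when the
    envelope was built for a different number of patches.
    """
    if env.n_i != ix.n_i:
        raise ValueError(
            f"envelope was built for n_i={env.n_i} but variable "
            f"{ix.variable_id!r} has n_i={ix.n_i}"
        )
    d = displacement(ix)
    if d > env.band_upper:
        return DynamicsRegion.synchrony
    if d < env.band_lower:
        return DynamicsRegion.persistence
    return DynamicsRegion.independent
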