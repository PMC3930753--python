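"""Spatiotemporal signatures: normalized variance components and dynamics
modes.

The three right-hand components of the regional temporal variance
decomposition — summed spatial variances, the synchrony covariance sum and
the persistence covariance sum — are standardized to proportions summing to
one, giving each variable a three-part "fingerprint" of its landscape
dynamics.  Because the two covariance sums may be negative (compensatory
dynamics), proportions are computed from absolute values and the raw signs
are carried alongside; this keeps every proportion in [0, 1] while
preserving compensation information.  A signed normalization (proportions of
the raw sums) is also available for the all-nonnegative case.

Each signature is then assigned one of five dynamics modes, the qualitative
classes of spatiotemporal behaviour:

====  ====================  ==========================================
mode  synchrony/persistence  interpretation
====  ====================  ==========================================
A     high / low            destabilized by synchrony
B     high / high           stabilized by persistence, destabilized by
                            synchrony
C     low / high            stabilized by persistence
D     low / low, some       stabilized by compensatory dynamics
      negative sign
intersection  ~zero / ~zero stochastic: independent from time to time,
                            site to site (stabilized by asynchrony)
====  ====================  ==========================================

"High" means the (positive-signed) proportion reaches the ``high``
threshold; "~zero" means both covariance proportions fall below the
``near_zero`` threshold.  The thresholds (defaults 0.25 and 0.10) are
package defaults — the underlying graph regions are visual, not numeric —
and are configurable.  A signature that is low/low with nonnegative signs
but not within the near-zero box is assigned to the intersection as the
nearest mode.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decomposition import VarianceComponents

__all__ = [
    "SignatureProportions",
    "ModeThresholds",
    "MODE_DESCRIPTIONS",
    "normalize_components",
    "classify_mode",
]

MODE_DESCRIPTIONS = {
    "A": "destabilized by synchrony",
    "B": "stabilized by persistence and destabilized by synchrony",
    "C": "stabilized by persistence",
    "D": "stabilized by compensatory dynamics",
    "intersection": "stochastic, independent from time to time, site to site",
}


@dataclass(frozen=True)
class SignatureProportions:
    """Normalized variance-component signature of one variable.

    ``p_spatial + p_synchrony + p_persistence == 1`` (to 1e-12); the signs of
    the raw covariance sums are recorded whenever those sums are nonzero
    ('+', '-', or '0').
    """

    variable_id: str
    p_spatial: float
    p_synchrony: float
    p_persistence: float
    sign_synchrony: str
    sign_persistence: str

    def as_dict(self) -> dict:
        return {
            "variable_id": self.variable_id,
            "p_spatial": self.p_spatial,
            "p_synchrony": self.p_synchrony,
            "p_persistence": self.p_persistence,
            "sign_synchrony": self.sign_synchrony,
            "sign_persistence": self.sign_persistence,
        }

    def ternary_coordinates(self) -> tuple[float, float]:
        """Cartesian coordinates for a ternary plot of the three proportions
        (spatial at top, synchrony bottom-left, persistence bottom-right)."""
        x = 0.5 * (2 * self.p_persistence + self.p_spatial)
        y = (3**0.5 / 2) * self.p_spatial
        return x, y


@dataclass(frozen=True)
class ModeThresholds:
    high: float = 0.25
    near_zero: float = 0.10


def _sign(x: float) -> str:
    return "+" if x > 0 else ("-" if x < 0 else "0")


def normalize_components(
    c: VarianceComponents, normalization: str = "absolute"
) -> SignatureProportions:
    """Standardize the three components to proportions summing to one.

    ``normalization='absolute'`` (default) divides each term's absolute
    value by the sum of absolute values; ``'signed'`` divides the raw terms
    by their raw sum and requires all three to be nonnegative.
    """
    terms = (c.sum_spatial_var, c.synchrony_sum, c.persistence_sum)
    if all(t == 0 for t in terms):
        raise ValueError(
            f"no variation: all three components of {c.variable_id!r} are zero"
        )
    if normalization == "absolute":
        total = sum(abs(t) for t in terms)
        props = tuple(abs(t) / total for t in terms)
    elif normalization == "signed":
        if any(t < 0 for t in terms):
            raise ValueError(
                "signed normalization requires nonnegative components; "
                f"got {terms} for {c.variable_id!r}"
            )
        total = sum(terms)
        props = tuple(t / total for t in terms)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return SignatureProportions(
        variable_id=c.variable_id,
        p_spatial=props[0],
        p_synchrony=props[1],
        p_persistence=props[2],
        sign_synchrony=_sign(c.synchrony_sum),
        sign_persistence=_sign(c.persistence_sum),
    )


def classify_mode(
    s: SignatureProportions, thresholds: ModeThresholds = ModeThresholds()
) -> str:
    """Assign one of the five dynamics modes to a signature.

    Synchrony (persistence) counts as "high" when its proportion reaches
    ``thresholds.high`` with positive sign.  When neither is high, a
    negative covariance sum (outside the near-zero box) marks compensatory
    dynamics (D); otherwise the signature sits at the intersection.
    """
    syn_high = s.p_synchrony >= thresholds.high and s.sign_synchrony == "+"
    per_high = s.p_persistence >= thresholds.high and s.sign_persistence == "+"
    if syn_high and per_high:
        return "B"
    if syn_high:
        return "A"
    if per_high:
        return "C"
    if (
        s.p_synchrony < thresholds.near_zero
        and s.p_persistence < thresholds.near_zero
    ):
        return "intersection"
    if s.sign_synchrony == "-" or s.sign_persistence == "-":
        return "D"
    return "intersection"
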