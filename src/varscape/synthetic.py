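"""Synthetic landscapes with controlled CV, synchrony and persistence.

Generators produce site-by-time matrices realizing the five qualitative
dynamics modes, for power studies, recovery experiments and null scatters:

``independent``
    iid lognormal cells with a given mean and CV.
``synchronized``
    a shared temporal factor enters multiplicatively: on the log scale each
    cell is ``mu + sigma*(sqrt(s)*f_k + sqrt(1-s)*e_ik)`` with ``f_k`` common
    to all patches, so ``s`` in [0, 1] is the share of log-variance that is
    synchronous and the cell marginal keeps the requested CV.
``persistent``
    a fixed multiplicative patch gradient ``exp(g * u_i)`` (``u_i`` evenly
    spaced in [-1, 1]) times iid lognormal temporal noise; ``g >= 0`` is the
    log-scale half-range of the gradient, so patch means span a factor
    ``exp(2g)`` while every value stays positive.
``compensatory``
    each time point redistributes a nearly-fixed regional total across
    patches by Dirichlet weights (anti-correlated patches).  The Dirichlet
    concentration is matched so patch-level CV ~ ``base_cv``, and the total
    itself fluctuates with temporal CV ``0.25 * base_cv / sqrt(n_i)`` — a
    quarter of what independent patches would produce — so regional
    temporal variance is "near zero" but CVs remain defined at any
    landscape size.
``mixed``
    synchronized and persistent combined (gradient times shared factor).

All generators are seeded and return values >= 0, so CVs are directly
computable without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import SiteTimeMatrix
from .decomposition import Convention
from .indices import compute_indices, expected_cv_independent

__all__ = [
    "MODES",
    "ModeSpec",
    "DEFAULT_SYNCHRONY_STRENGTH",
    "DEFAULT_PERSISTENCE_STRENGTH",
    "balanced_gradient",
    "default_spec",
    "generate_variable",
    "generate_landscape_set",
    "independent_scatter_set",
    "scatter_indices",
    "plot_anatomy_fixture",
]

MODES = ("independent", "synchronized", "persistent", "compensatory", "mixed")

#: default share of synchronous log-variance for the synchronized mode
DEFAULT_SYNCHRONY_STRENGTH = 0.8
#: default log-scale half-range of the patch gradient for the persistent mode
DEFAULT_PERSISTENCE_STRENGTH = 1.0


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv**2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def balanced_gradient(base_cv: float, s: float, n_i: int) -> float:
    """Gradient strength making persistence balance synchrony (mixed mode).

    Chooses ``g`` so the log-scale variance of the patch gradient equals the
    log-variance of the shared temporal factor (``sigma**2 * s``); the
    synchrony and persistence covariance sums then contribute equally to the
    variable's signature in the large-landscape limit.
    """
    _, sigma = _lognormal_params(1.0, base_cv)
    u_sd = np.std(np.linspace(-1.0, 1.0, n_i))
    return float(sigma * np.sqrt(s) / u_sd)


@dataclass(frozen=True)
class ModeSpec:
    """Specification of one synthetic variable.

    Strengths must be consistent with the mode: the synchronized mode needs
    ``synchrony_strength`` in (0, 1] and no gradient; the persistent mode a
    positive gradient and no synchrony; mixed needs both; independent and
    compensatory need neither.
    """

    mode: str
    n_i: int = 3
    n_k: int = 20
    base_mean: float = 10.0
    base_cv: float = 0.3
    synchrony_strength: float = 0.0
    persistence_strength: float = 0.0
    seed: int | None = None
    variable_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose one of {MODES}")
        if self.n_i < 2 or self.n_k < 2:
            raise ValueError("n_i and n_k must both be >= 2")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.base_cv < 0:
            raise ValueError("base_cv must be >= 0")
        s, g = self.synchrony_strength, self.persistence_strength
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"synchrony_strength must be in [0, 1], got {s}")
        if g < 0:
            raise ValueError(f"persistence_strength must be >= 0, got {g}")
        need = {
            "independent": (False, False),
            "synchronized": (True, False),
            "persistent": (False, True),
            "compensatory": (False, False),
            "mixed": (True, True),
        }[self.mode]
        if need[0] != (s > 0) or need[1] != (g > 0):
            raise ValueError(
                f"strengths (s={s}, g={g}) inconsistent with mode {self.mode!r}"
            )


def default_spec(mode: str, **kwargs) -> ModeSpec:
    """A :class:`ModeSpec` with the package's default strength for ``mode``."""
    defaults: dict = {}
    if mode == "synchronized":
        defaults["synchrony_strength"] = DEFAULT_SYNCHRONY_STRENGTH
    elif mode == "persistent":
        defaults["persistence_strength"] = DEFAULT_PERSISTENCE_STRENGTH
    elif mode == "mixed":
        s = kwargs.get("synchrony_strength", DEFAULT_SYNCHRONY_STRENGTH)
        defaults["synchrony_strength"] = s
        defaults["persistence_strength"] = balanced_gradient(
            kwargs.get("base_cv", 0.3), s, kwargs.get("n_i", 3)
        )
    defaults.update(kwargs)
    return ModeSpec(mode=mode, **defaults)


def generate_variable(
    spec: ModeSpec, rng: np.random.Generator | None = None
) -> SiteTimeMatrix:
    """Generate one site-by-time matrix realizing ``spec``.

    Reproducible: the same spec (with its seed) yields a bit-identical
    matrix.  All values are >= 0.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_i, n_k = spec.n_i, spec.n_k
    mu, sigma = _lognormal_params(spec.base_mean, spec.base_cv)
    u = np.linspace(-1.0, 1.0, n_i)[:, None]
    s, g = spec.synchrony_strength, spec.persistence_strength

    if spec.mode == "independent":
        X = np.exp(mu + sigma * rng.standard_normal((n_i, n_k)))
    elif spec.mode == "synchronized":
        f = rng.standard_normal(n_k)[None, :]
        e = rng.standard_normal((n_i, n_k))
        X = np.exp(mu + sigma * (np.sqrt(s) * f + np.sqrt(1 - s) * e))
    elif spec.mode == "persistent":
        e = rng.standard_normal((n_i, n_k))
        X = np.exp(mu + g * u + sigma * e)
    elif spec.mode == "mixed":
        f = rng.standard_normal(n_k)[None, :]
        e = rng.standard_normal((n_i, n_k))
        X = np.exp(mu + g * u + sigma * (np.sqrt(s) * f + np.sqrt(1 - s) * e))
    else:  # compensatory
        cv = max(spec.base_cv, 1e-6)
        # Dirichlet concentration with marginal weight CV ~ base_cv
        alpha = max(((n_i - 1) / cv**2 - 1) / n_i, 0.05)
        w = rng.dirichlet(np.full(n_i, alpha), size=n_k).T
        total_cv = 0.25 * cv / np.sqrt(n_i)
        st = np.sqrt(np.log1p(total_cv**2))
        total = n_i * spec.base_mean * np.exp(
            st * rng.standard_normal(n_k) - st**2 / 2
        )
        X = w * total[None, :]

    vid = spec.variable_id or f"{spec.mode}_{spec.seed if spec.seed is not None else 'x'}"
    meta = {"mode": spec.mode, "base_mean": spec.base_mean,
            "base_cv": spec.base_cv, "synchrony_strength": s,
            "persistence_strength": g, "seed": spec.seed}
    meta.update(spec.meta)
    return SiteTimeMatrix(variable_id=vid, values=X, meta=meta)


def generate_landscape_set(
    specs: Sequence[ModeSpec], master_seed: int | None = None
) -> list[SiteTimeMatrix]:
    """One matrix per spec, with independent child seeds.

    Specs without an explicit seed draw child generators from
    ``master_seed`` via ``numpy.random.SeedSequence.spawn``; metadata records
    the true mode of every variable for recovery experiments.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("no mode specs given")
    ids = [
        sp.variable_id or f"{sp.mode}_{j:03d}" for j, sp in enumerate(specs)
    ]
    if len(set(ids)) != len(ids):
        dup = next(v for v in ids if ids.count(v) > 1)
        raise ValueError(f"duplicate variable id {dup!r} in landscape set")
    children = np.random.SeedSequence(master_seed).spawn(len(specs))
    out = []
    for sp, vid, child in zip(specs, ids, children):
        rng = (
            np.random.default_rng(sp.seed)
            if sp.seed is not None
            else np.random.default_rng(child)
        )
        m = generate_variable(
            ModeSpec(**{**sp.__dict__, "variable_id": vid}), rng=rng
        )
        out.append(m)
    return out


def independent_scatter_set(
    n_vars: int = 50,
    cv_range: tuple[float, float] = (0.05, 1.5),
    n_i: int = 7,
    n_k: int = 30,
    replicates_per_point: int = 10,
    base_mean: float = 10.0,
    seed: int = 0,
) -> list[SiteTimeMatrix]:
    """Independent-dynamics variables spanning a CV range (null scatter).

    Marginal CVs are geometrically spaced over ``cv_range`` (uniform on the
    log scale of the plot).  Each variable is represented by
    ``replicates_per_point`` replicate matrices sharing a ``point`` metadata
    key; scatter summaries average indices over the replicates of each
    point, as the plotted points of the null model do.
    """
    rng = np.random.default_rng(seed)
    cvs = np.geomspace(cv_range[0], cv_range[1], n_vars)
    mats = []
    for j, cv in enumerate(cvs):
        mu, sigma = _lognormal_params(base_mean, cv)
        for r in range(replicates_per_point):
            X = np.exp(mu + sigma * rng.standard_normal((n_i, n_k)))
            mats.append(
                SiteTimeMatrix(
                    variable_id=f"indep_{j:03d}_r{r}",
                    values=X,
                    meta={"point": f"indep_{j:03d}", "true_cv": float(cv),
                          "mode": "independent"},
                )
            )
    return mats


def scatter_indices(
    matrices: Iterable[SiteTimeMatrix],
    convention: Convention = "sample",
    group_key: str = "point",
) -> pd.DataFrame:
    """Per-point scatter table: indices averaged over replicate matrices.

    Matrices sharing ``meta[group_key]`` form one plotted point; matrices
    without that key stand alone.  Columns: point, n_i, cv_spatial_mean,
    cv_y, expected_cv, phi_t, phi_s (+ true_cv / mode metadata when present).
    """
    rows = []
    for m in matrices:
        ix = compute_indices(m, convention)
        rows.append(
            {
                "point": m.meta.get(group_key, m.variable_id),
                "n_i": m.n_patches,
                "cv_spatial_mean": ix.cv_spatial_mean,
                "cv_y": ix.cv_y,
                "phi_t": ix.phi_t,
                "phi_s": ix.phi_s,
                "true_cv": m.meta.get("true_cv", np.nan),
                "mode": m.meta.get("mode", ""),
            }
        )
    df = pd.DataFrame(rows)
    agg = df.groupby("point", sort=True).agg(
        n_i=("n_i", "first"),
        cv_spatial_mean=("cv_spatial_mean", "mean"),
        cv_y=("cv_y", "mean"),
        phi_t=("phi_t", "mean"),
        phi_s=("phi_s", "mean"),
        true_cv=("true_cv", "first"),
        mode=("mode", "first"),
        replicates=("cv_y", "size"),
    )
    agg["expected_cv"] = [
        expected_cv_independent(v, n)
        for v, n in zip(agg["cv_spatial_mean"], agg["n_i"])
    ]
    return agg.reset_index()


def plot_anatomy_fixture(
    panel: str, seed: int = 0, n_i: int = 3, n_k: int = 20,
    replicates_per_point: int = 10,
) -> list[SiteTimeMatrix]:
    """Three-patch fixtures reproducing the anatomy of the spatial-vs-
    temporal CV plot, one panel at a time.

    * ``A`` — one wide-CV set per region: independent, uniformly
      synchronized and uniformly persistent variables.
    * ``B`` — variables confined to a narrow CV range, with random small
      amounts of synchrony and persistence: the stochastic displacements
      dominate the tiny CV spread and the log-log association is weak.
    * ``C`` — three wide-range sets (independent / uniformly synchronized /
      uniformly persistent): each is strongly linear, the displaced sets
      shifted up or down as a whole.  "Uniform" persistence means an equal
      log-space displacement for every variable, so the gradient strength
      scales with each variable's noise level.  (Same construction as ``A``
      but with more points per set.)
    * ``D`` — a gradient from synchronized low-CV variables to persistent
      high-CV variables, which skews the fitted slope away from 1.

    Each point is ``replicates_per_point`` replicate matrices (grouped by
    the ``point`` metadata key) whose indices are averaged when plotted.
    """
    panel = panel.upper()
    if panel not in ("A", "B", "C", "D"):
        raise ValueError(f"unknown panel {panel!r}")
    rng = np.random.default_rng(seed)
    mats: list[SiteTimeMatrix] = []

    def add_points(tag, cvs, s_vals, g_vals):
        for j, (cv, s, g) in enumerate(zip(cvs, s_vals, g_vals)):
            mu, sigma = _lognormal_params(10.0, cv)
            u = np.linspace(-1.0, 1.0, n_i)[:, None]
            for r in range(replicates_per_point):
                f = rng.standard_normal(n_k)[None, :]
                e = rng.standard_normal((n_i, n_k))
                X = np.exp(
                    mu + g * u + sigma * (np.sqrt(s) * f + np.sqrt(1 - s) * e)
                )
                mats.append(
                    SiteTimeMatrix(
                        variable_id=f"{tag}_{j:03d}_r{r}",
                        values=X,
                        meta={"point": f"{tag}_{j:03d}", "true_cv": float(cv),
                              "mode": tag},
                    )
                )

    n_pts = 10 if panel in ("A", "B") else 15
    wide = np.geomspace(0.05, 1.5, n_pts)
    zeros = np.zeros(n_pts)
    # gradient strength giving each variable the same log-space displacement
    sigma_of = lambda cv: np.sqrt(np.log1p(np.asarray(cv) ** 2))
    if panel == "B":
        narrow = np.geomspace(0.28, 0.32, n_pts)
        add_points(
            "independent",
            narrow,
            rng.uniform(0.0, 0.4, n_pts),
            rng.uniform(0.0, 2.0, n_pts) * sigma_of(narrow),
        )
    elif panel in ("A", "C"):
        add_points("independent", wide, zeros, zeros)
        add_points("synchronized", wide, np.full(n_pts, 0.6), zeros)
        add_points("persistent", wide, zeros, 2.0 * sigma_of(wide))
    else:  # D
        w = np.linspace(0.0, 1.0, n_pts)
        add_points("gradient", wide, (1 - w) * 0.8, w * 1.0)
    return mats
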