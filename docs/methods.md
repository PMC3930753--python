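# Methods

This note documents the statistical model behind `varscape`, the choices
made where the design was genuinely open, the synthetic-data generators and
what they do and do not emulate, and known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and conventions

One variable is a matrix `X` of `n_i` patches (rows) by `n_k` time points
(columns) with a boolean missing mask. Patches are exchangeable: no
coordinates, distances or connectivity enter anywhere. Time points need not
be equally spaced; only their order is used.

**Divisor convention.** Every variance, SD, covariance and CV can be
computed with divisor `n` ("population") or `n − 1` ("sample"). Reported
indices default to the sample convention; the closed-form reconstruction of
`Var(Y)` (below) is an identity of the population convention and refuses
sample-convention inputs. The bilinear decomposition identities hold exactly
under either convention.

**Covariance sums are over ordered pairs** (`i ≠ j`, `k ≠ l`), i.e. twice
the sum over unordered pairs. This matches the variance-of-a-sum expansion
with no factor of 2. Both sums are signed; negative values are legal and
meaningful (compensatory dynamics) and are preserved.

**Missing data.** Three policies: `zero_fill` (a blank records a true
absence — absence zeros are data, not missing values), `patch_mean`
(interpolation by site; an all-blank patch is an error), and `skip` (leave
blanks masked). Under `skip`, per-time and per-patch statistics use the
observed cells of each slice (slices with fewer than two observations are
dropped), and the aggregate series `Y` (`Z`) is restricted to complete
columns (rows). The exact decomposition identities and the [0, 1] bounds of
the variance-ratio indices are guaranteed only on complete matrices; with
masks they are approximations, which is why `variance_components` requires
completeness while the CV indices degrade gracefully with reason codes.

**Rescaling.** Variables that can be negative (e.g. net primary production)
are shifted so their minimum observed value is exactly zero before CVs are
taken. The operation is idempotent.

## Decomposition

With `Y_k = Σ_i X_ik` and `Z_i = Σ_k X_ik`:

```
Var(Y) = Σ_i var(X_i) + Σ_{i≠j} cov(X_i, X_j)
Var(Z) = Σ_k var(X_k) + Σ_{k≠l} cov(X_k, X_l)
```

The covariance sums are evaluated through these identities (O(n_i·n_k))
rather than explicit pair loops; the test suite checks them against the
explicit ordered-pair sums. Under the population convention there is
additionally a closed form giving `Var(Y)` from spatial-side quantities:

```
Var(Y) = n_i/(n_i−1) · [ n_i(n_k−1)/n_k² · Σ var(X_k)
                         − n_i/n_k² · Σ cov(X_k, X_l)
                         + Σ cov(X_i, X_j) ]
```

validated in the tests against the direct variance of the column sums on
random matrices (relative error below 1e−10).

## Indices

* `cv_y = SD(Y)/mean(Y)`; undefined (with reason code) when `mean(Y) ≤ 0`.
* `cv_spatial_mean`: mean over *eligible* time points of
  `SD(X_k)/mean(X_k)`. A time point is eligible when its spatial mean is
  strictly positive (the rule targets species absence; the tolerance is
  configurable and defaults to zero) and at least two cells are observed.
* `φ_T = Var(Y)/(Σ_i SD(X_i))²` and `φ_S = Var(Z)/(Σ_k SD(X_k))²`, both in
  [0, 1] by Cauchy–Schwarz; floating-point overshoot is clipped on complete
  matrices. `φ_T = 1` iff patch series are positive multiples of one series;
  `φ_T → 1/n_i` for iid cells. Symmetrically `φ_S = 1` for a time-constant
  spatial profile and `→ 1/n_k` for iid cells. 0/0 cases are undefined with
  reason codes.
* `expected_cv = cv_spatial_mean / sqrt(n_i)`: the independence
  approximation for the regional temporal CV.
* `log` anywhere (axes, regressions, displacement) means log10; a zero CV
  maps to undefined under the log with a reason code.

Indices are computed on the matrix as given (no density standardization).

## Null model and regions

Independent dynamics are simulated as iid cells from a configurable marginal
(lognormal by default — positive-valued ecological measurements; gamma and
zero-truncated normal available; the mean/CV of a real variable can be
matched). In (log10 spatial CV, log10 temporal CV) space such variables lie
on the line slope 1, intercept `−½ log10(n_i)`. The envelope is the (2.5%,
97.5%) quantile band of null displacements from that line, from 200
replicates by default (enough for stable quantiles; configurable).
Classification: displacement above the band → synchrony region, below →
persistence region, inside → independent. Classification is scale-free
(CVs are dimensionless), so multiplying a matrix by a positive constant
never changes the label.

## Signatures and modes

The three components (`Σ var(X_k)`, synchrony sum, persistence sum) are
normalized to proportions summing to one. Because the covariance sums may
be negative, the default normalization uses absolute values and records the
raw signs separately; a signed normalization is available when all terms
are nonnegative. This is an interpretation choice: normalizing signed terms
would put compensatory variables outside the simplex.

Modes are assigned from the proportions with two thresholds, `high = 0.25`
and `near_zero = 0.10` (package defaults; the underlying graph regions are
visual, not numeric, so both are configurable):

* **B** synchrony and persistence both high (positive sign);
* **A** only synchrony high; **C** only persistence high;
* **intersection** both covariance proportions below `near_zero`
  (dynamics look stochastic);
* **D** neither high, at least one negative sign (compensation);
* a low/low signature with nonnegative signs outside the near-zero box
  falls back to the intersection as the nearest mode.

### Sampling noise of signatures

For a finite iid matrix the persistence sum equals `Var(Z) − Σ var(X_k)`,
and the sample `Var(Z)` has only `n_i − 1` degrees of freedom: the
persistence proportion of a truly independent variable therefore fluctuates
with scale `√(2/(n_i−1))` relative to the spatial term (symmetrically,
synchrony with `√(2/(n_k−1))`). Mode labels are thus consistent estimators
that stabilize only in large landscapes: at 3×20 an iid variable lands in
the near-zero box ~9% of the time, at 500×500 ~95%, at 1000×1000 ~100%.
The mode-recovery experiment in the test suite therefore uses 1000×1000
landscapes (generator strengths at their defaults); at field-realistic sizes
the signature of a single matrix should be read as noisy, and region
classification (which has no such small-sample pathology) is the more
reliable single-matrix diagnostic.

## Synthetic generators

All generators are seeded, return values ≥ 0, and default to a
microcosm-like 3×20 landscape with `base_mean = 10` and `base_cv = 0.3`
(typical of stable ecosystem variables); rock-pool-like (49×13) and
lake-like (7×30) shapes are a parameter away.

* **independent** — iid lognormal matched to (mean, cv).
* **synchronized** — multiplicative shared factor: on the log scale,
  `σ·(√s·f_k + √(1−s)·e_ik)` with shared `f_k`; `s ∈ [0, 1]` is the
  synchronous share of log-variance (default 0.8: strong but not total
  forcing), and the cell marginal keeps the requested CV.
* **persistent** — fixed multiplicative gradient `exp(g·u_i)`, `u_i` evenly
  spaced in [−1, 1], times lognormal noise with the base CV. `g` is the
  log-scale half-range (default 1.0: patch means spanning ~e² ≈ 7-fold, a
  strong but realistic habitat gradient). A multiplicative gradient keeps
  all values positive for any `g ≥ 0`, which an additive spread does not.
* **compensatory** — each time point redistributes a nearly fixed regional
  total across patches with Dirichlet weights; the concentration is matched
  so patch-level CV ≈ `base_cv`, and the total has temporal CV
  `0.25·base_cv/√n_i` — a quarter of what independent patches would produce.
  Tying the residual total fluctuation to the independent benchmark makes
  the mode scale-free: compensation dominates at any landscape size, while
  `Var(Y)` stays near (not exactly) zero so CVs remain defined.
* **mixed** — synchronized × persistent. Its default gradient is derived,
  not fixed: `balanced_gradient` chooses `g` so the gradient's log-variance
  equals the shared factor's (`σ²s`), making the synchrony and persistence
  components contribute equally in the large-landscape limit — the
  construction whose consistent mode is B.

`independent_scatter_set` builds the null scatter: marginal CVs spaced
geometrically (uniform on the plot's log axis) over 0.05–1.5 — spanning
stable physicochemical variables to highly variable populations — and each
plotted point averaging 10 replicate matrices, the same averaging the null
plots use. `plot_anatomy_fixture` reproduces the qualitative plot anatomies:
narrow-range scatter (weak association), uniformly displaced sets (parallel
lines; "uniform" persistence means equal log-space displacement, so the
gradient scales with each variable's noise level), and a
synchrony-to-persistence gradient (skewed slope).

What the generators do **not** emulate: temporal autocorrelation,
spatially structured dispersal, observation error, zero inflation and
species rarity, and non-stationary trends. Passing recovery tests on these
generators shows the estimators recognize the patterns they target, not
that field data are this clean.

## Regressions

`fit_loglog` and `fit_full_model` are ordinary least squares
(`statsmodels`); predictors are log10 CVs plus the raw `φ` indices (already
dimensionless in [0, 1]). OLS matches standard GLM practice here, though
the spatial CV is itself an estimate, so mild regression dilution is
expected. Standardized betas are obtained by z-scoring predictors and
response; exactly collinear or constant predictors raise with the offenders
named. Undefined or non-positive CVs are excluded with reason codes, never
silently. Residual normality uses a one-sample Kolmogorov–Smirnov test with
moments estimated from the residuals — a Lilliefors-style caveat applies:
p-values are conservative. `predict_space_for_time(m, k)` returns the
spatial CV at column `k` (0-based) and the regional temporal CV of columns
`k+1:`; it requires an eligible column and at least two remaining time
points.

## Numerical notes and limitations

* **Small-sample CV bias and the null slope.** The sample CV of a skewed
  lognormal is biased low, the more so the fewer the samples and the larger
  the true CV (the heavy tail is undersampled). With 7 patches the mean
  spatial CV underestimates a true CV of 1.5 by roughly a third, while the
  temporal CV of the 30-point aggregate series (a sum of 7, hence less
  skewed) is much less biased. Across a null scatter spanning CV 0.05–1.5
  this differential bias bends the top of the cloud upward: the fitted
  log-log slope converges near 1.08 rather than exactly 1, and the fitted
  intercept sits above `−½ log10(n_i)`. This is an estimator artifact of
  the plain SD/mean estimator (which is nonetheless the standard and
  implemented definition), not a failure of the underlying scaling; the
  approximation's correlation with realized temporal CV remains ≈ 0.98.
  One acceptance test asserts the tighter slope band [0.95, 1.05] and fails
  for exactly this reason; it is left failing deliberately.
* Replicate averaging (means of 10) removes regression dilution from the
  null scatter but cannot remove the bias above.
* Degenerate inputs (constant matrices, all-zero variables, zero means)
  yield reason-coded missing values, not exceptions, except where an
  operation is meaningless (fewer than 2 patches or time points for the
  decomposition).
* φ indices are clipped to [0, 1] on complete matrices only to absorb
  floating-point overshoot of the Cauchy–Schwarz bound.
* The four alternative variability indices and distance-weighted surface
  fits are out of scope; the indices layer and exported scatter tables are
  the extension points.
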