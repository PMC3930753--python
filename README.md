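# varscape

Variance partitioning of site-by-time landscape data: linking the spatial
and the temporal variability of ecosystem variables.

## The problem

Long ecological time series are rare, but spatial snapshots are cheap.
Space-for-time substitution — inferring how variable a quantity will be over
time from how variable it is across a landscape right now — is widely used
but usually qualitative. `varscape` makes it quantitative for any variable
measured in `n_i` patches (microcosms, rock pools, lakes, ...) at `n_k`
time points.

For a patch-by-time matrix `X` with spatially-aggregated series
`Y_k = Σ_i X_ik` and temporally-aggregated series `Z_i = Σ_k X_ik`, the
regional temporal variance decomposes exactly as

```
Var(Y) = Σ_i var(X_i) + Σ_{i≠j} cov(X_i, X_j)        (inter-patch synchrony)
Var(Z) = Σ_k var(X_k) + Σ_{k≠l} cov(X_k, X_l)        (persistence of spatial gradients)
```

Synchrony (patches rising and falling together) inflates regional temporal
variance; persistence (patch differences retained through time) is the
spatial mirror image and accompanies lower temporal variance. When both
covariance sums vanish — values independent from patch to patch and time to
time — spatial and temporal variance scale by exactly `n_i/n_k`, and on the
CV scale

```
CV_Y ≈ mean spatial CV / sqrt(n_i)
```

so a snapshot of spatial patchiness predicts temporal variability. The
package computes:

* the exact variance components above, under sample or population
  conventions, plus a closed-form reconstruction of `Var(Y)` used as an
  internal consistency check;
* CV-scale indices: regional temporal CV, mean spatial CV, the synchrony
  variance ratio `φ_T = Var(Y)/(Σ_i SD(X_i))²` and its spatial counterpart
  `φ_S = Var(Z)/(Σ_k SD(X_k))²` (both in [0, 1]), and the independence
  approximation above;
* an independent-dynamics null model (iid simulations) giving the null line
  of slope 1 and intercept `−½·log10(n_i)` in log-log CV space, with an
  envelope that classifies each variable into a synchrony / independent /
  persistence region;
* normalized three-part signatures (spatial / synchrony / persistence
  proportions) and the five qualitative dynamics modes they imply
  (destabilized by synchrony, ... , stabilized by compensatory dynamics);
* OLS regressions of log temporal CV on log spatial CV (and on `φ_T`, `φ_S`)
  with standardized betas and Kolmogorov–Smirnov residual checks, plus a
  single-time-point space-for-time prediction;
* seeded synthetic-data generators for all five dynamics modes.

## Worked example

```python
import varscape as vs

m = vs.SiteTimeMatrix("worked", [[1, 2, 3], [2, 4, 6]])  # 2 patches x 3 times
print(vs.LandscapeVariability(m).fit().summary())
```

prints

```
                  Landscape Variability Results
==================================================================
Variable: worked                         convention: sample
Patches (n_i): 2      Time points (n_k): 3
------------------------------------------------------------------
Regional temporal CV (cv_y)          0.5000
Mean spatial CV                      0.4714   (eligible times: 3)
Expected CV if independent           0.3333
Synchrony index phi_T                1.0000
Persistence index phi_S              1.0000
------------------------------------------------------------------
Var(Y) regional temporal             9.0000
Var(Z) aggregate spatial            18.0000
Sum of spatial variances             7.0000
Synchrony covariance sum             4.0000
Persistence covariance sum          11.0000
------------------------------------------------------------------
Signature (spatial/synchrony/persistence): 0.318/0.182(+)/0.500(+)
Dynamics mode: C (stabilized by persistence)
==================================================================
```

Reading it: the two patches are perfectly correlated over time
(`φ_T = 1`) and their 1:2 spatial gradient is retained at every time point
(`φ_S = 1`). The realized regional temporal CV (0.50) exceeds the value
expected if patches fluctuated independently (0.4714/√2 = 0.33) — the
variable sits above the null line, in the synchrony region — while the
decomposition itself is dominated by the persistence term (0.50 of the
summed components).

The same pipeline runs from the shell on long-format CSV
(`variable,site,time,value`):

```bash
varscape simulate specs.yaml --seed 1 -o sim/       # synthetic landscape
varscape compute sim/data.csv -o out/ --classify --seed 2
varscape regress out/indices.csv -o out/report.json --full
```

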