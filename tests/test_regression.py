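import numpy as np
import pytest

from varscape import (
    SiteTimeMatrix,
    compute_indices,
    fit_full_model,
    fit_loglog,
    predict_space_for_time,
    residual_diagnostics,
)
from varscape.regression import RegressionResult, regression_frame
from varscape.synthetic import default_spec, generate_landscape_set


def _fake_ix(vid, cv_y, cv_sp, phi_t=0.5, phi_s=0.5, n_i=3):
    from varscape.indices import VariabilityIndices

    return VariabilityIndices(
        variable_id=vid, cv_y=cv_y, cv_spatial_mean=cv_sp, eligible_times=10,
        phi_t=phi_t, phi_s=phi_s, expected_cv=cv_sp / np.sqrt(n_i),
        n_i=n_i, n_k=10, convention="sample",
    )


def test_fit_loglog_recovers_exact_line():
    xs = np.array([0.05, 0.1, 0.4, 0.9, 1.5])
    ys = 10 ** (np.log10(xs) - 0.3)  # slope 1, intercept -0.3 exactly
    ixs = [_fake_ix(f"v{i}", y, x) for i, (x, y) in enumerate(zip(xs, ys))]
    r = fit_loglog(ixs)
    assert r.slope == pytest.approx(1.0, abs=1e-10)
    assert r.intercept == pytest.approx(-0.3, abs=1e-10)
    assert r.r2 == pytest.approx(1.0, abs=1e-10)
    assert r.n_used == 5 and not r.excluded


def test_fit_loglog_excludes_undefined_with_reasons():
    ixs = [
        _fake_ix("ok1", 0.2, 0.4),
        _fake_ix("ok2", 0.3, 0.5),
        _fake_ix("ok3", 0.4, 0.7),
        _fake_ix("zero", 0.0, 0.5),
        _fake_ix("nan", np.nan, 0.5),
    ]
    r = fit_loglog(ixs)
    assert r.n_used == 3
    assert sorted(v for v, _ in r.excluded) == ["nan", "zero"]
    assert r.n_used + len(r.excluded) == 5


def test_fit_loglog_needs_three_points():
    with pytest.raises(ValueError, match=">= 3"):
        fit_loglog([_fake_ix("a", 0.1, 0.2), _fake_ix("b", 0.2, 0.3)])


def test_full_model_on_mixed_landscape_explains_cv():
    """Spatial CV, synchrony and persistence jointly predict regional
    temporal CV across a landscape mixing all dynamics modes."""
    specs = []
    rng = np.random.default_rng(0)
    for j in range(20):
        cv = float(rng.uniform(0.1, 1.0))
        specs.append(default_spec("independent", base_cv=cv, n_i=4, n_k=30))
        specs.append(default_spec("synchronized", base_cv=cv, n_i=4, n_k=30))
        specs.append(default_spec("persistent", base_cv=cv, n_i=4, n_k=30))
    mats = generate_landscape_set(specs, master_seed=42)
    ixs = [compute_indices(m) for m in mats]
    r = fit_full_model(ixs)
    assert r.r2 >= 0.8
    assert r.n_used == 60
    assert np.isfinite(r.beta_ratio)


def test_full_model_collinear_predictors_rejected():
    """Indices from matrices identical up to scale are degenerate."""
    base = np.random.default_rng(3).lognormal(1, 0.5, size=(3, 12))
    ixs = [
        compute_indices(SiteTimeMatrix(f"v{i}", base * c))
        for i, c in enumerate([1.0, 2.0, 5.0, 10.0, 20.0])
    ]
    with pytest.raises(ValueError, match="collinear or constant"):
        fit_full_model(ixs)


def test_full_model_independent_set_spatial_beta_dominates():
    from varscape import Marginal, simulate_independent

    ixs = []
    rng = np.random.default_rng(9)
    for j in range(40):
        cv = float(np.geomspace(0.05, 1.2, 40)[j])
        m = simulate_independent(5, 40, Marginal(10, cv), 1, seed=int(rng.integers(2**31)))[0]
        m.variable_id = f"v{j}"
        ixs.append(compute_indices(m))
    r = fit_full_model(ixs)
    assert abs(r.betas["log10_cv_spatial_mean"]) > abs(r.betas["phi_t"])
    assert abs(r.betas["log10_cv_spatial_mean"]) > abs(r.betas["phi_s"])


def test_predict_space_for_time_worked(worked_matrix):
    cv_k, cv_rest = predict_space_for_time(worked_matrix, 0)
    assert cv_k == pytest.approx(0.4714, abs=5e-5)
    # remaining aggregate series [6, 9]: sd/mean = 2.1213/7.5
    assert cv_rest == pytest.approx(0.2828, abs=5e-5)


def test_predict_space_for_time_edge_cases():
    const = SiteTimeMatrix("c", np.full((2, 4), 3.0))
    assert predict_space_for_time(const, 0) == (0.0, 0.0)
    m = SiteTimeMatrix("z", [[0.0, 1.0, 2.0, 1.0], [0.0, 2.0, 1.0, 2.0]])
    with pytest.raises(ValueError, match="ineligible"):
        predict_space_for_time(m, 0)
    with pytest.raises(ValueError, match="remain"):
        predict_space_for_time(const, 3)
    with pytest.raises(ValueError, match="remain"):
        predict_space_for_time(const, 2)


def test_space_for_time_pairs_track_independent_line():
    """Across independent variables, single-time-point spatial CVs predict
    later temporal CVs along a log-log slope near 1."""
    from varscape import Marginal, simulate_independent

    xs, ys = [], []
    for j, cv in enumerate(np.geomspace(0.1, 1.2, 30)):
        reps = simulate_independent(5, 31, Marginal(10, cv), 10, seed=100 + j)
        pairs = [predict_space_for_time(m, 0) for m in reps]
        xs.append(np.mean([p[0] for p in pairs]))
        ys.append(np.mean([p[1] for p in pairs]))
    slope, _ = np.polyfit(np.log10(xs), np.log10(ys), 1)
    assert slope == pytest.approx(1.0, abs=0.15)


def _bare_result(resid):
    return RegressionResult(
        kind="x", slope=0, intercept=0, slope_se=0, intercept_se=0, r2=0,
        n_used=len(resid), excluded=[], residuals=np.asarray(resid),
        fitted=np.zeros(len(resid)),
        variable_ids=[f"v{i}" for i in range(len(resid))],
    )


def test_ks_null_is_roughly_uniform_and_conservative(rng):
    """With moments estimated from the residuals, the KS test rejects a true
    normal at most at (and typically below) its nominal rate."""
    pvals = [
        residual_diagnostics(_bare_result(rng.normal(size=50))).ks_p
        for _ in range(200)
    ]
    assert np.mean(np.array(pvals) < 0.05) <= 0.06


def test_ks_detects_heavy_tails(rng):
    rejected = sum(
        residual_diagnostics(_bare_result(rng.standard_t(1, size=200))).ks_p < 0.05
        for _ in range(20)
    )
    assert rejected >= 15


def test_ks_minimal_n_defined(rng):
    r = residual_diagnostics(_bare_result([0.1, -0.2, 0.05]))
    assert 0.0 <= r.ks_p <= 1.0
    with pytest.raises(ValueError, match=">= 3"):
        residual_diagnostics(_bare_result([0.1, 0.2]))


def test_regression_frame_shape():
    r = _bare_result(np.array([0.1, -0.1, 0.0]))
    df = regression_frame(r)
    assert list(df.columns) == ["variable_id", "fitted_log10_cv_y", "residual"]
    assert len(df) == 3
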