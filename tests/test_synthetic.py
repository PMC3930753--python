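import numpy as np
import pytest

from varscape import (
    ModeSpec,
    SiteTimeMatrix,
    balanced_gradient,
    compute_indices,
    default_spec,
    fit_loglog,
    generate_landscape_set,
    generate_variable,
    independent_scatter_set,
    phi_s,
    phi_t,
    plot_anatomy_fixture,
    scatter_indices,
    variance_components,
)


@pytest.mark.parametrize("mode", ["independent", "synchronized", "persistent",
                                  "compensatory", "mixed"])
def test_generators_seeded_and_nonnegative(mode):
    spec = default_spec(mode, seed=5)
    a = generate_variable(spec)
    b = generate_variable(spec)
    np.testing.assert_array_equal(a.values, b.values)
    assert (a.values >= 0).all()
    assert a.values.shape == (spec.n_i, spec.n_k)
    assert a.meta["mode"] == mode


def test_mode_spec_validation():
    with pytest.raises(ValueError, match="unknown mode"):
        ModeSpec(mode="chaotic")
    with pytest.raises(ValueError, match="inconsistent"):
        ModeSpec(mode="independent", synchrony_strength=0.5)
    with pytest.raises(ValueError, match="inconsistent"):
        ModeSpec(mode="synchronized")  # needs a strength
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        ModeSpec(mode="synchronized", synchrony_strength=1.5)
    with pytest.raises(ValueError, match=">= 0"):
        ModeSpec(mode="persistent", persistence_strength=-1.0)


def test_synchrony_strength_monotone_in_phi_t():
    """Mean synchrony index increases with the shared-factor share."""
    means = []
    for s in (0.1, 0.5, 0.9):
        vals = []
        for r in range(30):
            m = generate_variable(
                ModeSpec("synchronized", n_i=5, n_k=40,
                         synchrony_strength=s, seed=1000 + r)
            )
            vals.append(phi_t(m)[0])
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_persistence_strength_monotone_in_phi_s():
    means = []
    for g in (0.2, 0.8, 2.0):
        vals = []
        for r in range(30):
            m = generate_variable(
                ModeSpec("persistent", n_i=5, n_k=40,
                         persistence_strength=g, seed=2000 + r)
            )
            vals.append(phi_s(m)[0])
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_strongly_synchronized_variables_have_high_phi_t():
    high = [
        phi_t(
            generate_variable(
                ModeSpec("synchronized", synchrony_strength=0.9, seed=3000 + r)
            )
        )[0]
        for r in range(100)
    ]
    assert np.mean(np.array(high) > 0.5) >= 0.95


def test_compensatory_variables_suppress_regional_variance():
    for n_i in (2, 5):
        vals = [
            phi_t(generate_variable(ModeSpec("compensatory", n_i=n_i,
                                             seed=4000 + r)))[0]
            for r in range(50)
        ]
        assert np.mean(vals) < 0.1
        # regional temporal CV far below what independent patches would give
        m = generate_variable(ModeSpec("compensatory", n_i=n_i, seed=1))
        ix = compute_indices(m)
        assert ix.cv_y < ix.expected_cv


def test_independent_mode_iid_limits():
    pt = [
        phi_t(generate_variable(ModeSpec("independent", n_i=5, n_k=100,
                                         seed=5000 + r)))[0]
        for r in range(100)
    ]
    ps = [
        phi_s(generate_variable(ModeSpec("independent", n_i=100, n_k=5,
                                         seed=6000 + r)))[0]
        for r in range(100)
    ]
    assert np.mean(pt) == pytest.approx(1 / 5, abs=0.03)
    assert np.mean(ps) == pytest.approx(1 / 5, abs=0.03)


def test_balanced_gradient_balances_covariance_sums():
    """At the balanced gradient, synchrony and persistence contribute
    comparably to the mixed mode's signature in a large landscape."""
    s = 0.8
    g = balanced_gradient(0.3, s, 200)
    m = generate_variable(
        ModeSpec("mixed", n_i=200, n_k=200, synchrony_strength=s,
                 persistence_strength=g, seed=11)
    )
    c = variance_components(m)
    ratio = c.synchrony_sum / c.persistence_sum
    assert 1 / 3 < ratio < 3


def test_landscape_set_seed_derivation_and_errors():
    specs = [default_spec("independent"), default_spec("synchronized")]
    a = generate_landscape_set(specs, master_seed=7)
    b = generate_landscape_set(specs, master_seed=7)
    for m1, m2 in zip(a, b):
        np.testing.assert_array_equal(m1.values, m2.values)
    c = generate_landscape_set(specs, master_seed=8)
    assert not np.array_equal(a[0].values, c[0].values)
    with pytest.raises(ValueError, match="no mode specs"):
        generate_landscape_set([])
    with pytest.raises(ValueError, match="duplicate variable id"):
        generate_landscape_set(
            [default_spec("independent", variable_id="x"),
             default_spec("persistent", variable_id="x")]
        )
    assert {m.meta["mode"] for m in a} == {"independent", "synchronized"}


def test_independent_scatter_set_grouping():
    mats = independent_scatter_set(n_vars=5, replicates_per_point=4, seed=1)
    assert len(mats) == 20
    df = scatter_indices(mats)
    assert len(df) == 5
    assert (df["replicates"] == 4).all()
    assert df["cv_spatial_mean"].is_monotonic_increasing or (
        df["true_cv"].is_monotonic_increasing
    )
    assert np.allclose(df["expected_cv"], df["cv_spatial_mean"] / np.sqrt(7))


def test_anatomy_panel_b_weak_association():
    df = scatter_indices(plot_anatomy_fixture("B", seed=2))
    r = fit_loglog(df)
    assert r.r2 < 0.3


def test_anatomy_panel_c_displaced_sets_stay_linear():
    mats = plot_anatomy_fixture("C", seed=3)
    df = scatter_indices(mats)
    indep = df[df["mode"] == "independent"]
    r = fit_loglog(indep)
    assert 0.9 <= r.slope <= 1.1
    # uniformly synchronized set is shifted up, persistent set down,
    # both remain strongly linear
    for mode, sign in (("synchronized", 1), ("persistent", -1)):
        sub = df[df["mode"] == mode]
        rs = fit_loglog(sub)
        assert rs.r2 > 0.9
        shift = rs.intercept - r.intercept
        assert np.sign(shift) == sign


def test_anatomy_panel_d_gradient_skews_slope():
    df = scatter_indices(plot_anatomy_fixture("D", seed=4))
    r = fit_loglog(df)
    assert r.slope < 0.9 or r.slope > 1.1


def test_unknown_panel_rejected():
    with pytest.raises(ValueError, match="unknown panel"):
        plot_anatomy_fixture("E")
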