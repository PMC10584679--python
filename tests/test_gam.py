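"""Poisson GAM: PIRLS/GCV estimation, metrics, partitions, residual maps."""

import numpy as np
import pandas as pd
import pytest

import climspace as cs
from climspace.gam import PoissonGAM, map_residuals, poisson_deviance
from climspace.smooths import CubicRegressionSpline


# ------------------------------------------------------------- spline basis
def test_spline_interpolates_knot_values():
    # cardinal parameterization: basis at knot i is the i-th unit vector
    sp = CubicRegressionSpline([0.0, 1.0, 2.5, 4.0])
    assert np.allclose(sp.design(sp.knots), np.eye(4), atol=1e-10)


def test_spline_penalty_annihilates_linear_functions():
    sp = CubicRegressionSpline([0.0, 1.0, 2.0, 3.0])
    for beta in (np.ones(4), sp.knots, 2 * sp.knots - 1):
        assert beta @ sp.penalty @ beta == pytest.approx(0.0, abs=1e-10)
    # but curvature is penalized
    assert np.array([0, 1, 0, 0.0]) @ sp.penalty @ np.array([0, 1, 0, 0.0]) > 0


def test_spline_extends_linearly_outside_knots():
    sp = CubicRegressionSpline([0.0, 1.0, 2.0, 3.0])
    beta = np.array([0.3, -0.2, 0.5, 0.1])
    xs = np.array([-2.0, -1.0, -0.5])
    vals = sp.design(xs) @ beta
    slopes = np.diff(vals) / np.diff(xs)
    assert slopes[0] == pytest.approx(slopes[1], abs=1e-10)


# ------------------------------------------------------------- basic fitting
def test_constant_response_rejected_but_near_constant_flat():
    rng = np.random.default_rng(0)
    x = pd.DataFrame({"x": np.linspace(0, 1, 100)})
    with pytest.raises(ValueError, match="variance"):
        PoissonGAM(np.full(100, 5), x)
    y = rng.poisson(5.0, size=100)  # no signal
    res = PoissonGAM(y, x).fit()
    assert res.deviance_explained < 0.05
    assert res.params[0] == pytest.approx(np.log(y.mean()), abs=0.05)


def test_edf_bounded_by_basis_dimension(benchmark_fit):
    res, _, _ = benchmark_fit
    for t in res.model.term_names:
        assert 0 < res.edf_by_term[t] <= res.model.k - 1 + 1e-8


def test_response_validation():
    x = pd.DataFrame({"x": np.linspace(0, 1, 50)})
    with pytest.raises(ValueError, match="non-negative integers"):
        PoissonGAM(np.linspace(0.5, 1.5, 50), x)
    with pytest.raises(ValueError, match="too few"):
        PoissonGAM(np.arange(5), pd.DataFrame({"a": np.arange(5)}))


def test_sine_signal_recovered_and_gcv_near_oracle():
    rng = np.random.default_rng(10)
    x = rng.uniform(0, 1, 400)
    f = np.sin(2 * np.pi * x)
    y = rng.poisson(np.exp(1 + f))
    model = PoissonGAM(y, pd.DataFrame({"x": x}), k=6)
    res = model.fit()
    smooth = res.term_contribution("x")
    r = np.corrcoef(smooth, f)[0, 1]
    assert r > 0.95
    # exhaustive fine-grid oracle for the GCV optimum
    grid = np.logspace(-6, 8, 57)
    gcvs = []
    for lam in grid:
        st = model._pirls(model._penalty_matrix({"x": lam}))
        gcvs.append(model._gcv(st))
    lam_oracle = grid[int(np.argmin(gcvs))]
    assert res.lam["x"] / lam_oracle < 10 and lam_oracle / res.lam["x"] < 10


# -------------------------------------------------------------- fit metrics
def test_goodness_of_fit_identities(benchmark_fit):
    res, _, _ = benchmark_fit
    gof = res.goodness_of_fit()
    assert gof["prop_null_deviance"] == pytest.approx(
        1 - res.deviance / res.null_deviance
    )
    assert 0 < gof["prop_null_deviance"] <= 1
    assert gof["predicted_r2"] == pytest.approx(
        np.corrcoef(res.fittedvalues, res.model.endog)[0, 1] ** 2
    )
    assert 0 <= gof["mcfadden_r2"] <= 1


def test_intercept_only_metrics(benchmark_fit):
    res, _, _ = benchmark_fit
    null = res.refit([])
    assert null.deviance_explained == pytest.approx(0.0, abs=1e-12)
    poly0 = cs.fit_polynomial_glm(
        res.model.endog, res.model.exog[["area"]], degree=1
    )
    assert poly0.mcfadden_r2 >= 0


# ---------------------------------------------------------------- partition
def test_partition_components_sum_to_explained(benchmark_fit):
    res, _, _ = benchmark_fit
    part = res.partition()
    assert part.identity_gap() < 1e-6
    assert part.unexplained == pytest.approx(1 - part.explained)


def test_partition_attributes_area_signal(benchmark_fit):
    res, _, truth = benchmark_fit
    part = res.partition()
    share = part.unique["area"] / part.explained
    assert share >= 0.8
    for other in ("isolation", "pc1", "pc2"):
        assert part.unique[other] / part.explained <= 0.05


def test_partition_nesting_monotonicity(benchmark_fit):
    # frozen-lambda refits: adding predictors never worsens deviance
    res, _, _ = benchmark_fit
    names = res.model.term_names
    nested = [[], ["area"], ["area", "pc1"], ["area", "pc1", "isolation"], names]
    devs = [res.refit(s).deviance for s in nested]
    for bigger, smaller in zip(devs[:-1], devs[1:]):
        assert smaller <= bigger + 1e-6 * abs(bigger)


# --------------------------------------------------------- partial residuals
def test_partial_residuals_definitional_identity():
    rng = np.random.default_rng(3)
    x = rng.uniform(-1, 1, 200)
    y = rng.poisson(np.exp(1.0 + 0.8 * x))
    res = PoissonGAM(y, pd.DataFrame({"x": x})).fit()
    pr = res.partial_residuals("x")
    contribution = res.term_contribution("x")
    np.testing.assert_allclose(
        pr["partial_residual"], contribution + res.resid("working")
    )
    # regressing partial residuals on the term's contribution: slope ~ 1
    slope = np.polyfit(contribution, pr["partial_residual"], 1)[0]
    assert slope == pytest.approx(1.0, abs=0.1)


def test_partial_residuals_positive_area_effect(benchmark_fit):
    from scipy.stats import spearmanr

    res, _, _ = benchmark_fit
    pr = res.partial_residuals("area")
    rho = spearmanr(pr["x"], pr["partial_residual"]).statistic
    assert rho > 0.5


def test_partial_residuals_unknown_term(benchmark_fit):
    res, _, _ = benchmark_fit
    with pytest.raises(KeyError):
        res.partial_residuals("nope")


# ------------------------------------------------------------- residual maps
def test_map_residuals_inherit_through_duality(world, space20, cell_table):
    res = cs.PoissonGAM.from_cell_table(cell_table).fit()
    clim, geo = map_residuals(res, space20)
    # two geographic cells sharing a climate cell share the residual
    for cc in res.model.row_index[:5]:
        members = space20.members[cc]
        vals = geo.loc[members]
        assert (vals == clim.loc[cc]).all()
    # Poisson score equation with intercept: response residuals sum to ~0
    resp = res.resid("response")
    assert abs(resp.sum()) < 1e-6 * res.model.endog.sum()


def test_map_residuals_zero_for_perfect_fit(world, space20, cell_table):
    res = cs.PoissonGAM.from_cell_table(cell_table).fit()
    res.mu = res.model.endog.astype(float).copy()  # saturate
    clim, geo = map_residuals(res, space20)
    assert np.allclose(clim, 0.0)


# ----------------------------------------------------------- GLM cross-check
def test_large_lambda_gam_collapses_to_linear_glm(benchmark_fit):
    import statsmodels.api as sm

    res, table, _ = benchmark_fit
    model = res.model
    big = model.fit(lam=1e9)
    z = model.exog.apply(lambda c: (c - c.mean()) / c.std(ddof=0))
    glm = sm.GLM(
        model.endog, sm.add_constant(z), family=sm.families.Poisson()
    ).fit()
    assert big.deviance == pytest.approx(glm.deviance, rel=1e-3)


def test_gam_and_cubic_glm_agree_on_benchmark(benchmark_fit):
    res, _, _ = benchmark_fit
    poly = cs.fit_polynomial_glm(res.model.endog, res.model.exog, degree=3)
    assert abs(res.deviance_explained - poly.deviance_explained) < 0.05


def test_degree1_glm_recovers_log_linear_slope():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(300)
    y = rng.poisson(np.exp(1.0 + 0.5 * x))
    poly = cs.fit_polynomial_glm(y, pd.DataFrame({"x": x}), degree=1)
    # orthonormal column scaled by sqrt(n): slope on z-scale = 0.5 * sd(x)
    slope = poly.params["x^1"]
    se = poly.sm_results.bse["x^1"]
    expected = 0.5 * x.std(ddof=0)
    assert abs(slope - expected) < 2 * se


# ------------------------------------------------------------ deviance math
def test_poisson_deviance_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    y = rng.poisson(3.0, 50)
    mu = np.clip(rng.poisson(3.0, 50), 0.5, None).astype(float)
    expected = sm.families.Poisson().deviance(y.astype(float), mu)
    assert poisson_deviance(y, mu) == pytest.approx(expected)
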