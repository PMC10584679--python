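"""Moran's I, PCNM axes, MEM refits, VIF and the quantile envelope."""

import numpy as np
import pandas as pd
import pytest

import climspace as cs
from climspace.diagnostics import morans_i


# ------------------------------------------------------------------ Moran
def test_moran_null_expectation():
    # E[I] under randomization is -1/(n-1) for any weights
    rng = np.random.default_rng(0)
    n = 100
    w = np.ones((n, n)) - np.eye(n)
    vals = [morans_i(rng.standard_normal(n), w) for _ in range(2000)]
    assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.005)


def test_moran_detects_gradient_in_first_class():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 10, size=(100, 2))
    values = coords[:, 0]  # values equal the first coordinate
    cg = cs.morans_correlogram(values, coords, n_classes=5, n_permutations=199, seed=2)
    assert cg.moran_i[0] > 0.5
    assert cg.p_value[0] <= 0.05


def test_single_class_matches_double_sum_oracle():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 1, size=(30, 2))
    values = rng.standard_normal(30)
    cg = cs.morans_correlogram(values, coords, n_classes=1, n_permutations=99, seed=0)
    # brute-force double sum with all-pairs binary weights
    z = values - values.mean()
    n = len(values)
    num = sum(z[i] * z[j] for i in range(n) for j in range(n) if i != j)
    s0 = n * (n - 1)
    expected = n / s0 * num / (z @ z)
    assert cg.moran_i[0] == pytest.approx(expected, abs=1e-10)


def test_correlogram_pvalues_and_classes_partition():
    rng = np.random.default_rng(4)
    coords = rng.uniform(0, 1, size=(60, 2))
    values = rng.standard_normal(60)
    b = 199
    cg = cs.morans_correlogram(values, coords, n_classes=8, n_permutations=b, seed=1)
    assert (cg.p_value >= 1 / (b + 1)).all() and (cg.p_value <= 1).all()
    assert (cg.n_pairs >= 1).all()
    assert cg.n_pairs.sum() == 60 * 59 // 2  # classes partition all pairs


def test_correlogram_deterministic_given_seed():
    rng = np.random.default_rng(5)
    coords = rng.uniform(0, 1, size=(40, 2))
    values = rng.standard_normal(40)
    a = cs.morans_correlogram(values, coords, n_permutations=99, seed=9)
    b = cs.morans_correlogram(values, coords, n_permutations=99, seed=9)
    np.testing.assert_array_equal(a.p_value, b.p_value)


# -------------------------------------------------------------------- MEM
def test_mem_transect_leading_axis_is_half_cosine():
    # path-graph eigenfunctions are cosines cos(k*pi*x/L); with a
    # neighbourhood wide relative to the point spacing the leading PCNM
    # axis is the half-cosine.  At the minimal (longest-MST-edge)
    # truncation the 4t plateau mixes in the third harmonic, so the
    # correspondence is looser there.
    n = 40
    x = np.linspace(0, 1, n)
    coords = np.c_[x, np.zeros(n)]
    wave = np.cos(np.pi * x)
    basis = cs.mem_axes(coords, truncation=0.3)
    r = abs(np.corrcoef(basis.vectors[:, 0], wave)[0, 1])
    assert r > 0.95
    basis_auto = cs.mem_axes(coords)
    r_auto = abs(np.corrcoef(basis_auto.vectors[:, 0], wave)[0, 1])
    assert r_auto > 0.8


def test_mem_axes_orthogonal_and_ordered():
    rng = np.random.default_rng(6)
    coords = rng.uniform(0, 5, size=(50, 2))
    basis = cs.mem_axes(coords)
    g = basis.vectors.T @ basis.vectors
    assert np.allclose(g - np.diag(np.diag(g)), 0, atol=1e-8)
    assert (np.diff(basis.eigenvalues) <= 1e-9).all()


def test_mem_auto_truncation_is_longest_mst_edge():
    from scipy.sparse.csgraph import minimum_spanning_tree
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 3, size=(20, 2))
    d = squareform(pdist(coords))
    t_expected = minimum_spanning_tree(d).data.max()
    basis = cs.mem_axes(coords)
    assert basis.truncation == pytest.approx(t_expected)


def test_mem_explicit_truncation_too_small_fails():
    coords = np.c_[np.arange(10.0), np.zeros(10)]
    with pytest.raises(ValueError, match="truncation"):
        cs.mem_axes(coords, truncation=0.1)


# -------------------------------------------------------------- MEM refits
def _fit_on_table(table):
    return cs.PoissonGAM.from_cell_table(table).fit()


def test_refit_with_mem_no_axes_when_uncorrelated():
    table = cs.benchmark_cell_table(200, seed=11)
    rich, _ = cs.make_benchmark_scenario(table, {"beta0": np.log(40)}, seed=12)
    table = table.assign(richness=rich)
    res = _fit_on_table(table)
    basis = cs.mem_axes(res.model.exog[["pc1", "pc2"]].to_numpy())
    out = cs.refit_with_mem(res, basis, n_permutations=199, seed=3)
    assert out["selected_axes"] == []
    assert out["first_class_p"] > 0.05


def test_refit_with_mem_absorbs_constructed_autocorrelation():
    # plant one MEM axis in the log mean; the additive smooths of pc1/pc2
    # cannot represent it (it is a mid-frequency 2-D pattern), so the
    # residuals carry it and greedy selection must find exactly that axis
    table = cs.benchmark_cell_table(200, seed=13)
    coords = table[["mean_pc1", "mean_pc2"]].to_numpy()
    basis = cs.mem_axes(coords)
    rng = np.random.default_rng(14)
    eta = np.log(40) + basis.vectors[:, 20] * np.sqrt(len(table))
    richness = rng.poisson(np.exp(eta))
    assert richness.min() > 0  # no cells dropped: basis stays aligned
    table = table.assign(richness=richness)
    res = _fit_on_table(table)
    out = cs.refit_with_mem(res, basis, n_permutations=199, seed=4, max_axes=10)
    assert out["selected_axes"][0] == 20
    assert out["first_class_p"] > 0.05
    # augmentation never worsens the (frozen-lambda) deviance
    assert out["augmented_results"].deviance <= res.deviance + 1e-6 * res.deviance
    # reported headline metrics stay those of the un-augmented model
    assert out["unaugmented_metrics"]["prop_null_deviance"] == pytest.approx(
        res.deviance_explained
    )


# -------------------------------------------------------------------- VIF
def test_vif_orthogonal_predictors():
    # columns orthonormal and orthogonal to the constant: VIF exactly 1
    raw = np.c_[
        np.ones(50), np.random.default_rng(15).standard_normal((50, 3))
    ]
    q, _ = np.linalg.qr(raw)
    v = cs.vif(pd.DataFrame(q[:, 1:], columns=list("abc")))
    assert np.allclose(v, 1.0, atol=1e-8)
    assert (v >= 1.0 - 1e-12).all()


def test_vif_duplicate_predictor_is_infinite():
    x = np.random.default_rng(16).standard_normal(30)
    v = cs.vif(pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(17).standard_normal(30)}))
    assert np.isinf(v["a"]) and np.isinf(v["b"])


def test_vif_matches_direct_formula():
    rng = np.random.default_rng(18)
    df = pd.DataFrame(rng.standard_normal((5, 3)), columns=list("abc"))
    import statsmodels.api as sm

    v = cs.vif(df)
    for j, name in enumerate(df.columns):
        others = sm.add_constant(df.drop(columns=name))
        r2 = sm.OLS(df[name], others).fit().rsquared
        assert v[name] == pytest.approx(1 / (1 - r2), abs=1e-10)


# --------------------------------------------------------- quantile envelope
def test_envelope_exact_line():
    x = np.linspace(0, 10, 50)
    fits = cs.envelope_quantile_fit(x, 2 * x)
    for tau in (0.05, 0.95):
        assert fits[tau].slope == pytest.approx(2.0, abs=1e-6)
        assert fits[tau].intercept == pytest.approx(0.0, abs=1e-6)
    assert fits["ols"]["slope"] == pytest.approx(2.0)


def test_envelope_uniform_noise_coverage():
    rng = np.random.default_rng(19)
    x = rng.uniform(0, 1, 500)
    y = rng.uniform(0, 10, 500)
    fits = cs.envelope_quantile_fit(x, y)
    level = fits[0.95].intercept + fits[0.95].slope * 0.5
    assert level == pytest.approx(9.5, abs=0.35)
    assert fits[0.95].frac_below == pytest.approx(0.95, abs=0.02)
    assert fits[0.05].frac_below == pytest.approx(0.05, abs=0.02)


def test_envelope_small_n_is_pinball_optimal():
    # LP optimality: some optimal quantile line passes through two points,
    # so the fit's loss must not exceed any two-point line's loss
    rng = np.random.default_rng(20)
    x = rng.uniform(0, 1, 20)
    y = rng.uniform(0, 1, 20)
    fits = cs.envelope_quantile_fit(x, y, taus=(0.5,))
    from climspace.diagnostics import _pinball
    from itertools import combinations

    best = np.inf
    for i, j in combinations(range(20), 2):
        if x[i] == x[j]:
            continue
        b1 = (y[j] - y[i]) / (x[j] - x[i])
        b0 = y[i] - b1 * x[i]
        best = min(best, _pinball(y, b0 + b1 * x, 0.5))
    # small slack: QuantReg's IRLS stops within ~1e-8 of the LP optimum
    assert fits[0.5].pinball_loss <= best + 1e-6


def test_envelope_rejects_degenerate_x():
    with pytest.raises(ValueError):
        cs.envelope_quantile_fit(np.ones(30), np.arange(30.0))
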