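"""Autocorrelation diagnostics and envelope regressions in climate space.

Distances here are Euclidean in the (mean PC1, mean PC2) coordinates of
climate cells: residual autocorrelation among climate cells is *climate*
autocorrelation, not geographic.  Provides Moran's I correlograms with
permutation tests, Moran-eigenvector (PCNM) spatial filters and a greedy
filter-selection refit, variance inflation factors, and the
quantile-regression envelope of isolation against latitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------ Moran
def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I for a symmetric binary (or general) weight matrix."""
    z = values - values.mean()
    s0 = weights.sum()
    if s0 == 0:
        raise ValueError("weight matrix has zero total weight")
    n = len(values)
    return float(n / s0 * (z @ weights @ z) / (z @ z))


@dataclass
class Correlogram:
    """Moran's I per distance class with permutation p-values."""

    bounds: np.ndarray  # class edges, length n_classes + 1
    moran_i: np.ndarray
    p_value: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_lo": self.bounds[:-1],
                "d_hi": self.bounds[1:],
                "moran_i": self.moran_i,
                "p_value": self.p_value,
                "n_pairs": self.n_pairs,
            }
        )


def morans_correlogram(
    values,
    coords,
    n_classes: int = 10,
    n_permutations: int = 999,
    seed: int = 0,
) -> Correlogram:
    """Moran's I correlogram over equal-frequency distance classes.

    Distance classes partition the observed pairwise-distance range at
    quantile bounds (equal pair counts up to ties); weights are binary
    within a class.  p-values are two-sided permutation tests from seeded
    value shuffles, bounded below by 1/(B+1).  Empty classes (possible
    with heavy ties) are dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 cells for a correlogram")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    d = squareform(pdist(coords))
    iu = np.triu_indices(len(values), 1)
    dv = d[iu]
    qs = np.quantile(dv, np.linspace(0, 1, n_classes + 1))
    qs[0], qs[-1] = dv.min(), dv.max()
    bounds = np.unique(qs)
    if len(bounds) - 1 < n_classes:
        logger.warning(
            "distance ties reduce %d requested classes to %d",
            n_classes,
            len(bounds) - 1,
        )
    nc = len(bounds) - 1
    rng = np.random.default_rng(seed)
    perms = np.array(
        [rng.permutation(values) for _ in range(n_permutations)]
    )
    mi, pv, npairs, keep_lo, keep_hi = [], [], [], [], []
    for c in range(nc):
        lo, hi = bounds[c], bounds[c + 1]
        if c == 0:
            mask = (d >= lo) & (d <= hi)
        else:
            mask = (d > lo) & (d <= hi)
        np.fill_diagonal(mask, False)
        w = mask.astype(float)
        np_pairs = int(w.sum() // 2)
        if np_pairs == 0:
            logger.warning("empty distance class (%g, %g] dropped", lo, hi)
            continue
        i_obs = morans_i(values, w)
        i_perm = np.array([morans_i(p, w) for p in perms])
        b = n_permutations
        p_hi = (1 + np.sum(i_perm >= i_obs)) / (b + 1)
        p_lo = (1 + np.sum(i_perm <= i_obs)) / (b + 1)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
        mi.append(i_obs)
        pv.append(p)
        npairs.append(np_pairs)
        keep_lo.append(lo)
        keep_hi.append(hi)
    return Correlogram(
        bounds=np.r_[keep_lo, keep_hi[-1]],
        moran_i=np.asarray(mi),
        p_value=np.asarray(pv),
        n_pairs=np.asarray(npairs),
    )


# -------------------------------------------------------------------- MEM
@dataclass
class MEMBasis:
    """Positive-eigenvalue PCNM axes over climate cells."""

    vectors: np.ndarray  # n x m, columns ordered by decreasing eigenvalue
    eigenvalues: np.ndarray
    truncation: float

    @property
    def n_axes(self) -> int:
        return self.vectors.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.vectors,
            columns=[f"mem{j + 1}" for j in range(self.n_axes)],
        )


def mem_axes(
    coords=None, dist: np.ndarray | None = None, truncation="auto"
) -> MEMBasis:
    """Principal coordinates of neighbour matrices (PCNM construction).

    Distances beyond the truncation threshold t (auto = longest edge of
    the minimum spanning tree, so the neighbour graph stays connected) are
    replaced by 4t; the modified matrix is double-centered (Gower) and
    eigendecomposed; axes with positive eigenvalues are kept, ordered by
    decreasing eigenvalue.
    """
    if dist is None:
        if coords is None:
            raise ValueError("give coords or a distance matrix")
        dist = squareform(pdist(np.asarray(coords, dtype=float)))
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 5:
        raise ValueError("need at least 5 cells for MEM axes")
    if truncation == "auto":
        mst = minimum_spanning_tree(dist)
        t = float(mst.data.max())
    else:
        t = float(truncation)
        off = dist[~np.eye(n, dtype=bool)]
        if (off > t).all():
            raise ValueError("all distances beyond the truncation threshold")
    dstar = np.where(dist <= t, dist, 4.0 * t)
    np.fill_diagonal(dstar, 0.0)
    a = -0.5 * dstar**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = 0.5 * (g + g.T)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-8 * max(eigval.max(), 1.0)
    # deterministic sign: largest-magnitude entry positive
    vecs = eigvec[:, pos]
    for jcol in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, jcol])))
        if vecs[i, jcol] < 0:
            vecs[:, jcol] = -vecs[:, jcol]
    return MEMBasis(vectors=vecs, eigenvalues=eigval[pos], truncation=t)


def refit_with_mem(
    results,
    basis: MEMBasis,
    coords=None,
    alpha: float = 0.05,
    n_classes: int = 10,
    n_permutations: int = 999,
    seed: int = 0,
    max_axes: int | None = None,
) -> dict:
    """Absorb residual climate autocorrelation with MEM axes.

    Greedily adds the MEM axis most correlated with the current deviance
    residuals (as an unpenalized linear term, smooth lambdas frozen from
    the original fit) until the first correlogram class is non-significant
    at ``alpha`` or axes run out.  Goodness-of-fit metrics remain those of
    the *un-augmented* model; the augmented fit only checks whether the
    predictors stay significant once autocorrelation is absorbed.

    Returns a dict with the augmented results, selected axis indices, the
    final first-class p-value, and the term-significance table of the
    augmented model.
    """
    from climspace.gam import PoissonGAM

    model = results.model
    if coords is None:
        coords = model.exog[["pc1", "pc2"]].to_numpy(dtype=float)
    if len(basis.vectors) != results.nobs:
        raise ValueError("MEM basis computed on different cells than the fit")
    max_axes = basis.n_axes if max_axes is None else min(max_axes, basis.n_axes)

    selected: list[int] = []
    current = results
    first_p = np.nan
    for _ in range(max_axes + 1):
        resid = current.resid("deviance")
        cg = morans_correlogram(
            resid, coords, n_classes=n_classes, n_permutations=n_permutations, seed=seed
        )
        first_p = float(cg.p_value[0])
        if first_p > alpha or len(selected) >= max_axes:
            break
        remaining = [j for j in range(basis.n_axes) if j not in selected]
        cors = [
            abs(np.corrcoef(basis.vectors[:, j], resid)[0, 1]) for j in remaining
        ]
        selected.append(remaining[int(np.argmax(cors))])
        lin = pd.DataFrame(
            basis.vectors[:, selected],
            columns=[f"mem{j + 1}" for j in selected],
            index=model.row_index,
        )
        aug_model = PoissonGAM(model.endog, model.exog, k=model.k, linear_exog=lin)
        current = aug_model.fit(lam=dict(results.lam))
        current.null_deviance = results.null_deviance
    return {
        "augmented_results": current,
        "selected_axes": selected,
        "first_class_p": first_p,
        "term_significance": current.term_significance(),
        "unaugmented_metrics": results.goodness_of_fit(),
    }


# -------------------------------------------------------------------- VIF
def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R²_j).

    R²_j comes from the OLS regression (with intercept) of predictor j on
    the others.  Perfect collinearity reports inf rather than raising.
    """
    if predictors.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    x = predictors.to_numpy(dtype=float)
    if (x.std(axis=0) == 0).any():
        bad = predictors.columns[x.std(axis=0) == 0].tolist()
        raise ValueError(f"zero-variance predictor(s): {bad}")
    out = {}
    n = x.shape[0]
    for j, name in enumerate(predictors.columns):
        yj = x[:, j]
        others = np.c_[np.ones(n), np.delete(x, j, axis=1)]
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# -------------------------------------------------------- quantile envelope
@dataclass
class QuantileFit:
    """One linear quantile regression line."""

    tau: float
    intercept: float
    slope: float
    pinball_loss: float
    frac_below: float


def _pinball(y: np.ndarray, yhat: np.ndarray, tau: float) -> float:
    u = y - yhat
    return float(np.mean(np.where(u >= 0, tau * u, (tau - 1.0) * u)))


def envelope_quantile_fit(
    x, y, taus: tuple = (0.05, 0.95)
) -> dict:
    """Quantile-regression envelope of y on x, with an OLS line alongside.

    Fits a linear quantile regression (pinball-loss minimization) at each
    tau — the constraint-envelope reading of a scatter whose upper and
    lower bounds, not its mean, track the predictor.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 observations for the envelope fit")
    if x.std() == 0:
        raise ValueError("degenerate predictor: zero variance")
    design = sm.add_constant(x)
    fits = {}
    for tau in taus:
        qr = sm.QuantReg(y, design).fit(q=tau)
        b0, b1 = float(qr.params[0]), float(qr.params[1])
        yhat = b0 + b1 * x
        fits[tau] = QuantileFit(
            tau=tau,
            intercept=b0,
            slope=b1,
            pinball_loss=_pinball(y, yhat, tau),
            frac_below=float(np.mean(y < yhat)),
        )
    ols = sm.OLS(y, design).fit()
    fits["ols"] = {
        "intercept": float(ols.params[0]),
        "slope": float(ols.params[1]),
        "r2": float(ols.rsquared),
    }
    return fits
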