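"""Poisson generalized additive models for richness in climate space.

Model/results pair in the statsmodels idiom: :class:`PoissonGAM` is built
from a response vector and a predictor table; each predictor enters as a
penalized cubic regression spline (basis dimension ``k``, knots at
quantiles, second-derivative penalty) under a Poisson log link.
Coefficients are estimated by penalized iteratively reweighted least
squares; per-term smoothing parameters are selected by minimizing the GCV
score ``n * D / (n - edf)^2`` with a deterministic coordinate-descent grid
search.  :class:`PoissonGAMResults` carries deviances, effective degrees
of freedom, goodness-of-fit metrics, partial residuals, residual
back-projection to geographic space, and the frozen-smoothing deviance
partition into unique and joint contributions of predictor groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import gammaln

from climspace.smooths import CubicRegressionSpline

__all__ = [
    "PoissonGAM",
    "PoissonGAMResults",
    "PartitionTable",
    "fit_polynomial_glm",
    "map_residuals",
]

_DEFAULT_LAMBDA_GRID = np.logspace(-4.0, 8.0, 13)


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Total Poisson deviance 2*sum(y*log(y/mu) - (y - mu))."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


@dataclass
class _Term:
    name: str
    spline: CubicRegressionSpline
    z_transform: np.ndarray  # (k, k-1) sum-to-zero constraint basis
    x_raw: np.ndarray  # original predictor values
    x_std: np.ndarray  # standardized values the spline was built on
    mean: float
    sd: float
    cols: slice = field(default=None)  # columns in the model matrix
    penalty: np.ndarray = field(default=None)  # constrained penalty

    @property
    def n_coef(self) -> int:
        return self.z_transform.shape[1]

    def design(self, x_std: np.ndarray) -> np.ndarray:
        return self.spline.design(x_std) @ self.z_transform


def _constraint_basis(design: np.ndarray) -> np.ndarray:
    """Null-space basis of the column-sum vector (sum-to-zero constraint)."""
    c = design.sum(axis=0)[:, None]
    q, _ = np.linalg.qr(c, mode="complete")
    return q[:, 1:]


@dataclass
class _FitState:
    beta: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    deviance: float
    edf_total: float
    edf_by_col: np.ndarray
    n_iter: int
    converged: bool


class PoissonGAM:
    """Poisson GAM of a count response on smooth terms of each predictor.

    Parameters
    ----------
    endog : array-like of non-negative integers
        Response counts (per-climate-cell species richness).
    exog : pandas.DataFrame
        One column per smooth predictor.  Predictors are standardized
        internally; knots sit at quantiles of the standardized values.
    k : int
        Basis dimension per smooth (>= 3).  With the sum-to-zero
        identifiability constraint each smooth contributes k - 1 columns,
        so its effective degrees of freedom cannot exceed k - 1.
    linear_exog : pandas.DataFrame, optional
        Additional unpenalized linear columns (e.g. spatial-filter
        eigenvectors); not standardized.
    """

    def __init__(
        self,
        endog,
        exog: pd.DataFrame,
        k: int = 4,
        linear_exog: pd.DataFrame | None = None,
    ):
        y = np.asarray(endog, dtype=float)
        if y.ndim != 1 or len(y) != len(exog):
            raise ValueError("endog must be 1-D and aligned with exog")
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("response must be non-negative integers")
        if np.var(y) == 0:
            raise ValueError("response has zero variance")
        if k < 3:
            raise ValueError("basis dimension k must be >= 3")
        if len(exog) < 10 * exog.shape[1]:
            raise ValueError(
                f"too few observations ({len(exog)}) for {exog.shape[1]} smooth terms"
            )
        self.endog = y
        self.exog = exog.copy()
        self.k = k
        self.row_index = exog.index
        self.term_names = list(exog.columns)

        self.terms: list[_Term] = []
        col = 1  # column 0 is the intercept
        for name in self.term_names:
            x = exog[name].to_numpy(dtype=float)
            if not np.isfinite(x).all():
                raise ValueError(f"non-finite values in predictor {name!r}")
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"predictor {name!r} is constant")
            xs = (x - x.mean()) / sd
            spline = CubicRegressionSpline.from_quantiles(xs, k=k)
            raw = spline.design(xs)
            z = _constraint_basis(raw)
            t = _Term(
                name=name,
                spline=spline,
                z_transform=z,
                x_raw=x,
                x_std=xs,
                mean=float(x.mean()),
                sd=float(sd),
            )
            t.penalty = z.T @ spline.penalty @ z
            t.cols = slice(col, col + t.n_coef)
            col += t.n_coef
            self.terms.append(t)

        blocks = [np.ones((len(y), 1))] + [
            t.design(t.x_std) for t in self.terms
        ]
        self.n_linear = 0
        self.linear_names: list[str] = []
        if linear_exog is not None:
            if len(linear_exog) != len(y):
                raise ValueError("linear_exog misaligned with endog")
            blocks.append(linear_exog.to_numpy(dtype=float))
            self.n_linear = linear_exog.shape[1]
            self.linear_names = list(linear_exog.columns)
        self.design = np.hstack(blocks)
        self.n_params = self.design.shape[1]

    # ------------------------------------------------------------- fitting
    def _penalty_matrix(self, lam: dict[str, float]) -> np.ndarray:
        p = np.zeros((self.n_params, self.n_params))
        for t in self.terms:
            p[t.cols, t.cols] += lam[t.name] * t.penalty
        return p

    def _pirls(self, pen: np.ndarray, max_iter: int = 200, tol: float = 1e-9) -> _FitState:
        y, x = self.endog, self.design
        mu = (y + y.mean()) / 2.0
        mu = np.clip(mu, 1e-3, None)
        eta = np.log(mu)
        beta = np.zeros(self.n_params)
        dev = poisson_deviance(y, mu)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = mu
            z = eta + (y - mu) / mu
            xtw = x.T * w
            a = xtw @ x
            b = xtw @ z
            try:
                cf = linalg.cho_factor(a + pen, lower=True)
            except linalg.LinAlgError:
                jitter = 1e-8 * np.trace(a + pen) / self.n_params
                cf = linalg.cho_factor(
                    a + pen + jitter * np.eye(self.n_params), lower=True
                )
            beta_new = linalg.cho_solve(cf, b)
            step = 1.0
            for _ in range(30):  # step halving against divergence
                cand = beta + step * (beta_new - beta)
                eta_c = np.clip(x @ cand, -30.0, 30.0)
                mu_c = np.exp(eta_c)
                dev_c = poisson_deviance(y, mu_c)
                if np.isfinite(dev_c) and dev_c <= dev + 1e-10:
                    break
                step /= 2.0
            beta, eta, mu = cand, eta_c, mu_c
            if abs(dev - dev_c) < tol * (abs(dev_c) + 0.1):
                dev = dev_c
                converged = True
                break
            dev = dev_c
        if not converged:
            raise RuntimeError(
                f"PIRLS did not converge in {max_iter} iterations "
                f"(deviance {dev:.6g})"
            )
        w = mu
        a = (self.design.T * w) @ self.design
        try:
            h = linalg.solve(a + pen, a, assume_a="pos")
        except linalg.LinAlgError:
            h = np.linalg.lstsq(a + pen, a, rcond=None)[0]
        edf_by_col = np.diag(h).copy()
        return _FitState(
            beta=beta,
            eta=eta,
            mu=mu,
            deviance=dev,
            edf_total=float(edf_by_col.sum()),
            edf_by_col=edf_by_col,
            n_iter=it,
            converged=converged,
        )

    def _gcv(self, state: _FitState) -> float:
        n = len(self.endog)
        return n * state.deviance / (n - state.edf_total) ** 2

    def fit(
        self,
        lam: dict[str, float] | float | None = None,
        lambda_grid: np.ndarray | None = None,
        n_sweeps: int = 3,
        refine: bool = True,
    ) -> "PoissonGAMResults":
        """Fit the model; select per-term lambda by GCV unless given.

        ``lam`` may be a scalar (shared), a dict per term, or None
        (GCV selection by coordinate-descent grid search with one local
        refinement pass).  The search is deterministic.
        """
        grid = _DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
        if lam is not None:
            if np.isscalar(lam):
                lam = {t.name: float(lam) for t in self.terms}
            state = self._pirls(self._penalty_matrix(lam))
            return self._results(lam, state)

        lam = {t.name: 1.0 for t in self.terms}
        best_state = self._pirls(self._penalty_matrix(lam))
        best_gcv = self._gcv(best_state)
        for _ in range(n_sweeps):
            improved = False
            for t in self.terms:
                for cand in grid:
                    if cand == lam[t.name]:
                        continue
                    trial = dict(lam)
                    trial[t.name] = float(cand)
                    try:
                        st = self._pirls(self._penalty_matrix(trial))
                    except RuntimeError:
                        continue
                    g = self._gcv(st)
                    if g < best_gcv - 1e-12:
                        best_gcv, best_state, lam = g, st, trial
                        improved = True
            if not improved:
                break
        if refine:
            factors = np.logspace(-1.0, 1.0, 9)
            for t in self.terms:
                base = lam[t.name]
                for f in factors:
                    trial = dict(lam)
                    trial[t.name] = float(base * f)
                    try:
                        st = self._pirls(self._penalty_matrix(trial))
                    except RuntimeError:
                        continue
                    g = self._gcv(st)
                    if g < best_gcv - 1e-12:
                        best_gcv, best_state, lam = g, st, trial
        return self._results(lam, best_state)

    def _results(self, lam: dict[str, float], state: _FitState) -> "PoissonGAMResults":
        y = self.endog
        mu0 = np.full_like(y, y.mean())
        return PoissonGAMResults(
            model=self,
            lam=dict(lam),
            params=state.beta,
            eta=state.eta,
            mu=state.mu,
            deviance=state.deviance,
            null_deviance=poisson_deviance(y, mu0),
            edf_by_col=state.edf_by_col,
            edf_total=state.edf_total,
            n_iter=state.n_iter,
            converged=state.converged,
        )

    # convenience ------------------------------------------------------
    @classmethod
    def from_cell_table(
        cls,
        table: pd.DataFrame,
        response: str = "richness",
        log_area: bool = True,
        drop_zero: bool = True,
        k: int = 4,
    ) -> "PoissonGAM":
        """Build the standard richness model from a climate-cell table.

        Predictors: (log) climate area, between-fragment isolation and the
        mean PC1/PC2 coordinates of each climate cell.  Climate cells with
        zero richness are excluded by default (richness is modelled as a
        count >= 1, which reproduces differing per-taxon cell counts).
        """
        df = table.copy()
        if drop_zero:
            df = df[df[response] > 0]
        exog = pd.DataFrame(
            {
                "area": np.log(df["area_km2"].to_numpy(dtype=float))
                if log_area
                else df["area_km2"].to_numpy(dtype=float),
                "isolation": df["isolation_frag_km"].to_numpy(dtype=float),
                "pc1": df["mean_pc1"].to_numpy(dtype=float),
                "pc2": df["mean_pc2"].to_numpy(dtype=float),
            },
            index=df["climate_cell_id"].to_numpy()
            if "climate_cell_id" in df.columns
            else df.index,
        )
        return cls(df[response].to_numpy(), exog, k=k)


@dataclass
class PartitionTable:
    """Unique/joint shares of explained deviance, as proportions of null deviance.

    The seven explained components (four unique, joint within each predictor
    group, joint between groups) sum to the full model's proportion of null
    deviance by construction; ``unexplained`` is one minus that sum.  Small
    negative unique components can arise from frozen-lambda refits and are
    kept as-is here (clamp only when reporting).
    """

    unique: dict[str, float]
    joint_within_geography: float
    joint_within_climate: float
    joint_between_groups: float
    explained: float
    geography_terms: tuple
    climate_terms: tuple

    @property
    def unexplained(self) -> float:
        return 1.0 - self.explained

    def components(self) -> dict[str, float]:
        out = {f"unique_{k}": v for k, v in self.unique.items()}
        out["joint_within_geography"] = self.joint_within_geography
        out["joint_within_climate"] = self.joint_within_climate
        out["joint_between_groups"] = self.joint_between_groups
        return out

    def to_series(self) -> pd.Series:
        d = self.components()
        d["explained"] = self.explained
        d["unexplained"] = self.unexplained
        return pd.Series(d)

    def identity_gap(self) -> float:
        """|sum of the seven components - explained| (should be ~0)."""
        return abs(sum(self.components().values()) - self.explained)


class PoissonGAMResults:
    """Fitted Poisson GAM: estimates, deviances, diagnostics, partitions."""

    def __init__(
        self,
        model: PoissonGAM,
        lam: dict[str, float],
        params: np.ndarray,
        eta: np.ndarray,
        mu: np.ndarray,
        deviance: float,
        null_deviance: float,
        edf_by_col: np.ndarray,
        edf_total: float,
        n_iter: int,
        converged: bool,
    ):
        self.model = model
        self.lam = lam
        self.params = params
        self.eta = eta
        self.mu = mu
        self.deviance = deviance
        self.null_deviance = null_deviance
        self.edf_by_col = edf_by_col
        self.edf_total = edf_total
        self.n_iter = n_iter
        self.converged = converged

    # ---------------------------------------------------------- properties
    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.mu

    @property
    def deviance_explained(self) -> float:
        """Proportion of null deviance: 1 - D/D_null."""
        return 1.0 - self.deviance / self.null_deviance

    @property
    def edf_by_term(self) -> dict[str, float]:
        out = {"intercept": float(self.edf_by_col[0])}
        for t in self.model.terms:
            out[t.name] = float(self.edf_by_col[t.cols].sum())
        if self.model.n_linear:
            out["linear"] = float(self.edf_by_col[-self.model.n_linear :].sum())
        return out

    @property
    def gcv(self) -> float:
        n = self.nobs
        return n * self.deviance / (n - self.edf_total) ** 2

    @property
    def loglik(self) -> float:
        return poisson_loglik(self.model.endog, self.mu)

    @property
    def loglik_null(self) -> float:
        y = self.model.endog
        return poisson_loglik(y, np.full_like(y, y.mean()))

    # ----------------------------------------------------------- residuals
    def resid(self, kind: str = "deviance") -> np.ndarray:
        y, mu = self.model.endog, self.mu
        if kind == "response":
            return y - mu
        if kind == "working":
            return (y - mu) / mu
        if kind == "pearson":
            return (y - mu) / np.sqrt(mu)
        if kind == "deviance":
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
            d = 2.0 * (term - (y - mu))
            return np.sign(y - mu) * np.sqrt(np.clip(d, 0.0, None))
        raise ValueError(f"unknown residual kind {kind!r}")

    def term_contribution(self, name: str) -> np.ndarray:
        """This smooth's (sum-to-zero) contribution to the linear predictor."""
        t = self._term(name)
        return self.model.design[:, t.cols] @ self.params[t.cols]

    def partial_residuals(self, name: str) -> pd.DataFrame:
        """Term contribution plus working residuals, with the predictor values.

        The standard construction for plotting a smooth against 'richness
        not explained by the other predictors'.
        """
        t = self._term(name)
        pr = self.term_contribution(name) + self.resid("working")
        return pd.DataFrame(
            {"x": t.x_raw, "partial_residual": pr}, index=self.model.row_index
        )

    def _term(self, name: str):
        for t in self.model.terms:
            if t.name == name:
                return t
        raise KeyError(f"unknown term {name!r}; terms: {self.model.term_names}")

    # --------------------------------------------------------- diagnostics
    def goodness_of_fit(self) -> dict[str, float]:
        """Proportion of null deviance, adjusted/predicted R², McFadden's R²."""
        y, mu = self.model.endog, self.mu
        n = self.nobs
        ss_res = float(np.sum((y - mu) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (n - 1.0) / (n - self.edf_total) * (1.0 - r2)
        pred = float(np.corrcoef(mu, y)[0, 1] ** 2)
        mcfadden = 1.0 - self.loglik / self.loglik_null
        return {
            "prop_null_deviance": self.deviance_explained,
            "adjusted_r2": adj,
            "predicted_r2": pred,
            "mcfadden_r2": mcfadden,
        }

    def term_significance(self) -> pd.DataFrame:
        """Chi-square test of each smooth via frozen-lambda deviance drop."""
        rows = []
        for t in self.model.terms:
            red = self.refit([n for n in self.model.term_names if n != t.name])
            drop = red.deviance - self.deviance
            df_t = max(self.edf_by_term[t.name], 1e-8)
            rows.append(
                {
                    "term": t.name,
                    "deviance_drop": drop,
                    "edf": df_t,
                    "p_value": float(stats.chi2.sf(max(drop, 0.0), df_t)),
                }
            )
        return pd.DataFrame(rows)

    # --------------------------------------------------------- refits
    def refit(
        self, keep_terms: list[str], include_linear: bool = True
    ) -> "PoissonGAMResults":
        """Refit with a subset of smooth terms, smoothing parameters frozen.

        Coefficients are re-estimated; each kept term reuses the lambda
        selected for the full model (reduced models never reselect
        smoothing).  An empty subset gives the intercept-only model.
        """
        m = self.model
        if not set(keep_terms).issubset(m.term_names):
            raise KeyError(f"unknown terms in {keep_terms}")
        lin = None
        if include_linear and m.n_linear:
            lin = pd.DataFrame(
                m.design[:, -m.n_linear :], columns=m.linear_names, index=m.row_index
            )
        if not keep_terms and lin is None:
            y = m.endog
            mu0 = np.full_like(y, y.mean())
            dev0 = poisson_deviance(y, mu0)
            res = PoissonGAMResults(
                model=m,
                lam={},
                params=np.array([np.log(y.mean())]),
                eta=np.log(mu0),
                mu=mu0,
                deviance=dev0,
                null_deviance=dev0,
                edf_by_col=np.array([1.0]),
                edf_total=1.0,
                n_iter=0,
                converged=True,
            )
            res.null_deviance = self.null_deviance
            return res
        sub = PoissonGAM(
            m.endog,
            m.exog[list(keep_terms)],
            k=m.k,
            linear_exog=lin,
        )
        lam = {name: self.lam[name] for name in keep_terms}
        res = sub.fit(lam=lam if lam else 0.0)
        res.null_deviance = self.null_deviance
        return res

    def partition(
        self,
        geography_terms: tuple = ("area", "isolation"),
        climate_terms: tuple = ("pc1", "pc2"),
    ) -> PartitionTable:
        """Partition explained deviance into unique and joint shares.

        With D(S) the proportion of null deviance of the frozen-lambda
        model on predictor set S: unique(x) = D(all) - D(all minus x);
        the joint share within a group is the group's combined drop minus
        its members' unique shares; the between-group joint share is the
        remainder, so the seven components sum to D(all) exactly.
        """
        names = self.model.term_names
        for t in geography_terms + climate_terms:
            if t not in names:
                raise KeyError(f"partition term {t!r} not in model terms {names}")
        d_all = self.deviance_explained

        def d_without(drop: tuple) -> float:
            keep = [n for n in names if n not in drop]
            return self.refit(keep).deviance_explained

        unique = {t: d_all - d_without((t,)) for t in names}
        drop_geo = d_all - d_without(tuple(geography_terms))
        drop_clim = d_all - d_without(tuple(climate_terms))
        jwg = drop_geo - sum(unique[t] for t in geography_terms)
        jwc = drop_clim - sum(unique[t] for t in climate_terms)
        jbetween = d_all - sum(unique.values()) - jwg - jwc
        return PartitionTable(
            unique=unique,
            joint_within_geography=jwg,
            joint_within_climate=jwc,
            joint_between_groups=jbetween,
            explained=d_all,
            geography_terms=tuple(geography_terms),
            climate_terms=tuple(climate_terms),
        )

    # --------------------------------------------------------- reporting
    def summary(self) -> str:
        gof = self.goodness_of_fit()
        lines = [
            "Poisson GAM (log link, penalized cubic regression splines)",
            f"  n obs: {self.nobs}    basis dim k: {self.model.k}",
            f"  deviance: {self.deviance:.4f}   null deviance: {self.null_deviance:.4f}",
            f"  proportion of null deviance: {gof['prop_null_deviance']:.4f}",
            f"  adjusted R2: {gof['adjusted_r2']:.4f}   "
            f"predicted R2: {gof['predicted_r2']:.4f}   "
            f"McFadden R2: {gof['mcfadden_r2']:.4f}",
            f"  total edf: {self.edf_total:.3f}   GCV: {self.gcv:.5f}",
            "  term        lambda        edf",
        ]
        for t in self.model.terms:
            lines.append(
                f"  {t.name:<10} {self.lam[t.name]:<12.4g} "
                f"{self.edf_by_term[t.name]:.3f}"
            )
        if self.model.n_linear:
            lines.append(f"  + {self.model.n_linear} unpenalized linear column(s)")
        return "\n".join(lines)


def map_residuals(
    results: PoissonGAMResults, space, kind: str = "deviance"
) -> tuple[pd.Series, pd.Series]:
    """Residual per climate cell and its back-projection to geographic cells.

    The model rows are indexed by climate_cell_id; each geographic cell
    inherits the residual of its climate cell through the duality map
    (geographic cells whose climate cell was excluded from the model get
    NaN).
    """
    clim = pd.Series(
        results.resid(kind), index=results.model.row_index, name=f"resid_{kind}"
    )
    geo = space.geo_to_climate.map(clim)
    geo.name = f"resid_{kind}"
    return clim, geo


# ------------------------------------------------------------- GLM variant
@dataclass
class PolyGLMResults:
    """Poisson GLM with orthogonal polynomial terms (cross-check model)."""

    sm_results: object
    degree: int
    term_names: list[str]
    deviance: float
    null_deviance: float

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.deviance / self.null_deviance

    @property
    def mcfadden_r2(self) -> float:
        return 1.0 - self.sm_results.llf / self.sm_results.llnull

    @property
    def params(self) -> pd.Series:
        return self.sm_results.params


def _orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial columns of x, degrees 1..degree (QR based)."""
    xs = (x - x.mean()) / x.std(ddof=0)
    v = np.vander(xs, degree + 1, increasing=True)  # 1, x, x^2, ...
    q, _ = np.linalg.qr(v)
    return q[:, 1:] * np.sqrt(len(x))


def fit_polynomial_glm(endog, exog: pd.DataFrame, degree: int = 3) -> PolyGLMResults:
    """Poisson GLM with orthogonal polynomials per predictor.

    The paper's-scale cross-check: nonlinearity handled by polynomial terms
    instead of penalized smooths; proportions of null deviance should agree
    closely with the GAM on well-behaved data.
    """
    import statsmodels.api as sm

    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    y = np.asarray(endog, dtype=float)
    cols = [np.ones((len(y), 1))]
    names = ["intercept"]
    for c in exog.columns:
        p = _orthogonal_poly(exog[c].to_numpy(dtype=float), degree)
        cols.append(p)
        names.extend(f"{c}^{d}" for d in range(1, degree + 1))
    x = np.hstack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient polynomial design")
    res = sm.GLM(y, pd.DataFrame(x, columns=names), family=sm.families.Poisson()).fit()
    return PolyGLMResults(
        sm_results=res,
        degree=degree,
        term_names=names,
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
    )
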