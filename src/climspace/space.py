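"""Construction of the 2-D climate space and its duality with geography.

The climate space is spanned by the first two principal components of the
per-cell climate variables (PCA on the correlation matrix, i.e. on
standardized variables).  The plane is then gridded into equal intervals;
every geographic land cell falls in exactly one climate cell, and each
climate cell collects the geographic cells whose climate lies in its bin
(Hutchinson's duality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ----------------------------------------------------------------------- PCA
@dataclass
class PCAResult:
    """Principal components of the climate variables (correlation matrix).

    ``loadings`` is variables x components (orthonormal columns),
    ``variance_fraction`` the per-component share of total variance, and
    ``scores`` the per-geographic-cell component scores (indexed by
    cell_id, columns ``pc1, pc2, ...``).  ``mean`` and ``sd`` are the
    standardization parameters applied before projection.
    """

    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    scores: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    log_vars: tuple = ()

    def transform(self, climate_table: pd.DataFrame) -> pd.DataFrame:
        """Project new cells into the fitted component space."""
        x = climate_table[self.loadings.index].astype(float)
        for v in self.log_vars:
            x[v] = np.log(x[v])
        z = (x - self.mean) / self.sd
        s = z.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(s, index=climate_table.index, columns=self.scores.columns)


def fit_pca(climate_table: pd.DataFrame, log_vars: tuple = ()) -> PCAResult:
    """PCA on the correlation matrix of per-cell climate variables.

    Components are ordered by decreasing variance fraction; the sign of each
    loading vector is fixed so its largest-magnitude entry is positive.
    ``log_vars`` names variables to log-transform before standardization
    (for skewed variables such as precipitation sums); they must be
    strictly positive.
    """
    if climate_table.shape[0] < 3:
        raise ValueError("need at least 3 cells to fit a PCA")
    if climate_table.shape[1] < 2:
        raise ValueError("need at least 2 variables to fit a PCA")
    x = climate_table.astype(float).copy()
    for v in log_vars:
        if (x[v] <= 0).any():
            raise ValueError(f"variable {v!r} must be positive for log transform")
        x[v] = np.log(x[v])
    arr = x.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in climate table")
    sd = x.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant climate variable(s): {constant}")
    mean = x.mean()
    z = (x - mean) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    p = corr.shape[0]
    frac = eigval / eigval.sum()
    cols = [f"pc{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(eigvec, index=x.columns, columns=cols)
    scores = pd.DataFrame(z.to_numpy() @ eigvec, index=climate_table.index, columns=cols)
    return PCAResult(
        loadings=loadings,
        variance_fraction=frac,
        scores=scores,
        mean=mean,
        sd=sd,
        log_vars=tuple(log_vars),
    )


# ------------------------------------------------------------------- binning
@dataclass(frozen=True)
class AxisSpec:
    """Equal-interval binning of one climate axis on [lo, hi]."""

    lo: float
    hi: float
    n_intervals: int

    def __post_init__(self):
        if not (self.lo < self.hi):
            raise ValueError("axis requires lo < hi")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_intervals


def assign_bin(value, axis: AxisSpec):
    """Equal-interval bin index: half-open bins, last bin closed on the right.

    Bin i covers [lo + i*w, lo + (i+1)*w); value == hi maps to the last bin
    so the map is total on [lo, hi].  Values outside [lo, hi] raise.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < axis.lo) or np.any(v > axis.hi):
        raise ValueError(f"value outside axis range [{axis.lo}, {axis.hi}]")
    idx = np.floor((v - axis.lo) / axis.width).astype(int)
    idx = np.minimum(idx, axis.n_intervals - 1)  # right-edge closure
    return int(idx) if idx.ndim == 0 else idx


# ------------------------------------------------------------- climate grid
@dataclass
class ClimateSpaceGrid:
    """Gridded 2-D climate space with the geographic duality maps.

    ``climate_cell_id = bin_pc1 * axis2.n_intervals + bin_pc2``.  Only
    non-empty climate cells appear in ``members``; ``geo_to_climate`` is a
    total map on the land cells it was built from (a partition).
    """

    axis1: AxisSpec
    axis2: AxisSpec
    geo_to_climate: pd.Series  # index cell_id -> climate_cell_id
    members: dict[int, np.ndarray] = field(repr=False)  # climate_cell -> cell_ids
    cell_means: pd.DataFrame = field(repr=False)  # per climate cell mean pcs
    scores: pd.DataFrame = field(repr=False)  # per geo cell (pc1, pc2)

    @property
    def n_nonempty(self) -> int:
        return len(self.members)

    def climate_cell_of(self, cell_id: int) -> int:
        return int(self.geo_to_climate.loc[cell_id])

    def bin_indices(self, climate_cell_id: int) -> tuple[int, int]:
        n2 = self.axis2.n_intervals
        return climate_cell_id // n2, climate_cell_id % n2


def build_climate_grid(
    scores: pd.DataFrame,
    n_intervals: int,
    axis_cols: tuple[str, str] = ("pc1", "pc2"),
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> ClimateSpaceGrid:
    """Grid the climate plane into equal intervals and build the duality map.

    ``scores`` has one row per geographic cell (index = cell_id) with the
    two axis columns — PCA scores by default, or raw variables (e.g. mean
    temperature / annual precipitation) for a raw-variable space.  Axis
    bounds default to the observed min/max of each column, which makes the
    geo->climate assignment total.
    """
    s1 = scores[axis_cols[0]].to_numpy(dtype=float)
    s2 = scores[axis_cols[1]].to_numpy(dtype=float)
    for name, s in zip(axis_cols, (s1, s2)):
        if len(np.unique(s)) < 2:
            raise ValueError(f"axis {name!r} has fewer than 2 distinct score values")
    if bounds is None:
        bounds = ((s1.min(), s1.max()), (s2.min(), s2.max()))
    ax1 = AxisSpec(bounds[0][0], bounds[0][1], n_intervals)
    ax2 = AxisSpec(bounds[1][0], bounds[1][1], n_intervals)
    b1 = assign_bin(s1, ax1)
    b2 = assign_bin(s2, ax2)
    ccell = b1 * n_intervals + b2
    geo_to_climate = pd.Series(ccell, index=scores.index, name="climate_cell_id")
    members: dict[int, np.ndarray] = {}
    order = np.argsort(ccell, kind="stable")
    idx_sorted = scores.index.to_numpy()[order]
    cc_sorted = ccell[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cc_sorted) != 0])
    bounds_idx = np.r_[starts, len(cc_sorted)]
    for a, b in zip(bounds_idx[:-1], bounds_idx[1:]):
        members[int(cc_sorted[a])] = idx_sorted[a:b]
    rows = []
    for cc in sorted(members):
        m = members[cc]
        rows.append(
            {
                "climate_cell_id": cc,
                "mean_pc1": float(scores.loc[m, axis_cols[0]].mean()),
                "mean_pc2": float(scores.loc[m, axis_cols[1]].mean()),
                "n_members": len(m),
            }
        )
    cell_means = pd.DataFrame(rows)
    out_scores = scores[list(axis_cols)].copy()
    out_scores.columns = ["pc1", "pc2"]
    return ClimateSpaceGrid(
        axis1=ax1,
        axis2=ax2,
        geo_to_climate=geo_to_climate,
        members=members,
        cell_means=cell_means,
        scores=out_scores,
    )
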