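"""Cubic regression spline basis with a second-derivative penalty.

The basis is parameterized by the function's values at the knots (the
"cardinal" natural-cubic-spline parameterization): given knots x_1 < ... <
x_k and coefficients beta_j = f(x_j), the curve is the natural cubic spline
interpolating those values, and the wiggliness penalty int f''(t)^2 dt is
the quadratic form beta' S beta with S = D' B^{-1} D, where D and B are the
standard banded matrices built from the knot spacings.  Outside the knot
range the spline extends linearly (natural boundary conditions).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve


class CubicRegressionSpline:
    """Natural cubic regression spline on fixed knots.

    Parameters
    ----------
    knots : array-like
        Strictly increasing knot locations; the basis dimension equals the
        number of knots.
    """

    def __init__(self, knots):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or len(knots) < 3:
            raise ValueError("need at least 3 distinct knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        k = len(knots)
        h = np.diff(knots)
        d_mat = np.zeros((k - 2, k))
        b_mat = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            d_mat[i, i] = 1.0 / h[i]
            d_mat[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            d_mat[i, i + 2] = 1.0 / h[i + 1]
            b_mat[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                b_mat[i, i + 1] = h[i + 1] / 6.0
                b_mat[i + 1, i] = h[i + 1] / 6.0
        f_inner = solve(b_mat, d_mat, assume_a="pos")
        # second derivatives at the knots as a linear map of the values;
        # natural conditions pin the end second derivatives at zero
        self._f_full = np.vstack([np.zeros(k), f_inner, np.zeros(k)])
        self.penalty = d_mat.T @ f_inner  # = D' B^{-1} D, symmetric PSD
        self.penalty = 0.5 * (self.penalty + self.penalty.T)
        self._h = h

    @classmethod
    def from_quantiles(cls, x, k: int = 4) -> "CubicRegressionSpline":
        """Knots at evenly spaced quantiles of the data."""
        if k < 3:
            raise ValueError("basis dimension k must be >= 3")
        knots = np.unique(np.quantile(np.asarray(x, dtype=float), np.linspace(0, 1, k)))
        if len(knots) < 3:
            raise ValueError(
                f"predictor has too few distinct quantile knots ({len(knots)}) for k={k}"
            )
        return cls(knots)

    @property
    def k(self) -> int:
        return len(self.knots)

    def _rows_in_range(self, x: np.ndarray) -> np.ndarray:
        kn, h, ff = self.knots, self._h, self._f_full
        n, k = len(x), self.k
        out = np.zeros((n, k))
        j = np.clip(np.searchsorted(kn, x, side="right") - 1, 0, k - 2)
        for jj in range(k - 1):
            m = j == jj
            if not m.any():
                continue
            xm = x[m]
            lo, hi, hh = kn[jj], kn[jj + 1], h[jj]
            am = (hi - xm) / hh
            ap = (xm - lo) / hh
            cm = ((hi - xm) ** 3 / hh - hh * (hi - xm)) / 6.0
            cp = ((xm - lo) ** 3 / hh - hh * (xm - lo)) / 6.0
            rows = np.zeros((m.sum(), k))
            rows[:, jj] += am
            rows[:, jj + 1] += ap
            rows += cm[:, None] * ff[jj][None, :]
            rows += cp[:, None] * ff[jj + 1][None, :]
            out[m] = rows
        return out

    def _deriv_row(self, x0: float, j: int) -> np.ndarray:
        kn, h, ff = self.knots, self._h, self._f_full
        lo, hi, hh = kn[j], kn[j + 1], h[j]
        row = np.zeros(self.k)
        row[j] += -1.0 / hh
        row[j + 1] += 1.0 / hh
        dcm = (-3.0 * (hi - x0) ** 2 / hh + hh) / 6.0
        dcp = (3.0 * (x0 - lo) ** 2 / hh - hh) / 6.0
        row += dcm * ff[j]
        row += dcp * ff[j + 1]
        return row

    def design(self, x) -> np.ndarray:
        """Evaluate the k basis functions at x (linear extension outside)."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        if not np.isfinite(x).all():
            raise ValueError("non-finite values passed to spline design")
        kn = self.knots
        xc = np.clip(x, kn[0], kn[-1])
        out = self._rows_in_range(xc)
        below = x < kn[0]
        if below.any():
            base = self._rows_in_range(np.array([kn[0]]))[0]
            d = self._deriv_row(kn[0], 0)
            out[below] = base + (x[below] - kn[0])[:, None] * d[None, :]
        above = x > kn[-1]
        if above.any():
            base = self._rows_in_range(np.array([kn[-1]]))[0]
            d = self._deriv_row(kn[-1], self.k - 2)
            out[above] = base + (x[above] - kn[-1])[:, None] * d[None, :]
        return out[0] if scalar else out
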