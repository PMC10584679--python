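"""Minimal diagnostic figures for climate-space analyses."""

from __future__ import annotations

import numpy as np


def plot_climate_surface(space, values, ax=None, cmap="viridis", label=None):
    """Heatmap of a per-climate-cell quantity on the gridded climate plane.

    ``values`` is a mapping / pandas Series keyed by climate_cell_id.
    Empty climate cells stay blank.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n1, n2 = space.axis1.n_intervals, space.axis2.n_intervals
    img = np.full((n2, n1), np.nan)
    for cc in space.members:
        if cc in values:
            i1, i2 = space.bin_indices(cc)
            img[i2, i1] = values[cc]
    extent = (space.axis1.lo, space.axis1.hi, space.axis2.lo, space.axis2.hi)
    m = ax.imshow(img, origin="lower", extent=extent, aspect="auto", cmap=cmap)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.figure.colorbar(m, ax=ax, label=label)
    return ax


def plot_partial_residuals(results, term, ax=None):
    """Partial-residual scatter for one smooth with its fitted curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pr = results.partial_residuals(term)
    ax.scatter(pr["x"], pr["partial_residual"], s=10, alpha=0.5)
    order = np.argsort(pr["x"].to_numpy())
    curve = results.term_contribution(term)[order]
    ax.plot(pr["x"].to_numpy()[order], curve, color="C1")
    ax.set_xlabel(term)
    ax.set_ylabel("partial residual (link scale)")
    return ax
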