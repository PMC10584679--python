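"""Equal-area geographic grid container.

A :class:`GeoGrid` holds one row per land cell of an equal-area
latitude-longitude grid (Behrmann-like: latitude bands slice sin(latitude)
evenly, so every cell covers the same surface area).  Each cell carries its
grid indices, centroid coordinates, land area and a vector of climate
variable values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088

_CORE_COLUMNS = ["cell_id", "row", "col", "lon", "lat", "area_km2"]


@dataclass
class GeoGrid:
    """Land cells of an equal-area grid with per-cell climate values.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per land cell with columns ``cell_id, row, col, lon, lat,
        area_km2`` followed by one column per climate variable.
    n_rows, n_cols : int
        Shape of the full (land + ocean) grid; ``row`` runs 0 (northernmost
        band) to ``n_rows - 1``, ``col`` 0 to ``n_cols - 1`` west to east.
    var_names : list of str
        Names of the climate variable columns, in order.
    """

    table: pd.DataFrame
    n_rows: int
    n_cols: int
    var_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _CORE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GeoGrid table missing columns: {missing}")
        t = self.table
        if t["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id in GeoGrid table")
        if ((t["lat"] < -90) | (t["lat"] > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((t["lon"] < -180) | (t["lon"] >= 180)).any():
            raise ValueError("longitude outside [-180, 180)")
        if (t["area_km2"] <= 0).any():
            raise ValueError("non-positive cell area")
        for v in self.var_names:
            if v not in t.columns:
                raise ValueError(f"variable column {v!r} missing from table")
            if not np.isfinite(t[v].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite values in variable {v!r}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.table["cell_id"].to_numpy()

    @property
    def total_land_area_km2(self) -> float:
        return float(self.table["area_km2"].sum())

    def climate_table(self) -> pd.DataFrame:
        """Per-cell climate variable values, indexed by ``cell_id``."""
        return self.table.set_index("cell_id")[self.var_names]

    def rowcol_index(self) -> dict[int, tuple[int, int]]:
        """Map ``cell_id`` -> ``(row, col)``."""
        t = self.table
        return dict(
            zip(t["cell_id"].to_numpy(), zip(t["row"].to_numpy(), t["col"].to_numpy()))
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write the grid as CSV with a header comment carrying grid shape."""
        with open(path, "w") as fh:
            fh.write(f"# n_rows={self.n_rows} n_cols={self.n_cols}\n")
            fh.write(f"# vars={','.join(self.var_names)}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "GeoGrid":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh)
        if "n_rows" not in meta or "n_cols" not in meta:
            raise ValueError(f"{path}: missing grid-shape header comment")
        var_names = [v for v in meta.get("vars", "").split(",") if v]
        return cls(
            table=table,
            n_rows=int(meta["n_rows"]),
            n_cols=int(meta["n_cols"]),
            var_names=var_names,
        )


def equal_area_latitudes(n_bands: int) -> tuple[np.ndarray, np.ndarray]:
    """Latitude band edges and centroids for an equal-area grid.

    Bands partition sin(latitude) into ``n_bands`` equal slices, so each
    band (and hence each cell, with uniform longitude spacing) covers the
    same surface area.  Returns ``(edges_deg, centroids_deg)`` ordered
    north to south (row 0 = northernmost band).
    """
    s_edges = np.linspace(1.0, -1.0, n_bands + 1)
    edges = np.degrees(np.arcsin(s_edges))
    s_mid = 0.5 * (s_edges[:-1] + s_edges[1:])
    centroids = np.degrees(np.arcsin(s_mid))
    return edges, centroids


def cell_area_km2(n_rows: int, n_cols: int) -> float:
    """Area of one cell of an equal-area grid covering the full sphere."""
    return 4.0 * np.pi * EARTH_RADIUS_KM**2 / (n_rows * n_cols)
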