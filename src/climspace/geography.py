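"""Geography of climate: fragments, area, and geodesic isolation.

Each climate cell (a bin of the 2-D climate space) maps back to a scattered
set of geographic cells.  This module measures that geography: the total
land area of a climate, its connected fragments on the geographic grid, the
mean great-circle distance among fragments (climate isolation) or among all
member cells, and the mean absolute latitude of the climate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from climspace.grid import EARTH_RADIUS_KM, GeoGrid
from climspace.space import ClimateSpaceGrid

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- distances
def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or numpy arrays (broadcast).  Raises on non-finite or
    out-of-range coordinates.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(a, dtype=float) for a in (lon1, lat1, lon2, lat2))
    for a in (lon1, lat1, lon2, lat2):
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite coordinate")
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon1) > 360) or np.any(np.abs(lon2) > 360):
        raise ValueError("longitude outside sensible range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return float(d) if d.ndim == 0 else d


def pairwise_haversine_km(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Symmetric matrix of great-circle distances among points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def _mean_pairwise(lons: np.ndarray, lats: np.ndarray) -> float:
    n = len(lons)
    if n < 2:
        return 0.0
    d = pairwise_haversine_km(lons, lats)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


# ----------------------------------------------------------------- fragments
@dataclass(frozen=True)
class Fragment:
    """One maximal connected patch of geographic cells sharing a climate."""

    cell_ids: tuple
    centroid_lon: float
    centroid_lat: float
    area_km2: float


def _centroid(lons, lats, weights) -> tuple[float, float]:
    # area-weighted mean on the sphere via 3-D unit vectors: immune to the
    # antimeridian and to longitude averaging artifacts
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    w = np.asarray(weights, dtype=float)
    x = np.sum(w * np.cos(phi) * np.cos(lam))
    y = np.sum(w * np.cos(phi) * np.sin(lam))
    z = np.sum(w * np.sin(phi))
    norm = np.sqrt(x * x + y * y + z * z)
    if norm < 1e-12:  # degenerate (antipodal cancellation): fall back
        return float(lons[0]), float(lats[0])
    lon = np.degrees(np.arctan2(y, x))
    lat = np.degrees(np.arcsin(np.clip(z / norm, -1, 1)))
    if lon >= 180.0:
        lon -= 360.0
    return float(lon), float(lat)


def _neighbor_offsets(adjacency: str) -> list[tuple[int, int]]:
    if adjacency == "rook":
        return [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if adjacency == "queen":
        return [
            (-1, -1), (-1, 0), (-1, 1),
            (0, -1), (0, 1),
            (1, -1), (1, 0), (1, 1),
        ]
    raise ValueError(f"unknown adjacency {adjacency!r}; use 'rook' or 'queen'")


def find_fragments(
    space: ClimateSpaceGrid,
    grid: GeoGrid,
    adjacency: str = "queen",
    wrap: bool = True,
) -> dict[int, list[Fragment]]:
    """Connected components of each climate cell's member geographic cells.

    Two member cells are connected when adjacent on the geographic grid
    under ``adjacency`` ('queen' = 8 neighbours, 'rook' = 4).  With ``wrap``
    the first and last columns of a row are adjacent (antimeridian wrap);
    there is no polar wrap.  Fragments are ordered by their smallest member
    ``cell_id`` so the labelling is deterministic.
    """
    offsets = _neighbor_offsets(adjacency)
    t = grid.table
    pos = {
        int(cid): (int(r), int(c))
        for cid, r, c in zip(t["cell_id"], t["row"], t["col"])
    }
    lon = dict(zip(t["cell_id"].astype(int), t["lon"].astype(float)))
    lat = dict(zip(t["cell_id"].astype(int), t["lat"].astype(float)))
    area = dict(zip(t["cell_id"].astype(int), t["area_km2"].astype(float)))
    n_cols = grid.n_cols

    out: dict[int, list[Fragment]] = {}
    for ccell, members in space.members.items():
        members = [int(m) for m in members]
        for m in members:
            if m not in pos:
                raise ValueError(f"member cell {m} missing row/col on the grid")
        member_set = set(members)
        rc_to_id = {pos[m]: m for m in members}
        g = nx.Graph()
        g.add_nodes_from(members)
        for m in members:
            r, c = pos[m]
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if wrap:
                    c2 %= n_cols
                elif c2 < 0 or c2 >= n_cols:
                    continue
                nb = rc_to_id.get((r2, c2))
                if nb is not None and nb in member_set:
                    g.add_edge(m, nb)
        frags = []
        for comp in nx.connected_components(g):
            ids = tuple(sorted(comp))
            lons = [lon[i] for i in ids]
            lats = [lat[i] for i in ids]
            areas = [area[i] for i in ids]
            clon, clat = _centroid(lons, lats, areas)
            frags.append(
                Fragment(
                    cell_ids=ids,
                    centroid_lon=clon,
                    centroid_lat=clat,
                    area_km2=float(sum(areas)),
                )
            )
        frags.sort(key=lambda f: f.cell_ids[0])
        out[ccell] = frags
    return out


# ----------------------------------------------------------- per-cell record
def compute_cell_geography(
    space: ClimateSpaceGrid,
    grid: GeoGrid,
    fragments: dict[int, list[Fragment]],
) -> pd.DataFrame:
    """Area, fragment count, isolation metrics and |latitude| per climate cell.

    Returns a DataFrame with one row per non-empty climate cell:
    ``climate_cell_id, area_km2, n_fragments, isolation_frag_km,
    isolation_allcells_km, mean_abs_lat``.  Single-fragment climates take
    ``isolation_frag_km = 0`` (convention: no between-fragment distance
    exists), and single-member climates take ``isolation_allcells_km = 0``.
    """
    t = grid.table.set_index("cell_id")
    rows = []
    for ccell in sorted(space.members):
        members = np.asarray(space.members[ccell], dtype=int)
        sub = t.loc[members]
        frags = fragments[ccell]
        if len(frags) >= 2:
            iso_frag = _mean_pairwise(
                np.array([f.centroid_lon for f in frags]),
                np.array([f.centroid_lat for f in frags]),
            )
        else:
            iso_frag = 0.0
        iso_all = _mean_pairwise(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        rows.append(
            {
                "climate_cell_id": ccell,
                "area_km2": float(sub["area_km2"].sum()),
                "n_fragments": len(frags),
                "isolation_frag_km": iso_frag,
                "isolation_allcells_km": iso_all,
                "mean_abs_lat": float(np.abs(sub["lat"]).mean()),
            }
        )
    return pd.DataFrame(rows)


def geography_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among the geography metrics over climate cells.

    Reports, on raw (untransformed) values: area vs fragment count,
    all-cells vs between-fragment isolation, and area / fragment count vs
    isolation.  A pair where one variable has zero variance gets ``r = NaN``
    and is flagged, not raised.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 climate cells for correlations")
    pairs = [
        ("area_km2", "n_fragments"),
        ("isolation_allcells_km", "isolation_frag_km"),
        ("area_km2", "isolation_frag_km"),
        ("n_fragments", "isolation_frag_km"),
    ]
    rows = []
    for x, y in pairs:
        xv = records[x].to_numpy(dtype=float)
        yv = records[y].to_numpy(dtype=float)
        if np.std(xv) == 0 or np.std(yv) == 0:
            r, flag = np.nan, "zero-variance input"
            logger.warning("correlation %s vs %s: zero variance", x, y)
        else:
            r, flag = float(np.corrcoef(xv, yv)[0, 1]), ""
        rows.append({"x": x, "y": y, "pearson_r": r, "transform": "raw", "note": flag})
    return pd.DataFrame(rows)
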