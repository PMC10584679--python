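"""Synthetic worlds: equal-area grids, correlated climate fields, ranges.

Stands in for gridded real-world inputs (climate rasters and gridded range
maps).  Three generators:

* :func:`generate_world` — an equal-area grid whose land cells carry a
  suite of climate variables built from two spatially autocorrelated latent
  fields (a temperature-like field with a latitudinal gradient and a
  moisture-like field with an equatorial bump), so that two principal
  components capture most of the variance.
* :func:`generate_species_ranges` — niche-based species ranges grown by a
  spreading-dye process through climatically suitable cells, yielding a
  presence-absence matrix whose richness depends on how common each climate
  is.
* :func:`make_benchmark_scenario` — richness drawn directly from a Poisson
  log-linear model of climate-cell area, isolation and position, with the
  generating coefficients recorded for parameter-recovery checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from climspace.grid import GeoGrid, cell_area_km2, equal_area_latitudes
from climspace.geography import haversine_km, _neighbor_offsets
from climspace.space import ClimateSpaceGrid
from climspace.diversity import PresenceAbsence

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------- params
@dataclass
class WorldParams:
    """Parameters of the synthetic equal-area world.

    ``temp_gradient`` is in temperature units per degree of |latitude|
    (default 0.45: ~28 at the equator falling to ~-12 at the poles);
    ``grf_length_scale`` is the autocorrelation length of the latent random
    fields in km; ``grf_sd`` their standard deviation in the latent units.
    """

    n_lat_bands: int = 24
    n_lon: int = 48
    land_fraction: float = 0.7
    temp_gradient: float = 0.45
    grf_length_scale: float = 2000.0
    grf_sd: float = 3.0
    n_variables: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_lat_bands < 4 or self.n_lon < 8:
            raise ValueError("need n_lat_bands >= 4 and n_lon >= 8")
        if not (0 < self.land_fraction <= 1):
            raise ValueError("land_fraction must be in (0, 1]")
        if self.grf_length_scale <= 0:
            raise ValueError("grf_length_scale must be positive")
        if self.n_variables < 2:
            raise ValueError("need at least 2 climate variables")


@dataclass
class NicheParams:
    """Parameters of the niche-based range generator.

    ``breadth`` gives the ellipse semi-axes of climatic suitability in PC
    units; ``target_range_size`` is either a fixed cell count or
    ``("lognormal", mean_log, sd_log)`` / ``("uniform", lo, hi)``.
    ``optimum_density='occupied'`` draws optima uniformly over non-empty
    climate cells so no species targets structurally empty climate.
    """

    n_species: int = 200
    optimum_density: str = "occupied"
    breadth: tuple[float, float] = (1.5, 1.5)
    target_range_size: object = ("lognormal", 3.7, 0.8)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 0:
            raise ValueError("n_species must be >= 0")
        if any(b <= 0 for b in self.breadth):
            raise ValueError("breadth semi-axes must be positive")
        if isinstance(self.target_range_size, (int, np.integer)):
            if self.target_range_size < 1:
                raise ValueError("target_range_size must be >= 1")


@dataclass
class TruthRecord:
    """Provenance of a synthetic dataset, sufficient to recompute truth."""

    kind: str  # "range-based" | "direct-poisson"
    coefficients: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    n_dropped_species: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


# --------------------------------------------------------------- GRF helper
def _gaussian_random_field(
    lons: np.ndarray, lats: np.ndarray, length_scale_km: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth white noise with a great-circle Gaussian kernel; unit variance.

    Only the autocorrelation length matters downstream, so kernel smoothing
    of white noise (exact, O(n^2)) is used rather than a spectral method.
    """
    n = len(lons)
    w = rng.standard_normal(n)
    d = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    k = np.exp(-0.5 * (d / length_scale_km) ** 2)
    f = k @ w
    f = (f - f.mean()) / f.std()
    return f


# 12 fixed variable definitions: (name, weight on T latent, weight on M latent)
_VARIABLE_DEFS = [
    ("temp_mean", 1.0, 0.0),
    ("temp_diurnal_range", -0.30, -0.40),
    ("isothermality", 0.50, 0.20),
    ("temp_seasonality", -0.90, 0.10),
    ("temp_max_warmest", 0.95, 0.10),
    ("temp_min_coldest", 0.90, -0.15),
    ("temp_annual_range", -0.80, -0.20),
    ("prec_annual", 0.15, 1.0),
    ("prec_wettest", 0.20, 0.90),
    ("prec_driest", -0.10, 0.80),
    ("prec_seasonality", 0.30, -0.60),
    ("pet", 0.85, 0.30),
]


def generate_world(params: WorldParams) -> GeoGrid:
    """Equal-area world with autocorrelated, correlated climate variables.

    Latitude bands slice sin(latitude) evenly so every cell has the same
    area.  Land cells are the top ``land_fraction`` of a smooth random
    field (contiguous-ish continents).  Each climate variable is a fixed
    linear blend of the temperature-like and moisture-like latent fields
    plus small independent noise (5% of the blend's dispersion), so the
    first two principal components absorb most of the variance.
    Deterministic given ``params.seed``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    _, lat_centroids = equal_area_latitudes(p.n_lat_bands)
    lon_edges = np.linspace(-180.0, 180.0, p.n_lon + 1)
    lon_centroids = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    rows, cols = np.meshgrid(
        np.arange(p.n_lat_bands), np.arange(p.n_lon), indexing="ij"
    )
    rows, cols = rows.ravel(), cols.ravel()
    lats = lat_centroids[rows]
    lons = lon_centroids[cols]
    n_total = len(rows)

    # land mask from a smooth field: deterministic top-k by value then index
    if p.land_fraction >= 1.0:
        land = np.ones(n_total, dtype=bool)
    else:
        land_field = _gaussian_random_field(lons, lats, p.grf_length_scale, rng)
        n_land = max(2, int(round(p.land_fraction * n_total)))
        order = np.lexsort((np.arange(n_total), -land_field))
        land = np.zeros(n_total, dtype=bool)
        land[order[:n_land]] = True
    if land.sum() < 2:
        raise ValueError("degenerate world: fewer than 2 land cells")

    g_t = _gaussian_random_field(lons, lats, p.grf_length_scale, rng)
    g_m = _gaussian_random_field(lons, lats, p.grf_length_scale, rng)
    t_latent = 28.0 - p.temp_gradient * np.abs(lats) + p.grf_sd * g_t
    m_latent = 15.0 * np.exp(-((lats / 25.0) ** 2)) + p.grf_sd * g_m

    var_defs = _VARIABLE_DEFS[: p.n_variables]
    if p.n_variables > len(_VARIABLE_DEFS):
        extra = p.n_variables - len(_VARIABLE_DEFS)
        angles = np.linspace(0.1, np.pi / 2 - 0.1, extra)
        var_defs = var_defs + [
            (f"extra_{i + 1}", float(np.cos(a)), float(np.sin(a)))
            for i, a in enumerate(angles)
        ]

    data = {}
    for name, a_t, a_m in var_defs:
        combo = a_t * t_latent + a_m * m_latent
        sd = combo[land].std()
        noise = rng.standard_normal(n_total) * (0.05 * sd)
        data[name] = combo + noise

    table = pd.DataFrame(
        {
            "cell_id": rows * p.n_lon + cols,
            "row": rows,
            "col": cols,
            "lon": lons,
            "lat": lats,
            "area_km2": cell_area_km2(p.n_lat_bands, p.n_lon),
            **data,
        }
    )
    table = table[land].reset_index(drop=True)
    return GeoGrid(
        table=table,
        n_rows=p.n_lat_bands,
        n_cols=p.n_lon,
        var_names=[v[0] for v in var_defs],
    )


# ------------------------------------------------------------------- ranges
def _draw_range_size(spec, rng: np.random.Generator, n_cells: int) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    kind = spec[0]
    if kind == "lognormal":
        return int(np.clip(round(rng.lognormal(spec[1], spec[2])), 1, n_cells))
    if kind == "uniform":
        return int(rng.integers(spec[1], spec[2] + 1))
    raise ValueError(f"unknown target_range_size spec {spec!r}")


def generate_species_ranges(
    grid: GeoGrid,
    space: ClimateSpaceGrid,
    niche: NicheParams,
    adjacency: str = "queen",
    wrap: bool = True,
) -> tuple[PresenceAbsence, TruthRecord]:
    """Niche-based contiguous ranges via spreading dye through suitable cells.

    For each species: draw a climatic optimum (by default the mean-PC
    coordinates of a uniformly drawn non-empty climate cell), mark cells
    inside the breadth ellipse in PC space as suitable, then grow a
    connected range from a random suitable start cell through suitable
    neighbours until the target size or exhaustion.  Species with no
    suitable cell are dropped (counted in the TruthRecord).
    """
    rng = np.random.default_rng(niche.seed)
    scores = space.scores.loc[grid.cell_ids]
    pc1 = scores["pc1"].to_numpy()
    pc2 = scores["pc2"].to_numpy()
    cell_ids = grid.cell_ids.astype(int)
    pos = grid.rowcol_index()
    rc_to_id = {pos[c]: c for c in cell_ids}
    offsets = _neighbor_offsets(adjacency)
    n_cols = grid.n_cols
    b1, b2 = niche.breadth

    cc_ids = sorted(space.members)
    mean_pc = space.cell_means.set_index("climate_cell_id")

    triplets = []
    n_dropped = 0
    for sp in range(niche.n_species):
        if niche.optimum_density == "occupied":
            cc = cc_ids[int(rng.integers(len(cc_ids)))]
            o1 = float(mean_pc.loc[cc, "mean_pc1"])
            o2 = float(mean_pc.loc[cc, "mean_pc2"])
        elif niche.optimum_density == "uniform_plane":
            o1 = float(rng.uniform(space.axis1.lo, space.axis1.hi))
            o2 = float(rng.uniform(space.axis2.lo, space.axis2.hi))
        else:
            raise ValueError(f"unknown optimum_density {niche.optimum_density!r}")
        suitable = ((pc1 - o1) / b1) ** 2 + ((pc2 - o2) / b2) ** 2 <= 1.0
        suit_ids = set(cell_ids[suitable].tolist())
        if not suit_ids:
            n_dropped += 1
            logger.info("species %d dropped: no climatically suitable cell", sp)
            continue
        target = _draw_range_size(niche.target_range_size, rng, len(suit_ids))
        start = sorted(suit_ids)[int(rng.integers(len(suit_ids)))]
        occupied = {start}
        frontier = [start]
        while len(occupied) < target and frontier:
            i = int(rng.integers(len(frontier)))
            cell = frontier[i]
            r, c = pos[cell]
            added = False
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if wrap:
                    c2 %= n_cols
                elif c2 < 0 or c2 >= n_cols:
                    continue
                nb = rc_to_id.get((r2, c2))
                if nb is not None and nb in suit_ids and nb not in occupied:
                    occupied.add(nb)
                    frontier.append(nb)
                    added = True
                    break
            if not added:
                frontier.pop(i)
        for cell in sorted(occupied):
            triplets.append((sp, cell))

    if triplets:
        df = pd.DataFrame(triplets, columns=["species_id", "cell_id"])
    else:
        df = pd.DataFrame(columns=["species_id", "cell_id"])
    pam = PresenceAbsence.from_triplets(df)
    truth = TruthRecord(
        kind="range-based",
        coefficients={},
        seeds={"niche": niche.seed},
        n_dropped_species=n_dropped,
    )
    return pam, truth


# -------------------------------------------------------- direct benchmark
def benchmark_cell_table(n: int = 300, seed: int = 0) -> pd.DataFrame:
    """Climate-cell summary table with mutually independent predictors.

    Generates plausible magnitudes — log-uniform areas (1e4..1e7 km²),
    folded-normal between-fragment isolation (scale 2000 km), standard-
    normal PC coordinates — drawn independently so deviance partitions have
    no built-in joint share.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "climate_cell_id": np.arange(n),
            "area_km2": 10 ** rng.uniform(4, 7, n),
            "isolation_frag_km": np.abs(rng.normal(0, 2000, n)),
            "mean_pc1": rng.standard_normal(n),
            "mean_pc2": rng.standard_normal(n),
        }
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def make_benchmark_scenario(
    space_summary: pd.DataFrame,
    coeffs: dict,
    seed: int = 0,
) -> tuple[np.ndarray, TruthRecord]:
    """Draw per-climate-cell richness from a known Poisson log-linear model.

    ``coeffs`` maps {'beta0', 'beta_area', 'beta_isolation', 'beta_pc1',
    'beta_pc2'} to floats; the log mean is ``beta0 + beta_area*z(log area)
    + beta_isolation*z(isolation) + beta_pc1*z(pc1) + beta_pc2*z(pc2)``
    with z = standardization over the table's cells.  Returns the richness
    vector (aligned with ``space_summary`` rows) and a TruthRecord.
    """
    c = {
        "beta0": 0.0,
        "beta_area": 0.0,
        "beta_isolation": 0.0,
        "beta_pc1": 0.0,
        "beta_pc2": 0.0,
    }
    unknown = set(coeffs) - set(c)
    if unknown:
        raise ValueError(f"unknown coefficients: {sorted(unknown)}")
    c.update(coeffs)
    g = (
        c["beta0"]
        + c["beta_area"] * _zscore(np.log(space_summary["area_km2"].to_numpy(dtype=float)))
        + c["beta_isolation"] * _zscore(space_summary["isolation_frag_km"].to_numpy(dtype=float))
        + c["beta_pc1"] * _zscore(space_summary["mean_pc1"].to_numpy(dtype=float))
        + c["beta_pc2"] * _zscore(space_summary["mean_pc2"].to_numpy(dtype=float))
    )
    if not np.isfinite(g).all():
        raise ValueError("non-finite log mean in benchmark scenario")
    rng = np.random.default_rng(seed)
    richness = rng.poisson(np.exp(g))
    truth = TruthRecord(kind="direct-poisson", coefficients=c, seeds={"richness": seed})
    return richness, truth
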