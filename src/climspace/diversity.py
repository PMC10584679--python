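"""Richness and multi-site beta-diversity within climate cells.

Richness of a climate cell is the number of species occurring in any of
its member geographic cells.  Compositional dissimilarity among the member
cells is decomposed into turnover (multi-site Simpson dissimilarity) and
nestedness (Sorensen minus Simpson), following the Baselga decomposition:
with S_i the richness of site i, S_T the pooled richness, b_ij = |i \\ j|,
M = sum over pairs of min(b_ij, b_ji), X = sum of max(b_ij, b_ji) and
K = sum_i S_i - S_T,

    beta_SIM = M / (K + M)
    beta_SOR = (M + X) / (2 K + M + X)
    beta_SNE = beta_SOR - beta_SIM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from climspace.space import ClimateSpaceGrid

logger = logging.getLogger(__name__)


@dataclass
class PresenceAbsence:
    """Sparse species x geographic-cell incidence.

    ``triplets`` holds the unique (species_id, cell_id) pairs; species and
    cell indexers are derived lazily.  Duplicate pairs in the input are
    collapsed (counted in the log).
    """

    triplets: pd.DataFrame  # columns species_id, cell_id (unique pairs)

    @classmethod
    def from_triplets(cls, df: pd.DataFrame) -> "PresenceAbsence":
        if not {"species_id", "cell_id"}.issubset(df.columns):
            raise ValueError("triplet table needs species_id and cell_id columns")
        n0 = len(df)
        out = df[["species_id", "cell_id"]].drop_duplicates().reset_index(drop=True)
        dropped = n0 - len(out)
        if dropped:
            logger.warning("collapsed %d duplicate (species, cell) pairs", dropped)
        return cls(triplets=out)

    @property
    def species_ids(self) -> np.ndarray:
        return np.unique(self.triplets["species_id"].to_numpy())

    @property
    def cell_ids(self) -> np.ndarray:
        return np.unique(self.triplets["cell_id"].to_numpy())

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_sparse(self) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
        """(incidence, species index, cell index) with species as rows."""
        species = self.species_ids
        cells = self.cell_ids
        si = pd.Index(species).get_indexer(self.triplets["species_id"])
        ci = pd.Index(cells).get_indexer(self.triplets["cell_id"])
        mat = sp.csr_matrix(
            (np.ones(len(si), dtype=np.int8), (si, ci)),
            shape=(len(species), len(cells)),
        )
        return mat, species, cells

    def species_by_cell(self) -> dict:
        """Map cell_id -> set of species_id."""
        return {
            cid: set(grp["species_id"])
            for cid, grp in self.triplets.groupby("cell_id")
        }

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        self.triplets.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PresenceAbsence":
        return cls.from_triplets(pd.read_csv(path))


def richness_per_climate_cell(
    pam: PresenceAbsence, space: ClimateSpaceGrid
) -> pd.Series:
    """Species count per climate cell (union over member geographic cells).

    Every non-empty climate cell appears in the result; cells whose members
    hold no occurrences are reported as 0.  Occurrences in geographic cells
    unknown to the climate space raise, listing the offending ids.
    """
    trip = pam.triplets
    known = space.geo_to_climate.index
    unknown = np.setdiff1d(trip["cell_id"].unique(), known.to_numpy())
    if len(unknown) > 0:
        raise ValueError(
            f"occurrences reference cells absent from the grid: {unknown[:10].tolist()}"
        )
    cc = space.geo_to_climate.loc[trip["cell_id"]].to_numpy()
    richness = (
        pd.DataFrame({"climate_cell_id": cc, "species_id": trip["species_id"].to_numpy()})
        .groupby("climate_cell_id")["species_id"]
        .nunique()
    )
    all_cells = pd.Index(sorted(space.members), name="climate_cell_id")
    return richness.reindex(all_cells, fill_value=0).astype(int).rename("richness")


def pairwise_components(site_i: set, site_j: set) -> tuple[int, int, int]:
    """Shared and unique species counts between two sites: (a, b_ij, b_ji)."""
    a = len(site_i & site_j)
    return a, len(site_i) - a, len(site_j) - a


class BetaParts(NamedTuple):
    beta_sor: float
    beta_sim: float
    beta_sne: float


def multisite_beta(sites: list[set]) -> BetaParts:
    """Multi-site Sorensen/Simpson decomposition over a list of species sets.

    Requires >= 2 non-empty sites; otherwise the result is undefined and
    NaNs are returned (logged).  Order-invariant and deterministic.
    """
    sites = [s for s in sites if len(s) > 0]
    k = len(sites)
    if k < 2:
        logger.info("multisite_beta undefined: %d non-empty site(s)", k)
        return BetaParts(np.nan, np.nan, np.nan)
    all_species = sorted(set().union(*sites))
    idx = {s: i for i, s in enumerate(all_species)}
    inc = np.zeros((k, len(all_species)), dtype=np.int64)
    for i, s in enumerate(sites):
        inc[i, [idx[x] for x in s]] = 1
    s_i = inc.sum(axis=1)
    s_t = int((inc.sum(axis=0) > 0).sum())
    shared = inc @ inc.T
    b = s_i[:, None] - shared  # b[i, j] = |i \ j|
    iu = np.triu_indices(k, 1)
    m = np.minimum(b[iu], b.T[iu]).sum()
    x = np.maximum(b[iu], b.T[iu]).sum()
    kk = int(s_i.sum()) - s_t
    beta_sim = m / (kk + m) if (kk + m) > 0 else 0.0
    denom = 2 * kk + m + x
    beta_sor = (m + x) / denom if denom > 0 else 0.0
    return BetaParts(float(beta_sor), float(beta_sim), float(beta_sor - beta_sim))


def beta_per_climate_cell(
    pam: PresenceAbsence,
    space: ClimateSpaceGrid,
    resample_sites: int | None = None,
    n_resamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Beta decomposition among the member geographic cells of each climate cell.

    Sites are member cells holding at least one species (empty cells carry
    no compositional information).  Climate cells with fewer than 2 such
    sites get NaN betas.  With ``resample_sites`` set, each climate cell
    with more sites than that is repeatedly subsampled to exactly that many
    sites and the mean of each component over ``n_resamples`` draws is
    reported (seeded), for comparability across climate cells.
    """
    by_cell = pam.species_by_cell()
    rng = np.random.default_rng(seed)
    rows = []
    for cc in sorted(space.members):
        members = space.members[cc]
        sites = [by_cell[m] for m in members if m in by_cell and by_cell[m]]
        n_sites = len(sites)
        if n_sites < 2:
            parts = BetaParts(np.nan, np.nan, np.nan)
        elif resample_sites is not None and n_sites > resample_sites:
            acc = np.zeros(3)
            for _ in range(n_resamples):
                pick = rng.choice(n_sites, size=resample_sites, replace=False)
                acc += np.asarray(multisite_beta([sites[i] for i in pick]))
            parts = BetaParts(*(acc / n_resamples))
        else:
            parts = multisite_beta(sites)
        rows.append(
            {
                "climate_cell_id": cc,
                "n_sites": n_sites,
                "beta_sor": parts.beta_sor,
                "beta_sim": parts.beta_sim,
                "beta_sne": parts.beta_sne,
            }
        )
    return pd.DataFrame(rows)
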