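import numpy as np
import pytest

import climspace as cs


@pytest.fixture(scope="session")
def world():
    """Small equal-area world with continents and 12 correlated variables."""
    return cs.generate_world(cs.WorldParams(n_lat_bands=24, n_lon=48, seed=7))


@pytest.fixture(scope="session")
def pca(world):
    return cs.fit_pca(world.climate_table())


@pytest.fixture(scope="session")
def space20(pca):
    return cs.build_climate_grid(pca.scores, n_intervals=20)


@pytest.fixture(scope="session")
def pam(world, space20):
    pam, _ = cs.generate_species_ranges(
        world, space20, cs.NicheParams(n_species=150, seed=11)
    )
    return pam


@pytest.fixture(scope="session")
def cell_table(world, space20, pam):
    from climspace.pipeline import assemble_cell_table

    frags = cs.find_fragments(space20, world)
    geo = cs.compute_cell_geography(space20, world, frags)
    rich = cs.richness_per_climate_cell(pam, space20)
    beta = cs.beta_per_climate_cell(pam, space20)
    return assemble_cell_table(space20, geo, rich, beta)


@pytest.fixture(scope="session")
def benchmark_fit():
    """GAM fitted to a Poisson benchmark where only log-area is active."""
    table = cs.benchmark_cell_table(300, seed=1)
    richness, truth = cs.make_benchmark_scenario(
        table, {"beta0": np.log(50), "beta_area": 1.0}, seed=2
    )
    table = table.copy()
    table["richness"] = richness
    model = cs.PoissonGAM.from_cell_table(table)
    return model.fit(), table, truth
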