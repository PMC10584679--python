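"""Fragments, great-circle distances and per-climate-cell geography."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import climspace as cs
from climspace.grid import EARTH_RADIUS_KM, GeoGrid
from climspace.space import build_climate_grid


def _toy_grid(n_rows, n_cols, members_rc, area=12321.0):
    """GeoGrid holding exactly the given (row, col) cells."""
    rows = []
    lat_step = 180.0 / n_rows
    lon_step = 360.0 / n_cols
    for r, c in members_rc:
        rows.append(
            {
                "cell_id": r * n_cols + c,
                "row": r,
                "col": c,
                "lon": -180.0 + (c + 0.5) * lon_step,
                "lat": 90.0 - (r + 0.5) * lat_step,
                "area_km2": area,
            }
        )
    return GeoGrid(table=pd.DataFrame(rows), n_rows=n_rows, n_cols=n_cols)


def _space_of_single_climate(grid):
    """All cells of the grid mapped into one climate cell."""
    scores = pd.DataFrame(
        {"pc1": np.linspace(0, 1, len(grid)), "pc2": np.linspace(0, 1, len(grid))},
        index=grid.cell_ids,
    )
    return build_climate_grid(scores, n_intervals=1)


# ---------------------------------------------------------------- haversine
def test_haversine_closed_forms():
    assert cs.haversine_km(0, 0, 0, 0) == 0.0
    assert cs.haversine_km(0, 0, 180, 0) == pytest.approx(np.pi * EARTH_RADIUS_KM)
    assert cs.haversine_km(0, 0, 1, 0) == pytest.approx(
        np.pi / 180 * EARTH_RADIUS_KM
    )


def test_haversine_rejects_bad_coordinates():
    with pytest.raises(ValueError):
        cs.haversine_km(0, 91, 0, 0)
    with pytest.raises(ValueError):
        cs.haversine_km(np.nan, 0, 0, 0)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    lons=st.lists(st.floats(-180, 179.99), min_size=3, max_size=3),
    lats=st.lists(st.floats(-90, 90), min_size=3, max_size=3),
)
def test_haversine_metric_properties(lons, lats):
    d01 = cs.haversine_km(lons[0], lats[0], lons[1], lats[1])
    d10 = cs.haversine_km(lons[1], lats[1], lons[0], lats[0])
    d02 = cs.haversine_km(lons[0], lats[0], lons[2], lats[2])
    d12 = cs.haversine_km(lons[1], lats[1], lons[2], lats[2])
    assert d01 == pytest.approx(d10, abs=1e-9)
    assert d01 >= 0
    assert d02 <= d01 + d12 + 1e-6  # triangle inequality on the sphere


# ---------------------------------------------------------------- fragments
def test_fragments_row_example():
    grid = _toy_grid(1, 8, [(0, 0), (0, 1), (0, 3)])
    space = _space_of_single_climate(grid)
    frags = cs.find_fragments(space, grid, adjacency="rook", wrap=False)
    (fl,) = frags.values()
    assert [set(f.cell_ids) for f in fl] == [{0, 1}, {3}]


def test_fragments_antimeridian_wrap():
    grid = _toy_grid(1, 8, [(0, 0), (0, 7)])
    space = _space_of_single_climate(grid)
    fl = next(iter(cs.find_fragments(space, grid, wrap=True).values()))
    assert len(fl) == 1
    fl = next(iter(cs.find_fragments(space, grid, wrap=False).values()))
    assert len(fl) == 2


def _flood_fill_oracle(members_rc, n_cols, adjacency, wrap):
    """Independent fragment labelling by breadth-first flood fill."""
    from climspace.geography import _neighbor_offsets

    cells = set(members_rc)
    seen = set()
    comps = []
    for start in sorted(cells):
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            r, c = queue.pop()
            for dr, dc in _neighbor_offsets(adjacency):
                r2, c2 = r + dr, c + dc
                if wrap:
                    c2 %= n_cols
                elif not (0 <= c2 < n_cols):
                    continue
                if (r2, c2) in cells and (r2, c2) not in comp:
                    comp.add((r2, c2))
                    queue.append((r2, c2))
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


@pytest.mark.parametrize("adjacency,wrap", [("queen", True), ("rook", False)])
def test_fragments_match_flood_fill_oracle(adjacency, wrap):
    rng = np.random.default_rng(42)
    n_rows, n_cols = 12, 24
    for _ in range(50):
        k = int(rng.integers(3, 60))
        rc = {
            (int(r), int(c))
            for r, c in zip(rng.integers(0, n_rows, k), rng.integers(0, n_cols, k))
        }
        grid = _toy_grid(n_rows, n_cols, sorted(rc))
        space = _space_of_single_climate(grid)
        frags = next(
            iter(cs.find_fragments(space, grid, adjacency=adjacency, wrap=wrap).values())
        )
        got = {
            frozenset((cid // n_cols, cid % n_cols) for cid in f.cell_ids)
            for f in frags
        }
        assert got == _flood_fill_oracle(rc, n_cols, adjacency, wrap)


def test_fragment_invariants_on_synthetic_world(world, space20):
    frags = cs.find_fragments(space20, world)
    pos = world.rowcol_index()
    from climspace.geography import _neighbor_offsets

    for cc, fl in frags.items():
        members = set(space20.members[cc])
        union = set()
        for f in fl:
            assert not (union & set(f.cell_ids))  # disjoint
            union |= set(f.cell_ids)
        assert union == members
        # maximality: no adjacency between different fragments
        frag_of = {c: i for i, f in enumerate(fl) for c in f.cell_ids}
        rc_map = {pos[c]: c for c in members}
        for c in members:
            r, col = pos[c]
            for dr, dc in _neighbor_offsets("queen"):
                nb = rc_map.get((r + dr, (col + dc) % world.n_cols))
                if nb is not None:
                    assert frag_of[nb] == frag_of[c]


# ---------------------------------------------------------------- geography
def test_cell_geography_examples():
    grid = _toy_grid(1, 8, [(0, 0), (0, 1), (0, 3)], area=12321.0)
    space = _space_of_single_climate(grid)
    frags = cs.find_fragments(space, grid, adjacency="rook", wrap=False)
    rec = cs.compute_cell_geography(space, grid, frags).iloc[0]
    assert rec["area_km2"] == pytest.approx(3 * 12321.0)
    assert rec["n_fragments"] == 2


def test_single_fragment_isolation_is_zero(world, space20):
    frags = cs.find_fragments(space20, world)
    geo = cs.compute_cell_geography(space20, world, frags)
    single = geo[geo["n_fragments"] == 1]
    assert (single["isolation_frag_km"] == 0).all()
    singleton = geo.merge(
        space20.cell_means, on="climate_cell_id"
    ).query("n_members == 1")
    assert (singleton["isolation_allcells_km"] == 0).all()


def test_two_fragment_isolation_matches_arc():
    # two isolated equatorial cells one degree apart
    grid = _toy_grid(180, 360, [(89, 180), (89, 182)])
    space = _space_of_single_climate(grid)
    frags = cs.find_fragments(space, grid, adjacency="rook", wrap=False)
    rec = cs.compute_cell_geography(space, grid, frags).iloc[0]
    assert rec["n_fragments"] == 2
    assert rec["isolation_frag_km"] == pytest.approx(
        2 * np.pi / 180 * EARTH_RADIUS_KM * np.cos(np.radians(0.5)), rel=1e-4
    )


def test_area_conservation(world, space20):
    frags = cs.find_fragments(space20, world)
    geo = cs.compute_cell_geography(space20, world, frags)
    assert geo["area_km2"].sum() == pytest.approx(world.total_land_area_km2)


def test_geography_correlations_trivial_cases():
    rec = pd.DataFrame(
        {
            "area_km2": [1.0, 2.0, 3.0],
            "n_fragments": [2, 4, 6],
            "isolation_frag_km": [3.0, 2.0, 1.0],
            "isolation_allcells_km": [1.0, 1.5, 2.0],
        }
    )
    out = cs.geography_correlations(rec).set_index(["x", "y"])
    assert out.loc[("area_km2", "n_fragments"), "pearson_r"] == pytest.approx(1.0)
    assert out.loc[("area_km2", "isolation_frag_km"), "pearson_r"] == pytest.approx(-1.0)


def test_geography_correlations_recomputation(world, space20, tmp_path):
    frags = cs.find_fragments(space20, world)
    geo = cs.compute_cell_geography(space20, world, frags)
    path = tmp_path / "geo.csv"
    geo.to_csv(path, index=False)
    out = cs.geography_correlations(geo).set_index(["x", "y"])
    reread = pd.read_csv(path)
    expect = np.corrcoef(reread["area_km2"], reread["n_fragments"])[0, 1]
    assert out.loc[("area_km2", "n_fragments"), "pearson_r"] == pytest.approx(expect)
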