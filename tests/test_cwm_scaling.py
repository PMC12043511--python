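"""Crown geometry, trait resolution and CWM rasterization checks."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from canopyscale.cwm_scaling import (
    GENUS_MEAN,
    MISSING,
    SPECIES_MEAN,
    TraitLookup,
    crown_polygon,
    crown_polygons,
    crown_radius_from_allometry,
    pixel_cwm,
    plot_pixel_tree_areas,
    rasterize_landscape,
    resolve_trait,
)
from canopyscale.grids import PixelGrid
from canopyscale.synthetic_landscape import PlotInventory, TreeRecord


# ---------------------------------------------------------------------------
# allometry


def test_crown_radius_closed_form():
    # independent arithmetic: r = 0.5 * exp(0.6 * ln 30)
    expected = 0.5 * math.exp(0.6 * math.log(30.0))
    assert crown_radius_from_allometry(30.0, 0.5, 0.6) == pytest.approx(expected, rel=1e-12)
    poly = crown_polygon(0.0, 0.0, expected)
    assert poly.area == pytest.approx(math.pi * expected**2, rel=5e-3)


def test_crown_radius_degenerate_cases():
    assert crown_radius_from_allometry(0.0, 0.5, 0.6) == 0.0
    assert crown_polygon(3.0, 4.0, 0.0).area == 0.0
    assert crown_radius_from_allometry(17.0, 0.7, 0.0) == 0.7
    with pytest.raises(ValueError):
        crown_radius_from_allometry(-1.0, 0.5, 0.6)


def test_crown_polygon_area_within_half_percent():
    r = 4.2
    poly = crown_polygon(1.0, 2.0, r, n_vertices=64)
    assert abs(poly.area - math.pi * r**2) / (math.pi * r**2) < 0.005


# ---------------------------------------------------------------------------
# trait resolution


def _records(rows):
    return pd.DataFrame(rows, columns=["species", "genus", "leaf_n"])


def test_species_mean_over_records():
    table = _records([("A x", "A", 2.0), ("A x", "A", 4.0)])
    value, prov = resolve_trait("A x", "A", "leaf_n", table)
    assert value == 3.0 and prov == SPECIES_MEAN


def test_genus_mean_fallback():
    table = _records([("A x", "A", 1.0), ("A y", "A", 3.0)])
    value, prov = resolve_trait("A z", "A", "leaf_n", table)
    assert value == 2.0 and prov == GENUS_MEAN


def test_missing_when_species_and_genus_absent():
    table = _records([("A x", "A", 1.0)])
    value, prov = resolve_trait("B z", "B", "leaf_n", table)
    assert math.isnan(value) and prov == MISSING


def test_name_matching_normalizes_case_and_whitespace():
    table = _records([("A  x", "A", 5.0)])
    value, prov = resolve_trait("a X ", " a", "leaf_n", table)
    assert value == 5.0 and prov == SPECIES_MEAN


# ---------------------------------------------------------------------------
# pixel CWM (engineered crown geometries)


def _toy_plot(trees):
    return PlotInventory("plot000", 0.0, 0.0, 30.0, trees)


GRID = PixelGrid(0.0, 0.0, 10.0, 3, 3)


def test_monoculture_identity():
    trees = [TreeRecord("plot000", 15.0, 15.0, 40.0, "A x", "A")]
    crowns = [box(10.0, 10.0, 20.0, 20.0)]  # covers pixel (1,1) exactly
    table = _records([("A x", "A", 5.0)])
    r = pixel_cwm(_toy_plot(trees), crowns, table, GRID, "leaf_n")
    assert r.values[1, 1] == pytest.approx(5.0)
    assert r.coverage[1, 1] == pytest.approx(1.0)
    assert bool(r.retained[1, 1])


def test_two_crown_weighted_mean():
    """60 m^2 at trait 2.0 plus 40 m^2 at 3.0 in a 100 m^2 pixel -> CWM 2.4."""
    trees = [
        TreeRecord("plot000", 15.0, 13.0, 30.0, "A x", "A"),
        TreeRecord("plot000", 15.0, 18.0, 30.0, "B y", "B"),
    ]
    crowns = [box(10.0, 10.0, 20.0, 16.0), box(10.0, 16.0, 20.0, 20.0)]
    table = _records([("A x", "A", 2.0), ("B y", "B", 3.0)])
    r = pixel_cwm(_toy_plot(trees), crowns, table, GRID, "leaf_n")
    assert r.values[1, 1] == pytest.approx(2.4, abs=1e-12)
    assert r.coverage[1, 1] == pytest.approx(1.0)


def test_coverage_filter_boundary():
    """Resolved share 0.65 -> excluded; 0.70 -> retained (inclusive)."""
    table = _records([("A x", "A", 2.0)])
    for resolved_frac, keep in ((0.65, False), (0.70, True)):
        trees = [
            TreeRecord("plot000", 15.0, 13.0, 30.0, "A x", "A"),
            TreeRecord("plot000", 15.0, 18.0, 30.0, "Unknown sp", "Unknownus"),
        ]
        split = 10.0 + 10.0 * resolved_frac
        crowns = [box(10.0, 10.0, 20.0, split), box(10.0, split, 20.0, 20.0)]
        r = pixel_cwm(_toy_plot(trees), crowns, table, GRID, "leaf_n")
        assert r.coverage[1, 1] == pytest.approx(resolved_frac)
        assert bool(r.retained[1, 1]) is keep


def test_cwm_invariant_to_species_relabeling():
    trees = [
        TreeRecord("plot000", 12.0, 12.0, 25.0, "A x", "A"),
        TreeRecord("plot000", 18.0, 18.0, 35.0, "B y", "B"),
    ]
    inv = _toy_plot(trees)
    crowns = crown_polygons(inv, 0.5, 0.6)
    table1 = _records([("A x", "A", 2.0), ("B y", "B", 3.0)])
    trees2 = [
        TreeRecord("plot000", 12.0, 12.0, 25.0, "C z", "C"),
        TreeRecord("plot000", 18.0, 18.0, 35.0, "D w", "D"),
    ]
    table2 = _records([("C z", "C", 2.0), ("D w", "D", 3.0)])
    r1 = pixel_cwm(inv, crowns, table1, GRID, "leaf_n")
    r2 = pixel_cwm(_toy_plot(trees2), crowns, table2, GRID, "leaf_n")
    assert np.array_equal(r1.values, r2.values, equal_nan=True)


def test_cwm_convexity(small_landscape, small_cwm):
    """Every retained CWM lies within the range of the contributing taxa."""
    rasters, _, _ = small_cwm
    r = rasters["leaf_n"]
    lookup = TraitLookup(small_landscape.field_table)
    values = []
    for inv in small_landscape.inventories:
        vals, _ = lookup.resolve_many(
            np.array([t.species for t in inv.trees]),
            np.array([t.genus for t in inv.trees]), "leaf_n",
        )
        values.append(vals[np.isfinite(vals)])
    lo = min(v.min() for v in values)
    hi = max(v.max() for v in values)
    retained_vals = r.values[r.retained]
    assert retained_vals.min() >= lo - 1e-9
    assert retained_vals.max() <= hi + 1e-9


def test_monte_carlo_area_oracle():
    """Crown-pixel intersection areas match a 1e5-point Monte-Carlo estimate
    within 3 MC standard errors, over 20 seeded random plots."""
    rng = np.random.default_rng(42)
    grid = PixelGrid(0.0, 0.0, 10.0, 4, 4)
    n_pts = 100_000
    for rep in range(20):
        trees = [
            TreeRecord("plot000", rng.uniform(0, 40), rng.uniform(0, 40),
                       rng.uniform(10, 60), "A x", "A")
            for _ in range(5)
        ]
        inv = PlotInventory("plot000", 0.0, 0.0, 40.0, trees)
        crowns = crown_polygons(inv, 0.5, 0.6)
        rows, cols, tree_idx, areas = plot_pixel_tree_areas(inv, crowns, grid)
        # densest pixel
        flat = rows * grid.n_cols + cols
        target = np.bincount(flat, weights=areas).argmax()
        ti, tj = divmod(int(target), grid.n_cols)
        sel = (rows == ti) & (cols == tj)
        geometric = areas[sel].sum()
        x0, y0, x1, y1 = grid.pixel_bounds(ti, tj)
        pts = shapely.points(
            rng.uniform(x0, x1, n_pts), rng.uniform(y0, y1, n_pts)
        )
        hits = np.zeros(n_pts)
        for k in np.unique(tree_idx[sel]):
            hits += shapely.contains(crowns[k], pts).astype(float)
        pixel_area = (x1 - x0) * (y1 - y0)
        est = hits.mean() * pixel_area
        se = hits.std(ddof=1) / math.sqrt(n_pts) * pixel_area
        assert abs(geometric - est) <= 3 * se + 1e-9


def test_removing_species_never_increases_coverage(small_landscape):
    land = small_landscape
    inv = land.inventories[0]
    crowns = crown_polygons(inv, land.config.crown_a, land.config.crown_b)
    full = pixel_cwm(inv, crowns, land.field_table, land.grid, "leaf_n")
    drop_sp = inv.trees[0].species
    reduced_table = land.field_table[land.field_table["species"] != drop_sp]
    reduced = pixel_cwm(inv, crowns, reduced_table, land.grid, "leaf_n")
    both = np.isfinite(full.coverage) & np.isfinite(reduced.coverage)
    assert (reduced.coverage[both] <= full.coverage[both] + 1e-12).all()


def test_basis_flip_changes_coverage_not_cwm(small_landscape):
    land = small_landscape
    inv = land.inventories[0]
    crowns = crown_polygons(inv, land.config.crown_a, land.config.crown_b)
    canopy = pixel_cwm(inv, crowns, land.field_table, land.grid, "leaf_n",
                       coverage_basis="canopy-area")
    basal = pixel_cwm(inv, crowns, land.field_table, land.grid, "leaf_n",
                      coverage_basis="basal-area")
    both = canopy.retained & basal.retained
    assert both.any()
    assert np.allclose(canopy.values[both], basal.values[both])


def test_rasterize_toy_landscape_counts():
    """2 plots x 4 fully-covered pixels -> 8 retained pixels per trait."""
    table = _records([("A x", "A", 2.0)])
    invs = []
    for p, ox in enumerate((0.0, 30.0)):
        # one giant tree whose clipped crown covers the whole 20x20 plot
        trees = [TreeRecord(f"plot{p:03d}", 10.0, 10.0, 300.0, "A x", "A")]
        invs.append(PlotInventory(f"plot{p:03d}", ox, 0.0, 20.0, trees))
    grid = PixelGrid(0.0, 0.0, 10.0, 2, 5)
    rasters, report, plot_layer = rasterize_landscape(invs, table, grid, ["leaf_n"])
    assert int(rasters["leaf_n"].retained.sum()) == 8
    assert report["retained_pixels"].sum() == 8
    assert set(np.unique(plot_layer)) == {-1, 0, 1}


def test_retained_counts_match_independent_recount(small_cwm):
    rasters, report, _ = small_cwm
    for trait, r in rasters.items():
        recount = int(
            np.sum(np.isfinite(r.coverage) & (r.coverage >= r.threshold)
                   & np.isfinite(r.values))
        )
        assert recount == int(r.retained.sum())
        assert recount == report.loc[report["trait"] == trait, "retained_pixels"].sum()


def test_grid_not_covering_plot_raises():
    inv = _toy_plot([TreeRecord("plot000", 5.0, 5.0, 20.0, "A x", "A")])
    small_grid = PixelGrid(100.0, 100.0, 10.0, 2, 2)
    with pytest.raises(ValueError, match="cover"):
        plot_pixel_tree_areas(inv, crown_polygons(inv, 0.5, 0.6), small_grid)
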