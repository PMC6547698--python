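"""Climate-field geometry, point sampling, anomalies and coarse aggregation."""

import numpy as np
import pandas as pd
import pytest

from vegrisk.grids import (
    ClimateField,
    CoarseGrid,
    aggregate_to_coarse,
    median_anomaly,
    read_ascii_grid,
    sample_climate,
    write_ascii_grid,
)


class TestSampleClimate:
    def test_cell_centre_returns_stored_value(self, tiny_field):
        assert sample_climate(tiny_field, [5.0], [5.0])[0] == 1.0
        assert sample_climate(tiny_field, [15.0], [15.0])[0] == 4.0

    def test_point_outside_extent_is_missing(self, tiny_field):
        out = sample_climate(tiny_field, [-1.0, 25.0, 5.0], [5.0, 5.0, 5.0])
        assert np.isnan(out[0]) and np.isnan(out[1]) and out[2] == 1.0

    def test_three_points_two_cells_match_hand_lookup(self, tiny_field):
        # (2,2)->cell(0,0)=1; (12,3)->cell(0,1)=2; (19,2)->cell(0,1)=2
        got = sample_climate(tiny_field, [2.0, 12.0, 19.0], [2.0, 3.0, 2.0])
        assert got.tolist() == [1.0, 2.0, 2.0]

    def test_boundary_points_use_half_open_cells(self, tiny_field):
        # x=10 is the west edge of column 1; y=10 the south edge of row 1
        assert sample_climate(tiny_field, [10.0], [0.0])[0] == 2.0
        assert sample_climate(tiny_field, [0.0], [10.0])[0] == 3.0

    def test_nodata_cell_yields_missing(self, tiny_field):
        tiny_field.values[0, 0] = np.nan
        assert np.isnan(sample_climate(tiny_field, [5.0], [5.0])[0])

    def test_all_nodata_field_errors(self, tiny_field):
        tiny_field.values[:] = np.nan
        with pytest.raises(ValueError):
            sample_climate(tiny_field, [5.0], [5.0])

    def test_roundtrip_known_cell_index_exact(self):
        rng = np.random.default_rng(0)
        f = ClimateField(rng.normal(size=(7, 9)), x0=-30.0, y0=100.0, cell=2.5)
        for r, c in [(0, 0), (6, 8), (3, 4)]:
            x = f.x0 + (c + 0.5) * f.cell
            y = f.y0 + (r + 0.5) * f.cell
            assert sample_climate(f, [x], [y])[0] == f.values[r, c]


class TestMedianAnomaly:
    def test_identical_futures_give_zero(self, tiny_field):
        futs = [tiny_field.copy_with(tiny_field.values, epoch=f"future:g{i}")
                for i in range(5)]
        anom = median_anomaly(tiny_field, futs)
        assert np.allclose(anom.values, 0.0)

    def test_known_five_layer_median(self, tiny_field):
        deltas = [1.8, 2.0, 2.4, 3.1, 3.3]
        futs = [tiny_field.copy_with(tiny_field.values + d) for d in deltas]
        anom = median_anomaly(tiny_field, futs)
        assert np.allclose(anom.values, 2.4)

    def test_even_layer_count_averages_central_pair(self, tiny_field):
        futs = [tiny_field.copy_with(tiny_field.values + d) for d in (1.0, 2.0)]
        assert np.allclose(median_anomaly(tiny_field, futs).values, 1.5)

    def test_layer_order_permutation_invariance(self, tiny_field):
        rng = np.random.default_rng(1)
        futs = [tiny_field.copy_with(tiny_field.values + rng.normal(size=(2, 2)))
                for _ in range(5)]
        a = median_anomaly(tiny_field, futs).values
        b = median_anomaly(tiny_field, futs[::-1]).values
        assert np.array_equal(a, b)

    def test_nodata_propagates(self, tiny_field):
        fut = tiny_field.copy_with(tiny_field.values + 1)
        fut.values[1, 1] = np.nan
        anom = median_anomaly(tiny_field, [fut, fut, fut])
        assert np.isnan(anom.values[1, 1]) and anom.values[0, 0] == 1.0

    def test_mismatched_geometry_names_layer(self, tiny_field):
        bad = ClimateField(np.ones((3, 3)), 0.0, 0.0, 10.0, epoch="future:odd")
        with pytest.raises(ValueError, match="future:odd"):
            median_anomaly(tiny_field, [bad])


class TestAggregateToCoarse:
    def test_constant_field_preserved(self):
        f = ClimateField(np.full((10, 10), 500.0), 0.0, 0.0, 10.0, variable="MAP")
        grid = CoarseGrid.from_extent(f.extent, 50.0)
        out = aggregate_to_coarse(f, grid)
        assert np.allclose(out["value"], 500.0) and len(out) == 4

    def test_known_block_mean(self):
        f = ClimateField(np.array([[10.0, 12.0], [14.0, 16.0]]), 0.0, 0.0, 10.0)
        grid = CoarseGrid.from_extent(f.extent, 20.0)
        out = aggregate_to_coarse(f, grid)
        assert len(out) == 1 and out["value"].iloc[0] == 13.0

    def test_value_within_fine_bounds(self, small_scenario):
        f = small_scenario.current["MAT"]
        grid = small_scenario.coarse_grid
        out = aggregate_to_coarse(f, grid)
        xs, ys = np.meshgrid(f.x_centers(), f.y_centers())
        ids = grid.cell_of(xs.ravel(), ys.ravel())
        vals = f.values.ravel()
        for rec in out.itertuples(index=False):
            sub = vals[ids == rec.cell_id]
            assert sub.min() - 1e-12 <= rec.value <= sub.max() + 1e-12

    def test_low_land_fraction_cells_excluded(self):
        vals = np.full((4, 4), 7.0)
        vals[:, 2:] = np.nan  # eastern half is sea
        f = ClimateField(vals, 0.0, 0.0, 10.0)
        grid = CoarseGrid.from_extent(f.extent, 20.0)
        out = aggregate_to_coarse(f, grid, min_land_fraction=0.5)
        assert set(out["cell_id"]) == {0, 2}  # western column only

    def test_empty_intersection_errors(self, tiny_field):
        grid = CoarseGrid(x0=1000.0, y0=1000.0, edge=100.0, nrows=2, ncols=2)
        with pytest.raises(ValueError):
            aggregate_to_coarse(tiny_field, grid)


class TestAsciiGridRoundtrip:
    def test_roundtrip_exact(self, tmp_path, small_scenario):
        f = small_scenario.current["MAP"]
        f = f.copy_with(f.values.copy())
        f.values[3, 4] = np.nan
        p = tmp_path / "g.asc"
        write_ascii_grid(f, p)
        g = read_ascii_grid(p, variable="MAP")
        assert g.cell == f.cell and g.x0 == f.x0 and g.y0 == f.y0
        assert np.array_equal(g.values, f.values, equal_nan=True)


class TestCoarseGrid:
    def test_default_edge_is_100km(self):
        import inspect
        sig = inspect.signature(CoarseGrid.from_extent)
        assert sig.parameters["edge"].default == 100.0

    def test_cells_partition_points(self):
        grid = CoarseGrid.from_extent((0, 0, 300, 200), 100.0)
        assert grid.n_cells == 6
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 300, 500)
        y = rng.uniform(0, 200, 500)
        ids = grid.cell_of(x, y)
        assert ids.min() >= 0 and ids.max() < 6

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            CoarseGrid.from_extent((0, 0, 0, 100), 100.0)
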