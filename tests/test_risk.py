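"""Vessel density gridding, encounter-probability layers, overlap statistics."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from movescape.raster import GridRaster, aggregate_mean
from movescape.risk import overlap_stats, rpew, rpvew, traverse_cells, vessel_density
from movescape.tracks import VesselRecord


def grid(values, cell=8.0):
    return GridRaster(values=np.asarray(values, dtype=float), x_origin=0.0, y_origin=0.0, cell_size=cell)


def record(vessel, x, y, day=1, hour=0, fleet="aquaculture"):
    """Vessel record with planar coordinates stored in lon/lat slots (km grid)."""
    return VesselRecord(
        vessel_id=vessel,
        fleet=fleet,
        timestamp=datetime(2019, 3, day, hour, tzinfo=timezone.utc),
        lon=x,
        lat=y,
    )


class TestTraverseCells:
    def test_straight_segment_matches_dense_sampling_oracle(self, rng):
        g = grid(np.zeros((10, 10)), cell=1.0)
        for _ in range(25):
            x0, y0, x1, y1 = rng.uniform(0.2, 9.8, 4)
            got = set(traverse_cells(g, x0, y0, x1, y1))
            ts = np.linspace(0, 1, 4000)
            oracle = {
                g.index_of(x0 + t * (x1 - x0), y0 + t * (y1 - y0)) for t in ts
            }
            # dense sampling may skip a corner-clip cell; traversal may not miss any
            assert oracle <= got
            assert len(got) <= len(oracle) + 2

    def test_segment_outside_grid_is_empty(self):
        g = grid(np.zeros((4, 4)), cell=1.0)
        assert traverse_cells(g, -5.0, -5.0, -1.0, -5.0) == []


class TestVesselDensity:
    def test_worked_two_day_example(self):
        # day 1: vessels A and B cross the cell; day 2: A only -> (2 + 1)/2
        g = grid(np.zeros((3, 3)))
        records = [
            record("A", 4.0, 4.0, day=1),
            record("B", 4.5, 4.5, day=1),
            record("A", 4.0, 4.0, day=2),
        ]
        vd = vessel_density(records, g)
        assert vd.values[2, 0] == pytest.approx(1.5)

    def test_vessel_counted_once_per_day_per_cell(self):
        g = grid(np.zeros((3, 3)))
        records = [record("A", 4.0, 4.0, hour=h) for h in range(5)]
        vd = vessel_density(records, g)
        assert vd.values[2, 0] == pytest.approx(1.0)

    def test_segment_rasterization_credits_intermediate_cells(self):
        g = grid(np.zeros((1, 4)))
        records = [record("A", 2.0, 4.0, hour=0), record("A", 30.0, 4.0, hour=1)]
        vd = vessel_density(records, g)
        np.testing.assert_allclose(vd.values[0], [1.0, 1.0, 1.0, 1.0])
        vd2 = vessel_density(records, g, crossing="containment")
        np.testing.assert_allclose(vd2.values[0], [1.0, 0.0, 0.0, 1.0])

    def test_months_averaged_after_per_month_normalization(self):
        g = grid(np.zeros((2, 2)))
        records = [
            record("A", 4.0, 4.0, day=1),  # March: 1 vessel / 1 day = 1
            VesselRecord("A", "aquaculture", datetime(2019, 4, 1, tzinfo=timezone.utc), 4.0, 4.0),
            VesselRecord("B", "aquaculture", datetime(2019, 4, 2, tzinfo=timezone.utc), 12.0, 12.0),
        ]
        vd = vessel_density(records, g)
        # April: cell (1,0) got 1 vessel over 2 days-with-data = 0.5
        assert vd.values[1, 0] == pytest.approx((1.0 + 0.5) / 2)

    def test_missing_month_warns(self):
        g = grid(np.zeros((2, 2)))
        with pytest.warns(UserWarning, match="2019-05"):
            vessel_density([record("A", 4.0, 4.0)], g, months=["2019-03", "2019-05"])


class TestAggregateMean:
    def test_uniform_unchanged(self):
        fine = GridRaster(values=np.full((16, 16), 3.0), cell_size=1.0)
        out = aggregate_mean(fine, 8)
        assert out.shape == (2, 2)
        np.testing.assert_allclose(out.values, 3.0)
        assert out.cell_size == 8.0

    def test_block_of_1_to_64(self):
        fine = GridRaster(values=np.arange(1.0, 65.0).reshape(8, 8), cell_size=1.0)
        out = aggregate_mean(fine, 8)
        assert out.values[0, 0] == pytest.approx(32.5)

    def test_half_masked_block_uses_unmasked_half(self):
        vals = np.full((4, 4), 2.0)
        vals[:2, :] = np.nan
        out = aggregate_mean(GridRaster(values=vals, cell_size=1.0), 4)
        assert out.values[0, 0] == pytest.approx(2.0)

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mean(GridRaster(values=np.zeros((10, 10)), cell_size=1.0), 8)


class TestEncounterLayers:
    def test_rpew_uniform_inputs(self):
        out = rpew(grid(np.full((3, 3), 2.0)), grid(np.full((3, 3), 1.5)))
        np.testing.assert_allclose(out.values, 1.0 / 9.0)

    def test_rpew_scale_invariance(self):
        n = grid(np.array([[2.0, 1.0]]))
        nu = grid(np.array([[1.0, 2.0]]))
        a = rpew(n, nu).values
        b = rpew(grid(n.values * 7.0), nu).values
        np.testing.assert_allclose(a, b)

    def test_rpew_two_cell_hand_example(self):
        out = rpew(grid(np.array([[2.0, 1.0]])), grid(np.array([[1.0, 2.0]])))
        np.testing.assert_allclose(out.values, [[0.8, 0.2]])

    def test_rpvew_two_cell_hand_example(self):
        layers = rpvew(
            grid(np.array([[1.0, 1.0]])),
            grid(np.array([[1.0, 1.0]])),
            grid(np.array([[3.0, 1.0]])),
        )
        np.testing.assert_allclose(layers.rpvew.values, [[0.75, 0.25]])

    def test_rpvew_zero_vessel_cell_annihilates(self):
        layers = rpvew(
            grid(np.array([[5.0, 1.0]])),
            grid(np.array([[1.0, 1.0]])),
            grid(np.array([[0.0, 2.0]])),
        )
        assert layers.rpvew.values[0, 0] == 0.0
        assert layers.rpvew.values[0, 1] == 1.0

    def test_layers_sum_to_one_on_random_fixtures(self, rng):
        for _ in range(5):
            n = grid(rng.uniform(0.1, 5.0, (6, 6)))
            nu = grid(rng.uniform(0.5, 3.0, (6, 6)))
            vd = grid(rng.uniform(0.0, 4.0, (6, 6)))
            layers = rpvew(n, nu, vd)
            for layer in (layers.pw, layers.pt, layers.pv, layers.rpew, layers.rpvew):
                assert np.nansum(layer.values) == pytest.approx(1.0)
                assert np.nanmin(layer.values) >= 0.0

    def test_all_zero_vd_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rpvew(
                grid(np.ones((2, 2))), grid(np.ones((2, 2))), grid(np.zeros((2, 2)))
            )


class TestOverlapStats:
    def test_identical_layers_full_overlap(self, rng):
        a = grid(rng.uniform(0, 3, (5, 5)))
        d, i = overlap_stats(a, a)
        assert d == pytest.approx(1.0)
        assert i == pytest.approx(1.0)

    def test_disjoint_supports_zero_overlap(self):
        d, i = overlap_stats(grid(np.array([[1.0, 0.0]])), grid(np.array([[0.0, 1.0]])))
        assert d == pytest.approx(0.0)
        assert i == pytest.approx(0.0)

    def test_antithetic_hand_example(self):
        from movescape.risk import schoener_d, warren_i

        p, q = [0.75, 0.25], [0.25, 0.75]
        assert schoener_d(p, q) == pytest.approx(0.5)
        assert warren_i(p, q) == pytest.approx(0.8660, abs=1e-4)

    def test_symmetry_and_range(self, rng):
        a = grid(rng.uniform(0, 1, (4, 4)))
        b = grid(rng.uniform(0, 1, (4, 4)))
        d1, i1 = overlap_stats(a, b)
        d2, i2 = overlap_stats(b, a)
        assert d1 == pytest.approx(d2)
        assert i1 == pytest.approx(i2)
        assert 0.0 <= d1 <= 1.0 and 0.0 <= i1 <= 1.0

    def test_rescale_is_noop_when_minima_are_zero(self, rng):
        # with zero minima the min-max rescale cancels in the normalization
        a_vals = rng.uniform(0, 2, (4, 4))
        a_vals[0, 0] = 0.0
        b_vals = rng.uniform(0, 3, (4, 4))
        b_vals[1, 1] = 0.0
        d, i = overlap_stats(grid(a_vals), grid(b_vals))
        pa = a_vals / a_vals.sum()
        pb = b_vals / b_vals.sum()
        assert d == pytest.approx(1 - 0.5 * np.abs(pa - pb).sum())
        assert i == pytest.approx(1 - 0.5 * ((np.sqrt(pa) - np.sqrt(pb)) ** 2).sum())

    def test_constant_layer_rejected(self):
        with pytest.raises(ValueError, match="rescale"):
            overlap_stats(grid(np.full((2, 2), 3.0)), grid(np.ones((2, 2))))
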