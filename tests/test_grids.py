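"""Raster overlay, locality classification, and ESRI ASCII I/O."""

import io

import numpy as np
import pandas as pd
import pytest

from parapatry.grids import (
    BinaryMap,
    SuitabilityGrid,
    ZoneBox,
    classify_localities,
    dedup_localities,
    dominance_map,
    potential_sympatry,
    read_ascii_grid,
    read_localities,
    threshold_mtp,
    write_ascii_grid,
    GridAlignmentError,
    LocalityError,
)


def grid_from(values, **kw):
    defaults = dict(origin_lon=0.0, origin_lat=0.0, cell_size=1.0)
    defaults.update(kw)
    return SuitabilityGrid(np.asarray(values, dtype=float), **defaults)


def points(pairs, species="sp"):
    return pd.DataFrame([{"species": species, "lon": x, "lat": y}
                         for x, y in pairs])


class TestAsciiRoundTrip:
    def test_values_and_georef_survive(self, rng):
        values = rng.uniform(0, 1, size=(7, 5))
        values[2, 3] = np.nan
        grid = grid_from(values, origin_lon=-52.25, origin_lat=-33.5,
                         cell_size=0.125)
        buf = io.StringIO()
        write_ascii_grid(grid, buf)
        back = read_ascii_grid(io.StringIO(buf.getvalue()))
        np.testing.assert_array_equal(back.values, grid.values)
        assert back.georef() == grid.georef()
        assert back.nodata_value == grid.nodata_value

    def test_missing_header_key_rejected(self):
        with pytest.raises(ValueError, match="header"):
            read_ascii_grid(io.StringIO("ncols 2\nnrows 2\n1 2\n3 4\n"))


class TestCellConvention:
    def test_point_on_lower_left_corner_belongs_to_cell(self):
        grid = grid_from(np.arange(9).reshape(3, 3) / 10.0)
        # lower-left corner of the cell at column 1, bottom row
        assert grid.cell_index(1.0, 0.0) == (2, 1)
        # exactly on the upper edge falls in the next cell up
        assert grid.cell_index(1.0, 1.0) == (1, 1)

    def test_out_of_extent_is_none(self):
        grid = grid_from(np.ones((2, 2)))
        assert grid.cell_index(-0.001, 0.5) is None
        assert grid.cell_index(2.0, 0.5) is None  # half-open upper edge

    def test_top_row_is_northernmost(self):
        grid = grid_from([[0.9, 0.9], [0.1, 0.1]])
        assert grid.value_at(0.5, 1.5) == 0.9
        assert grid.value_at(0.5, 0.5) == 0.1


class TestDedup:
    def test_exact_duplicates_collapse_and_order_is_stable(self):
        t = pd.DataFrame({
            "species": ["a", "a", "b", "a"],
            "lon": [1.0, 1.0, 1.0, 2.0],
            "lat": [3.0, 3.0, 3.0, 3.0],
        })
        out = dedup_localities(t)
        assert len(out) == 3
        assert out.iloc[0]["species"] == "a" and out.iloc[1]["species"] == "b"

    def test_same_point_two_species_both_kept(self):
        t = points([(1, 2)], "a")
        t = pd.concat([t, points([(1, 2)], "b")], ignore_index=True)
        assert len(dedup_localities(t)) == 2

    def test_unique_table_is_unchanged(self, rng):
        # 74 unique localities split 45 + 29 across the two species
        a = points([(x, 0.0) for x in range(45)], "minutus")
        b = points([(x, 1.0) for x in range(29)], "flamarioni")
        t = pd.concat([a, b], ignore_index=True)
        out = dedup_localities(t)
        assert len(out) == 74
        assert (out["species"] == "minutus").sum() == 45

    def test_bad_coordinates_raise(self):
        t = points([(1.0, np.nan)])
        with pytest.raises(LocalityError, match="rows"):
            dedup_localities(t)


class TestThresholdMTP:
    def test_threshold_is_min_over_training_cells(self):
        grid = grid_from(np.arange(1, 10).reshape(3, 3) / 10.0)
        # centers of the cells holding 0.4 and 0.7 (row-major from top)
        train = points([(0.5, 1.5), (0.5, 0.5)])  # values 0.4 and 0.7
        bm = threshold_mtp(grid, train)
        assert bm.threshold == pytest.approx(0.4)
        assert bm.n_suitable() == 6
        # every training point's own cell is suitable
        for r in train.itertuples(index=False):
            assert bm.values[bm.cell_index(r.lon, r.lat)] == 1

    def test_training_at_global_minimum_keeps_whole_grid(self):
        grid = grid_from(np.arange(1, 10).reshape(3, 3) / 10.0)
        bm = threshold_mtp(grid, points([(0.5, 2.5)]))  # the 0.1 cell
        assert bm.n_suitable() == 9

    def test_matches_bruteforce_scan(self, rng):
        values = rng.uniform(0, 1, size=(12, 9))
        grid = grid_from(values)
        pts = [(rng.uniform(0, 9), rng.uniform(0, 12)) for _ in range(6)]
        bm = threshold_mtp(grid, points(pts))
        thr = min(values[grid.cell_index(x, y)] for x, y in pts)
        np.testing.assert_array_equal(bm.suitable, values >= thr)

    def test_adding_training_point_never_shrinks_suitable_set(self, rng):
        values = rng.uniform(0, 1, size=(8, 8))
        grid = grid_from(values)
        pts = [(rng.uniform(0, 8), rng.uniform(0, 8)) for _ in range(5)]
        before = threshold_mtp(grid, points(pts))
        after = threshold_mtp(grid, points(pts + [(0.5, 0.5)]))
        assert after.threshold <= before.threshold
        assert (before.suitable <= after.suitable).all()

    def test_training_point_in_nodata_cell_is_reported(self):
        values = np.ones((2, 2))
        values[0, 0] = np.nan
        with pytest.raises(LocalityError, match="nodata"):
            threshold_mtp(grid_from(values), points([(0.5, 1.5)]))


class TestPotentialSympatry:
    @staticmethod
    def binmaps(rng, shape=(10, 10)):
        def make():
            vals = rng.integers(0, 2, size=shape).astype(np.int8)
            vals[rng.uniform(size=shape) < 0.1] = -1
            return BinaryMap(vals, 0.0, 0.0, 1.0)
        return make(), make()

    def test_all_suitable_is_identity_element(self, rng):
        a = BinaryMap(np.ones((5, 5), dtype=np.int8), 0, 0, 1.0)
        _, b = self.binmaps(rng, (5, 5))
        out = potential_sympatry(a, b)
        np.testing.assert_array_equal(out.values, b.values)

    def test_disjoint_sets_yield_empty_intersection(self):
        a = BinaryMap(np.array([[1, 0], [1, 0]], dtype=np.int8), 0, 0, 1.0)
        b = BinaryMap(np.array([[0, 1], [0, 1]], dtype=np.int8), 0, 0, 1.0)
        assert potential_sympatry(a, b).n_suitable() == 0

    def test_matches_cellwise_and_oracle(self, rng):
        a, b = self.binmaps(rng)
        out = potential_sympatry(a, b)
        for i in range(a.n_rows):
            for j in range(a.n_cols):
                if a.values[i, j] == -1 or b.values[i, j] == -1:
                    assert out.values[i, j] == -1
                else:
                    expected = int(a.values[i, j] == 1 and b.values[i, j] == 1)
                    assert out.values[i, j] == expected

    def test_commutative_idempotent_and_subset(self, rng):
        a, b = self.binmaps(rng)
        ab = potential_sympatry(a, b)
        ba = potential_sympatry(b, a)
        np.testing.assert_array_equal(ab.values, ba.values)
        np.testing.assert_array_equal(
            potential_sympatry(a, a).suitable, a.suitable)
        assert (ab.suitable <= a.suitable).all()
        assert (ab.suitable <= b.suitable).all()

    def test_georef_mismatch_rejected(self, rng):
        a, _ = self.binmaps(rng)
        shifted = BinaryMap(a.values, 1.0, 0.0, 1.0)
        with pytest.raises(GridAlignmentError):
            potential_sympatry(a, shifted)


class TestDominance:
    def test_identical_grids_tie_everywhere_in_mask(self, random_grid_pair):
        a, _ = random_grid_pair
        mask = BinaryMap(np.where(np.isnan(a.values), -1, 1).astype(np.int8),
                         a.origin_lon, a.origin_lat, a.cell_size)
        dom = dominance_map(a, a, mask)
        counts = dom.counts()
        assert counts["a_higher"] == counts["b_higher"] == 0
        assert counts["tie"] == mask.n_suitable()

    def test_empty_mask_all_outside(self, random_grid_pair):
        a, b = random_grid_pair
        mask = BinaryMap(np.zeros_like(a.values, dtype=np.int8),
                         a.origin_lon, a.origin_lat, a.cell_size)
        dom = dominance_map(a, b, mask)
        assert dom.counts()["outside"] == a.values.size

    def test_matches_percell_oracle_and_partitions_mask(
            self, random_grid_pair, rng):
        a, b = random_grid_pair
        mvals = rng.integers(0, 2, size=a.values.shape).astype(np.int8)
        mask = BinaryMap(mvals, a.origin_lon, a.origin_lat, a.cell_size)
        dom = dominance_map(a, b, mask)
        n_a = n_b = n_tie = 0
        for i in range(a.n_rows):
            for j in range(a.n_cols):
                if mask.values[i, j] != 1:
                    assert dom.values[i, j] == -1
                    continue
                va, vb = a.values[i, j], b.values[i, j]
                if np.isnan(va) or np.isnan(vb):
                    continue
                if va > vb:
                    assert dom.values[i, j] == 1
                    n_a += 1
                elif vb > va:
                    assert dom.values[i, j] == 2
                    n_b += 1
                else:
                    assert dom.values[i, j] == 0
                    n_tie += 1
        counts = dom.counts()
        assert (counts["a_higher"], counts["b_higher"]) == (n_a, n_b)


class TestClassifyLocalities:
    @pytest.fixture
    def mask(self):
        # 4x4, left half suitable
        vals = np.zeros((4, 4), dtype=np.int8)
        vals[:, :2] = 1
        return BinaryMap(vals, 0.0, 0.0, 1.0)

    @pytest.fixture
    def zones(self):
        return [ZoneBox("north", 0.0, 2.0, 2.0, 4.0),
                ZoneBox("south", 0.0, 2.0, 0.0, 2.0)]

    def test_zone_box_but_unsuitable_cell_not_in_sympatry(self, mask, zones):
        t = points([(2.5, 2.5)])  # inside nothing suitable, north box excludes it
        t = pd.concat([t, points([(0.5, 2.5)], "b")], ignore_index=True)
        out = classify_localities(t, mask, zones)
        assert not out.loc[0, "in_potential_sympatry"]
        assert out.loc[1, "in_potential_sympatry"]
        assert out.loc[1, "zone"] == "north"

    def test_counts_match_hand_enumeration(self, mask, zones):
        rows = [
            ("a", 0.5, 3.5, True, "north"),
            ("a", 1.5, 0.5, True, "south"),
            ("a", 0.5, 1.5, True, "south"),
            ("b", 1.5, 3.5, True, "north"),
            ("b", 3.5, 3.5, False, ""),   # suitable-for-nobody right half
            ("a", 2.5, 0.5, False, ""),
        ]
        t = pd.DataFrame([{"species": s, "lon": x, "lat": y}
                          for s, x, y, _, _ in rows])
        out = classify_localities(t, mask, zones)
        for i, (_, _, _, symp, zone) in enumerate(rows):
            assert out.loc[i, "in_potential_sympatry"] == symp
            assert out.loc[i, "zone"] == zone

    def test_order_invariance(self, mask, zones, rng):
        t = points([(rng.uniform(0, 4), rng.uniform(0, 4))
                    for _ in range(20)])
        out = classify_localities(t, mask, zones)
        perm = rng.permutation(len(t))
        out_perm = classify_localities(t.iloc[perm], mask, zones)
        merged = out_perm.sort_values(["lon", "lat"]).reset_index(drop=True)
        base = out.sort_values(["lon", "lat"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, base)

    def test_out_of_extent_flagged_with_warning(self, mask, zones):
        t = points([(10.0, 10.0), (0.5, 0.5)])
        with pytest.warns(UserWarning, match="outside grid extent"):
            out = classify_localities(t, mask, zones)
        assert not out.loc[0, "in_extent"]
        assert out.loc[1, "in_extent"]

    def test_overlapping_zones_rejected(self, mask):
        zones = [ZoneBox("x", 0, 2, 0, 2), ZoneBox("y", 1, 3, 1, 3)]
        with pytest.raises(ValueError, match="overlap"):
            classify_localities(points([(0.5, 0.5)]), mask, zones)


def test_locality_csv_requires_header(tmp_path):
    p = tmp_path / "loc.csv"
    p.write_text("sp,x,y\na,1,2\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_localities(p)
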