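import json

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from treefuse.geospatial_io import (
    CrownRecord,
    PointCloud,
    RasterTile,
    centroid_pixel,
    clip_raster,
    load_crowns,
    read_raster,
    read_xyz,
    split_individuals,
    write_raster,
    write_xyz,
)


def make_tile(side_m=20.0, res=0.1, origin=(0.0, 20.0), channels=1):
    n = int(round(side_m / res))
    vals = np.arange(n * n * channels, dtype=float).reshape(n, n, channels)
    return RasterTile(origin=origin, resolution=res, values=vals)


class TestClipRaster:
    def test_box_dimensions(self):
        tile = make_tile()
        # 3 m wide (x), 2 m tall (y) -> 20 rows x 30 cols at 0.1 m
        clipped = clip_raster(tile, box(5.0, 10.0, 8.0, 12.0))
        assert clipped.values.shape[:2] == (20, 30)

    def test_single_cell_center(self):
        tile = make_tile()
        clipped = clip_raster(tile, box(5.04, 10.04, 5.06, 10.06))
        assert clipped.values.shape[:2] == (1, 1)

    def test_outside_tile_raises(self):
        tile = make_tile()
        with pytest.raises(ValueError):
            clip_raster(tile, box(100, 100, 105, 105))

    def test_clipped_values_match_source(self):
        tile = make_tile()
        poly = box(2.0, 3.0, 4.0, 6.0)
        clipped = clip_raster(tile, poly)
        r, c = centroid_pixel(tile, poly)
        rc, cc = centroid_pixel(clipped, poly)
        assert np.array_equal(clipped.values[rc, cc], tile.values[r, c])


class TestCentroidPixel:
    def test_box_centered_on_cell_center(self):
        tile = make_tile(res=1.0)
        # centroid (5.5, 12.5): col 5; row = floor(20 - 12.5) = 7
        assert centroid_pixel(tile, box(5.0, 12.0, 6.0, 13.0)) == (7, 5)

    def test_edge_centroid_goes_to_larger_index(self):
        tile = make_tile(res=1.0)
        # centroid exactly on the x = 5.0 cell edge -> col 5 (not 4)
        row, col = centroid_pixel(tile, box(4.0, 12.0, 6.0, 13.0))
        assert col == 5

    def test_coordinate_arithmetic_oracle(self):
        # 1 m tile anchored at the NW corner; centroid offset (x=5.4 east,
        # 7.9 south of the north edge) must land in row 7, col 5
        tile = make_tile(side_m=20.0, res=1.0, origin=(0.0, 20.0))
        poly = box(5.4 - 0.1, 20.0 - 7.9 - 0.1, 5.4 + 0.1, 20.0 - 7.9 + 0.1)
        assert centroid_pixel(tile, poly) == (7, 5)

    def test_outside_extent_raises(self):
        tile = make_tile()
        with pytest.raises(ValueError):
            centroid_pixel(tile, box(30, 30, 32, 32))

    def test_clip_then_centroid_consistent(self, rng):
        # oracle equivalence: centroid pixel on the clipped tile, offset by
        # the clip window origin, equals the centroid pixel on the source
        tile = make_tile()
        for _ in range(50):
            x0 = rng.uniform(1, 15)
            y0 = rng.uniform(1, 15)
            poly = box(x0, y0, x0 + rng.uniform(0.5, 4), y0 + rng.uniform(0.5, 4))
            r, c = centroid_pixel(tile, poly)
            clipped = clip_raster(tile, poly)
            rc, cc = centroid_pixel(clipped, poly)
            dr = int(round((tile.origin[1] - clipped.origin[1]) / tile.resolution))
            dc = int(round((clipped.origin[0] - tile.origin[0]) / tile.resolution))
            assert (rc + dr, cc + dc) == (r, c)


class TestSplitIndividuals:
    def records(self, n):
        return [
            CrownRecord(f"I{i}", "TX00", box(i, 0, i + 1, 1), "S", "P") for i in range(n)
        ]

    @pytest.mark.parametrize(
        "n,fraction,expected_train", [(100, 0.75, 75), (10, 0.8, 8), (7, 0.5, 4)]
    )
    def test_split_sizes(self, n, fraction, expected_train):
        train, hold = split_individuals(self.records(n), fraction, seed=2)
        assert len(train) == expected_train
        assert len(hold) == n - expected_train

    def test_deterministic(self):
        recs = self.records(30)
        a = split_individuals(recs, 0.75, seed=5)
        b = split_individuals(recs, 0.75, seed=5)
        assert [r.individual_id for r in a[0]] == [r.individual_id for r in b[0]]

    def test_exhaustive_and_disjoint(self, rng):
        recs = self.records(23)
        for fraction in (0.2, 0.5, 0.9):
            train, hold = split_individuals(recs, fraction, seed=int(rng.integers(1000)))
            ids = {r.individual_id for r in train} | {r.individual_id for r in hold}
            assert len(ids) == 23
            assert not ({r.individual_id for r in train} & {r.individual_id for r in hold})

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_individuals(self.records(5), 1.0, seed=0)


class TestLoadCrowns:
    def write_inputs(self, tmp_path, features, field_rows):
        gj = {"type": "FeatureCollection", "features": features}
        vec = tmp_path / "crowns.geojson"
        vec.write_text(json.dumps(gj))
        csv = tmp_path / "field.csv"
        lines = ["individual_id,taxon_code,site_id,plot_id"] + field_rows
        csv.write_text("\n".join(lines) + "\n")
        return vec, csv

    @staticmethod
    def feature(ind, poly):
        from shapely.geometry import mapping

        return {
            "type": "Feature",
            "properties": {"individual_id": ind},
            "geometry": mapping(poly),
        }

    def test_join(self, tmp_path):
        feats = [self.feature(f"A{i}", box(i, 0, i + 1, 1)) for i in range(3)]
        rows = [f"A{i},TX0{i},S1,P1" for i in range(3)]
        vec, csv = self.write_inputs(tmp_path, feats, rows)
        recs = load_crowns(vec, csv)
        assert len(recs) == 3
        assert {r.taxon_code for r in recs} == {"TX00", "TX01", "TX02"}

    def test_unmatched_polygon_retained_without_taxon(self, tmp_path, caplog):
        feats = [self.feature("A0", box(0, 0, 1, 1)), self.feature("A9", box(2, 0, 3, 1))]
        vec, csv = self.write_inputs(tmp_path, feats, ["A0,TX00,S1,P1"])
        import logging

        with caplog.at_level(logging.WARNING):
            recs = load_crowns(vec, csv)
        assert len(recs) == 2
        unmatched = next(r for r in recs if r.individual_id == "A9")
        assert unmatched.taxon_code is None
        assert any("A9" in m for m in caplog.messages)

    def test_empty_vector_file(self, tmp_path):
        vec, csv = self.write_inputs(tmp_path, [], ["A0,TX00,S1,P1"])
        assert load_crowns(vec, csv) == []

    def test_missing_join_key_raises(self, tmp_path):
        feats = [self.feature("A0", box(0, 0, 1, 1))]
        vec = tmp_path / "crowns.geojson"
        vec.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        bad = tmp_path / "field.csv"
        bad.write_text("some_id,taxon_code\nA0,TX00\n")
        with pytest.raises(ValueError):
            load_crowns(vec, bad)

    def test_non_rectangular_polygon_becomes_bounding_box(self, tmp_path, caplog):
        tri = Polygon([(0, 0), (2, 0), (0, 2)])
        vec, csv = self.write_inputs(tmp_path, [self.feature("A0", tri)], ["A0,TX00,S1,P1"])
        import logging

        with caplog.at_level(logging.WARNING):
            recs = load_crowns(vec, csv)
        assert recs[0].polygon.bounds == (0.0, 0.0, 2.0, 2.0)
        assert recs[0].polygon.area == pytest.approx(4.0)


class TestRoundTrips:
    def test_raster_world_file_round_trip(self, tmp_path):
        tile = RasterTile(origin=(310.0, 4705.0), resolution=0.5, values=np.ones((4, 6), dtype=np.uint8))
        write_raster(tmp_path / "t.tif", tile)
        back = read_raster(tmp_path / "t.tif")
        assert back.origin == pytest.approx(tile.origin)
        assert back.resolution == pytest.approx(0.5)
        assert np.array_equal(back.values, tile.values)

    def test_xyz_round_trip(self, tmp_path, rng):
        cloud = PointCloud(rng.uniform(0, 50, (25, 3)))
        write_xyz(tmp_path / "p.xyz", cloud)
        back = read_xyz(tmp_path / "p.xyz")
        assert np.allclose(back.points, cloud.points, atol=1e-4)
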