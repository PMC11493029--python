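"""Hydrology (fill, D8, accumulation, sub-basins) and buffer geometry."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point, Polygon

from mcrisk import (Raster, VectorLayer, buffer_zones, d8_flow_direction,
                    delineate_subbasins, fill_sinks, flow_accumulation,
                    lakeshore_zone)
from mcrisk.spatial_scales import D8_OFFSETS, OUTLET


def _dem(values, cell=10.0):
    return Raster(values=np.asarray(values, dtype=float), cell_size=cell,
                  origin=(0.0, np.asarray(values).shape[0] * cell),
                  semantic="dem")


def has_interior_local_min(z: np.ndarray) -> bool:
    nr, nc = z.shape
    for i in range(1, nr - 1):
        for j in range(1, nc - 1):
            if all(z[i, j] < z[i + di, j + dj] for di, dj in D8_OFFSETS):
                return True
    return False


class TestFillSinks:
    def test_depressionless_dem_unchanged(self):
        ramp = np.add.outer(np.arange(5.0), np.arange(5.0))
        out = fill_sinks(_dem(ramp))
        np.testing.assert_array_equal(out.values, ramp)

    def test_single_pit_raised_to_pour_elevation(self):
        z = np.full((5, 5), 10.0)
        z[2, 2] = 3.0          # pit of depth 7
        z[2, 3] = 8.0          # spill path to the border at elevation 8
        z[2, 4] = 8.0
        out = fill_sinks(_dem(z))
        assert out.values[2, 2] == 8.0

    def test_no_local_minima_after_filling(self):
        rng = np.random.default_rng(12)
        z = rng.uniform(0, 100, size=(20, 20))
        out = fill_sinks(_dem(z))
        assert not has_interior_local_min(out.values)
        assert np.all(out.values >= z - 1e-12)


class TestFlowDirection:
    def test_east_tilted_plane_points_east(self):
        z = np.tile(np.arange(6.0, 0.0, -1.0), (6, 1))
        d = d8_flow_direction(fill_sinks(_dem(z))).values
        east = D8_OFFSETS.index((0, 1))
        assert np.all(d[1:-1, 1:-1] == east)

    def test_cone_summit_tie_resolves_east(self):
        ii, jj = np.mgrid[0:7, 0:7]
        z = -np.hypot(ii - 3, jj - 3)  # symmetric cone, summit at centre
        d = d8_flow_direction(fill_sinks(_dem(z))).values
        assert d[3, 3] == D8_OFFSETS.index((0, 1))

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(21)
        z = fill_sinks(_dem(rng.uniform(0, 50, size=(12, 12)))).values
        d = d8_flow_direction(_dem(z)).values
        nr, nc = z.shape
        dists = [1.0 if di == 0 or dj == 0 else np.sqrt(2)
                 for di, dj in D8_OFFSETS]
        for i in range(nr):
            for j in range(nc):
                drops = []
                for k, (di, dj) in enumerate(D8_OFFSETS):
                    ni, nj = i + di, j + dj
                    if 0 <= ni < nr and 0 <= nj < nc:
                        drops.append(((z[i, j] - z[ni, nj]) / dists[k], k))
                best_drop = max(drops)[0] if drops else 0.0
                on_border = i in (0, nr - 1) or j in (0, nc - 1)
                if best_drop > 0:
                    # first k attaining the max (fixed tie order)
                    want = next(k for dr, k in drops
                                if dr == best_drop)
                    assert d[i, j] == want
                elif on_border:
                    assert d[i, j] == OUTLET
                else:
                    # flat cell: resolved toward an equal-elevation neighbour
                    k = d[i, j]
                    assert 0 <= k < 8
                    di, dj = D8_OFFSETS[k]
                    assert z[i + di, j + dj] == z[i, j]


class TestFlowAccumulation:
    def test_chain_counts_upstream(self):
        z = np.array([[5.0, 4.0, 3.0, 2.0, 1.0]])
        acc = flow_accumulation(d8_flow_direction(_dem(z))).values
        np.testing.assert_array_equal(acc, [[0, 1, 2, 3, 4]])

    def test_fully_convergent_basin_outlet(self):
        # inward cone with an outlet notch at the border
        ii, jj = np.mgrid[0:9, 0:9]
        z = np.hypot(ii - 4, jj - 4) + 1.0
        z[4, 0] = 0.5  # border outlet
        fdir = d8_flow_direction(fill_sinks(_dem(z)))
        acc = flow_accumulation(fdir).values
        assert acc.max() == acc[4, 0]


class TestSubbasins:
    def _y_drainage(self):
        # two valleys joining at a single outlet on the south edge
        z = np.zeros((7, 7))
        for i in range(7):
            for j in range(7):
                z[i, j] = (6 - i) + min(abs(j - 1), abs(j - 5)) * 2
        z[:, 3] += 3.0  # ridge between the branches
        return _dem(z)

    def test_two_branches_give_disjoint_zones(self):
        dem = self._y_drainage()
        fdir = d8_flow_direction(fill_sinks(dem))
        s = dem.cell_size
        pours = VectorLayer(features=[
            (Point(1.5 * s, 0.5 * s), {"name": "west"}),
            (Point(5.5 * s, 0.5 * s), {"name": "east"}),
        ], geometry_kind="point")
        zs = delineate_subbasins(fdir, pours, snap_radius=1)
        west, east = zs.zones[1].mask, zs.zones[2].mask
        assert not np.any(west & east)
        assert west.sum() > 5 and east.sum() > 5

    def test_zone_size_is_one_plus_accumulation(self):
        dem = self._y_drainage()
        fdir = d8_flow_direction(fill_sinks(dem))
        acc = flow_accumulation(fdir).values
        s = dem.cell_size
        pours = VectorLayer(
            features=[(Point(1.5 * s, 0.5 * s), {"name": "west"})],
            geometry_kind="point")
        zs = delineate_subbasins(fdir, pours, snap_radius=1)
        zone = zs.zones[1]
        # locate the snapped pour cell: the zone cell with max accumulation
        pour_acc = acc[zone.mask].max()
        assert zone.n_cells == pour_acc + 1

    def test_colliding_pour_points_rejected(self):
        dem = self._y_drainage()
        fdir = d8_flow_direction(fill_sinks(dem))
        s = dem.cell_size
        pours = VectorLayer(features=[
            (Point(1.5 * s, 0.5 * s), {"name": "a"}),
            (Point(1.5 * s, 0.5 * s), {"name": "b"}),
        ], geometry_kind="point")
        with pytest.raises(ValueError):
            delineate_subbasins(fdir, pours, snap_radius=0)


class TestBuffers:
    def template(self, n=160, cell=20.0):
        return Raster(values=np.zeros((n, n)), cell_size=cell,
                      origin=(0.0, n * cell), semantic="dem")

    def rivers(self):
        # straight 1000 m west-east segment through the middle
        line = LineString([(1100.0, 1600.0), (2100.0, 1600.0)])
        return VectorLayer(features=[(line, {"name": "River A"})],
                           geometry_kind="polyline")

    def test_capsule_area_analytic(self):
        t = self.template()
        zs = buffer_zones(self.rivers(), t, distances=(100.0,))[100.0]
        area = zs.zones[1].n_cells * t.cell_size ** 2
        want = 2 * 1000.0 * 100.0 + np.pi * 100.0 ** 2
        assert area == pytest.approx(want, rel=0.02)

    def test_nesting_across_distances(self):
        t = self.template(n=80, cell=40.0)
        buf = buffer_zones(self.rivers(), t,
                           distances=(100.0, 300.0, 500.0, 700.0, 1000.0))
        masks = [buf[w].zones[1].mask for w in (100, 300, 500, 700, 1000)]
        for inner, outer in zip(masks, masks[1:]):
            assert np.all(outer[inner])

    def test_membership_matches_bruteforce_distance(self):
        t = self.template(n=30, cell=50.0)
        line = LineString([(200.0, 200.0), (900.0, 1100.0)])
        v = VectorLayer(features=[(line, {"name": "R"})],
                        geometry_kind="polyline")
        zs = buffer_zones(v, t, distances=(300.0,))[300.0]
        xs, ys = t.cell_centers()
        for i in range(t.shape[0]):
            for j in range(t.shape[1]):
                d = line.distance(Point(xs[i, j], ys[i, j]))
                assert zs.zones[1].mask[i, j] == (d <= 300.0)

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError):
            buffer_zones(VectorLayer(features=[], geometry_kind="polyline"),
                         self.template())


class TestLakeshore:
    def test_land_side_band(self):
        t = Raster(values=np.zeros((40, 40)), cell_size=20.0,
                   origin=(0.0, 800.0), semantic="dem")
        lake_poly = Polygon([(300, 300), (500, 300), (500, 500), (300, 500)])
        lake = VectorLayer(features=[(lake_poly, {"name": "lake"})],
                           geometry_kind="polygon")
        zs = lakeshore_zone(lake, t, width=110.0)
        mask = zs.zones[1].mask
        xs, ys = t.cell_centers()
        inside = np.array([
            lake_poly.contains(Point(x, y))
            for x, y in zip(xs.ravel(), ys.ravel())]).reshape(t.shape)
        assert not np.any(mask & inside)  # lake cells excluded
        # brute-force membership: within 110 m of the boundary, outside
        for i in range(t.shape[0]):
            for j in range(t.shape[1]):
                d = lake_poly.exterior.distance(Point(xs[i, j], ys[i, j]))
                want = (d <= 110.0) and not inside[i, j]
                assert mask[i, j] == want

    def test_nested_in_wider_band(self):
        t = Raster(values=np.zeros((40, 40)), cell_size=20.0,
                   origin=(0.0, 800.0), semantic="dem")
        lake_poly = Polygon([(300, 300), (500, 300), (500, 500), (300, 500)])
        lake = VectorLayer(features=[(lake_poly, {"name": "lake"})],
                           geometry_kind="polygon")
        narrow = lakeshore_zone(lake, t, width=110.0).zones[1].mask
        wide = lakeshore_zone(lake, t, width=300.0).zones[1].mask
        assert np.all(wide[narrow])
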