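"""Terrain surface areas and the 2.5D area correction."""

import math

import numpy as np
import pytest

import movekde as mk


def planar_dem(a=2.0, b=3.0, n=7, cell=10.0):
    """DEM sampling the plane z = a*x + b*y at cell centers."""
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    x = (jj + 0.5) * cell
    y = (ii + 0.5) * cell
    return mk.ElevationRaster(x0=0.0, y0=0.0, cell=cell, values=a * x + b * y)


class TestBilinear:
    def test_cell_center_node(self):
        dem = planar_dem()
        assert mk.bilinear_elevation(dem, 25.0, 35.0) == pytest.approx(
            2 * 25.0 + 3 * 35.0
        )

    def test_plane_reproduced_anywhere(self):
        dem = planar_dem()
        rng = np.random.default_rng(1)
        xs = rng.uniform(6.0, 64.0, 25)
        ys = rng.uniform(6.0, 64.0, 25)
        got = mk.bilinear_elevation(dem, xs, ys)
        assert np.allclose(got, 2 * xs + 3 * ys, atol=1e-9)

    def test_midpoint_average(self):
        dem = mk.ElevationRaster(x0=0, y0=0, cell=10.0,
                                 values=np.arange(9.0).reshape(3, 3))
        mid = mk.bilinear_elevation(dem, 10.0, 5.0)
        assert mid == pytest.approx(0.5 * (dem.values[0, 0] + dem.values[0, 1]))

    def test_outside_hull_raises(self):
        dem = planar_dem()
        with pytest.raises(ValueError, match="hull"):
            mk.bilinear_elevation(dem, 1.0, 1.0)

    def test_nodata_neighbor_raises(self):
        values = np.zeros((3, 3))
        values[1, 1] = np.nan
        dem = mk.ElevationRaster(x0=0, y0=0, cell=10.0, values=values)
        with pytest.raises(ValueError, match="nodata"):
            mk.bilinear_elevation(dem, 10.0, 10.0)


class TestCellSurfaceArea:
    def test_flat_30m_cell_is_900(self):
        dem = mk.generate_dem("flat", 5, 5, 30.0)
        assert mk.cell_surface_area(dem, 2, 2) == pytest.approx(900.0, abs=1e-9)

    def test_tilted_plane_cosine_rule(self):
        dem = mk.generate_dem("ramp", 7, 7, 30.0, theta_deg=45.0)
        assert mk.cell_surface_area(dem, 3, 3) == pytest.approx(
            900.0 * math.sqrt(2.0), rel=1e-9
        )

    def test_never_below_planimetric(self):
        dem = mk.generate_dem("gaussian_hill", 9, 9, 30.0, amp=120.0, width=60.0)
        for i in range(1, 8):
            for j in range(1, 8):
                assert mk.cell_surface_area(dem, i, j) >= 900.0 - 1e-9

    def test_edge_cell_rejected(self):
        dem = mk.generate_dem("flat", 5, 5, 30.0)
        with pytest.raises(ValueError, match="interior"):
            mk.cell_surface_area(dem, 0, 2)

    def test_dense_triangulation_oracle(self):
        # subdivide the same bilinear surface into 100x100 triangles per cell
        dem = mk.generate_dem("gaussian_hill", 9, 9, 30.0, amp=150.0, width=50.0)
        i = j = 4
        area = mk.cell_surface_area(dem, i, j)
        n = 100
        c = dem.cell
        xs = np.linspace(j * c, (j + 1) * c, n + 1)
        ys = np.linspace(i * c, (i + 1) * c, n + 1)
        xx, yy = np.meshgrid(xs, ys)
        zz = mk.bilinear_elevation(dem, xx.ravel(), yy.ravel()).reshape(xx.shape)
        dense = 0.0
        for a in range(n):
            for b in range(n):
                p00 = np.array([xx[a, b], yy[a, b], zz[a, b]])
                p01 = np.array([xx[a, b + 1], yy[a, b + 1], zz[a, b + 1]])
                p10 = np.array([xx[a + 1, b], yy[a + 1, b], zz[a + 1, b]])
                p11 = np.array([xx[a + 1, b + 1], yy[a + 1, b + 1], zz[a + 1, b + 1]])
                dense += 0.5 * np.linalg.norm(np.cross(p01 - p00, p10 - p00))
                dense += 0.5 * np.linalg.norm(np.cross(p01 - p11, p10 - p11))
        assert area == pytest.approx(dense, rel=0.01)


class TestSurfaceAreaRaster:
    def test_flat_interior(self):
        dem = mk.generate_dem("flat", 5, 5, 30.0)
        sar = mk.surface_area_raster(dem)
        interior = sar.values[1:-1, 1:-1]
        assert np.allclose(interior, 900.0)
        assert np.all(np.isnan(sar.values[0, :]))  # edge ring excluded

    def test_replicate_edge_policy_fills_ring(self):
        dem = mk.generate_dem("flat", 5, 5, 30.0)
        sar = mk.surface_area_raster(dem, edge_policy="replicate")
        assert np.allclose(sar.values, 900.0)

    def test_steeper_terrain_larger_area(self):
        areas = []
        for theta in (0.0, 15.0, 30.0):
            dem = mk.generate_dem("ramp", 5, 5, 30.0, theta_deg=theta)
            sar = mk.surface_area_raster(dem)
            areas.append(np.nanmean(sar.values))
        assert areas[0] < areas[1] < areas[2]

    def test_nodata_propagates_to_neighborhood(self):
        values = np.zeros((5, 5))
        values[2, 2] = np.nan
        dem = mk.ElevationRaster(x0=0, y0=0, cell=30.0, values=values)
        sar = mk.surface_area_raster(dem)
        assert np.all(np.isnan(sar.values[1:4, 1:4]))


def make_ud2d(probs, cell=30.0):
    probs = np.asarray(probs, dtype=float)
    spec = mk.GridSpec3D(x0=0, y0=0, z0=0, hx=cell / 2, hy=cell / 2, hz=0.5,
                         I=probs.shape[0], J=probs.shape[1])
    return mk.UDGrid(spec=spec, probs=probs, ndim=2, total_time=60.0)


class TestAdjust25D:
    def test_flat_terrain_is_identity(self):
        dem = mk.generate_dem("flat", 5, 5, 30.0)
        sar = mk.surface_area_raster(dem, edge_policy="replicate")
        probs = np.random.default_rng(2).random((5, 5))
        probs /= probs.sum()
        ud = make_ud2d(probs)
        adj = mk.adjust_ud_25d(ud, sar)
        assert np.allclose(adj.probs, ud.probs, atol=1e-12)

    def test_hand_normalization(self):
        sar = mk.SurfaceAreaRaster(
            x0=0, y0=0, cell=30.0, values=np.array([[900.0, 1100.0]])
        )
        ud = make_ud2d([[0.5, 0.5]])
        adj = mk.adjust_ud_25d(ud, sar)
        assert adj.probs[0, 0] == pytest.approx(0.45)
        assert adj.probs[0, 1] == pytest.approx(0.55)
        assert adj.probs.sum() == pytest.approx(1.0)

    def test_geometry_mismatch(self):
        sar = mk.SurfaceAreaRaster(x0=0, y0=0, cell=10.0,
                                   values=np.full((5, 5), 100.0))
        ud = make_ud2d(np.full((5, 5), 0.04), cell=30.0)
        with pytest.raises(ValueError, match="co-registered"):
            mk.adjust_ud_25d(ud, sar)


class TestAreaWithinContour:
    def _fixture(self, kind="gaussian_hill", **kw):
        n, cell = 9, 30.0
        dem = mk.generate_dem(kind, n, n, cell, **kw)
        sar = mk.surface_area_raster(dem, edge_policy="replicate")
        # unimodal synthetic UD centred on the grid
        jj, ii = np.meshgrid(np.arange(n), np.arange(n))
        w = np.exp(-((ii - n // 2) ** 2 + (jj - n // 2) ** 2) / 6.0)
        ud = make_ud2d(w / w.sum(), cell=cell)
        return dem, sar, ud

    def test_full_contour_on_flat_terrain_is_planimetric(self):
        _, sar, ud = self._fixture("flat")
        ud25 = mk.adjust_ud_25d(ud, sar)
        area = mk.area_within_contour(ud25, sar, 1.0)
        n_support = int((ud.probs > 0).sum())
        assert area == pytest.approx(n_support * 900.0)

    def test_rough_terrain_exceeds_planimetric(self):
        _, sar, ud = self._fixture("gaussian_hill", amp=150.0, width=50.0)
        ud25 = mk.adjust_ud_25d(ud, sar)
        for p in (0.5, 0.95):
            a25 = mk.area_within_contour(ud25, sar, p)
            thr = mk.contour_threshold(ud25.probs, p)
            planimetric = float((ud25.probs >= thr).sum()) * 900.0
            assert a25 > planimetric

    def test_contour_nesting(self):
        _, sar, ud = self._fixture("gaussian_hill", amp=150.0, width=50.0)
        ud25 = mk.adjust_ud_25d(ud, sar)
        assert mk.area_within_contour(ud25, sar, 0.5) <= mk.area_within_contour(
            ud25, sar, 0.95
        )
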