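"""Grid geometry, cell areas, regridding, and the light mask."""

import numpy as np
import pytest
from scipy import integrate

from macrorange.grid import (EARTH_RADIUS_KM, GridError, GridSpec, RasterLayer,
                             cell_area, light_mask, regrid)

SPHERE_AREA = 4.0 * np.pi * EARTH_RADIUS_KM**2


def make_layer(grid, values, valid=None, variable="sst"):
    if np.isscalar(values):
        values = np.full(grid.shape, float(values))
    if valid is None:
        valid = np.ones(grid.shape, dtype=bool)
    return RasterLayer(grid=grid, variable=variable, values=values,
                       valid_mask=valid)


class TestGridSpec:
    def test_shape_and_centers(self):
        g = GridSpec(resolution_deg=0.5)
        assert g.shape == (360, 720)
        assert g.lat_centers[0] == -89.75
        assert g.lon_centers[-1] == 179.75
        # centers strictly inside bounds
        assert g.lat_centers.min() > g.lat_min
        assert g.lat_centers.max() < g.lat_max

    @pytest.mark.parametrize("kwargs", [
        dict(resolution_deg=0.7),               # span not a multiple
        dict(lat_min=10, lat_max=5),            # inverted
        dict(lon_min=170, lon_max=190),         # crosses the antimeridian
        dict(resolution_deg=-1.0),
    ])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(GridError):
            GridSpec(**kwargs)

    def test_cell_of_half_open_convention(self):
        g = GridSpec(resolution_deg=1.0, lat_min=0, lat_max=10,
                     lon_min=0, lon_max=10)
        # a point exactly on a cell's south/west edge belongs to that cell
        row, col = g.cell_of(3.0, 4.0)
        assert (row, col) == (4, 3)
        row, col = g.cell_of(3.5, 4.5)
        assert (row, col) == (4, 3)
        # outside the bounds -> -1
        row, col = g.cell_of(10.0, 5.0)  # lon == lon_max is outside
        assert row == -1 and col == -1


class TestCellArea:
    def test_global_sum_closes_on_sphere(self):
        area = cell_area(GridSpec(resolution_deg=0.5)).area_km2
        assert area.sum() == pytest.approx(SPHERE_AREA, rel=1e-6)

    def test_positive_and_hemispherically_symmetric(self):
        g = GridSpec(resolution_deg=2.0)
        area = cell_area(g).area_km2
        assert (area > 0).all()
        assert np.allclose(area, area[::-1, :])  # phi vs -phi

    def test_strictly_decreasing_with_absolute_latitude(self):
        g = GridSpec(resolution_deg=1.0)
        band = cell_area(g).area_km2[:, 0]
        north = band[g.lat_centers > 0]
        assert (np.diff(north) < 0).all()

    def test_equator_cell_matches_quadrature(self):
        """Spherical surface integral over one 0.5 deg cell on the equator."""
        g = GridSpec(resolution_deg=0.5, lat_min=-0.5, lat_max=0.5,
                     lon_min=0, lon_max=0.5)
        area = cell_area(g).area_km2
        cell = area[1, 0]  # cell spanning [0, 0.5) deg latitude
        expected, _ = integrate.dblquad(
            lambda lam, phi: EARTH_RADIUS_KM**2 * np.cos(phi),
            0.0, np.deg2rad(0.5), 0.0, np.deg2rad(0.5))
        assert cell == pytest.approx(expected, rel=1e-9)


class TestRegrid:
    @pytest.mark.parametrize("method", ["nearest", "bilinear", "block_mean"])
    def test_constant_field_preserved(self, method):
        src = GridSpec(resolution_deg=0.25, lat_min=0, lat_max=10,
                       lon_min=0, lon_max=10)
        dst = GridSpec(resolution_deg=0.5, lat_min=0, lat_max=10,
                       lon_min=0, lon_max=10)
        out = regrid(make_layer(src, 7.0), dst, method=method)
        assert out.valid_mask.all()
        assert np.allclose(out.values, 7.0)

    def test_block_mean_is_area_weighted_child_mean(self):
        src = GridSpec(resolution_deg=0.25, lat_min=40, lat_max=41,
                       lon_min=0, lon_max=1)
        dst = GridSpec(resolution_deg=0.5, lat_min=40, lat_max=41,
                       lon_min=0, lon_max=1)
        lat_field = np.broadcast_to(src.lat_centers[:, None], src.shape).copy()
        out = regrid(make_layer(src, lat_field), dst, method="block_mean")
        w = cell_area(src).area_km2
        expected = ((lat_field * w)[:2].sum() / w[:2].sum())
        assert out.values[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_block_mean_conserves_area_weighted_global_mean(self, rng):
        src = GridSpec(resolution_deg=1.0)
        dst = GridSpec(resolution_deg=4.0)
        field = rng.normal(size=src.shape)
        out = regrid(make_layer(src, field), dst, method="block_mean")
        w_src = cell_area(src).area_km2
        w_dst = cell_area(dst).area_km2
        m_src = (field * w_src).sum() / w_src.sum()
        m_dst = (out.values * w_dst).sum() / w_dst.sum()
        assert m_dst == pytest.approx(m_src, rel=1e-9)

    def test_all_missing_source_gives_all_missing_target(self):
        src = GridSpec(resolution_deg=0.5, lat_min=0, lat_max=10,
                       lon_min=0, lon_max=10)
        dst = GridSpec(resolution_deg=1.0, lat_min=0, lat_max=10,
                       lon_min=0, lon_max=10)
        layer = make_layer(src, 1.0, valid=np.zeros(src.shape, dtype=bool))
        for method in ("nearest", "bilinear", "block_mean"):
            out = regrid(layer, dst, method=method)
            assert not out.valid_mask.any()

    def test_non_overlapping_grids_rejected(self):
        src = GridSpec(resolution_deg=1.0, lat_min=0, lat_max=10,
                       lon_min=0, lon_max=10)
        dst = GridSpec(resolution_deg=1.0, lat_min=40, lat_max=50,
                       lon_min=40, lon_max=50)
        with pytest.raises(GridError):
            regrid(make_layer(src, 1.0), dst)


class TestLightMask:
    def grid(self):
        return GridSpec(resolution_deg=1.0, lat_min=0, lat_max=2,
                        lon_min=0, lon_max=2)

    def test_threshold_boundary_inclusive(self):
        g = self.grid()
        vals = np.array([[49.999, 50.0], [0.0, 120.0]])
        layer = make_layer(g, vals, variable="light_bottom")
        mask = light_mask(layer)
        assert mask.tolist() == [[False, True], [False, True]]

    def test_all_land_gives_empty_mask(self):
        g = self.grid()
        layer = make_layer(g, 100.0, valid=np.zeros(g.shape, dtype=bool),
                           variable="light_bottom")
        assert not light_mask(layer).any()

    def test_anti_monotone_in_threshold(self, rng):
        g = GridSpec(resolution_deg=1.0, lat_min=0, lat_max=10,
                     lon_min=0, lon_max=10)
        layer = make_layer(g, rng.uniform(0, 100, g.shape),
                           variable="light_bottom")
        m_lo = light_mask(layer, threshold=30.0)
        m_hi = light_mask(layer, threshold=60.0)
        assert not (m_hi & ~m_lo).any()  # raising threshold never adds cells

    def test_wrong_variable_rejected(self):
        layer = make_layer(self.grid(), 60.0, variable="sst")
        with pytest.raises(ValueError, match="light_bottom"):
            light_mask(layer)
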