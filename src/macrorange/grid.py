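"""Regular latitude/longitude grids, raster layers, cell areas, regridding, masks.

All spatial data in the package lives on an equal-angle geographic grid.
Cells are half-open intervals ``[lat, lat + res) x [lon, lon + res)`` with
centers at ``lat + res/2``, so every point maps to exactly one cell.
Longitudes are restricted to ``[-180, 180)``; grids crossing the
antimeridian are rejected rather than silently wrapped.

Areas are computed on the authalic sphere (R = 6371.0 km) with the exact
spherical-band formula ``A = R^2 * dlon * (sin(lat2) - sin(lat1))``, so the
sum over a full global grid closes on ``4*pi*R^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.interpolate import RegularGridInterpolator

EARTH_RADIUS_KM = 6371.0

#: variable name -> units, for the layers the pipeline understands
VARIABLE_UNITS = {
    "sst": "degC",
    "air_temp": "degC",
    "salinity": "PSU",
    "productivity": "g m-3 day-1",
    "shortwave": "W m-2",
    "ice_cover": "%",
    "depth": "m",
    "light_bottom": "E m-2 yr-1",
}

#: light at bottom below which macrophyte photosynthesis is considered impossible
LIGHT_THRESHOLD = 50.0


class GridError(ValueError):
    """Invalid grid definition or incompatible grids."""


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid.

    Parameters
    ----------
    resolution_deg : float
        Cell size in decimal degrees (same in both axes).
    lat_min, lat_max, lon_min, lon_max : float
        Grid bounds in degrees; each span must be an integer multiple of
        the resolution.
    """

    resolution_deg: float = 0.5
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0

    def __post_init__(self) -> None:
        res = self.resolution_deg
        if res <= 0:
            raise GridError(f"resolution must be positive, got {res}")
        if not (-90 <= self.lat_min < self.lat_max <= 90):
            raise GridError("latitude bounds must satisfy -90 <= min < max <= 90")
        if not (-180 <= self.lon_min < self.lon_max <= 180):
            raise GridError(
                "longitude bounds must lie in [-180, 180]; antimeridian-crossing "
                "grids are not supported"
            )
        for name, span in (("lat", self.lat_span), ("lon", self.lon_span)):
            n = span / res
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise GridError(f"{name} span {span} is not a multiple of {res}")

    @property
    def lat_span(self) -> float:
        return self.lat_max - self.lat_min

    @property
    def lon_span(self) -> float:
        return self.lon_max - self.lon_min

    @property
    def n_rows(self) -> int:
        return int(round(self.lat_span / self.resolution_deg))

    @property
    def n_cols(self) -> int:
        return int(round(self.lon_span / self.resolution_deg))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, south to north (row axis)."""
        res = self.resolution_deg
        return self.lat_min + res * (np.arange(self.n_rows) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        res = self.resolution_deg
        return self.lon_min + res * (np.arange(self.n_cols) + 0.5)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_min + self.resolution_deg * np.arange(self.n_rows + 1)

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.resolution_deg * np.arange(self.n_cols + 1)

    def cell_of(self, lon, lat):
        """Row/col indices of the cells containing the given points.

        Half-open convention: a point on a cell's south or west edge belongs
        to that cell. Points outside the bounds get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        res = self.resolution_deg
        row = np.floor((lat - self.lat_min) / res).astype(int)
        col = np.floor((lon - self.lon_min) / res).astype(int)
        bad = (lat < self.lat_min) | (lat >= self.lat_max) | \
              (lon < self.lon_min) | (lon >= self.lon_max)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def refine(self, factor: int) -> "GridSpec":
        """A grid with the same bounds at ``resolution/factor``."""
        return replace(self, resolution_deg=self.resolution_deg / factor)


@dataclass
class RasterLayer:
    """One 2-D field on a grid, with a validity mask.

    ``values`` is indexed ``[row, col]`` = ``[lat, lon]`` with row 0 at
    ``lat_min`` (south). Cells where ``valid_mask`` is False carry no data.
    """

    grid: GridSpec
    variable: str
    values: np.ndarray
    valid_mask: np.ndarray
    units: str = ""
    time: tuple[int, int] | None = None  # (year, month); None = static
    scenario: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.valid_mask.shape != self.grid.shape:
            raise GridError("valid_mask shape mismatch")
        if not self.units and self.variable in VARIABLE_UNITS:
            self.units = VARIABLE_UNITS[self.variable]
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise GridError(f"{self.variable}: non-finite values on valid cells")

    def masked(self) -> np.ndarray:
        """Values with invalid cells as NaN."""
        out = self.values.astype(float).copy()
        out[~self.valid_mask] = np.nan
        return out


@dataclass
class CellAreaField:
    """Per-cell area in km^2 (depends on latitude only)."""

    grid: GridSpec
    area_km2: np.ndarray = field(repr=False)


def cell_area(grid: GridSpec, radius_km: float = EARTH_RADIUS_KM) -> CellAreaField:
    """Exact spherical cell areas for a regular lat/lon grid.

    Each cell spans a latitude band ``[phi1, phi2]`` and a longitude interval
    of width ``dlam``; its spherical area is
    ``R^2 * dlam * (sin phi2 - sin phi1)``, independent of longitude.
    """
    lat_edges = np.deg2rad(grid.lat_edges)
    dlam = np.deg2rad(grid.resolution_deg)
    band = radius_km**2 * dlam * np.diff(np.sin(lat_edges))  # (n_rows,)
    area = np.repeat(band[:, None], grid.n_cols, axis=1)
    return CellAreaField(grid=grid, area_km2=area)


RegridMethod = Literal["nearest", "bilinear", "block_mean"]


def regrid(layer: RasterLayer, target: GridSpec,
           method: RegridMethod = "bilinear") -> RasterLayer:
    """Interpolate a layer onto another grid.

    ``nearest`` and ``bilinear`` sample at target cell centers (bilinear on
    the source cell-center lattice, with nearest-edge extension at the rim).
    ``block_mean`` requires the target resolution to be an integer multiple
    of the source resolution and takes the area-weighted mean of the child
    cells, which conserves the area-weighted global mean of fully valid
    fields. Invalid source cells propagate: bilinear/nearest results touching
    them are masked; block means are taken over the valid children only.
    """
    src_g = layer.grid
    if (target.lat_min >= src_g.lat_max or target.lat_max <= src_g.lat_min or
            target.lon_min >= src_g.lon_max or target.lon_max <= src_g.lon_min):
        raise GridError("source and target grids do not overlap")

    if method == "block_mean":
        return _regrid_block_mean(layer, target)

    src_vals = layer.masked()
    lats, lons = src_g.lat_centers, src_g.lon_centers
    tlat, tlon = np.meshgrid(target.lat_centers, target.lon_centers, indexing="ij")
    if method == "nearest":
        interp = RegularGridInterpolator(
            (lats, lons), src_vals, method="nearest",
            bounds_error=False, fill_value=np.nan)
        out = interp(np.stack([tlat.ravel(), tlon.ravel()], axis=1))
    elif method == "bilinear":
        # clamp to the center lattice so rim cells take the nearest edge value
        qlat = np.clip(tlat.ravel(), lats[0], lats[-1])
        qlon = np.clip(tlon.ravel(), lons[0], lons[-1])
        interp = RegularGridInterpolator(
            (lats, lons), src_vals, method="linear",
            bounds_error=False, fill_value=np.nan)
        out = interp(np.stack([qlat, qlon], axis=1))
    else:
        raise ValueError(f"unknown regrid method {method!r}")
    out = out.reshape(target.shape)
    valid = np.isfinite(out)
    out[~valid] = 0.0
    return RasterLayer(grid=target, variable=layer.variable, values=out,
                       valid_mask=valid, units=layer.units,
                       time=layer.time, scenario=layer.scenario)


def _regrid_block_mean(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    src_g = layer.grid
    ratio = target.resolution_deg / src_g.resolution_deg
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise GridError(
            f"block_mean needs target resolution {target.resolution_deg} to be an "
            f"integer multiple of source resolution {src_g.resolution_deg}")
    if (abs(target.lat_min - src_g.lat_min) > 1e-9 or
            abs(target.lon_min - src_g.lon_min) > 1e-9 or
            abs(target.lat_max - src_g.lat_max) > 1e-9 or
            abs(target.lon_max - src_g.lon_max) > 1e-9):
        raise GridError("block_mean requires identical grid bounds")
    nr, nc = target.shape
    vals = layer.values.reshape(nr, k, nc, k)
    valid = layer.valid_mask.reshape(nr, k, nc, k)
    w = cell_area(src_g).area_km2.reshape(nr, k, nc, k)
    w = np.where(valid, w, 0.0)
    wsum = w.sum(axis=(1, 3))
    out_valid = wsum > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_valid, (vals * w).sum(axis=(1, 3)) / wsum, 0.0)
    return RasterLayer(grid=target, variable=layer.variable, values=out,
                       valid_mask=out_valid, units=layer.units,
                       time=layer.time, scenario=layer.scenario)


def light_mask(light_bottom: RasterLayer,
               threshold: float = LIGHT_THRESHOLD) -> np.ndarray:
    """Boolean mask of cells with enough light at the seabed for macrophytes.

    True exactly where the cell is valid (ocean) and light at bottom is at
    least ``threshold`` (E m^-2 yr^-1); cells below the threshold are
    considered light-limited and excluded from all habitat computations.
    """
    if light_bottom.variable != "light_bottom":
        raise ValueError(
            f"light_mask expects a light_bottom layer, got {light_bottom.variable!r}")
    return light_bottom.valid_mask & (light_bottom.values >= threshold)
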