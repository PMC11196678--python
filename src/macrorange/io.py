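"""File formats: CF-style NetCDF rasters and tidy CSV tables.

NetCDF files are written with the scipy (netCDF3) backend so they remain
readable anywhere; every load can be validated against the run's declared
grid. Missing values travel as NaN fill values and are restored to the
layer's validity mask.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

from .grid import GridSpec, RasterLayer


def grid_from_dataset(ds: xr.Dataset) -> GridSpec:
    lat = ds["lat"].values
    lon = ds["lon"].values
    res = float(lat[1] - lat[0]) if len(lat) > 1 else float(lon[1] - lon[0])
    return GridSpec(resolution_deg=res,
                    lat_min=float(lat[0] - res / 2),
                    lat_max=float(lat[-1] + res / 2),
                    lon_min=float(lon[0] - res / 2),
                    lon_max=float(lon[-1] + res / 2))


def layer_to_dataarray(layer: RasterLayer) -> xr.DataArray:
    da = xr.DataArray(
        layer.masked(),
        dims=("lat", "lon"),
        coords={"lat": layer.grid.lat_centers, "lon": layer.grid.lon_centers},
        name=layer.variable,
        attrs={"units": layer.units, "scenario": layer.scenario or ""})
    if layer.time is not None:
        da.attrs["year"], da.attrs["month"] = layer.time
    return da


def save_field(path: Path, name: str, values: np.ndarray, grid: GridSpec,
               attrs: dict | None = None) -> None:
    """Write one 2-D field (NaN = missing) as a small NetCDF file."""
    da = xr.DataArray(values, dims=("lat", "lon"),
                      coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
                      name=name, attrs=attrs or {})
    da.to_dataset().to_netcdf(path, engine="scipy")


def load_field(path: Path, name: str,
               expected_grid: GridSpec | None = None) -> tuple[np.ndarray, GridSpec]:
    with xr.open_dataset(path, engine="scipy") as ds:
        grid = grid_from_dataset(ds)
        values = ds[name].values.copy()
    if expected_grid is not None and grid != expected_grid:
        raise ValueError(f"{path}: grid {grid} does not match declared "
                         f"{expected_grid}")
    return values, grid


def layer_from_file(path: Path, variable: str,
                    expected_grid: GridSpec | None = None) -> RasterLayer:
    values, grid = load_field(path, variable, expected_grid)
    valid = np.isfinite(values)
    values = np.where(valid, values, 0.0)
    return RasterLayer(grid=grid, variable=variable, values=values,
                       valid_mask=valid)
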