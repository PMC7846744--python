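"""File interchange: NetCDF climate cubes, TIFF rasters, CSV tables.

Cubes are written as classic NetCDF (CF-style ``year``/``month``/``y``/``x``
dimensions with units attributes) through xarray's scipy backend.  Raster
maps (realm masks, species ranges, richness/deficit grids) are written as
single- or multi-band TIFF via tifffile, with the grid geometry stored in
the image description tag as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .climate_prep import BIOCLIM_VARS, BioclimStack
from .cube import CLIMATE_VARS, ClimateCube
from .grid import GridSpec, RealmMask

_UNITS = {"tmin": "degC", "tmax": "degC", "tmean": "degC", "prec": "mm/month"}


def cube_to_dataset(cube: ClimateCube) -> xr.Dataset:
    coords = {
        "year": cube.years,
        "month": np.arange(1, 13),
        "y": cube.grid.lat_centers(),
        "x": cube.grid.lon_centers(),
    }
    data_vars = {
        var: xr.DataArray(
            cube.data[var],
            dims=("year", "month", "y", "x"),
            attrs={"units": _UNITS[var]},
        )
        for var in CLIMATE_VARS
    }
    ds = xr.Dataset(data_vars, coords=coords)
    ds.attrs.update(
        label=cube.label,
        cell_size=cube.grid.cell_size,
        lon0=cube.grid.lon0,
        lat0=cube.grid.lat0,
    )
    return ds


def write_cube(cube: ClimateCube, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cube_to_dataset(cube).to_netcdf(path, engine="scipy")
    return path


def read_cube(path: str | Path) -> ClimateCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = GridSpec(
        n_rows=ds.sizes["y"],
        n_cols=ds.sizes["x"],
        cell_size=float(ds.attrs["cell_size"]),
        lon0=float(ds.attrs["lon0"]),
        lat0=float(ds.attrs["lat0"]),
    )
    return ClimateCube(
        grid=grid,
        years=ds["year"].values,
        data={var: ds[var].values for var in CLIMATE_VARS},
        label=str(ds.attrs.get("label", "")),
    )


def _grid_meta(grid: GridSpec, **extra) -> str:
    return json.dumps(
        {
            "n_rows": grid.n_rows,
            "n_cols": grid.n_cols,
            "cell_size": grid.cell_size,
            "lon0": grid.lon0,
            "lat0": grid.lat0,
            **extra,
        }
    )


def write_raster(
    array: np.ndarray, grid: GridSpec, path: str | Path, **tags
) -> Path:
    """Write a 2-D array (or band-stack) as TIFF with grid metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array), description=_grid_meta(grid, **tags))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec, dict]:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    grid = GridSpec(
        n_rows=meta.pop("n_rows"),
        n_cols=meta.pop("n_cols"),
        cell_size=meta.pop("cell_size"),
        lon0=meta.pop("lon0", 0.0),
        lat0=meta.pop("lat0", 60.0),
    )
    return arr, grid, meta


def write_bioclim_stack(stack: BioclimStack, path: str | Path) -> Path:
    """Five-band TIFF in bio1/bio5/bio6/bio12/bio15 order."""
    bands = np.stack([stack.data[v] for v in BIOCLIM_VARS]).astype(np.float32)
    return write_raster(
        bands, stack.grid, path, bands=list(BIOCLIM_VARS), period=stack.label
    )


def read_bioclim_stack(path: str | Path) -> BioclimStack:
    arr, grid, meta = read_raster(path)
    bands = meta.get("bands", list(BIOCLIM_VARS))
    return BioclimStack(
        grid=grid,
        data={b: arr[i].astype(float) for i, b in enumerate(bands)},
        label=meta.get("period", ""),
    )


def write_realm_mask(mask: RealmMask, path: str | Path) -> Path:
    return write_raster(
        mask.labels.astype(np.int16), mask.grid, path, realm_names=list(mask.names)
    )


def read_realm_mask(path: str | Path) -> RealmMask:
    arr, grid, meta = read_raster(path)
    return RealmMask(grid=grid, labels=arr, names=tuple(meta["realm_names"]))


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV with stable column order and no index, for bit-reproducible runs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path
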