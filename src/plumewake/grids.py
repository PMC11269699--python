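"""Raster primitives on regular lon/lat grids.

Everything in this package lives on cell-center-registered rectangular
grids in geographic coordinates: daily NO2 columns, vehicle-kilometer
rasters and sectoral emission fluxes all share :class:`RasterField`.
Satellite footprints (quadrilaterals at native sensor resolution) are
averaged onto the fine grid by area-weighted oversampling; coarse
reanalysis fields are brought to the fine grid by bilinear interpolation.

Grid convention: 0-based indices, cell (0, 0) at the south-west corner,
cell centers at ``origin + (index + 0.5) * step``.  Arrays are indexed
``[lat_index, lon_index]`` (row 0 = southernmost row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from shapely.geometry import Polygon, box


@dataclass(frozen=True)
class GridSpec:
    """Definition of a regular lon/lat grid.

    Parameters
    ----------
    lon_origin, lat_origin : float
        Coordinates of the south-west *corner* of cell (0, 0), degrees.
    step : float
        Cell size in degrees (same in both axes).
    n_lon, n_lat : int
        Number of columns / rows.
    """

    lon_origin: float
    lat_origin: float
    step: float
    n_lon: int
    n_lat: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_origin + (np.arange(self.n_lon) + 0.5) * self.step

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_origin + (np.arange(self.n_lat) + 0.5) * self.step

    @property
    def lon_max(self) -> float:
        return self.lon_origin + self.n_lon * self.step

    @property
    def lat_max(self) -> float:
        return self.lat_origin + self.n_lat * self.step

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lon_origin <= lon <= self.lon_max
            and self.lat_origin <= lat <= self.lat_max
        )

    def cell_of(self, lon, lat):
        """Indices (iy, ix) of the cell whose center is nearest (lon, lat).

        A point equidistant to two centers is assigned the lower index.
        """
        fx = (np.asarray(lon) - self.lon_origin) / self.step - 0.5
        fy = (np.asarray(lat) - self.lat_origin) / self.step - 0.5
        # round-half-down implements the lower-index tie-break
        ix = np.ceil(fx - 0.5).astype(int)
        iy = np.ceil(fy - 0.5).astype(int)
        ix = np.clip(ix, 0, self.n_lon - 1)
        iy = np.clip(iy, 0, self.n_lat - 1)
        return iy, ix


@dataclass
class RasterField:
    """A value grid plus a validity mask on a :class:`GridSpec`."""

    spec: GridSpec
    values: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.spec.shape:
                raise ValueError("valid_mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite values inside the valid mask")

    def copy(self) -> "RasterField":
        return RasterField(self.spec, self.values.copy(), self.valid_mask.copy())

    def masked(self) -> np.ndarray:
        """Values with invalid cells replaced by NaN."""
        out = self.values.copy()
        out[~self.valid_mask] = np.nan
        return out


@dataclass(frozen=True)
class FootprintObservation:
    """One satellite footprint: a quadrilateral, a column value and a QA flag."""

    corners: tuple  # four (lon, lat) pairs
    value: float
    qa: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qa <= 1.0):
            raise ValueError("qa must be in [0, 1]")
        if Polygon(self.corners).area <= 0:
            raise ValueError("footprint must have positive area")


@dataclass
class Window:
    """A square neighbourhood extracted around a point.

    ``values``/``valid`` have shape (2R+1, 2R+1); ``center`` records the
    (iy, ix) cell of the parent field at the window center.
    """

    values: np.ndarray
    valid: np.ndarray
    center: tuple[int, int]

    @property
    def radius(self) -> int:
        return self.values.shape[0] // 2


def oversample(
    footprints,
    grid: GridSpec,
    qa_threshold: float = 0.75,
) -> RasterField:
    """Average footprints onto a fine grid, weighting by overlap area.

    Footprints with ``qa < qa_threshold`` are discarded.  Each retained
    footprint contributes to every fine cell it intersects with weight
    equal to the footprint-cell overlap area; a cell's value is the
    weighted mean of contributions and cells touched by no retained
    footprint are masked invalid.  The result does not depend on the
    order of the footprints.
    """
    if not (0.0 <= qa_threshold <= 1.0):
        raise ValueError("qa_threshold must be in [0, 1]")
    wsum = np.zeros(grid.shape)
    vsum = np.zeros(grid.shape)
    for fp in footprints:
        if fp.qa < qa_threshold:
            continue
        poly = Polygon(fp.corners)
        lon0, lat0, lon1, lat1 = poly.bounds
        ix0 = max(int(np.floor((lon0 - grid.lon_origin) / grid.step)), 0)
        ix1 = min(int(np.ceil((lon1 - grid.lon_origin) / grid.step)), grid.n_lon)
        iy0 = max(int(np.floor((lat0 - grid.lat_origin) / grid.step)), 0)
        iy1 = min(int(np.ceil((lat1 - grid.lat_origin) / grid.step)), grid.n_lat)
        for iy in range(iy0, iy1):
            cy = grid.lat_origin + iy * grid.step
            for ix in range(ix0, ix1):
                cx = grid.lon_origin + ix * grid.step
                cell = box(cx, cy, cx + grid.step, cy + grid.step)
                a = poly.intersection(cell).area
                if a > 0:
                    wsum[iy, ix] += a
                    vsum[iy, ix] += a * fp.value
    valid = wsum > 0
    values = np.full(grid.shape, np.nan)
    values[valid] = vsum[valid] / wsum[valid]
    return RasterField(grid, values, valid)


def _bilinear_weights(xf: np.ndarray, n: int):
    """Neighbour indices and weights along one axis of cell-center samples.

    ``xf`` is the fractional cell-center coordinate (0 at the first
    center, n-1 at the last).  Returns (i0, i1, w1, inside) where the
    interpolated value is ``(1-w1)*v[i0] + w1*v[i1]``.
    """
    inside = (xf >= 0.0) & (xf <= n - 1)
    xc = np.clip(xf, 0.0, n - 1)
    i0 = np.floor(xc).astype(int)
    i0 = np.minimum(i0, n - 2) if n > 1 else np.zeros_like(i0)
    i1 = np.minimum(i0 + 1, n - 1)
    w1 = xc - i0
    return i0, i1, w1, inside


def bilinear_at_points(coarse: RasterField, lons, lats):
    """Bilinear interpolation of cell-center values at arbitrary points.

    Returns (values, valid); a point is valid only when all four
    surrounding coarse cells are valid and the point lies inside the
    convex hull of cell centers.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    g = coarse.spec
    xf = (lons - g.lon_origin) / g.step - 0.5
    yf = (lats - g.lat_origin) / g.step - 0.5
    ix0, ix1, wx, in_x = _bilinear_weights(xf, g.n_lon)
    iy0, iy1, wy, in_y = _bilinear_weights(yf, g.n_lat)
    v = coarse.values
    m = coarse.valid_mask
    out = (
        v[iy0, ix0] * (1 - wy) * (1 - wx)
        + v[iy0, ix1] * (1 - wy) * wx
        + v[iy1, ix0] * wy * (1 - wx)
        + v[iy1, ix1] * wy * wx
    )
    ok = (
        in_x
        & in_y
        & m[iy0, ix0]
        & m[iy0, ix1]
        & m[iy1, ix0]
        & m[iy1, ix1]
    )
    out = np.where(ok, out, np.nan)
    return out, ok


def bilinear_to_fine(coarse: RasterField, fine_grid: GridSpec) -> RasterField:
    """Interpolate a coarse field onto a finer grid (cell centers).

    Output cells outside the coarse cell-center hull, or whose four
    surrounding coarse cells are not all valid, are masked.
    """
    lon = fine_grid.lon_centers
    lat = fine_grid.lat_centers
    LON, LAT = np.meshgrid(lon, lat)
    vals, ok = bilinear_at_points(coarse, LON.ravel(), LAT.ravel())
    return RasterField(
        fine_grid, vals.reshape(fine_grid.shape), ok.reshape(fine_grid.shape)
    )


def extract_window(field: RasterField, lon: float, lat: float, radius_cells: int) -> Window:
    """Square (2R+1)² window centered on the cell nearest (lon, lat).

    Cells falling outside the field are marked invalid; the point itself
    must lie inside the field.
    """
    if radius_cells < 1:
        raise ValueError("radius_cells must be >= 1")
    if not field.spec.contains(lon, lat):
        raise ValueError(f"point ({lon}, {lat}) outside the field domain")
    iy, ix = field.spec.cell_of(lon, lat)
    iy, ix = int(iy), int(ix)
    R = radius_cells
    size = 2 * R + 1
    values = np.full((size, size), np.nan)
    valid = np.zeros((size, size), dtype=bool)
    y0, y1 = iy - R, iy + R + 1
    x0, x1 = ix - R, ix + R + 1
    sy0, sx0 = max(y0, 0), max(x0, 0)
    sy1, sx1 = min(y1, field.spec.n_lat), min(x1, field.spec.n_lon)
    values[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = field.values[sy0:sy1, sx0:sx1]
    valid[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = field.valid_mask[sy0:sy1, sx0:sx1]
    values[~valid] = np.nan
    return Window(values, valid, (iy, ix))


# ---------------------------------------------------------------------------
# netCDF I/O (scipy backend; classic netCDF3 files)

def field_to_dataset(fld: RasterField, name: str = "value") -> xr.Dataset:
    data = fld.masked()
    ds = xr.Dataset(
        {name: (("lat", "lon"), data)},
        coords={"lon": fld.spec.lon_centers, "lat": fld.spec.lat_centers},
        attrs={
            "lon_origin": fld.spec.lon_origin,
            "lat_origin": fld.spec.lat_origin,
            "step": fld.spec.step,
        },
    )
    return ds


def write_field(fld: RasterField, path, name: str = "value") -> None:
    field_to_dataset(fld, name).to_netcdf(path, engine="scipy")


def write_daily_stack(fields, path, name: str = "value", dates=None) -> None:
    """Write a list of same-grid fields as one netCDF with a time axis."""
    spec = fields[0].spec
    for f in fields:
        if f.spec != spec:
            raise ValueError("all fields must share one grid")
    data = np.stack([f.masked() for f in fields])
    if dates is None:
        dates = np.arange(len(fields))
    ds = xr.Dataset(
        {name: (("time", "lat", "lon"), data)},
        coords={"time": np.asarray(dates), "lon": spec.lon_centers, "lat": spec.lat_centers},
        attrs={"lon_origin": spec.lon_origin, "lat_origin": spec.lat_origin, "step": spec.step},
    )
    ds.to_netcdf(path, engine="scipy")


def _spec_from_dataset(ds: xr.Dataset) -> GridSpec:
    lon = np.asarray(ds["lon"])
    lat = np.asarray(ds["lat"])
    step = float(ds.attrs.get("step", lon[1] - lon[0] if lon.size > 1 else 1.0))
    lon0 = float(ds.attrs.get("lon_origin", lon[0] - step / 2))
    lat0 = float(ds.attrs.get("lat_origin", lat[0] - step / 2))
    return GridSpec(lon0, lat0, step, lon.size, lat.size)


def read_field(path, name: str = "value") -> RasterField:
    with xr.open_dataset(path, engine="scipy") as ds:
        spec = _spec_from_dataset(ds)
        vals = np.asarray(ds[name], dtype=float)
    return RasterField(spec, vals, np.isfinite(vals))


def read_daily_stack(path, name: str = "value"):
    with xr.open_dataset(path, engine="scipy") as ds:
        spec = _spec_from_dataset(ds)
        data = np.asarray(ds[name], dtype=float)
    return [RasterField(spec, d, np.isfinite(d)) for d in data]
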