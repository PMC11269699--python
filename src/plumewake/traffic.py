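"""Road-segment traffic to gridded vehicle-kilometers traveled (VKT).

VKT = AADT x segment length, computed separately for all vehicles and
for trucks (heavy vehicle classes).  Segment AADT can be scaled so each
state's summed VKT matches a nationally consistent reference total.
Segment VKT is apportioned to 0.01-degree grid cells by the fraction of
the segment's length inside each cell (exactly conservative), summed
over a ±R-cell window around each facility, and regressed on facility
characteristics within decile bins of total near-facility VKT.

Road tables are pandas DataFrames with a ``geometry`` column of
shapely LineStrings (coordinates in degrees) plus ``id``, ``length_km``,
``aadt_total``, ``aadt_truck`` and ``state`` columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from . import stats as pstats
from .grids import GridSpec, RasterField, extract_window

ROAD_COLUMNS = ("id", "geometry", "length_km", "aadt_total", "aadt_truck", "state")

# characteristic display scaling used in the binned regressions:
# parking spaces enter the fit divided by 10, so the slope reads
# "km truck VKT per 10 parking spaces"
CHARACTERISTIC_SCALE = {"parking_spaces": 0.1}


def validate_roads(roads: pd.DataFrame) -> pd.DataFrame:
    for col in ROAD_COLUMNS:
        if col not in roads.columns:
            raise ValueError(f"road table missing column {col!r}")
    if (roads["length_km"] <= 0).any():
        raise ValueError("segment lengths must be positive")
    if (roads["aadt_total"] < 0).any() or (roads["aadt_truck"] < 0).any():
        raise ValueError("negative AADT")
    if (roads["aadt_truck"] > roads["aadt_total"] + 1e-9).any():
        raise ValueError("truck AADT exceeds total AADT")
    return roads


def segment_vkt(roads: pd.DataFrame) -> pd.DataFrame:
    """Per-segment total and truck VKT (vehicle-km/day) = AADT x length."""
    validate_roads(roads)
    out = roads.copy()
    out["vkt_total"] = out["aadt_total"] * out["length_km"]
    out["vkt_truck"] = out["aadt_truck"] * out["length_km"]
    return out


def scale_to_reference(roads: pd.DataFrame, reference_state_totals: dict) -> pd.DataFrame:
    """Scale each state's AADT so its summed total VKT matches a reference.

    The same factor multiplies total and truck AADT (preserving the truck
    share).  After scaling, per-state summed total VKT equals the
    reference exactly; applying the function again with the same
    reference is a no-op.
    """
    validate_roads(roads)
    out = roads.copy()
    out["aadt_total"] = out["aadt_total"].astype(float)
    out["aadt_truck"] = out["aadt_truck"].astype(float)
    current = (out["aadt_total"] * out["length_km"]).groupby(out["state"]).sum()
    for state in out["state"].unique():
        if state not in reference_state_totals:
            raise ValueError(f"state {state!r} missing from reference totals")
        ref = float(reference_state_totals[state])
        cur = float(current[state])
        if cur == 0:
            if ref != 0:
                raise ValueError(f"state {state!r} has zero segment VKT but nonzero reference")
            continue
        k = ref / cur
        sel = out["state"] == state
        out.loc[sel, "aadt_total"] *= k
        out.loc[sel, "aadt_truck"] *= k
    return out


def _split_length_by_cell(coords: np.ndarray, grid: GridSpec):
    """Exact apportionment of a polyline's length (degree metric) to cells.

    Each straight piece between consecutive vertices is cut at every grid
    line it crosses; each sub-piece is assigned to the cell containing
    its midpoint.  Yields ((iy, ix), length_deg) pairs; pieces outside
    the grid are dropped (caller warns).
    """
    out: dict = {}
    clipped = 0.0
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        dx, dy = x1 - x0, y1 - y0
        seg_len = float(np.hypot(dx, dy))
        if seg_len == 0:
            continue
        ts = [0.0, 1.0]
        if dx != 0:
            k0 = int(np.ceil((min(x0, x1) - grid.lon_origin) / grid.step))
            k1 = int(np.floor((max(x0, x1) - grid.lon_origin) / grid.step))
            for k in range(k0, k1 + 1):
                ts.append((grid.lon_origin + k * grid.step - x0) / dx)
        if dy != 0:
            k0 = int(np.ceil((min(y0, y1) - grid.lat_origin) / grid.step))
            k1 = int(np.floor((max(y0, y1) - grid.lat_origin) / grid.step))
            for k in range(k0, k1 + 1):
                ts.append((grid.lat_origin + k * grid.step - y0) / dy)
        ts = np.unique(np.clip(ts, 0.0, 1.0))
        for t0, t1 in zip(ts[:-1], ts[1:]):
            if t1 <= t0:
                continue
            tm = 0.5 * (t0 + t1)
            mx, my = x0 + tm * dx, y0 + tm * dy
            ix = int(np.floor((mx - grid.lon_origin) / grid.step))
            iy = int(np.floor((my - grid.lat_origin) / grid.step))
            piece = (t1 - t0) * seg_len
            if 0 <= ix < grid.n_lon and 0 <= iy < grid.n_lat:
                out[(iy, ix)] = out.get((iy, ix), 0.0) + piece
            else:
                clipped += piece
    return out, clipped


def rasterize_vkt(roads: pd.DataFrame, grid: GridSpec):
    """Grid total and truck VKT by length-in-cell apportionment.

    Each segment's VKT is split across cells in proportion to the length
    of the segment inside each cell, so the raster sum equals the
    segment sum exactly (up to floating point).  Segments extending
    beyond the grid are clipped with a warning.

    Returns (total_field, truck_field).
    """
    roads = segment_vkt(roads)
    total = np.zeros(grid.shape)
    truck = np.zeros(grid.shape)
    any_clipped = False
    for row in roads.itertuples():
        geom = row.geometry
        coords = np.asarray(geom.coords if isinstance(geom, LineString) else geom)
        pieces, clipped = _split_length_by_cell(coords, grid)
        total_len = sum(pieces.values()) + clipped
        if total_len == 0:
            continue
        if clipped > 0:
            any_clipped = True
        for (iy, ix), ln in pieces.items():
            frac = ln / total_len
            total[iy, ix] += row.vkt_total * frac
            truck[iy, ix] += row.vkt_truck * frac
    if any_clipped:
        warnings.warn("some segments extend beyond the grid and were clipped", stacklevel=2)
    ones = np.ones(grid.shape, dtype=bool)
    return RasterField(grid, total, ones), RasterField(grid, truck, ones.copy())


def near_facility_traffic(
    total_field: RasterField,
    truck_field: RasterField,
    facilities: pd.DataFrame,
    radius_cells: int = 7,
) -> pd.DataFrame:
    """Sum total and truck VKT over the ±R window around each facility."""
    rows = []
    for row in facilities.itertuples():
        wt = extract_window(total_field, row.lon, row.lat, radius_cells)
        wk = extract_window(truck_field, row.lon, row.lat, radius_cells)
        rows.append(
            {
                "id": row.id,
                "total_vkt": float(np.nansum(np.where(wt.valid, wt.values, 0.0))),
                "truck_vkt": float(np.nansum(np.where(wk.valid, wk.values, 0.0))),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BinnedSlopeResult:
    """Decile-binned simple-regression slopes of truck VKT on one
    facility characteristic."""

    characteristic: str
    table: pd.DataFrame  # columns: bin, n, slope, se, p, significant, defined
    mean_slope: float
    residuals: np.ndarray
    scale: float

    @property
    def slopes(self) -> np.ndarray:
        return self.table["slope"].to_numpy()

    def residual_normality_p(self) -> float:
        """Omnibus normality test p-value of the pooled bin residuals."""
        from scipy import stats as sps

        r = self.residuals[np.isfinite(self.residuals)]
        if r.size < 20:
            return np.nan
        return float(sps.normaltest(r).pvalue)

    def summary(self) -> str:
        lines = [
            f"Truck-VKT decile-bin regression: {self.characteristic}"
            + (f" (x{self.scale:g} scale)" if self.scale != 1.0 else ""),
            "bin    n     slope          se             p",
        ]
        for row in self.table.itertuples():
            if row.defined:
                star = "*" if row.significant else " "
                lines.append(
                    f"{row.bin:3d} {row.n:5d}  {row.slope:12.3f}  {row.se:12.3f}  {row.p:10.3g}{star}"
                )
            else:
                lines.append(f"{row.bin:3d} {row.n:5d}  (undefined)")
        lines.append(f"mean slope across bins: {self.mean_slope:.3f}")
        return "\n".join(lines)


def decile_bin_regression(
    facilities: pd.DataFrame,
    near_traffic: pd.DataFrame,
    characteristic: str,
    scale: float | None = None,
) -> BinnedSlopeResult:
    """OLS of truck VKT on a characteristic within total-VKT decile bins.

    Facilities are binned into deciles of near-facility total VKT (ties
    to the lower bin); within each bin truck VKT is regressed on the
    characteristic (parking spaces are divided by 10 before the fit, so
    that slope is per 10 spaces).  Facilities missing the characteristic
    are dropped from this characteristic only.  Bins with fewer than 3
    points or zero characteristic variance get an undefined slope and
    are flagged.
    """
    if scale is None:
        scale = CHARACTERISTIC_SCALE.get(characteristic, 1.0)
    df = facilities.merge(near_traffic, on="id")
    df = df[np.isfinite(pd.to_numeric(df[characteristic], errors="coerce"))]
    if len(df) < 10:
        raise ValueError("need at least 10 facilities with the characteristic")
    x_all = pd.to_numeric(df[characteristic]).to_numpy() * scale
    y_all = df["truck_vkt"].to_numpy(dtype=float)
    bins = pstats.assign_deciles(df["total_vkt"].to_numpy(dtype=float))
    rows = []
    residuals = []
    for b in range(10):
        sel = bins == b
        x, y = x_all[sel], y_all[sel]
        if sel.sum() < 3 or np.ptp(x) == 0:
            rows.append({"bin": b + 1, "n": int(sel.sum()), "slope": np.nan,
                         "se": np.nan, "p": np.nan, "significant": False,
                         "defined": False})
            continue
        fit = pstats.ols_slope_wald(x, y)
        residuals.append(y - (fit.intercept + fit.slope * x))
        rows.append({"bin": b + 1, "n": fit.n, "slope": fit.slope, "se": fit.se,
                     "p": fit.p, "significant": fit.significant, "defined": True})
    table = pd.DataFrame(rows)
    defined = table.loc[table["defined"], "slope"]
    mean_slope = float(defined.mean()) if len(defined) else np.nan
    res = np.concatenate(residuals) if residuals else np.array([])
    return BinnedSlopeResult(
        characteristic=characteristic,
        table=table,
        mean_slope=mean_slope,
        residuals=res,
        scale=scale,
    )


class TruckTrafficModel:
    """Decile-binned association of near-facility truck VKT with
    facility characteristics.

    Parameters
    ----------
    facilities : DataFrame with ``id`` and characteristic columns.
    near_traffic : DataFrame with ``id``, ``total_vkt``, ``truck_vkt``
        (e.g. from :func:`near_facility_traffic`).
    """

    def __init__(self, facilities: pd.DataFrame, near_traffic: pd.DataFrame) -> None:
        self.facilities = facilities
        self.near_traffic = near_traffic

    def fit(self, characteristics=("loading_docks", "parking_spaces", "clustering")) -> "TruckTrafficResults":
        results = {
            c: decile_bin_regression(self.facilities, self.near_traffic, c)
            for c in characteristics
        }
        return TruckTrafficResults(self, results)


@dataclass
class TruckTrafficResults:
    model: TruckTrafficModel
    by_characteristic: dict

    def mean_slopes(self) -> pd.Series:
        return pd.Series({c: r.mean_slope for c, r in self.by_characteristic.items()})

    def table(self) -> pd.DataFrame:
        frames = []
        for c, r in self.by_characteristic.items():
            t = r.table.copy()
            t.insert(0, "characteristic", c)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        return "\n\n".join(r.summary() for r in self.by_characteristic.values())
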