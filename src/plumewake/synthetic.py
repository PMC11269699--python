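"""Seeded synthetic scenarios with recorded ground truth.

Every stage of the analysis is validated by parameter recovery on data
whose generative truth is known.  A scenario emulates the statistical
structure of the real inputs: clustered facility siting (optionally
biased toward tracts with a high share of a favored subgroup),
positively correlated facility characteristics with configurable
missingness, spatially smooth AR(1) hourly winds on a coarse grid,
daily NO2 fields built as a density-scaled background plus per-facility
Gaussian plumes displaced downwind of each facility along that day's
overpass-window mean wind (multiplicative lognormal noise, random
missing swath cells), a road lattice whose truck traffic increases near
facilities with planted per-characteristic slopes, rectangular tracts
with six non-mutually-exclusive subgroup populations, and eight
nonnegative sectoral emission rasters (the agricultural-ammonia sector
carries no NOx and is deliberately absent).

Cells are nominally 1 km x 1 km (0.01 degrees); no latitude correction
is applied.  Each sub-generator draws from its own child stream of the
master seed, so e.g. adding facilities does not perturb the winds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, box, mapping

from . import composite as pcomposite
from .grids import GridSpec, RasterField, FootprintObservation
from .composite import WindFieldSeries

SECTORS = (
    "dust",
    "non_point",
    "oil_and_gas",
    "rail",
    "residential_wood_combustion",
    "on_road",
    "non_road",
    "airports",
)


@dataclass
class ScenarioConfig:
    """All knobs of a synthetic scenario.

    NO2 units are arbitrary column units (think 1e15 molec/cm2); one
    grid cell is nominally 1 km.
    """

    domain_bounds: tuple = (0.0, 0.0, 4.0, 4.0)  # lon0, lat0, lon1, lat1
    grid_step: float = 0.01
    n_facilities: int = 200
    cluster_intensity: float = 3.0  # mean facilities per cluster
    cluster_radius_km: float = 8.0
    plume_amplitude_per_dock: float = 0.058  # NO2 units per loading dock
    plume_amplitude_per_cluster: float = 0.058  # NO2 units per co-located facility
    plume_displacement_km: float = 4.0
    plume_sigma_km: float = 2.0
    background_base: float = 4.0
    background_density_coeff: float = 5e-4  # NO2 units per (people/km^2)
    noise_cv: float = 0.3
    swath_missing_frac: float = 0.3
    qa_low_frac: float = 0.05  # footprint mode: fraction below QA threshold
    missing_docks_frac: float = 0.407
    missing_parking_frac: float = 0.311
    missing_bias: float = 0.0  # >0 ties missingness to the characteristic's rank
    siting_bias: float = 1.0
    siting_pop_exponent: float = 1.0  # 1: tract weight ~ population; 0: uniform
    min_separation_km: float = 0.0  # >0 enforces a hard-core (Poisson-disk) process
    favored_subgroup: str = "hispanic"
    n_days: int = 60
    seed: int = 0
    # tracts / states
    tract_nx: int = 20
    tract_ny: int = 20
    n_states: int = 4
    # roads
    road_spacing_deg: float = 0.04
    road_piece_deg: float = 0.02
    aadt_total_median: float = 20000.0
    truck_base_frac: float = 0.05
    slope_vkt_per_dock: float = 1456.0
    slope_vkt_per_cluster: float = 485.0
    slope_vkt_per_parking: float = -13.0
    # winds
    wind_speed_mean: float = 4.0
    wind_ar1: float = 0.8
    wind_perturb_sd: float = 1.0
    wind_constant_uv: tuple | None = None
    # keep facilities away from the domain edge so windows are complete
    edge_margin_deg: float = 0.15

    def __post_init__(self) -> None:
        for name in ("swath_missing_frac", "qa_low_frac", "missing_docks_frac",
                     "missing_parking_frac"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_facilities < 1:
            raise ValueError("at least one facility must be requested")
        if self.siting_bias < 0:
            raise ValueError("siting_bias must be >= 0")
        if not (0 < self.wind_ar1 <= 1) and self.wind_ar1 != 0:
            raise ValueError("wind_ar1 must be in [0, 1]")

    @property
    def grid(self) -> GridSpec:
        lon0, lat0, lon1, lat1 = self.domain_bounds
        return GridSpec(
            lon0, lat0, self.grid_step,
            int(round((lon1 - lon0) / self.grid_step)),
            int(round((lat1 - lat0) / self.grid_step)),
        )

    @property
    def km_to_deg(self) -> float:
        # 1 cell == 1 km nominally
        return self.grid_step


@dataclass
class ScenarioTruth:
    """Generative ground truth recorded for parameter-recovery tests."""

    displacement_km: float
    enhancement_pct: float  # statistic applied to the noise-free fields
    per_facility: pd.DataFrame  # id, docks, parking, clustering, amplitude, enhancement_pct
    vkt_slopes: dict  # characteristic -> planted slope
    siting_direction: dict  # subgroup -> expected sign of the relative difference
    daily_wind_direction_deg: np.ndarray


@dataclass
class Scenario:
    config: ScenarioConfig
    grid: GridSpec
    tracts: pd.DataFrame
    facilities: pd.DataFrame
    winds: WindFieldSeries
    no2_daily: list
    no2_daily_noisefree: list
    roads: pd.DataFrame
    emissions: dict
    truth: ScenarioTruth


# ---------------------------------------------------------------------------
# tracts


def _smooth_unit_field(shape, rng, sigma=2.0):
    """Spatially smooth field rescaled to zero mean, unit-ish amplitude."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_tracts(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Rectangular tracts tiling the domain with demographics.

    Subgroup shares vary smoothly in space and are drawn independently of
    population density; Hispanic and non-Hispanic populations partition
    the total exactly, the remaining categories are non-mutually
    exclusive.
    """
    lon0, lat0, lon1, lat1 = config.domain_bounds
    nx, ny = config.tract_nx, config.tract_ny
    wx, wy = (lon1 - lon0) / nx, (lat1 - lat0) / ny
    area_km2 = (wx / config.grid_step) * (wy / config.grid_step)  # nominal km cells

    log10_density = rng.normal(2.4, 0.55, size=(ny, nx))
    density = 10.0 ** log10_density
    shares = {
        "hispanic": np.clip(0.10 + 0.12 * _smooth_unit_field((ny, nx), rng), 0.02, 0.75),
        "white": np.clip(0.55 + 0.15 * _smooth_unit_field((ny, nx), rng), 0.05, 0.95),
        "black": np.clip(0.12 + 0.07 * _smooth_unit_field((ny, nx), rng), 0.005, 0.80),
        "asian_nhpi": np.clip(0.05 + 0.03 * _smooth_unit_field((ny, nx), rng), 0.002, 0.60),
        "other": np.clip(0.10 + 0.04 * _smooth_unit_field((ny, nx), rng), 0.005, 0.50),
    }
    rows = []
    for j in range(ny):
        for i in range(nx):
            total = int(round(density[j, i] * area_km2))
            pop_h = int(round(shares["hispanic"][j, i] * total))
            state = f"S{int(i * config.n_states / nx):02d}"
            rows.append({
                "tract_id": f"T{j:03d}_{i:03d}",
                "state": state,
                "lon0": lon0 + i * wx, "lat0": lat0 + j * wy,
                "lon1": lon0 + (i + 1) * wx, "lat1": lat0 + (j + 1) * wy,
                "area_km2": area_km2,
                "population_total": total,
                "pop_hispanic": pop_h,
                "pop_non_hispanic": total - pop_h,
                "pop_white": int(round(shares["white"][j, i] * total)),
                "pop_black": int(round(shares["black"][j, i] * total)),
                "pop_asian_nhpi": int(round(shares["asian_nhpi"][j, i] * total)),
                "pop_other": int(round(shares["other"][j, i] * total)),
                "facility_count": 0,
            })
    return pd.DataFrame(rows)


def tract_index_of(config: ScenarioConfig, lon, lat):
    """Row index into the tract table for points inside the domain."""
    lon0, lat0, lon1, lat1 = config.domain_bounds
    nx, ny = config.tract_nx, config.tract_ny
    i = np.clip(((np.asarray(lon) - lon0) / (lon1 - lon0) * nx).astype(int), 0, nx - 1)
    j = np.clip(((np.asarray(lat) - lat0) / (lat1 - lat0) * ny).astype(int), 0, ny - 1)
    return j * nx + i


# ---------------------------------------------------------------------------
# facilities


def generate_facilities(
    config: ScenarioConfig,
    tracts: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clustered facility point process with correlated characteristics.

    Cluster parents are placed in tracts sampled with probability
    proportional to population times (favored-subgroup share)^siting_bias;
    offspring scatter around parents within roughly cluster_radius_km.
    Characteristics (building area, loading docks, parking spaces) share
    a latent size factor so they are positively correlated; docks and
    parking are set missing at the configured rates.  The returned table
    keeps the complete values in ``*_true`` columns for truth bookkeeping.
    """
    if len(tracts) == 0:
        raise ValueError("tract table is empty")
    lon0, lat0, lon1, lat1 = config.domain_bounds
    m = config.edge_margin_deg
    share = tracts[f"pop_{config.favored_subgroup}"] / tracts["population_total"].clip(lower=1)
    weights = (
        tracts["population_total"] ** config.siting_pop_exponent
        * share ** config.siting_bias
    )
    weights = (weights / weights.sum()).to_numpy()

    n = config.n_facilities
    n_clusters = max(1, int(round(n / max(config.cluster_intensity, 1e-9))))
    parent_tracts = rng.choice(len(tracts), size=n_clusters, p=weights)
    px = np.empty(n_clusters)
    py = np.empty(n_clusters)
    for k, ti in enumerate(parent_tracts):
        t = tracts.iloc[ti]
        px[k] = rng.uniform(max(t.lon0, lon0 + m), min(t.lon1, lon1 - m))
        py[k] = rng.uniform(max(t.lat0, lat0 + m), min(t.lat1, lat1 - m))

    sigma = config.cluster_radius_km * config.km_to_deg
    min_sep = config.min_separation_km * config.km_to_deg
    assign = rng.integers(0, n_clusters, size=n)
    lons = np.empty(n)
    lats = np.empty(n)
    for i in range(n):
        for attempt in range(2000):
            if min_sep > 0 and attempt >= 100:
                # cluster region full: fall back to uniform dart throwing
                x = rng.uniform(lon0 + m, lon1 - m)
                y = rng.uniform(lat0 + m, lat1 - m)
            else:
                x = px[assign[i]] + rng.normal(0, sigma)
                y = py[assign[i]] + rng.normal(0, sigma)
            if not (lon0 + m <= x <= lon1 - m and lat0 + m <= y <= lat1 - m):
                continue
            if min_sep > 0 and i > 0:
                # hard-core rejection (Chebyshev metric, matching the windows)
                cheb = np.maximum(np.abs(lons[:i] - x), np.abs(lats[:i] - y))
                if cheb.min() < min_sep:
                    continue
            lons[i], lats[i] = x, y
            break
        else:
            raise ValueError(
                "could not place facilities with the requested minimum "
                "separation; reduce n_facilities or min_separation_km"
            )

    z = rng.standard_normal(n)
    docks = rng.poisson(np.exp(2.4 + 0.35 * z))
    parking = rng.poisson(np.exp(4.7 + 0.30 * z))
    area = np.exp(11.2 + 0.5 * z + 0.3 * rng.standard_normal(n))
    year = rng.integers(1970, 2022, size=n)

    ti = tract_index_of(config, lons, lats)
    counts = np.bincount(ti, minlength=len(tracts))
    clustering = counts[ti]

    def missing_mask(frac, values):
        if config.missing_bias > 0:
            ranks = pd.Series(values).rank(pct=True).to_numpy()
            p = np.clip(frac + config.missing_bias * (ranks - 0.5), 0.0, 1.0)
        else:
            p = np.full(n, frac)
        return rng.random(n) < p

    docks_missing = missing_mask(config.missing_docks_frac, docks)
    parking_missing = missing_mask(config.missing_parking_frac, parking)

    fac = pd.DataFrame({
        "id": [f"W{i:05d}" for i in range(n)],
        "lon": lons,
        "lat": lats,
        "building_area_sqft": area,
        "loading_docks": np.where(docks_missing, np.nan, docks.astype(float)),
        "parking_spaces": np.where(parking_missing, np.nan, parking.astype(float)),
        "year_built": year,
        "tract_id": tracts["tract_id"].to_numpy()[ti],
        "clustering": clustering,
        "loading_docks_true": docks,
        "parking_spaces_true": parking,
    })
    return fac


# ---------------------------------------------------------------------------
# winds


def generate_wind_fields(config: ScenarioConfig, rng: np.random.Generator):
    """Hourly coarse (0.25 degree) u/v winds for the scenario days.

    Each day has a random prevailing direction and gamma-distributed
    speed; hourly spatially smooth perturbations follow an AR(1) chain.
    Returns (WindFieldSeries, daily_direction_deg).
    """
    lon0, lat0, lon1, lat1 = config.domain_bounds
    step = 0.25
    nx = int(np.ceil((lon1 - lon0) / step)) + 2
    ny = int(np.ceil((lat1 - lat0) / step)) + 2
    spec = GridSpec(lon0 - step, lat0 - step, step, nx, ny)
    nd = config.n_days
    u = np.empty((nd, 24, ny, nx))
    v = np.empty((nd, 24, ny, nx))
    if config.wind_constant_uv is not None:
        u0, v0 = config.wind_constant_uv
        u[:] = u0
        v[:] = v0
        daily_dir = np.full(nd, np.degrees(np.arctan2(v0, u0)) % 360.0)
        return WindFieldSeries(spec, u, v), daily_dir

    daily_dir = rng.uniform(0.0, 360.0, size=nd)
    daily_speed = rng.gamma(4.0, config.wind_speed_mean / 4.0, size=nd)
    a = config.wind_ar1
    innov_sd = config.wind_perturb_sd * np.sqrt(max(1.0 - a * a, 0.0)) if a > 0 else config.wind_perturb_sd
    for d in range(nd):
        mu = daily_speed[d] * np.cos(np.radians(daily_dir[d]))
        mv = daily_speed[d] * np.sin(np.radians(daily_dir[d]))
        eu = _smooth_unit_field((ny, nx), rng, sigma=1.5) * config.wind_perturb_sd
        ev = _smooth_unit_field((ny, nx), rng, sigma=1.5) * config.wind_perturb_sd
        for h in range(24):
            u[d, h] = mu + eu
            v[d, h] = mv + ev
            eu = a * eu + _smooth_unit_field((ny, nx), rng, sigma=1.5) * innov_sd
            ev = a * ev + _smooth_unit_field((ny, nx), rng, sigma=1.5) * innov_sd
    return WindFieldSeries(spec, u, v), daily_dir


# ---------------------------------------------------------------------------
# NO2 fields


def _background_field(config: ScenarioConfig, tracts: pd.DataFrame) -> np.ndarray:
    grid = config.grid
    dens_tract = (tracts["population_total"] / tracts["area_km2"]).to_numpy()
    iy, ix = np.meshgrid(np.arange(grid.n_lat), np.arange(grid.n_lon), indexing="ij")
    lon = grid.lon_centers[ix]
    lat = grid.lat_centers[iy]
    ti = tract_index_of(config, lon.ravel(), lat.ravel()).reshape(grid.shape)
    bg = config.background_base + config.background_density_coeff * dens_tract[ti]
    return gaussian_filter(bg, sigma=5.0, mode="nearest")


def generate_no2_fields(
    facilities: pd.DataFrame,
    winds: WindFieldSeries,
    config: ScenarioConfig,
    rng: np.random.Generator,
    tracts: pd.DataFrame,
    noise: bool = True,
):
    """Daily NO2 fields: background + downwind-displaced Gaussian plumes.

    Returns (noisy_fields, noisefree_fields); when ``noise`` is False the
    two lists are the same objects.  Plume amplitude is linear in the
    facility's true loading docks and its tract clustering; the plume
    center sits ``plume_displacement_km`` downwind along the facility's
    overpass-window mean wind for that day.
    """
    grid = config.grid
    for row in facilities.itertuples():
        if not grid.contains(row.lon, row.lat):
            raise ValueError(f"facility {row.id} outside the raster domain")
    bg = _background_field(config, tracts)
    amp = (
        config.plume_amplitude_per_dock * facilities["loading_docks_true"].to_numpy()
        + config.plume_amplitude_per_cluster * facilities["clustering"].to_numpy()
    )
    mu, mv = pcomposite.overpass_mean_winds(
        winds, facilities["lon"].to_numpy(), facilities["lat"].to_numpy()
    )
    speed = np.hypot(mu, mv)
    sigma_c = config.plume_sigma_km  # cells
    disp_c = config.plume_displacement_km  # cells
    half = int(np.ceil(4 * sigma_c))
    off = np.arange(-half, half + 1)
    OX, OY = np.meshgrid(off, off)

    fy = (facilities["lat"].to_numpy() - grid.lat_origin) / grid.step - 0.5
    fx = (facilities["lon"].to_numpy() - grid.lon_origin) / grid.step - 0.5

    s = np.sqrt(np.log(1.0 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    noisefree = []
    noisy = []
    for d in range(config.n_days):
        fld = bg.copy()
        for i in range(len(facilities)):
            if speed[i, d] > 0:
                ux, uy = mu[i, d] / speed[i, d], mv[i, d] / speed[i, d]
            else:
                ux, uy = 0.0, 0.0
            cx = fx[i] + disp_c * ux
            cy = fy[i] + disp_c * uy
            jx = int(round(cx))
            jy = int(round(cy))
            gx = jx + OX
            gy = jy + OY
            bump = amp[i] * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma_c**2))
            ok = (gx >= 0) & (gx < grid.n_lon) & (gy >= 0) & (gy < grid.n_lat)
            np.add.at(fld, (gy[ok], gx[ok]), bump[ok])
        clean = RasterField(grid, fld, np.ones(grid.shape, dtype=bool))
        noisefree.append(clean)
        if noise:
            vals = fld.copy()
            if s > 0:
                vals = vals * np.exp(rng.normal(-0.5 * s * s, s, size=grid.shape))
            mask = rng.random(grid.shape) >= config.swath_missing_frac
            vals = np.where(mask, vals, np.nan)
            noisy.append(RasterField(grid, vals, mask))
        else:
            noisy.append(clean)
    return noisy, noisefree


def simulate_footprints(
    fld: RasterField,
    config: ScenarioConfig,
    rng: np.random.Generator,
    fp_lon_cells: int = 5,
    fp_lat_cells: int = 3,
    qa_threshold_low: float = 0.5,
):
    """Coarse rectangular footprints sampling a field, with QA values.

    Footprints tile the domain at roughly the native sensor size (a few
    fine cells per footprint); each takes the mean of the underlying
    field over its extent, and a configured fraction is assigned a QA
    value below the retention threshold.
    """
    g = fld.spec
    out = []
    for j0 in range(0, g.n_lat - fp_lat_cells + 1, fp_lat_cells):
        for i0 in range(0, g.n_lon - fp_lon_cells + 1, fp_lon_cells):
            block = fld.values[j0 : j0 + fp_lat_cells, i0 : i0 + fp_lon_cells]
            x0 = g.lon_origin + i0 * g.step
            y0 = g.lat_origin + j0 * g.step
            x1 = x0 + fp_lon_cells * g.step
            y1 = y0 + fp_lat_cells * g.step
            qa = qa_threshold_low if rng.random() < config.qa_low_frac else 0.95
            out.append(
                FootprintObservation(
                    corners=((x0, y0), (x1, y0), (x1, y1), (x0, y1)),
                    value=float(np.nanmean(block)),
                    qa=qa,
                )
            )
    return out


# ---------------------------------------------------------------------------
# roads


def generate_roads(
    config: ScenarioConfig,
    facilities: pd.DataFrame | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Lattice-plus-random road pieces with planted near-facility truck VKT.

    Base AADT is lognormal with a fixed truck share.  For each facility,
    lattice pieces lying wholly within the near-facility window receive
    extra truck (and total) AADT sized so the added truck VKT equals
    slope_per_dock*docks + slope_per_cluster*clustering +
    slope_per_parking*parking — the slopes the decile regressions are
    asked to recover.
    """
    lon0, lat0, lon1, lat1 = config.domain_bounds
    sp, pc = config.road_spacing_deg, config.road_piece_deg
    n_piece = int(round((lon1 - lon0) / pc))
    xs = lon0 + np.arange(n_piece + 1) * pc
    rows = []

    def add_line(fixed, horizontal):
        for k in range(n_piece):
            if horizontal:
                p0, p1 = (xs[k], fixed), (xs[k + 1], fixed)
            else:
                p0, p1 = (fixed, xs[k]), (fixed, xs[k + 1])
            rows.append((p0, p1))

    y = lat0 + sp
    while y < lat1 - 1e-9:
        add_line(round(y, 9), True)
        y += sp
    x = lon0 + sp
    while x < lon1 - 1e-9:
        add_line(round(x, 9), False)
        x += sp

    n_lattice = len(rows)
    # a few random diagonal connectors for realism
    for _ in range(100):
        x0 = rng.uniform(lon0 + 0.06, lon1 - 0.06)
        y0 = rng.uniform(lat0 + 0.06, lat1 - 0.06)
        ang = rng.uniform(0, 2 * np.pi)
        ln = rng.uniform(0.02, 0.05)
        rows.append(((x0, y0), (x0 + ln * np.cos(ang), y0 + ln * np.sin(ang))))

    p0 = np.array([r[0] for r in rows])
    p1 = np.array([r[1] for r in rows])
    lengths_deg = np.hypot(*(p1 - p0).T)
    length_km = lengths_deg / config.grid_step  # nominal 1 km cells
    aadt_total = np.exp(rng.normal(np.log(config.aadt_total_median), 0.6, len(rows)))
    aadt_truck = aadt_total * config.truck_base_frac * rng.uniform(0.8, 1.2, len(rows))

    if facilities is not None and len(facilities):
        # whole piece inside the +-7 cell window: both endpoints within
        # 4.4 cells (Chebyshev) of the facility
        reach = 4.4 * config.grid_step
        docks = facilities["loading_docks_true"].to_numpy(dtype=float)
        parking = facilities["parking_spaces_true"].to_numpy(dtype=float)
        clustering = facilities["clustering"].to_numpy(dtype=float)
        targets = np.maximum(
            config.slope_vkt_per_dock * docks
            + config.slope_vkt_per_cluster * clustering
            + config.slope_vkt_per_parking * parking,
            0.0,
        )
        lattice_sel = np.arange(len(rows)) < n_lattice
        for i, row in enumerate(facilities.itertuples()):
            cheb = np.maximum(
                np.maximum(np.abs(p0[:, 0] - row.lon), np.abs(p1[:, 0] - row.lon)),
                np.maximum(np.abs(p0[:, 1] - row.lat), np.abs(p1[:, 1] - row.lat)),
            )
            sel = (cheb <= reach) & lattice_sel
            if not sel.any():  # pragma: no cover - lattice spacing guarantees hits
                sel = cheb <= 2 * reach
            total_len = length_km[sel].sum()
            add = targets[i] / total_len  # uniform AADT increment, VKT sums to target
            aadt_truck[sel] += add
    if facilities is not None and len(facilities):
        # attracted trucks are a small part of total traffic; only bump the
        # total where the truck increment would otherwise exceed it
        aadt_total = np.maximum(aadt_total, aadt_truck)

    state_ids = np.clip(
        ((0.5 * (p0[:, 0] + p1[:, 0]) - lon0) / (lon1 - lon0) * config.n_states).astype(int),
        0, config.n_states - 1,
    )
    return pd.DataFrame({
        "id": [f"R{i:06d}" for i in range(len(rows))],
        "geometry": [LineString([tuple(a), tuple(b)]) for a, b in zip(p0, p1)],
        "length_km": length_km,
        "aadt_total": aadt_total,
        "aadt_truck": aadt_truck,
        "state": [f"S{s:02d}" for s in state_ids],
    })


def generate_roads_and_tracts(
    config: ScenarioConfig,
    rng: np.random.Generator,
    facilities: pd.DataFrame | None = None,
    tracts: pd.DataFrame | None = None,
):
    """Convenience wrapper returning (roads, tracts)."""
    if tracts is None:
        tracts = generate_tracts(config, rng)
    roads = generate_roads(config, facilities, rng)
    return roads, tracts


# ---------------------------------------------------------------------------
# emissions


def generate_emission_layers(
    config: ScenarioConfig,
    vkt_total: RasterField,
    facilities: pd.DataFrame,
    rng: np.random.Generator,
) -> dict:
    """Eight nonnegative sectoral emission rasters.

    The on-road raster is proportional to the total-VKT raster; the
    others are smooth random nonnegative fields (airports: a few point
    hotspots; rail: a corridor).  The agricultural-ammonia sector is
    absent because it carries no NOx emissions.
    """
    grid = config.grid
    shape = grid.shape
    ones = np.ones(shape, dtype=bool)

    def smooth_pos(scale, sigma):
        f = gaussian_filter(rng.exponential(1.0, shape), sigma=sigma, mode="nearest")
        return np.maximum(f, 0.0) * scale

    layers = {}
    layers["dust"] = smooth_pos(0.5, 12)
    layers["non_point"] = smooth_pos(1.0, 10)
    layers["oil_and_gas"] = smooth_pos(0.3, 15)
    layers["residential_wood_combustion"] = smooth_pos(0.4, 12)
    layers["non_road"] = smooth_pos(0.6, 8)

    rail = np.zeros(shape)
    r0 = rng.integers(0, shape[0])
    rail[max(r0 - 1, 0) : r0 + 2, :] = 1.0
    layers["rail"] = gaussian_filter(rail, sigma=2, mode="nearest") * 2.0

    airports = np.zeros(shape)
    for _ in range(3):
        ay, ax = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        airports[ay, ax] = 50.0
    layers["airports"] = gaussian_filter(airports, sigma=3, mode="nearest")

    layers["on_road"] = 1e-3 * vkt_total.values

    return {k: RasterField(grid, v, ones.copy()) for k, v in layers.items()}


def total_emissions(layers: dict) -> RasterField:
    """Sum of the sectoral rasters."""
    fields = list(layers.values())
    tot = np.sum([f.values for f in fields], axis=0)
    return RasterField(fields[0].spec, tot, np.ones(fields[0].spec.shape, dtype=bool))


# ---------------------------------------------------------------------------
# full scenario


def generate_scenario(config: ScenarioConfig, compute_truth: bool = True) -> Scenario:
    """Generate a complete seeded scenario with recorded truth.

    Each sub-generator uses its own child stream of the master seed.
    Truth enhancement values are obtained by applying the enhancement
    statistic to the noise-free fields (the only correct reference when
    plumes of nearby facilities overlap).
    """
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rngs = [np.random.default_rng(s) for s in streams]
    r_tracts, r_fac, r_wind, r_no2, r_roads, r_emis, _r_fp = rngs

    tracts = generate_tracts(config, r_tracts)
    facilities = generate_facilities(config, tracts, r_fac)
    counts = facilities["tract_id"].value_counts()
    tracts["facility_count"] = tracts["tract_id"].map(counts).fillna(0).astype(int)

    winds, daily_dir = generate_wind_fields(config, r_wind)
    no2, no2_clean = generate_no2_fields(facilities, winds, config, r_no2, tracts)
    roads = generate_roads(config, facilities, r_roads)

    from .traffic import rasterize_vkt

    vkt_total, _ = rasterize_vkt(roads, config.grid)
    emissions = generate_emission_layers(config, vkt_total, facilities, r_emis)

    truth_fac = facilities[["id", "loading_docks_true", "parking_spaces_true", "clustering"]].copy()
    truth_fac["amplitude"] = (
        config.plume_amplitude_per_dock * facilities["loading_docks_true"]
        + config.plume_amplitude_per_cluster * facilities["clustering"]
    )
    enh_pct = np.nan
    if compute_truth:
        model = pcomposite.PlumeCompositeModel(
            no2_clean, facilities, winds, radius=7, cell_km=1.0
        )
        res = model.fit()
        enh_pct = res.enhancement_pct
        per_fac = {}
        for fid, win in res.facility_windows.items():
            comp = pcomposite.RotatedComposite(win, np.isfinite(win).astype(int))
            try:
                per_fac[fid] = pcomposite.enhancement(comp).enhancement_pct
            except ValueError:
                per_fac[fid] = np.nan
        truth_fac["enhancement_pct"] = truth_fac["id"].map(per_fac)
    else:
        truth_fac["enhancement_pct"] = np.nan

    siting = {sg: 0 for sg in ("white", "non_hispanic", "hispanic", "black", "asian_nhpi", "other")}
    if config.siting_bias > 0:
        siting[config.favored_subgroup] = 1

    truth = ScenarioTruth(
        displacement_km=config.plume_displacement_km,
        enhancement_pct=float(enh_pct),
        per_facility=truth_fac,
        vkt_slopes={
            "loading_docks": config.slope_vkt_per_dock,
            "clustering": config.slope_vkt_per_cluster,
            "parking_spaces": config.slope_vkt_per_parking,
        },
        siting_direction=siting,
        daily_wind_direction_deg=np.asarray(daily_dir),
    )
    return Scenario(
        config=config,
        grid=config.grid,
        tracts=tracts,
        facilities=facilities,
        winds=winds,
        no2_daily=no2,
        no2_daily_noisefree=no2_clean,
        roads=roads,
        emissions=emissions,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization


def write_scenario(scn: Scenario, outdir, write_rasters: bool = False) -> None:
    """Write a scenario: facilities CSV, tracts/roads GeoJSON, truth JSON,
    config YAML, and (optionally) the daily NO2 and emission netCDF stacks."""
    from pathlib import Path

    from .grids import write_daily_stack, write_field

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scn.facilities.to_csv(out / "facilities.csv", index=False)

    feats = []
    for row in scn.tracts.itertuples():
        geom = box(row.lon0, row.lat0, row.lon1, row.lat1)
        props = {k: getattr(row, k) for k in
                 ("tract_id", "state", "area_km2", "population_total",
                  "pop_white", "pop_non_hispanic", "pop_hispanic", "pop_black",
                  "pop_asian_nhpi", "pop_other", "facility_count")}
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    (out / "tracts.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )

    feats = []
    for row in scn.roads.itertuples():
        props = {"id": row.id, "length_km": row.length_km,
                 "aadt_total": row.aadt_total, "aadt_truck": row.aadt_truck,
                 "state": row.state}
        feats.append({"type": "Feature", "geometry": mapping(row.geometry),
                      "properties": props})
    (out / "roads.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )

    truth = scn.truth
    (out / "truth.json").write_text(json.dumps({
        "displacement_km": truth.displacement_km,
        "enhancement_pct": truth.enhancement_pct,
        "vkt_slopes": truth.vkt_slopes,
        "siting_direction": truth.siting_direction,
        "daily_wind_direction_deg": truth.daily_wind_direction_deg.tolist(),
        "per_facility": truth.per_facility.to_dict(orient="list"),
    }))
    cfg = asdict(scn.config)
    cfg["domain_bounds"] = list(cfg["domain_bounds"])
    if cfg["wind_constant_uv"] is not None:
        cfg["wind_constant_uv"] = list(cfg["wind_constant_uv"])
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))

    if write_rasters:
        write_daily_stack(scn.no2_daily, out / "no2_daily.nc", name="no2")
        for name, fld in scn.emissions.items():
            write_field(fld, out / f"emissions_{name}.nc", name="flux")


def read_roads_geojson(path) -> pd.DataFrame:
    """Read a roads GeoJSON written by :func:`write_scenario`."""
    data = json.loads(open(path).read())
    rows = []
    for f in data["features"]:
        props = f["properties"]
        rows.append({**props, "geometry": LineString(f["geometry"]["coordinates"])})
    return pd.DataFrame(rows)


def read_tracts_geojson(path) -> pd.DataFrame:
    data = json.loads(open(path).read())
    rows = []
    for f in data["features"]:
        props = dict(f["properties"])
        xs = [c[0] for c in f["geometry"]["coordinates"][0]]
        ys = [c[1] for c in f["geometry"]["coordinates"][0]]
        props.update({"lon0": min(xs), "lat0": min(ys), "lon1": max(xs), "lat1": max(ys)})
        rows.append(props)
    return pd.DataFrame(rows)
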