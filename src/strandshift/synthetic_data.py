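"""Synthetic stranding sets, SST cubes, shelf worlds, and census tables.

Every downstream stage of the pipeline is testable without downloads because
this module generates all three input families with known ground truth:

* **Stranding sets** — per-species poleward distances follow the same linear
  drift model the power analysis assumes, d = a + b·t + ε, ε ~ Normal(0, σ²),
  with a configurable number of events per year; each event is placed on the
  synthetic coastline at its along-shelf distance so the geometry stage can
  recover the generating distance.
* **SST cubes** — annual-mean temperature fields with a prescribed per-cell
  warming rate, a prescribed north–south spatial gradient (cooler poleward),
  and optional i.i.d. noise; land cells are missing.
* **Census tables** — coastal county centroids spaced along the coast with a
  prescribed linear relation between percent population change and poleward
  distance.

The synthetic world is a deliberately simple shelf: a meridional (optionally
wavy) coastline with land to the west, a fixed-width shelf band to the east,
and off-shelf water beyond.  It is plumbing for the method, not a model of
any real coastline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .shelf_geometry import KM_PER_DEG, DistanceField, ShelfGrid, build_distance_field

CLIMATIC_CATEGORIES = ("warm", "cool", "arctic", "cosmopolitan")

DEFAULT_START_YEAR = 1996


@dataclass
class SpeciesSimSpec:
    """Ground-truth drift model for one simulated species.

    slope_b       true poleward drift, km/yr
    intercept_a   poleward distance at year 1, km
    sd_sigma      event-level SD of poleward distance within a year, km
    annual_n      events per year: a constant or a per-year sequence
    """

    species_id: str
    slope_b: float
    intercept_a: float
    sd_sigma: float
    annual_n: int | Sequence[int]
    climatic_category: str = "warm"
    trailing_edge: bool = False

    def __post_init__(self):
        if self.sd_sigma < 0:
            raise ValueError("sd_sigma must be >= 0")
        if self.climatic_category not in CLIMATIC_CATEGORIES:
            raise ValueError(f"climatic_category must be one of {CLIMATIC_CATEGORIES}")

    def annual_counts(self, n_years: int) -> np.ndarray:
        if np.isscalar(self.annual_n):
            counts = np.full(n_years, int(self.annual_n))
        else:
            counts = np.asarray(self.annual_n, dtype=int)
            if counts.size != n_years:
                raise ValueError("annual_n sequence length must equal n_years")
        if (counts < 0).any():
            raise ValueError("annual_n entries must be >= 0")
        return counts


@dataclass
class WorldSpec:
    """Synthetic shelf-world geometry.

    The coastline runs roughly north–south at ``coast_lon``;
    ``coastline_profile`` (latitude → longitude offset in degrees) makes it
    wavy.  Sea cells east of the coast within ``shelf_width_km`` are the
    traversable shelf; beyond is off-shelf barrier; west is land.
    """

    n_years: int = 25
    grid_shape: tuple[int, int] = (300, 36)
    cell_km: float = 10.0
    lat0: float = 25.0
    coast_lon: float = -80.5
    coastline_profile: Callable[[np.ndarray], np.ndarray] | None = None
    shelf_width_km: float = 150.0
    n_land_cols: int = 4
    start_year: int = DEFAULT_START_YEAR
    origin_location: tuple[int, int] | None = None  # grid (row, col); default auto

    def __post_init__(self):
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3 (no trend estimable otherwise)")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


@dataclass
class SyntheticWorld:
    spec: WorldSpec
    grid: ShelfGrid
    origin: tuple[int, int]
    coast_lon_by_row: np.ndarray
    distance_field: DistanceField | None = field(default=None, repr=False)

    @property
    def origin_lat(self) -> float:
        return float(self.grid.lat[self.origin[0]])

    @property
    def max_distance_km(self) -> float:
        return (self.grid.lat.size - 1 - self.origin[0]) * self.spec.cell_km

    def field(self) -> DistanceField:
        if self.distance_field is None:
            self.distance_field = build_distance_field(self.grid, self.origin)
        return self.distance_field

    def coastline_position(self, distance_km: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) on the first sea column at the given along-shelf distance."""
        d = np.asarray(distance_km, dtype=float)
        lat = self.origin_lat + d / KM_PER_DEG
        row = np.clip(
            np.rint((lat - self.grid.lat[0]) / (self.grid.lat[1] - self.grid.lat[0])).astype(int),
            0,
            self.grid.lat.size - 1,
        )
        dlon = float(np.diff(self.grid.lon).mean())
        lon = self.coast_lon_by_row[row] + 0.75 * dlon  # just seaward of the coast
        return lat, lon


def build_world(spec: WorldSpec) -> SyntheticWorld:
    """Materialize the raster world (masks + origin) from a WorldSpec."""
    nrow, ncol = spec.grid_shape
    dlat = spec.cell_km / KM_PER_DEG
    lat = spec.lat0 + dlat * (np.arange(nrow) + 0.5)
    lat_mid = lat.mean()
    dlon = spec.cell_km / (KM_PER_DEG * np.cos(np.radians(lat_mid)))
    lon = spec.coast_lon + dlon * (np.arange(ncol) - spec.n_land_cols + 0.5)

    offset = spec.coastline_profile(lat) if spec.coastline_profile is not None else np.zeros(nrow)
    coast = spec.coast_lon + np.asarray(offset, dtype=float)

    lon2 = np.broadcast_to(lon, (nrow, ncol))
    east_km = (lon2 - coast[:, None]) * KM_PER_DEG * np.cos(np.radians(lat))[:, None]
    land = east_km < 0
    offshelf = east_km > spec.shelf_width_km
    grid = ShelfGrid(lat=lat, lon=lon, land_mask=land, offshelf_mask=offshelf)

    if spec.origin_location is not None:
        origin = spec.origin_location
        if not grid.traversable[origin]:
            raise ValueError(f"origin_location {origin} is not a traversable sea cell")
    else:
        sea_cols = np.nonzero(grid.traversable[0])[0]
        origin = (0, int(sea_cols[0]))
    return SyntheticWorld(spec, grid, origin, coast)


# ---------------------------------------------------------------------------
# Strandings
# ---------------------------------------------------------------------------

def gen_strandings(
    spec: SpeciesSimSpec, world: SyntheticWorld | WorldSpec, seed: int
) -> pd.DataFrame:
    """Simulate stranding events for one species over the world's time span.

    Year t (1..T) contributes ``annual_n[t]`` events at poleward distance
    d = a + b·t + ε, ε ~ Normal(0, σ²).  Coordinates are placed
    deterministically on the synthetic coastline at that distance (clipped to
    the domain; both the model draw ``true_distance_km`` and the in-domain
    ``placed_distance_km`` are retained).  Years with zero events contribute
    no rows.
    """
    if isinstance(world, WorldSpec):
        world = build_world(world)
    wspec = world.spec
    counts = spec.annual_counts(wspec.n_years)
    rng = np.random.default_rng(seed)

    years, dists = [], []
    for t in range(1, wspec.n_years + 1):
        n = counts[t - 1]
        if n == 0:
            continue
        d = spec.intercept_a + spec.slope_b * t + spec.sd_sigma * rng.standard_normal(n)
        years.append(np.full(n, wspec.start_year + t - 1))
        dists.append(d)
    if not years:
        raise ValueError("spec generates no events in any year")
    year = np.concatenate(years)
    true_d = np.concatenate(dists)
    placed = np.clip(true_d, 0.0, world.max_distance_km)
    lat, lon = world.coastline_position(placed)

    df = pd.DataFrame(
        {
            "event_id": [f"{spec.species_id}_{i:05d}" for i in range(year.size)],
            "species_id": spec.species_id,
            "year": year,
            "latitude": lat,
            "longitude": lon,
            "true_distance_km": true_d,
            "placed_distance_km": placed,
            "state": "",
            "county": "",
            "description": "synthetic coastline event",
            "qc_flags": "",
        }
    )
    df.attrs["truth"] = {
        "species_id": spec.species_id,
        "slope_b": spec.slope_b,
        "intercept_a": spec.intercept_a,
        "sd_sigma": spec.sd_sigma,
        "seed": int(seed),
        "start_year": wspec.start_year,
        "n_years": wspec.n_years,
    }
    return df


# ---------------------------------------------------------------------------
# SST cubes
# ---------------------------------------------------------------------------

def gen_sst_cube(
    world: SyntheticWorld | WorldSpec,
    temporal_gradient: float | np.ndarray = 0.05,
    spatial_gradient: float = 0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_sst: float = 22.0,
) -> xr.DataArray:
    """Annual-mean SST cube with prescribed warming rate and N–S gradient.

    SST(lat, lon, t) = base(lat) + g_t(lat, lon)·t + noise, where the base
    field decreases poleward at ``spatial_gradient`` °C/km, t counts years
    from 0, and noise is i.i.d. Normal(0, noise_sd²).  Land cells are NaN.
    The implied scalar climate velocity is g_t / spatial_gradient km/yr on
    interior sea cells.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(world, WorldSpec):
        world = build_world(world)
    grid = world.grid
    wspec = world.spec
    nlat, nlon = grid.shape
    gt = np.broadcast_to(np.asarray(temporal_gradient, dtype=float), (nlat, nlon))

    y_km = (grid.lat - grid.lat[0]) * KM_PER_DEG
    base = base_sst - spatial_gradient * y_km
    t = np.arange(wspec.n_years, dtype=float)
    sst = base[:, None, None] + gt[:, :, None] * t[None, None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sst = sst + noise_sd * rng.standard_normal(sst.shape)
    sst[grid.land_mask] = np.nan
    return xr.DataArray(
        sst,
        coords={"lat": grid.lat, "lon": grid.lon, "year": wspec.years},
        dims=("lat", "lon", "year"),
        name="sst",
        attrs={"units": "degC", "description": "synthetic annual-mean SST"},
    )


# ---------------------------------------------------------------------------
# Census tables
# ---------------------------------------------------------------------------

def gen_census(
    world: SyntheticWorld | WorldSpec,
    n_counties: int = 40,
    beta_pop_vs_distance: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    alpha_pct: float = 10.0,
    pop_2000: int = 100_000,
) -> pd.DataFrame:
    """Coastal county table with a prescribed population-change-vs-distance slope.

    County centroids are spaced evenly along the coastline; percent population
    change 2000→2020 is α + β·poleward_distance + Normal(0, noise_sd²).
    """
    if n_counties < 3:
        raise ValueError("need at least 3 counties")
    if isinstance(world, WorldSpec):
        world = build_world(world)
    rng = np.random.default_rng(seed)
    dmax = world.max_distance_km
    d = (np.arange(n_counties) + 0.5) * dmax / n_counties
    lat, lon = world.coastline_position(d)
    pct = alpha_pct + beta_pop_vs_distance * d + noise_sd * rng.standard_normal(n_counties)
    pop0 = np.full(n_counties, pop_2000)
    pop1 = np.rint(pop0 * (1.0 + pct / 100.0)).astype(int)
    return pd.DataFrame(
        {
            "county_id": [f"county_{i:03d}" for i in range(n_counties)],
            "latitude": lat,
            "longitude": lon,
            "poleward_distance_km": d,
            "pop_2000": pop0,
            "pop_2020": pop1,
            "pct_change": 100.0 * (pop1 - pop0) / pop0,
        }
    )


# ---------------------------------------------------------------------------
# Fixture bundles on disk
# ---------------------------------------------------------------------------

def write_strandings_csv(records: pd.DataFrame, path) -> None:
    """Write records in the Level-A-style CSV schema the parser reads."""
    out = pd.DataFrame(
        {
            "event_id": records["event_id"],
            "species": records["species_id"],
            "date": records["year"].astype(int).astype(str) + "-07-01",
            "latitude": records["latitude"].map("{:.6f}".format),
            "longitude": records["longitude"].map("{:.6f}".format),
            "state": records.get("state", ""),
            "county": records.get("county", ""),
            "description": records.get("description", ""),
        }
    )
    out.to_csv(path, index=False)


def write_fixture_bundle(
    outdir,
    world: SyntheticWorld,
    strandings: pd.DataFrame | None = None,
    sst: xr.DataArray | None = None,
    census: pd.DataFrame | None = None,
) -> dict:
    """Write a self-describing fixture bundle: CSV records, NetCDF SST cube and
    world masks, census CSV, and a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"world": {"cell_km": world.spec.cell_km, "origin": list(world.origin),
                             "start_year": world.spec.start_year, "n_years": world.spec.n_years}}
    masks = xr.Dataset(
        {
            "land_mask": (("lat", "lon"), world.grid.land_mask.astype("i1")),
            "offshelf_mask": (("lat", "lon"), world.grid.offshelf_mask.astype("i1")),
        },
        coords={"lat": world.grid.lat, "lon": world.grid.lon},
    )
    masks.to_netcdf(outdir / "world_masks.nc", engine="scipy")
    if strandings is not None:
        write_strandings_csv(strandings, outdir / "strandings.csv")
        truth["strandings"] = strandings.attrs.get("truth", {})
    if sst is not None:
        sst.to_dataset(name="sst").to_netcdf(outdir / "sst.nc", engine="scipy")
    if census is not None:
        census.to_csv(outdir / "census.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
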