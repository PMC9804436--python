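"""Gradient-based (scalar) climate velocity and regional SST trend summaries.

Climate velocity is the speed at which a parcel of water would have to move to
keep its temperature constant: the ratio of the local warming rate to the
local spatial temperature gradient,

    v [km/yr] = g_t [°C/yr] / |∇T| [°C/km].

The temporal gradient g_t is the per-cell OLS slope of annual-mean SST on
year; the spatial gradient magnitude is computed from mean west–east and
south–north central differences over a 3 × 3 cell neighborhood of the
time-mean field, with km-per-degree-longitude scaled by cos(latitude).
Positive velocity means isotherms moving poleward (sign follows g_t).

Cubes are xarray DataArrays with dims (lat, lon, year); land cells are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .shelf_geometry import KM_PER_DEG
from .shift_inference import TrendFit, ols_fit

#: spatial-gradient floor (°C/km) below which velocity is masked rather than
#: allowed to blow up.
GRADIENT_EPS = 1e-5

CUBE_DIMS = ("lat", "lon", "year")


def _as_cube(cube: xr.DataArray) -> xr.DataArray:
    cube = cube.transpose(*CUBE_DIMS)
    if cube.sizes["year"] < 3:
        raise ValueError("SST cube needs at least 3 years")
    return cube


def temporal_gradient(cube: xr.DataArray) -> xr.DataArray:
    """Per-cell OLS slope of SST on year (°C/yr); cells with < 3 valid years NaN."""
    cube = _as_cube(cube)
    y = cube.values
    t = cube["year"].values.astype(float)
    valid = np.isfinite(y)
    nv = valid.sum(axis=-1)
    yz = np.where(valid, y, 0.0)
    tz = np.where(valid, t, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = tz.sum(-1) / nv
        ybar = yz.sum(-1) / nv
        sxy = (np.where(valid, (t - tbar[..., None]) * y, 0.0)).sum(-1)
        sxx = (np.where(valid, (t - tbar[..., None]) ** 2, 0.0)).sum(-1)
        slope = sxy / sxx
    slope[nv < 3] = np.nan
    return xr.DataArray(slope, coords={"lat": cube["lat"], "lon": cube["lon"]}, dims=("lat", "lon"), name="temporal_gradient")


def spatial_gradient(cube: xr.DataArray) -> xr.DataArray:
    """Magnitude of the spatial gradient of time-mean SST (°C/km).

    For each cell, the south–north component is the mean central difference
    down the three columns of its 3 × 3 neighborhood and the west–east
    component the mean central difference along the three rows; the magnitude
    is the hypotenuse.  Cells with fewer than 3 valid neighbors, or on the
    raster border, are masked.
    """
    cube = _as_cube(cube)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN land cells
        T = np.nanmean(cube.values, axis=-1)
    lat = cube["lat"].values
    lon = cube["lon"].values
    dy_km = float(np.diff(lat).mean()) * KM_PER_DEG
    dx_km = float(np.diff(lon).mean()) * KM_PER_DEG * np.cos(np.radians(lat))  # per row

    P = np.pad(T, 1, constant_values=np.nan)
    # south-north central differences for the 3 columns of the neighborhood
    ns = np.stack([(P[2:, c : c + T.shape[1]] - P[:-2, c : c + T.shape[1]]) / (2 * dy_km) for c in range(3)])
    # west-east central differences for the 3 rows; row spacing uses that row's dx
    dxp = np.pad(dx_km, 1, mode="edge")
    we = np.stack(
        [
            (P[r : r + T.shape[0], 2:] - P[r : r + T.shape[0], :-2]) / (2 * dxp[r : r + T.shape[0], None])
            for r in range(3)
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighborhoods
        gy = np.nanmean(ns, axis=0)
        gx = np.nanmean(we, axis=0)
        mag = np.hypot(gx, gy)

    nb_valid = np.zeros_like(T)
    V = np.isfinite(P).astype(float)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            if dr == dc == 1:
                continue
            nb_valid += V[dr : dr + T.shape[0], dc : dc + T.shape[1]]
    mag[(nb_valid < 3) | ~np.isfinite(T)] = np.nan
    # border cells lack a full neighborhood for central differences
    mag[0, :] = mag[-1, :] = np.nan
    mag[:, 0] = mag[:, -1] = np.nan
    return xr.DataArray(mag, coords={"lat": cube["lat"], "lon": cube["lon"]}, dims=("lat", "lon"), name="spatial_gradient")


@dataclass
class VelocityField:
    temporal_gradient: xr.DataArray  # °C/yr
    spatial_gradient: xr.DataArray  # °C/km
    velocity: xr.DataArray  # km/yr
    valid: xr.DataArray  # bool


def climate_velocity(
    g_t: xr.DataArray, grad: xr.DataArray, eps: float = GRADIENT_EPS
) -> VelocityField:
    """v = g_t / |∇T| where the spatial gradient clears the ``eps`` floor."""
    if g_t.shape != grad.shape:
        raise ValueError("temporal and spatial gradient fields must align")
    valid = np.isfinite(g_t.values) & np.isfinite(grad.values) & (grad.values >= eps)
    v = np.where(valid, g_t.values / np.where(valid, grad.values, 1.0), np.nan)
    vel = xr.DataArray(v, coords=g_t.coords, dims=g_t.dims, name="climate_velocity")
    return VelocityField(g_t, grad, vel, xr.DataArray(valid, coords=g_t.coords, dims=g_t.dims))


def velocity_from_cube(cube: xr.DataArray, eps: float = GRADIENT_EPS) -> VelocityField:
    """Convenience: full velocity pipeline from an annual SST cube."""
    return climate_velocity(temporal_gradient(cube), spatial_gradient(cube), eps)


@dataclass
class RegionalSummary:
    median: float
    q25: float
    q75: float
    n_cells: int


def _weighted_quantiles(vals: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(vals)
    v, w = vals[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w  # midpoint rule
    return np.interp(np.asarray(qs) * w.sum(), cw, v)


def regional_summary(
    field: xr.DataArray, region_mask: np.ndarray, area_weighted: bool = False
) -> RegionalSummary:
    """Median and quartiles of a per-cell field over valid cells in a region.

    With ``area_weighted`` each cell is weighted by cos(latitude) (cell area
    on a regular lat/lon grid); on a grid of equal-area cells this coincides
    with the unweighted default.
    """
    mask = np.asarray(region_mask, dtype=bool)
    vals = field.values[mask]
    keep = np.isfinite(vals)
    vals = vals[keep]
    if vals.size == 0:
        raise ValueError("region contains no valid cells")
    if area_weighted:
        if "lat" not in field.dims:
            raise ValueError("area weighting needs a lat dimension")
        lat2 = np.broadcast_to(field["lat"].values[:, None], field.shape)
        w = np.cos(np.radians(lat2[mask][keep]))
        q25, med, q75 = _weighted_quantiles(vals, w, [0.25, 0.5, 0.75])
    else:
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
    return RegionalSummary(float(med), float(q25), float(q75), int(vals.size))


def sst_anomaly_series(
    cube: xr.DataArray,
    region_mask: np.ndarray,
    baseline: tuple[int, int] | None = None,
) -> tuple[pd.Series, TrendFit]:
    """Regional annual-mean SST anomaly series and its trend.

    The anomaly is the unweighted regional annual mean minus the climatology
    (mean of the regional annual means over the baseline window; default the
    full record).  Returns the year-indexed series and its OLS trend on year.
    """
    cube = _as_cube(cube)
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    sub = cube.values[mask]  # (ncell, nyear)
    annual = np.nanmean(sub, axis=0)
    years = cube["year"].values.astype(int)
    if baseline is None:
        base = annual.mean()
    else:
        y0, y1 = baseline
        sel = (years >= y0) & (years <= y1)
        if not sel.any():
            raise ValueError("baseline window outside cube years")
        base = annual[sel].mean()
    anom = pd.Series(annual - base, index=years, name="sst_anomaly")
    return anom, ols_fit(years, anom.values)
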