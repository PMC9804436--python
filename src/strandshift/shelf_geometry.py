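"""Along-shelf distance over a raster world with coastline and shelf-break barriers.

The 1-D coordinate used throughout the package — "poleward distance" — is the
shortest along-shelf path, in km, from an origin at the equatorward end of the
continental shelf (in the real study system, the southern end of mainland
Florida) to each sea-and-on-shelf raster cell.  Land and off-shelf cells are
barriers.  Paths move between 8-connected traversable cells; an orthogonal step
costs the local cell size and a diagonal step the hypotenuse of the two local
cell sizes, with longitude spacing scaled by cos(latitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0  # ~111.195 km per degree of latitude


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class ShelfGrid:
    """Raster world: cell-center coordinates plus land and off-shelf barrier masks.

    ``lat`` and ``lon`` are strictly increasing cell-center coordinate vectors;
    masks are (nlat, nlon) booleans, True where the cell is a barrier.
    """

    lat: np.ndarray
    lon: np.ndarray
    land_mask: np.ndarray
    offshelf_mask: np.ndarray

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self.offshelf_mask = np.asarray(self.offshelf_mask, dtype=bool)
        if self.land_mask.shape != self.offshelf_mask.shape:
            raise ValueError("land_mask and offshelf_mask must have the same shape")
        if self.land_mask.shape != (self.lat.size, self.lon.size):
            raise ValueError("mask shape must be (len(lat), len(lon))")
        for name, v in (("lat", self.lat), ("lon", self.lon)):
            if v.size > 1 and not np.all(np.diff(v) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not self.traversable.any():
            raise ValueError("grid has no traversable (sea-and-on-shelf) cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_mask.shape

    @property
    def traversable(self) -> np.ndarray:
        return ~(self.land_mask | self.offshelf_mask)

    @property
    def cell_dy_km(self) -> float:
        """North-south cell extent in km (uniform latitude spacing assumed)."""
        if self.lat.size < 2:
            return KM_PER_DEG * 0.05
        return float(np.diff(self.lat).mean() * KM_PER_DEG)

    @property
    def cell_dx_km(self) -> np.ndarray:
        """Per-row east-west cell extent in km, scaled by cos(latitude)."""
        dlon = float(np.diff(self.lon).mean()) if self.lon.size > 1 else 0.05
        return dlon * KM_PER_DEG * np.cos(np.radians(self.lat))

    def snap_origin(self, lat: float, lon: float) -> tuple[int, int]:
        """Index of the traversable cell nearest to (lat, lon)."""
        rows, cols = np.nonzero(self.traversable)
        d = haversine_km(lat, lon, self.lat[rows], self.lon[cols])
        k = int(np.argmin(d))
        return int(rows[k]), int(cols[k])


@dataclass
class DistanceField:
    """Along-shelf distance from the origin for every cell; inf where unreachable."""

    grid: ShelfGrid
    origin: tuple[int, int]
    distance_km: np.ndarray = field(repr=False)

    @property
    def reachable(self) -> np.ndarray:
        return np.isfinite(self.distance_km)


# 8-connected neighborhood offsets
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def step_length_km(grid: ShelfGrid, r: int, dr: int, dc: int) -> float:
    """Cost of moving (dr, dc) from a cell in row r.

    Orthogonal steps cost the local cell dimension; diagonal steps the
    hypotenuse, with the east-west dimension averaged over the two rows.
    """
    dy = grid.cell_dy_km
    dx = grid.cell_dx_km
    if dc == 0:
        return dy
    if dr == 0:
        return float(dx[r])
    return float(np.hypot(0.5 * (dx[r] + dx[r + dr]), dy))


def build_distance_field(grid: ShelfGrid, origin: tuple[int, int]) -> DistanceField:
    """Exact single-source shortest-path distances over traversable cells.

    Parameters
    ----------
    origin : (row, col) index of the distance origin; must be traversable.
    """
    trav = grid.traversable
    r0, c0 = origin
    if not trav[r0, c0]:
        raise ValueError(f"origin {origin} is on a barrier cell")

    nlat, nlon = grid.shape
    idx = -np.ones(grid.shape, dtype=np.int64)
    rows, cols = np.nonzero(trav)
    idx[rows, cols] = np.arange(rows.size)

    src, dst, w = [], [], []
    for dr, dc in _OFFSETS:
        r2 = rows + dr
        c2 = cols + dc
        ok = (r2 >= 0) & (r2 < nlat) & (c2 >= 0) & (c2 < nlon)
        ok[ok] &= trav[r2[ok], c2[ok]]
        rr, cc = rows[ok], cols[ok]
        src.append(idx[rr, cc])
        dst.append(idx[r2[ok], c2[ok]])
        dy = grid.cell_dy_km
        dx = grid.cell_dx_km
        if dc == 0:
            w.append(np.full(rr.size, dy))
        elif dr == 0:
            w.append(dx[rr])
        else:
            w.append(np.hypot(0.5 * (dx[rr] + dx[rr + dr]), dy))
    n = rows.size
    graph = coo_matrix(
        (np.concatenate(w), (np.concatenate(src), np.concatenate(dst))), shape=(n, n)
    ).tocsr()
    d = dijkstra(graph, directed=False, indices=idx[r0, c0])

    out = np.full(grid.shape, np.inf)
    out[rows, cols] = d
    return DistanceField(grid=grid, origin=(r0, c0), distance_km=out)


def _cell_xyz(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Unit-sphere cartesian coordinates scaled to km, for chord-distance queries."""
    la, lo = np.radians(lat), np.radians(lon)
    return EARTH_RADIUS_KM * np.column_stack(
        [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)]
    )


def poleward_distance(
    records: pd.DataFrame, dist: DistanceField, snap_km: float = 25.0
) -> pd.DataFrame:
    """Attach ``poleward_distance_km`` to records by snapping to the nearest
    reachable shelf cell.

    Each record gets the along-shelf distance of the nearest reachable
    traversable cell within ``snap_km`` great-circle km of its coordinate.
    Records farther than ``snap_km`` from any reachable cell keep a missing
    distance and gain the qc flag ``unsnappable``.
    """
    grid = dist.grid
    usable = grid.traversable & dist.reachable
    rows, cols = np.nonzero(usable)
    if rows.size == 0:
        raise ValueError("distance field has no reachable traversable cells")
    tree = cKDTree(_cell_xyz(grid.lat[rows], grid.lon[cols]))

    out = records.copy()
    pts = _cell_xyz(out["latitude"].to_numpy(float), out["longitude"].to_numpy(float))
    chord, k = tree.query(pts)
    # chord -> great-circle arc length
    arc = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / (2.0 * EARTH_RADIUS_KM), 0.0, 1.0))
    ok = arc <= snap_km
    dist_vals = np.where(ok, dist.distance_km[rows[k], cols[k]], np.nan)
    out["poleward_distance_km"] = dist_vals
    if "qc_flags" not in out.columns:
        out["qc_flags"] = ""
    flagged = ~ok
    if flagged.any():
        out.loc[flagged, "qc_flags"] = (
            out.loc[flagged, "qc_flags"].astype(str).str.rstrip(";")
            + np.where(out.loc[flagged, "qc_flags"].astype(str) == "", "", ";")
            + "unsnappable"
        )
    return out
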