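import numpy as np
import pytest

from strandshift import synthetic_data
from strandshift.shelf_geometry import KM_PER_DEG, ShelfGrid


@pytest.fixture(scope="session")
def small_world():
    """100x20 straight-coast world, 10 km cells, 25 years."""
    return synthetic_data.build_world(
        synthetic_data.WorldSpec(grid_shape=(100, 20), cell_km=10.0)
    )


@pytest.fixture(scope="session")
def small_field(small_world):
    return small_world.field()


def make_random_grid(rng, shape=(15, 15), p_land=0.3, p_offshelf=0.1):
    """Random barrier world with at least one traversable cell; returns
    (grid, origin) with origin on a traversable cell."""
    while True:
        land = rng.random(shape) < p_land
        offshelf = rng.random(shape) < p_offshelf
        trav = ~(land | offshelf)
        if trav.sum() >= 2:
            break
    lat = 30.0 + 0.1 * np.arange(shape[0])
    lon = -75.0 + 0.1 * np.arange(shape[1])
    grid = ShelfGrid(lat=lat, lon=lon, land_mask=land, offshelf_mask=offshelf)
    rows, cols = np.nonzero(trav)
    k = rng.integers(rows.size)
    return grid, (int(rows[k]), int(cols[k]))


def bellman_ford_distances(grid, origin):
    """Independent shortest-path oracle: iterate relaxations to a fixpoint.

    Step weights recomputed from coordinates: orthogonal = local cell size,
    diagonal = hypotenuse of the two local cell sizes.
    """
    trav = grid.traversable
    nlat, nlon = grid.shape
    dy = float(np.diff(grid.lat).mean()) * KM_PER_DEG
    dlon = float(np.diff(grid.lon).mean())
    dx = dlon * KM_PER_DEG * np.cos(np.radians(grid.lat))
    dist = np.full(grid.shape, np.inf)
    dist[origin] = 0.0
    changed = True
    while changed:
        changed = False
        for r in range(nlat):
            for c in range(nlon):
                if not trav[r, c] or not np.isfinite(dist[r, c]):
                    continue
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        r2, c2 = r + dr, c + dc
                        if not (0 <= r2 < nlat and 0 <= c2 < nlon) or not trav[r2, c2]:
                            continue
                        if dc == 0:
                            w = dy
                        elif dr == 0:
                            w = dx[r]
                        else:
                            w = np.hypot(0.5 * (dx[r] + dx[r2]), dy)
                        if dist[r, c] + w < dist[r2, c2] - 1e-12:
                            dist[r2, c2] = dist[r, c] + w
                            changed = True
    return dist
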