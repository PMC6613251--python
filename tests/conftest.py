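"""Shared fixtures: small synthetic regions and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
import shapely

from abode.allocation import BlockIndex
from abode.rhu import assign_block, censor_nonresidential
from abode.synthetic import ScenarioConfig, generate_region


@pytest.fixture(scope="session")
def uniform_region():
    """Uniformly placed households, modest contamination; 6x6 blocks."""
    cfg = ScenarioConfig(nx=6, ny=6, n_wells=60, seed=11, placement="uniform")
    return generate_region(cfg)


@pytest.fixture(scope="session")
def clustered_region():
    """Households clustered along block boundaries (roadway pattern)."""
    cfg = ScenarioConfig(
        nx=6, ny=6, n_wells=60, seed=12, placement="boundary_clustered"
    )
    return generate_region(cfg)


def prepared(region):
    """Censor, assign, and index a region: (rhus, BlockIndex)."""
    rhus = assign_block(
        censor_nonresidential(region.candidates, region.land_use), region.blocks
    )
    return rhus, BlockIndex(region.blocks)


@pytest.fixture(scope="session")
def uniform_prepared(uniform_region):
    return prepared(uniform_region)


@pytest.fixture(scope="session")
def clustered_prepared(clustered_region):
    return prepared(clustered_region)


# --- independent oracles -----------------------------------------------------


def haversine_m(lon1, lat1, lon2, lat2, radius=6_371_008.8):
    """Great-circle distance on the mean sphere (projection-free oracle)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(a))


def monte_carlo_area(geom, n=1_000_000, seed=0):
    """Point-sampling area estimate over the geometry's bounding box."""
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = geom.bounds
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    inside = shapely.contains_xy(geom, xs, ys)
    return (maxx - minx) * (maxy - miny) * inside.mean()


def ray_casting_contains(ring, x, y):
    """Crossing-number point-in-polygon (open region; boundary unspecified)."""
    n = len(ring)
    inside = False
    for i in range(n - 1):
        x1, y1 = ring[i]
        x2, y2 = ring[i + 1]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside
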