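"""Seeded synthetic study regions for end-to-end testing of the pipeline.

The generator emulates the statistical structure the allocation methods
assume: a tiling of jittered-rectangle census blocks with heterogeneous
(negative-binomial) housing-unit counts, household points placed either
uniformly or clustered along block boundaries (the roadway pattern that
makes areal weighting fail at small radii, since census block edges often
run along roads lined with homes), multi-unit buildings as duplicate
coordinates, non-residential contaminant points in commercial land-use
cells, a 30 m land-use grid, and hazard wells.  A ``truth`` table records
the exact number of persons at every candidate point, giving an exact
ground-truth population for any query polygon.

All randomness flows from one ``numpy`` Generator seeded from the config;
the draw order is fixed (block-node jitter, per-block housing-unit counts,
group quarters, commercial cells, per-block unit placement and household
sizes, multi-unit duplication, contaminant points, wells), so outputs are
bit-reproducible across runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .allocation import Well
from .census import CensusBlock
from .geometry import Frame, GeoPoint
from .landuse import LandUseGrid
from .rhu import CandidateLocation

__all__ = ["ScenarioConfig", "RegionData", "generate_region", "truth_population"]

log = logging.getLogger(__name__)

RESIDENTIAL_CLASS = 1
COMMERCIAL_CLASS = 2


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study region.

    Defaults sketch a suburban-to-exurban region: 500 m blocks with ~40
    housing units each (overdispersed across blocks), mean household size
    2.5 persons, a small group-quarters and commercial presence, and one
    hazard well per ~1.25 blocks.
    """

    nx: int = 10
    ny: int = 10
    block_size: float = 500.0
    boundary_jitter: float = 0.15
    mean_hu_per_block: float = 40.0
    hu_dispersion: float = 3.0
    household_size_mean: float = 2.5
    household_size_sd: float = 1.2
    gq_fraction: float = 0.02
    gq_mean_population: float = 40.0
    placement: str = "uniform"  # uniform | boundary_clustered
    boundary_bandwidth: float = 40.0
    multiunit_rate: float = 0.05
    nonresidential_rate: float = 0.05
    commercial_cell_fraction: float = 0.08
    cell_size: float = 30.0
    n_wells: int = 200
    well_placement: str = "uniform"  # uniform | near_boundary
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "n_wells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("block_size", "boundary_bandwidth", "cell_size", "hu_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "gq_fraction",
            "multiunit_rate",
            "nonresidential_rate",
            "commercial_cell_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.boundary_jitter <= 0.3:
            raise ValueError("boundary_jitter must be in [0, 0.3] (blocks must tile)")
        if self.household_size_mean < 1.0:
            raise ValueError("household_size_mean must be >= 1")
        if self.household_size_sd < 0.0:
            raise ValueError("household_size_sd must be >= 0")
        if self.placement not in ("uniform", "boundary_clustered"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.well_placement not in ("uniform", "near_boundary"):
            raise ValueError(f"unknown well_placement {self.well_placement!r}")


@dataclass
class RegionData:
    """Everything the pipeline consumes, plus the ground truth."""

    blocks: list[CensusBlock]
    candidates: list[CandidateLocation]
    land_use: LandUseGrid
    wells: list[Well]
    truth: pd.DataFrame  # candidate_id, x, y, persons
    config: ScenarioConfig = field(repr=False, default=None)


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Normal(mean, sd) truncated below at 1 by resampling (household sizes)."""
    if n == 0:
        return np.zeros(0)
    if sd == 0.0:
        return np.full(n, mean)
    out = mean + sd * rng.standard_normal(n)
    for _ in range(1000):
        bad = out < 1.0
        if not bad.any():
            break
        out[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
    return np.maximum(out, 1.0)


def _sample_in_polygon(
    rng: np.random.Generator,
    poly: Polygon,
    n: int,
    grid: LandUseGrid | None,
    band: float | None,
) -> np.ndarray:
    """Rejection-sample n points in poly, avoiding commercial cells and,
    when ``band`` is set, staying within that distance of the boundary.

    Constraints are relaxed in order (band first, then land use) if the
    polygon cannot supply enough points, so generation always terminates.
    """
    minx, miny, maxx, maxy = poly.bounds
    boundary = poly.exterior
    collected: list[np.ndarray] = []
    need = n
    relax_band = False
    relax_grid = False
    for attempt in range(400):
        m = max(4 * need, 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        pts = shapely.points(xs, ys)
        ok = shapely.covers(poly, pts)
        if band is not None and not relax_band:
            ok &= shapely.distance(boundary, pts) <= band
        if grid is not None and not relax_grid:
            codes = grid.lookup_many(xs, ys)
            ok &= codes != COMMERCIAL_CLASS
        took = np.column_stack([xs[ok], ys[ok]])[:need]
        if len(took):
            collected.append(took)
            need -= len(took)
        if need == 0:
            break
        if attempt == 100:
            relax_band = True
        if attempt == 200:
            relax_grid = True
    if need > 0:
        raise RuntimeError("could not place points inside polygon")
    return np.concatenate(collected) if collected else np.zeros((0, 2))


def generate_region(cfg: ScenarioConfig) -> RegionData:
    """Generate a complete synthetic region; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    bs = cfg.block_size

    # --- block tiling: shared jittered node lattice -> no gaps/overlaps ----
    nodes = np.zeros((cfg.nx + 1, cfg.ny + 1, 2))
    for ix in range(cfg.nx + 1):
        for iy in range(cfg.ny + 1):
            x, y = ix * bs, iy * bs
            if 0 < ix < cfg.nx:
                x += rng.uniform(-cfg.boundary_jitter, cfg.boundary_jitter) * bs
            if 0 < iy < cfg.ny:
                y += rng.uniform(-cfg.boundary_jitter, cfg.boundary_jitter) * bs
            nodes[ix, iy] = (x, y)

    geoms: dict[str, Polygon] = {}
    for iy in range(cfg.ny):
        for ix in range(cfg.nx):
            ring = [
                tuple(nodes[ix, iy]),
                tuple(nodes[ix + 1, iy]),
                tuple(nodes[ix + 1, iy + 1]),
                tuple(nodes[ix, iy + 1]),
                tuple(nodes[ix, iy]),
            ]
            geoms[f"B{iy:03d}{ix:03d}"] = Polygon(ring)
    block_ids = sorted(geoms)

    # --- per-block housing-unit counts and group quarters ------------------
    p_nb = cfg.hu_dispersion / (cfg.hu_dispersion + cfg.mean_hu_per_block)
    hu_counts = {
        bid: int(rng.negative_binomial(cfg.hu_dispersion, p_nb)) for bid in block_ids
    }
    gq_pops = {
        bid: (int(rng.poisson(cfg.gq_mean_population)) if rng.uniform() < cfg.gq_fraction else 0)
        for bid in block_ids
    }

    # --- land-use grid ------------------------------------------------------
    all_geom = shapely.geometry.MultiPolygon([geoms[b] for b in block_ids])
    minx, miny, maxx, maxy = all_geom.bounds
    x0 = math.floor(minx / cfg.cell_size) * cfg.cell_size
    y0 = math.floor(miny / cfg.cell_size) * cfg.cell_size
    n_cols = math.ceil((maxx - x0) / cfg.cell_size)
    n_rows = math.ceil((maxy - y0) / cfg.cell_size)
    codes = np.full((n_rows, n_cols), RESIDENTIAL_CLASS, dtype=int)
    commercial_mask = rng.uniform(size=codes.shape) < cfg.commercial_cell_fraction
    codes[commercial_mask] = COMMERCIAL_CLASS
    grid = LandUseGrid(
        x0=x0,
        y0=y0,
        cell_size=cfg.cell_size,
        codes=codes,
        excluded_classes=frozenset({COMMERCIAL_CLASS}),
    )

    # --- household points, sizes, multi-unit duplication --------------------
    band = cfg.boundary_bandwidth if cfg.placement == "boundary_clustered" else None
    candidates: list[CandidateLocation] = []
    truth_rows: list[tuple[str, float, float, float]] = []
    blocks: list[CensusBlock] = []
    counter = 0
    for bid in block_ids:
        n_hu = hu_counts[bid]
        sizes = _truncated_normal(rng, n_hu, cfg.household_size_mean, cfg.household_size_sd)
        pts = (
            _sample_in_polygon(rng, geoms[bid], n_hu, grid, band)
            if n_hu
            else np.zeros((0, 2))
        )
        # multi-unit buildings: a unit may reuse an earlier unit's coordinates
        if cfg.multiunit_rate > 0 and n_hu > 1:
            dup = rng.uniform(size=n_hu) < cfg.multiunit_rate
            dup[0] = False
            for i in np.flatnonzero(dup):
                pts[i] = pts[rng.integers(0, i)]
        for i in range(n_hu):
            cid = f"C{counter:06d}"
            counter += 1
            candidates.append(
                CandidateLocation(cid, GeoPoint(pts[i, 0], pts[i, 1], Frame.PLANAR))
            )
            truth_rows.append((cid, pts[i, 0], pts[i, 1], float(sizes[i])))
        blocks.append(
            CensusBlock(
                block_id=bid,
                geometry=geoms[bid],
                total_population=float(sizes.sum()) + gq_pops[bid],
                group_quarters_population=float(gq_pops[bid]),
                housing_units=n_hu,
            )
        )

    # --- non-residential contaminant points in commercial cells -------------
    total_hu = sum(hu_counts.values())
    n_nonres = round(cfg.nonresidential_rate * total_hu)
    comm_cells = np.argwhere(codes == COMMERCIAL_CLASS)
    if n_nonres > 0 and len(comm_cells) == 0:
        log.warning("no commercial cells; contaminant points skipped")
        n_nonres = 0
    for _ in range(n_nonres):
        row, col = comm_cells[rng.integers(0, len(comm_cells))]
        cx = x0 + (col + rng.uniform()) * cfg.cell_size
        cy = y0 + (n_rows - 1 - row + rng.uniform()) * cfg.cell_size
        cid = f"C{counter:06d}"
        counter += 1
        candidates.append(CandidateLocation(cid, GeoPoint(cx, cy, Frame.PLANAR)))
        truth_rows.append((cid, cx, cy, 0.0))

    # --- wells ---------------------------------------------------------------
    wells: list[Well] = []
    if cfg.well_placement == "uniform":
        wx = rng.uniform(0, cfg.nx * bs, cfg.n_wells)
        wy = rng.uniform(0, cfg.ny * bs, cfg.n_wells)
        coords = np.column_stack([wx, wy])
    else:  # near_boundary
        rows = []
        for _ in range(cfg.n_wells):
            bid = block_ids[rng.integers(0, len(block_ids))]
            rows.append(
                _sample_in_polygon(rng, geoms[bid], 1, None, cfg.boundary_bandwidth)[0]
            )
        coords = np.asarray(rows)
    for i, (x, y) in enumerate(coords):
        wells.append(
            Well(f"W{i:04d}", float(x), float(y), state="SYN", facility_id=f"F{i // 10:03d}")
        )

    truth = pd.DataFrame(truth_rows, columns=["candidate_id", "x", "y", "persons"])
    return RegionData(blocks, candidates, grid, wells, truth, cfg)


def truth_population(truth: pd.DataFrame, polygon) -> float:
    """Exact ground-truth persons whose household point is in the polygon.

    Boundary-inclusive, matching the allocation convention.
    """
    if len(truth) == 0:
        return 0.0
    pts = shapely.points(truth["x"].to_numpy(), truth["y"].to_numpy())
    mask = shapely.covers(polygon, pts)
    return float(truth["persons"].to_numpy()[mask].sum())


def truth_population_circle(truth: pd.DataFrame, cx: float, cy: float, r: float) -> float:
    """Ground truth for a circular area via the exact distance test."""
    if len(truth) == 0:
        return 0.0
    d2 = (truth["x"].to_numpy() - cx) ** 2 + (truth["y"].to_numpy() - cy) ** 2
    return float(truth["persons"].to_numpy()[d2 <= r * r].sum())
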