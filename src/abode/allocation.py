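"""The two population-at-risk estimators: ABODE and PPA.

ABODE (Allocation By Occupied Domicile Estimation) counts the residential
housing units (RHUs) inside a hazard area, grouped by the census block each
RHU is anchored in, and allocates each block's average persons-per-household
to each counted unit:

    Pop_j = sum_i RHU_ij * pph_i

Optionally the contribution of each block is capped so that the RHUs counted
block-wide never exceed the census housing-unit count — guarding against
address misclassification and post-census housing growth.

PPA (proportional population allocation) is classical areal weighting: the
hazard polygon is intersected with each census block, and the clipped area
is multiplied by the block's population density.

ABODE is anchored to discrete dwellings, so an area with no RHUs gets
exactly zero population; PPA spreads population continuously and therefore
produces false positives wherever a block-overlapping area contains no
dwelling.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.strtree import STRtree

from .census import CensusBlock, compute_pph, population_density
from .geometry import FOOT_M, buffer_point, clip, dissolve, polygon_area
from .rhu import ResidentialHousingUnit

__all__ = [
    "Well",
    "WellArea",
    "AllocationResult",
    "SetbackRecord",
    "BlockIndex",
    "build_well_area",
    "rhus_in_area",
    "block_rhu_totals",
    "block_cap_factor",
    "abode_population",
    "ppa_population",
    "universe_totals",
    "classify_agreement",
    "setback_conflicts",
    "AGREEMENT_CATEGORIES",
]

log = logging.getLogger(__name__)

AGREEMENT_CATEGORIES = ("both_positive", "both_zero", "fp_low", "fp_high", "other")


@dataclass(frozen=True)
class Well:
    """A hazard site (planar metres); state drives setback-rule lookup."""

    well_id: str
    x: float
    y: float
    state: str | None = None
    facility_id: str | None = None


@dataclass
class WellArea:
    """A radial hazard buffer with its per-block clipped intersection areas."""

    well_id: str
    center: tuple[float, float]
    radius: float
    polygon: Polygon
    intersections: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [b for b, _ in self.intersections]
        if len(ids) != len(set(ids)):
            raise ValueError(f"well {self.well_id}: duplicate block in intersections")
        total = sum(a for _, a in self.intersections)
        if total > polygon_area(self.polygon) * (1 + 1e-9):
            raise ValueError(
                f"well {self.well_id}: clipped areas exceed buffer area"
            )


@dataclass(frozen=True)
class AllocationResult:
    """Population estimate for one area under one method.

    ``well_id`` is ``"UNIVERSE"`` for dissolved-union totals.  ``rhu_count``
    is the uncapped RHU count for ABODE methods and None for PPA.
    ``gq_warning`` flags intersected blocks with group-quarters population,
    which neither estimator allocates.
    """

    well_id: str
    method: str  # abode_capped | abode_uncapped | ppa
    population: float
    rhu_count: int | None = None
    gq_warning: bool = False

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError("population must be >= 0")
        if self.method.startswith("abode") and self.rhu_count == 0 and self.population != 0:
            raise ValueError("ABODE with zero RHUs must report zero population")


@dataclass(frozen=True)
class SetbackRecord:
    """Per-well setback-conflict record: RHUs within the regulated distance."""

    well_id: str
    state: str
    facility_id: str | None
    setback_ft: float
    n_conflict_rhus: int
    abode_capped: float
    abode_uncapped: float
    ppa: float


class BlockIndex:
    """Spatial index over census blocks with cached derived quantities."""

    def __init__(self, blocks: Sequence[CensusBlock], density_mode: str = "total"):
        self.blocks = list(blocks)
        self.by_id: dict[str, CensusBlock] = {b.block_id: b for b in self.blocks}
        if len(self.by_id) != len(self.blocks):
            raise ValueError("duplicate block_id in blocks")
        self.tree = STRtree([b.geometry for b in self.blocks])
        self.density_mode = density_mode
        self.pph: dict[str, float] = {
            b.block_id: compute_pph(b).value for b in self.blocks
        }
        self.density: dict[str, float] = {
            b.block_id: population_density(b, density_mode) for b in self.blocks
        }

    def query(self, geom) -> list[CensusBlock]:
        return [self.blocks[int(i)] for i in self.tree.query(geom)]


def _as_index(blocks, density_mode: str = "total") -> BlockIndex:
    if isinstance(blocks, BlockIndex):
        return blocks
    return BlockIndex(blocks, density_mode)


def build_well_area(
    well: Well,
    radius: float,
    blocks: Sequence[CensusBlock] | BlockIndex,
    n_segments: int = 64,
) -> WellArea:
    """Buffer a well and clip the buffer against every overlapping block."""
    index = _as_index(blocks)
    poly = buffer_point((well.x, well.y), radius, n_segments)
    inters: list[tuple[str, float]] = []
    for b in index.query(poly):
        piece = clip(poly, b.geometry)
        a = polygon_area(piece)
        if a > 0:
            inters.append((b.block_id, a))
    return WellArea(well.well_id, (well.x, well.y), radius, poly, inters)


def rhus_in_area(
    area: WellArea, rhus: Sequence[ResidentialHousingUnit]
) -> dict[str, int]:
    """Count RHUs inside the circular well-area, grouped by assigned block.

    The membership test is the exact Euclidean distance |p - c| <= r
    (boundary-inclusive): a dwelling exactly at the radius counts.  The
    buffer polygon, being an inscribed approximation of the circle, is used
    only on the PPA (area-weighting) side.
    """
    cx, cy = area.center
    counts: Counter[str] = Counter()
    for r in rhus:
        if r.block_id is None:
            continue
        dx = r.point.x - cx
        dy = r.point.y - cy
        if dx * dx + dy * dy <= area.radius * area.radius:
            counts[r.block_id] += 1
    return dict(counts)


def block_rhu_totals(rhus: Sequence[ResidentialHousingUnit]) -> dict[str, int]:
    """RHUs assigned to each block over its whole extent (capping denominator)."""
    return dict(Counter(r.block_id for r in rhus if r.block_id is not None))


def block_cap_factor(block: CensusBlock, rhu_total_in_block: int) -> float:
    """Block-level scaling so counted RHUs never exceed census housing units.

    min(1, housing_units / block-wide RHU count); 1 when the block holds no
    RHUs (nothing to scale).  A zero-housing-unit block yields 0: its RHUs
    contribute no population.
    """
    if rhu_total_in_block < 0 or block.housing_units < 0:
        raise ValueError("negative inputs to block_cap_factor")
    if rhu_total_in_block == 0:
        return 1.0
    return min(1.0, block.housing_units / rhu_total_in_block)


def abode_population(
    area: WellArea,
    blocks: Sequence[CensusBlock] | BlockIndex,
    rhus: Sequence[ResidentialHousingUnit],
    capped: bool = True,
    cap_mode: str = "scale",
    rhu_totals: Mapping[str, int] | None = None,
) -> AllocationResult:
    """ABODE estimate for one well-area: Pop_j = sum_i RHU_ij * f_i * pph_i.

    ``capped`` applies the census housing-unit cap; ``cap_mode="scale"``
    scales every block's counted RHUs by a block-wide factor (preserving the
    intra-block spatial pattern), ``"hard"`` truncates the per-area count at
    the block's housing units.  ``rhu_totals`` may carry precomputed
    block-wide RHU counts.
    """
    index = _as_index(blocks)
    counts = rhus_in_area(area, rhus)
    if capped and rhu_totals is None:
        rhu_totals = block_rhu_totals(rhus)
    pop = 0.0
    for block_id, n in counts.items():
        block = index.by_id[block_id]
        pph = index.pph[block_id]
        if not capped:
            pop += n * pph
        elif cap_mode == "scale":
            f = block_cap_factor(block, rhu_totals.get(block_id, 0))
            pop += n * f * pph
        elif cap_mode == "hard":
            pop += min(n, block.housing_units) * pph
        else:
            raise ValueError(f"unknown cap_mode {cap_mode!r}")
    gq = any(
        index.by_id[b].group_quarters_population > 0 for b, _ in area.intersections
    )
    return AllocationResult(
        well_id=area.well_id,
        method="abode_capped" if capped else "abode_uncapped",
        population=pop,
        rhu_count=sum(counts.values()),
        gq_warning=gq,
    )


def ppa_population(
    area_polygon: Polygon | MultiPolygon,
    blocks: Sequence[CensusBlock] | BlockIndex,
    density_mode: str = "total",
    well_id: str = "",
) -> AllocationResult:
    """PPA estimate: sum over blocks of clipped area times block density."""
    index = _as_index(blocks, density_mode)
    if isinstance(blocks, BlockIndex) and blocks.density_mode != density_mode:
        index = BlockIndex(blocks.blocks, density_mode)
    pop = 0.0
    gq = False
    for b in index.query(area_polygon):
        a = polygon_area(clip(area_polygon, b.geometry))
        if a > 0:
            pop += a * index.density[b.block_id]
            gq = gq or b.group_quarters_population > 0
    return AllocationResult(
        well_id=well_id or "AREA", method="ppa", population=pop, gq_warning=gq
    )


def universe_totals(
    areas: Sequence[WellArea],
    blocks: Sequence[CensusBlock] | BlockIndex,
    rhus: Sequence[ResidentialHousingUnit],
    method: str,
    cap_mode: str = "scale",
    density_mode: str = "total",
    rhu_totals: Mapping[str, int] | None = None,
) -> AllocationResult:
    """Dissolved-union total over a set of well-areas (no double counting).

    PPA runs on the dissolved union of the buffer polygons; ABODE counts
    each RHU at most once across the union (an RHU within reach of several
    wells contributes a single household).
    """
    if not areas:
        raise ValueError("universe_totals requires at least one well-area")
    index = _as_index(blocks, density_mode)
    if method == "ppa":
        merged = dissolve([a.polygon for a in areas])
        pop = 0.0
        gq = False
        for component in merged:
            res = ppa_population(component, index, density_mode)
            pop += res.population
            gq = gq or res.gq_warning
        return AllocationResult("UNIVERSE", "ppa", pop, gq_warning=gq)

    if method not in ("abode_capped", "abode_uncapped"):
        raise ValueError(f"unknown method {method!r}")
    capped = method == "abode_capped"
    if capped and rhu_totals is None:
        rhu_totals = block_rhu_totals(rhus)
    centers = np.array([a.center for a in areas])
    radii = np.array([a.radius for a in areas])
    counts: Counter[str] = Counter()
    for r in rhus:
        if r.block_id is None:
            continue
        d2 = (centers[:, 0] - r.point.x) ** 2 + (centers[:, 1] - r.point.y) ** 2
        if np.any(d2 <= radii * radii):
            counts[r.block_id] += 1
    pop = 0.0
    for block_id, n in counts.items():
        block = index.by_id[block_id]
        pph = index.pph[block_id]
        if not capped:
            pop += n * pph
        elif cap_mode == "scale":
            pop += n * block_cap_factor(block, rhu_totals.get(block_id, 0)) * pph
        elif cap_mode == "hard":
            pop += min(n, block.housing_units) * pph
        else:
            raise ValueError(f"unknown cap_mode {cap_mode!r}")
    gq = any(
        index.by_id[b].group_quarters_population > 0
        for a in areas
        for b, _ in a.intersections
    )
    return AllocationResult(
        "UNIVERSE", method, pop, rhu_count=sum(counts.values()), gq_warning=gq
    )


def classify_agreement(abode: float, ppa: float) -> str:
    """Agreement taxonomy between the two estimates for one area.

    ``fp_low`` / ``fp_high`` are PPA false positives — PPA predicts people
    (at most one / more than one) where no dwelling exists, so the true
    nighttime residential population is zero.  ``other`` (ABODE positive,
    PPA zero) closes the taxonomy.
    """
    if abode < 0 or ppa < 0:
        raise ValueError("estimates must be >= 0")
    if abode == 0 and ppa == 0:
        return "both_zero"
    if abode == 0 and ppa <= 1:
        return "fp_low"
    if abode == 0:
        return "fp_high"
    if ppa == 0:
        return "other"
    return "both_positive"


def setback_conflicts(
    wells: Sequence[Well],
    setback_rules: Mapping[str, float],
    rhus: Sequence[ResidentialHousingUnit],
    blocks: Sequence[CensusBlock] | BlockIndex,
    cap_mode: str = "scale",
    density_mode: str = "total",
    n_segments: int = 64,
) -> list[SetbackRecord]:
    """Per-well dwelling conflicts within the state's regulated setback.

    ``setback_rules`` maps state code to setback distance in feet.  A well
    in a state without a rule is skipped with a warning (e.g. California has
    no building setback rule).  The distance test is boundary-inclusive.
    """
    for state, ft in setback_rules.items():
        if ft <= 0:
            raise ValueError(f"setback for {state} must be > 0 ft, got {ft}")
    index = _as_index(blocks, density_mode)
    rhu_totals = block_rhu_totals(rhus)
    out: list[SetbackRecord] = []
    skipped: Counter[str] = Counter()
    for w in wells:
        if w.state not in setback_rules:
            skipped[w.state or "?"] += 1
            continue
        ft = setback_rules[w.state]
        radius = ft * FOOT_M
        area = build_well_area(w, radius, index, n_segments)
        capped = abode_population(area, index, rhus, True, cap_mode, rhu_totals)
        uncapped = abode_population(area, index, rhus, False)
        ppa = ppa_population(area.polygon, index, density_mode, w.well_id)
        out.append(
            SetbackRecord(
                well_id=w.well_id,
                state=w.state,
                facility_id=w.facility_id,
                setback_ft=ft,
                n_conflict_rhus=uncapped.rhu_count or 0,
                abode_capped=capped.population,
                abode_uncapped=uncapped.population,
                ppa=ppa.population,
            )
        )
    for state, n in skipped.items():
        log.warning("setback_conflicts: no setback rule for state %s; %d wells skipped", state, n)
    return out
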