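"""Residential housing unit (RHU) construction from candidate points.

Candidate address points and building centroids are turned into RHUs in
three steps: dasymetric censoring against the land-use grid (drop points in
commercial / industrial / institutional cells), optional removal of points
that a visual verification flagged as uninhabitable, and assignment of each
surviving point to the census block that contains it.

Duplicate coordinates are deliberately permitted for address-sourced points:
a multi-unit building (apartment complex) is represented by one address
point per unit.  For building centroids, where duplication is an artefact of
the source rather than a unit count, exact duplicates can be collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.strtree import STRtree

from .census import CensusBlock
from .geometry import Frame, GeoPoint
from .landuse import LandUseGrid

__all__ = [
    "CandidateLocation",
    "ResidentialHousingUnit",
    "censor_nonresidential",
    "apply_verification",
    "assign_block",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateLocation:
    """A candidate dwelling point before censoring."""

    candidate_id: str
    point: GeoPoint
    source: str = "address"  # address | building_centroid | manual
    verified_removed: bool = False
    location_type: str | None = None  # optional annotation, no behaviour


@dataclass(frozen=True)
class ResidentialHousingUnit:
    """An accepted dwelling point; ``block_id`` is None until assignment."""

    rhu_id: str
    point: GeoPoint
    source: str = "address"
    block_id: str | None = None


def censor_nonresidential(
    candidates: Sequence[CandidateLocation],
    grid: LandUseGrid,
    keep_unknown: bool = True,
    dedupe_building_centroids: bool = False,
) -> list[ResidentialHousingUnit]:
    """Dasymetric censoring: drop candidates in non-habitable land-use cells.

    Points whose grid cell class is in ``grid.excluded_classes`` are removed;
    off-grid points are retained unless ``keep_unknown`` is False.  Duplicate
    coordinates survive (multi-unit buildings), except that exact duplicates
    among building-centroid candidates are collapsed when
    ``dedupe_building_centroids`` is set.
    """
    out: list[ResidentialHousingUnit] = []
    seen_centroids: set[tuple[float, float]] = set()
    n_censored = 0
    n_deduped = 0
    for c in candidates:
        if c.point.frame is not Frame.PLANAR:
            raise ValueError(f"candidate {c.candidate_id}: point must be planar")
        if grid.is_excluded(c.point.x, c.point.y, keep_unknown=keep_unknown):
            n_censored += 1
            continue
        if dedupe_building_centroids and c.source == "building_centroid":
            key = (c.point.x, c.point.y)
            if key in seen_centroids:
                n_deduped += 1
                continue
            seen_centroids.add(key)
        out.append(ResidentialHousingUnit(c.candidate_id, c.point, c.source))
    log.info(
        "censor_nonresidential: %d candidates -> %d RHUs (%d censored, %d deduped)",
        len(candidates),
        len(out),
        n_censored,
        n_deduped,
    )
    return out


def apply_verification(
    rhus: Sequence[ResidentialHousingUnit], removal_ids: Sequence[str]
) -> list[ResidentialHousingUnit]:
    """Remove RHUs flagged by visual verification; additions are impossible.

    Every id in ``removal_ids`` must name an existing RHU.
    """
    removals = set(removal_ids)
    existing = {r.rhu_id for r in rhus}
    unknown = removals - existing
    if unknown:
        raise KeyError(f"removal ids not present: {sorted(unknown)[:5]}")
    kept = [r for r in rhus if r.rhu_id not in removals]
    log.info("apply_verification: removed %d of %d RHUs", len(removals), len(rhus))
    return kept


def assign_block(
    rhus: Sequence[ResidentialHousingUnit], blocks: Sequence[CensusBlock]
) -> list[ResidentialHousingUnit]:
    """Assign each RHU to the census block containing it (boundary-inclusive).

    A point on a shared boundary belongs to the block with the
    lexicographically smallest ``block_id`` (stable tie-break).  RHUs covered
    by no block keep ``block_id=None``; allocation ignores them.
    """
    if not rhus:
        return []
    tree = STRtree([b.geometry for b in blocks])
    pts = shapely.points([(r.point.x, r.point.y) for r in rhus])
    out: list[ResidentialHousingUnit] = []
    n_unassigned = 0
    # covered-by predicate is boundary-inclusive: matches contains() convention
    pairs = tree.query(pts, predicate="covered_by")
    hits: dict[int, list[str]] = {}
    for pi, bi in zip(*pairs):
        hits.setdefault(int(pi), []).append(blocks[int(bi)].block_id)
    for i, r in enumerate(rhus):
        ids = hits.get(i)
        if not ids:
            n_unassigned += 1
            out.append(replace(r, block_id=None))
        else:
            out.append(replace(r, block_id=min(ids)))
    if n_unassigned:
        log.warning("assign_block: %d RHUs outside all blocks (unassigned)", n_unassigned)
    return out
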