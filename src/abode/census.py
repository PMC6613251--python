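"""Census block data model: persons-per-household and population density.

A census block is the smallest aggregation polygon carrying a total
population, a group-quarters population (institutional residents: prisons,
dormitories), and a housing-unit count.  Two derived quantities drive the
allocation methods:

* ``pph`` — persons per household: household population (total minus group
  quarters) divided by housing units.  ABODE assigns this to each dwelling
  anchored in the block.
* population density — persons per square metre of block area.  PPA
  multiplies it by intersection areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

from shapely.geometry import MultiPolygon, Polygon

from .geometry import polygon_area

__all__ = ["CensusBlock", "Pph", "compute_pph", "population_density"]

log = logging.getLogger(__name__)


class Pph(NamedTuple):
    """Persons-per-household with a flag for the zero-housing-unit case."""

    value: float
    degenerate: bool = False


@dataclass
class CensusBlock:
    """One census block polygon with its population and housing counts.

    ``pph_override``, when given, mirrors the published "average household
    size" table value and takes precedence over the derived ratio.
    """

    block_id: str
    geometry: Polygon | MultiPolygon
    total_population: float
    group_quarters_population: float = 0.0
    housing_units: int = 0
    pph_override: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.total_population < 0 or self.housing_units < 0:
            raise ValueError(f"block {self.block_id}: negative counts")
        if self.group_quarters_population < 0:
            raise ValueError(f"block {self.block_id}: negative group quarters")
        if self.group_quarters_population > self.total_population:
            raise ValueError(
                f"block {self.block_id}: group quarters "
                f"({self.group_quarters_population}) exceed total population "
                f"({self.total_population})"
            )

    @property
    def household_population(self) -> float:
        return self.total_population - self.group_quarters_population

    @property
    def area_m2(self) -> float:
        return polygon_area(self.geometry)


def compute_pph(block: CensusBlock) -> Pph:
    """Average persons per household of a block.

    Defined as household population / housing units.  A block with zero
    housing units yields 0.0 with ``degenerate=True``: any dwelling point
    mistakenly located there contributes no population.
    """
    if block.pph_override is not None:
        return Pph(float(block.pph_override), False)
    if block.housing_units == 0:
        if block.household_population > 0:
            log.warning(
                "block %s has population %s but zero housing units; pph set to 0",
                block.block_id,
                block.household_population,
            )
        return Pph(0.0, True)
    return Pph(block.household_population / block.housing_units, False)


def population_density(block: CensusBlock, mode: str = "total") -> float:
    """Block population density in persons per square metre.

    ``mode="total"`` (default) uses the full census population, matching the
    standard census density that areal weighting normally consumes;
    ``mode="household"`` excludes group quarters, for symmetry with ABODE.
    """
    area = block.area_m2
    if area <= 0:
        raise ValueError(f"block {block.block_id}: zero-area geometry")
    if mode == "total":
        pop = block.total_population
    elif mode == "household":
        pop = block.household_population
    else:
        raise ValueError(f"unknown density mode {mode!r}")
    return pop / area
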