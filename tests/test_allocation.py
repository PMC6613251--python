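"""ABODE and PPA estimators, capping, universe totals, agreement, setbacks."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from abode.allocation import (
    BlockIndex,
    Well,
    WellArea,
    abode_population,
    block_cap_factor,
    block_rhu_totals,
    build_well_area,
    classify_agreement,
    ppa_population,
    rhus_in_area,
    setback_conflicts,
    universe_totals,
)
from abode.census import CensusBlock
from abode.geometry import FOOT_M, buffer_point, polygon_area
from abode.rhu import ResidentialHousingUnit
from abode.geometry import Frame, GeoPoint
from abode.synthetic import truth_population_circle

from conftest import monte_carlo_area


def rhu(rid, x, y, block="A"):
    return ResidentialHousingUnit(rid, GeoPoint(x, y, Frame.PLANAR), block_id=block)


def one_block(pop=10.0, gq=0.0, hu=4, side=10_000.0, bid="A"):
    return CensusBlock(bid, box(0, 0, side, side), pop, gq, hu)


def circle_area(cx, cy, r, blocks, well_id="w"):
    w = Well(well_id, cx, cy)
    return build_well_area(w, r, blocks)


class TestRhusInArea:
    def test_counts_grouped_by_block(self):
        area = circle_area(100, 100, 50, [one_block()])
        rhus = [rhu("1", 100, 100), rhu("2", 110, 90), rhu("3", 130, 100)]
        assert rhus_in_area(area, rhus) == {"A": 3}

    def test_boundary_point_counted(self):
        area = circle_area(0, 0, 50, [one_block()])
        assert rhus_in_area(area, [rhu("1", 50.0, 0.0)]) == {"A": 1}
        assert rhus_in_area(area, [rhu("1", 50.001, 0.0)]) == {}

    def test_unassigned_rhus_excluded(self):
        area = circle_area(100, 100, 50, [one_block()])
        assert rhus_in_area(area, [rhu("1", 100, 100, block=None)]) == {}

    def test_agreement_with_distance_oracle(self, uniform_prepared):
        rhus, index = uniform_prepared
        rng = np.random.default_rng(23)
        pts = np.array([(r.point.x, r.point.y) for r in rhus if r.block_id])
        assigned = [r for r in rhus if r.block_id]
        for _ in range(200):
            cx, cy = rng.uniform(0, 3000, 2)
            r = rng.uniform(50, 400)
            area = WellArea("w", (cx, cy), r, buffer_point((cx, cy), r))
            counts = rhus_in_area(area, assigned)
            d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
            assert sum(counts.values()) == int(np.sum(d2 <= r * r))


class TestCapFactor:
    @pytest.mark.parametrize(
        "hu,total,expected", [(5, 10, 0.5), (10, 7, 1.0), (0, 3, 0.0), (4, 0, 1.0)]
    )
    def test_scaling_rule(self, hu, total, expected):
        assert block_cap_factor(one_block(hu=hu), total) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            block_cap_factor(one_block(), -1)


class TestAbode:
    def test_single_block_uncapped(self):
        blocks = [one_block(pop=10, hu=4)]  # pph 2.5
        area = circle_area(100, 100, 60, blocks)
        rhus = [rhu(str(i), 100 + 5 * i, 100) for i in range(4)]
        res = abode_population(area, blocks, rhus, capped=False)
        assert res.population == pytest.approx(10.0)
        assert res.rhu_count == 4

    def test_two_blocks_uncapped(self):
        b1 = one_block(pop=10, hu=4, bid="A")  # pph 2.5
        b2 = CensusBlock("B", box(10_000, 0, 20_000, 10_000), 9, 0, 3)  # pph 3.0
        area = WellArea("w", (10_000, 100), 500, buffer_point((10_000, 100), 500))
        rhus = [rhu("1", 9990, 100), rhu("2", 9980, 100), rhu("3", 9970, 100)] + [
            rhu("4", 10_010, 100, "B"),
            rhu("5", 10_020, 100, "B"),
        ]
        res = abode_population(area, [b1, b2], rhus, capped=False)
        assert res.population == pytest.approx(3 * 2.5 + 2 * 3.0)

    def test_block_cap_scales_contribution(self):
        # pph 2, 5 census units but 10 block-wide RHUs -> factor 0.5
        blocks = [one_block(pop=10, hu=5)]
        area = circle_area(100, 100, 100, blocks)
        in_area = [rhu(str(i), 100 + i, 100) for i in range(4)]
        elsewhere = [rhu(f"e{i}", 5000, 5000) for i in range(6)]
        rhus = in_area + elsewhere
        capped = abode_population(area, blocks, rhus, capped=True)
        uncapped = abode_population(area, blocks, rhus, capped=False)
        assert uncapped.population == pytest.approx(8.0)
        assert capped.population == pytest.approx(4.0)

    def test_hard_cap_mode_truncates_per_area(self):
        blocks = [one_block(pop=10, hu=2)]  # pph 5
        area = circle_area(100, 100, 100, blocks)
        rhus = [rhu(str(i), 100 + i, 100) for i in range(4)]
        res = abode_population(area, blocks, rhus, capped=True, cap_mode="hard")
        assert res.population == pytest.approx(2 * 5.0)

    def test_zero_rhus_zero_population(self):
        blocks = [one_block(pop=1000, hu=10)]
        area = circle_area(100, 100, 50, blocks)
        res = abode_population(area, blocks, [], capped=False)
        assert res.population == 0.0 and res.rhu_count == 0

    def test_group_quarters_warning(self):
        blocks = [one_block(pop=10, gq=3, hu=4)]
        area = circle_area(100, 100, 50, blocks)
        assert abode_population(area, blocks, [], capped=False).gq_warning


class TestPpa:
    def test_circle_inside_one_block_closed_form(self):
        blocks = [one_block(pop=10_000.0, hu=100, side=10_000.0)]  # density 1e-4
        poly = buffer_point((5000, 5000), 200.0, 64)
        res = ppa_population(poly, blocks)
        assert res.population == pytest.approx(1e-4 * polygon_area(poly), rel=1e-9)
        assert res.population == pytest.approx(12.566, rel=0.005)

    def test_half_block_by_symmetry(self):
        blocks = [CensusBlock("A", box(0, 0, 1000, 1000), 100, 0, 10)]
        left = box(0, 0, 500, 1000)
        assert ppa_population(left, blocks).population == pytest.approx(50.0)

    def test_area_outside_all_blocks(self):
        blocks = [one_block()]
        poly = box(50_000, 50_000, 51_000, 51_000)
        assert ppa_population(poly, blocks).population == 0.0

    def test_matches_monte_carlo_oracle(self, uniform_region, uniform_prepared):
        # sum over blocks of density x (MC-estimated clip area), >=1e6 samples
        _, index = uniform_prepared
        poly = buffer_point((1480.0, 1520.0), 420.0, 64)
        expected = 0.0
        for b in index.query(poly):
            inter = poly.intersection(b.geometry)
            if not inter.is_empty:
                expected += index.density[b.block_id] * monte_carlo_area(
                    inter, n=1_000_000, seed=29
                )
        got = ppa_population(poly, index).population
        assert got == pytest.approx(expected, rel=0.01)

    def test_full_block_conservation(self, uniform_region):
        # PPA over a block's own geometry returns its census population
        for b in uniform_region.blocks[:20]:
            res = ppa_population(b.geometry, [b])
            assert res.population == pytest.approx(b.total_population, rel=1e-6)

    def test_household_density_mode(self):
        blocks = [CensusBlock("A", box(0, 0, 1000, 1000), 100, 40, 10)]
        res = ppa_population(box(0, 0, 1000, 1000), blocks, density_mode="household")
        assert res.population == pytest.approx(60.0)


class TestMonotonicityAndOrdering:
    def test_both_estimators_nondecreasing_in_radius(self, uniform_prepared):
        rhus, index = uniform_prepared
        rng = np.random.default_rng(31)
        for _ in range(10):
            cx, cy = rng.uniform(500, 2500, 2)
            prev_a = prev_p = -1.0
            for radius in (50, 100, 200, 400, 800):
                area = build_well_area(Well("w", cx, cy), radius, index)
                a = abode_population(area, index, rhus, capped=False).population
                p = ppa_population(area.polygon, index).population
                assert a >= prev_a - 1e-9 and p >= prev_p - 1e-9
                prev_a, prev_p = a, p

    def test_capped_never_exceeds_uncapped(self, uniform_prepared):
        rhus, index = uniform_prepared
        totals = block_rhu_totals(rhus)
        rng = np.random.default_rng(37)
        for _ in range(50):
            cx, cy = rng.uniform(0, 3000, 2)
            area = build_well_area(Well("w", cx, cy), rng.uniform(50, 500), index)
            cap = abode_population(area, index, rhus, True, rhu_totals=totals)
            unc = abode_population(area, index, rhus, False)
            assert cap.population <= unc.population + 1e-9


class TestUniverse:
    def setup_scene(self):
        blocks = [one_block(pop=100, hu=50, side=10_000)]  # pph 2
        rhus = [rhu(str(i), 1000 + 10 * i, 1000) for i in range(5)]
        return blocks, rhus

    def test_disjoint_wells_sum(self):
        blocks, rhus = self.setup_scene()
        a1 = circle_area(1020, 1000, 200, blocks, "w1")
        a2 = circle_area(8000, 8000, 200, blocks, "w2")
        uni = universe_totals([a1, a2], blocks, rhus, "abode_uncapped")
        per = [abode_population(a, blocks, rhus, False) for a in (a1, a2)]
        assert uni.population == pytest.approx(sum(p.population for p in per))

    def test_coincident_wells_count_once(self):
        blocks, rhus = self.setup_scene()
        a1 = circle_area(1020, 1000, 200, blocks, "w1")
        a2 = circle_area(1020, 1000, 200, blocks, "w2")
        uni = universe_totals([a1, a2], blocks, rhus, "abode_uncapped")
        single = abode_population(a1, blocks, rhus, False)
        assert uni.population == pytest.approx(single.population)
        uni_ppa = universe_totals([a1, a2], blocks, rhus, "ppa")
        single_ppa = ppa_population(a1.polygon, blocks)
        assert uni_ppa.population == pytest.approx(single_ppa.population)

    def test_shared_rhu_counted_once(self):
        blocks, _ = self.setup_scene()
        shared = [rhu("s", 1000, 1000)]
        a1 = circle_area(950, 1000, 100, blocks, "w1")
        a2 = circle_area(1050, 1000, 100, blocks, "w2")
        uni = universe_totals([a1, a2], blocks, shared, "abode_uncapped")
        assert uni.rhu_count == 1
        assert uni.population == pytest.approx(2.0)  # one household at pph 2

    def test_dissolved_ppa_at_most_sum_of_per_well(self, uniform_prepared):
        rhus, index = uniform_prepared
        rng = np.random.default_rng(41)
        areas = [
            build_well_area(Well(f"w{i}", *rng.uniform(500, 2500, 2)), 300, index)
            for i in range(8)
        ]
        uni = universe_totals(areas, index, rhus, "ppa")
        per = sum(ppa_population(a.polygon, index).population for a in areas)
        assert uni.population <= per + 1e-9


class TestAgreement:
    @pytest.mark.parametrize(
        "a,p,expected",
        [
            (0, 0, "both_zero"),
            (0, 0.4, "fp_low"),
            (0, 1.0, "fp_low"),
            (0, 1.5, "fp_high"),
            (5, 3, "both_positive"),
            (2, 0, "other"),
        ],
    )
    def test_taxonomy(self, a, p, expected):
        assert classify_agreement(a, p) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_agreement(-1, 0)


class TestSetbacks:
    def test_exact_distance_is_conflict(self):
        blocks = [one_block(pop=100, hu=50)]
        wells = [Well("w", 1000, 1000, state="PA")]
        rules = {"PA": 200.0}  # 200 ft = 60.96 m
        at_60 = [rhu("a", 1060.0, 1000.0)]
        at_61 = [rhu("a", 1061.0, 1000.0)]
        rec60 = setback_conflicts(wells, rules, at_60, blocks)[0]
        rec61 = setback_conflicts(wells, rules, at_61, blocks)[0]
        assert rec60.n_conflict_rhus == 1
        assert rec61.n_conflict_rhus == 0
        assert rec60.setback_ft * FOOT_M == pytest.approx(60.96)

    def test_missing_state_rule_skipped(self, caplog):
        blocks = [one_block()]
        wells = [Well("w1", 1000, 1000, state="CA"), Well("w2", 1000, 1000, state="PA")]
        records = setback_conflicts(wells, {"PA": 200.0}, [], blocks)
        assert [r.well_id for r in records] == ["w2"]

    def test_counts_match_distance_filter(self, uniform_prepared, uniform_region):
        rhus, index = uniform_prepared
        assigned = [r for r in rhus if r.block_id]
        pts = np.array([(r.point.x, r.point.y) for r in assigned])
        rules = {"SYN": 200.0}
        records = setback_conflicts(uniform_region.wells[:40], rules, assigned, index)
        radius = 200.0 * FOOT_M
        for rec, w in zip(records, uniform_region.wells[:40]):
            d2 = (pts[:, 0] - w.x) ** 2 + (pts[:, 1] - w.y) ** 2
            assert rec.n_conflict_rhus == int(np.sum(d2 <= radius * radius))
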