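# Methods

## Estimators

**ABODE.** For a hazard area *j* (a radial buffer around a well), count the
residential housing units of each census block *i* that lie inside the area
(`RHU_ij`, boundary-inclusive) and allocate each block's average household
size to each unit:

    Pop_j = Σ_i RHU_ij · f_i · pph_i ,
    pph_i = (total_population_i − group_quarters_i) / housing_units_i .

Uncapped, `f_i = 1`. Capped, the default `f_i = min(1, HU_i / RHU_i^block)`
scales every block's counted units by a block-wide factor so that the units
counted across the block's whole extent never exceed the census housing-unit
count. The cap is applied as a multiplicative block-level factor rather than
a per-area truncation because the excess-unit problem (address
misclassification, post-census growth) is a block-level property; scaling
preserves the intra-block spatial pattern of dwellings, which is the whole
point of the method. A per-area truncation `min(RHU_ij, HU_i)` is available
as `cap_mode="hard"`. A block with zero census housing units has `pph = 0`
(flagged degenerate), so stray units located there contribute nothing.

Neither estimator allocates group-quarters populations (prisons, dorms);
results carry a `gq_warning` whenever an intersected block has group
quarters, rather than imputing.

**PPA.** Areal weighting: `Pop_j = Σ_i area(clip(j, block_i)) · d_i` with
`d_i` the block's population density. By default `d_i` uses the total census
population (including group quarters), matching the standard census density
that areal-weighting workflows consume; `ppa_density="household"` excludes
group quarters for symmetry with ABODE.

**Universe totals.** State and overall totals dissolve the buffer polygons
into a disjoint union before PPA, and count each RHU at most once across all
buffers for ABODE, so overlapping well-areas never double-count.

**Agreement taxonomy.** Per area: `both_zero`, `both_positive`, `fp_low`
(ABODE 0, 0 < PPA ≤ 1), `fp_high` (ABODE 0, PPA > 1), and `other` (ABODE
positive, PPA 0 — possible only when an RHU-bearing area has zero
geometric overlap contribution, e.g. off-block units; included so the five
categories partition all cases). The `fp_*` classes are confirmable false
positives: PPA predicts residents where no dwelling exists.

## Geometry

All computation is planar, in metres. Input lon/lat is projected with a
Lambert azimuthal equal-area projection on the authalic sphere
(R = 6 371 007.18 m), centred by default on the data's bounding-box centre.
Equal-area is required because PPA weights by area; an azimuthal projection
centred on the data keeps local distances length-true to well under 0.5%
within 300 km of the centre (the radial scale error is ~c²/24 for angular
distance c, about 9·10⁻⁵ at 300 km), so 200 m buffers are effectively exact.
Analyses of the same data under a different projection will differ at the
sub-percent level; such differences are expected and irreducible.

Circles are inscribed regular polygons (default 64 vertices), which
understate πr² by sin(t)/t, t = π/64 — a ≤ 0.2% area deficit on the PPA
side. The ABODE side never uses the polygon: membership of a dwelling in a
circular area is the exact Euclidean test |p − c| ≤ r, so a dwelling exactly
at the radius (or the setback distance) counts. Boundary-inclusive
("closed region") conventions are used throughout — for containment, block
assignment, and setbacks — the precautionary choice when overestimating PAR
is preferable to underestimating. Points on a shared block boundary are
assigned to the lexicographically smallest block id (deterministic
tie-break).

Unit conversions are exact: 1 ft = 0.3048 m, 1 mi² = 2 589 988.110336 m².

## RHU construction

Candidate points (address points, building centroids, manual entries) pass
through three stages:

1. **Dasymetric censoring.** The land-use grid (30 m cells, half-open
   `[x0+j·s, x0+(j+1)·s)` so every in-extent point maps to exactly one cell)
   removes candidates in excluded classes (built-up commercial / industrial
   / institutional; the class list is configuration, not logic). Off-grid
   points are retained by default (`keep_unknown`), again precautionary.
   Duplicate coordinates are distinct units — multi-unit buildings are
   represented by one address point per unit. For building-centroid sources,
   where duplication is a data artefact rather than a unit count, exact
   duplicates can be collapsed (`dedupe_building_centroids`).
2. **Verification removals.** A removal list (ids flagged by visual
   inspection as uninhabitable) only ever shrinks the set; additions are
   impossible by construction.
3. **Block assignment** via an STRtree spatial join, boundary-inclusive with
   the lexicographic tie-break; units covered by no block are excluded from
   allocation.

## Metrics

* FAC2: fraction of pairs with 0.5 ≤ predicted/observed ≤ 2.0, closed on
  both ends; observed-zero pairs excluded and counted.
* MAPE: zero *predictions* are removed by definition of the comparison, and
  zero *observations* must also be removed (division guard); both exclusion
  counts are reported so the rule is visible.
* Spearman ρ via mid-ranks (scipy). Zero-census blocks are included in the
  correlation by default (only MAPE/FAC2 have exclusion rules).
* Fractional bias: `FB = (1/n)·Σ(a−b)/Σ((a+b)/2)` — note the leading 1/n,
  which deliberately departs from the conventional normalised mean bias to
  match the reference tables this package aggregates; `standard=True` drops
  it. Antisymmetric under swapping the series.
* Wilcoxon signed-rank: differences a − b, zero differences dropped
  (Wilcoxon's original rule; Pratt available), mid-ranks of |d|, and
  `z = (W⁺ − Σr/2 ∓ ½) / sqrt(Σr²/4)` — the Σr²/4 variance incorporates the
  tie correction automatically, and the ±½ continuity correction keeps the
  normal approximation within 0.02 of the exact p down to n = 10. With ≤ 12
  nonzero differences the p-value comes from exhaustive 2ⁿ sign-flip
  enumeration (exact even under ties; the null distribution of W⁺ is
  symmetric about Σr/2 because flipping all signs maps W⁺ to Σr − W⁺).

## Synthetic regions

The generator emulates the features the estimators are sensitive to, with
one seeded `numpy` Generator and a fixed draw order (node jitter → unit
counts → group quarters → commercial cells → per-block placement and
household sizes → multi-unit duplication → contaminants → wells), so output
is bit-reproducible.

* **Blocks**: an `nx × ny` lattice of nominally `block_size` = 500 m squares
  whose interior nodes are jittered (±15% of the block size); sharing the
  node lattice guarantees a gap- and overlap-free tiling.
* **Housing units** per block: negative binomial (mean 40, dispersion 3),
  giving the strong across-block overdispersion of real block data.
* **Household sizes**: normal (mean 2.5 — the U.S. average household size —
  sd 1.2) truncated below at 1 by resampling. Block population = Σ household
  sizes (+ group quarters), kept real-valued so conservation identities are
  exact.
* **Group quarters**: 2% of blocks receive a Poisson(40) institutional
  population, exercising the gq warning path.
* **Placement**: `uniform` within the block, or `boundary_clustered` within
  40 m of the block edges — the roadway pattern under which areal weighting
  systematically misallocates. Unit points avoid commercial cells so the
  census unit count stays consistent with the surviving candidates.
* **Multi-unit buildings**: each unit after the first reuses an earlier
  unit's coordinates with probability 5%.
* **Contaminants**: non-residential points (zero persons in truth) equal to
  5% of the unit count, placed in the 8% of 30 m land-use cells marked
  commercial; dasymetric censoring is expected to remove them.
* **Wells**: 200 by default, placed uniformly (or near boundaries to stress
  the failure mode), grouped ten per facility, all in one synthetic state.

`truth` records exact persons per candidate point, so
`truth_population(_circle)` is an exact oracle for any query region.

What the generator does **not** emulate: real TIGER block shapes, road
networks, spatially correlated land use, address-data temporal misalignment,
or geocoding error. Tests passing on synthetic regions therefore validate
the estimators' arithmetic, geometry, and their relative behaviour under
boundary clustering — not the accuracy of any particular real-world address
dataset.

Default problem sizes (10×10 blocks, 200 wells for studies; 5×5–8×8 for unit
fixtures) keep any full run in seconds while leaving hundreds of wells for
the paired comparisons; all sizes scale through `ScenarioConfig`.

## Reference tables

Small state-level reference summaries for active underground gas storage
wells in six U.S. states (200 m well-areas; state setbacks of 100–300 ft)
ship as CSVs. The reporting module re-derives their totals, percentages and
ranked-well differences by column arithmetic. One capped-ABODE total in the
source tables does not equal the sum of its state rows (48 126 stated vs
47 269 summed); the reporting path computes and reports column sums and
flags such inconsistencies instead of reproducing them. The stated
percentage column has similar rounding inconsistencies (e.g. a stated total
of 41% where the counts give 39%); computed percentages always derive from
the counts.

## Numerical and degenerate-case choices

* Tolerances: PPA conservation to 1e-6 relative; Monte-Carlo cross-checks at
  1% with ≥10⁶ samples; exact-arithmetic identities asserted to 1e-9.
* Metrics with no usable pairs return NaN with `defined=False` rather than
  raising, so report tables stay writable.
* `dissolve` of an empty list, nonpositive buffer radii, unclosed rings,
  invalid polygons, unknown removal ids, and group quarters exceeding total
  population are rejected with explicit errors.
* The land-use ASCII grid is tied to the planar frame it was produced in;
  `write_region` therefore emits a `run.ini` pinning the matching projection
  centre, and mixed-frame runs are a documented user error.

## Known limitations

* The setback table reports conflicts for wells whose state has a rule;
  stateless wells are skipped with a warning, not imputed.
* Capped ABODE under `cap_mode="scale"` can exceed a block's census
  population in a *sub*-area if units cluster there (the cap is block-level
  by design); `cap_mode="hard"` bounds each area individually.
* The Wilcoxon exact path is O(2ⁿ) and is only used for n ≤ 12.
* GeoJSON input is assumed WGS84; no CRS negotiation is attempted.
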