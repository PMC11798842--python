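# Methods

This note records the models implemented in `surrosai`, the choices made
where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Landscape model

All computation runs on a planar `n_rows × n_cols` grid with row-major
integer cell ids, standing in for a 0.5° latitude–longitude raster.
No equal-area weighting is applied: a lat–lon grid is itself not
equal-area, and all statistics here are in cell counts. Species ranges
are binary incidence rows of a sparse species × cell matrix; richness is
the per-cell count of overlapping ranges. Range features carry the IUCN
mapping-standard attribute codes, restricted on ingest to presence
{1, 2, 4}, origin {1, 2, 6} and seasonality {1, 2, 3, 4}; anything else
(e.g. presence 5, extinct range) is rejected rather than silently
dropped, so filter behaviour is auditable. Richness maps union presence
{1, 2, 4}; surrogacy matrices drop possibly-extinct ranges (presence 4),
and a species left with no cells keeps an all-zero row and a flag so
downstream denominators can account for it.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes,
not the geography of any real dataset.

- **Range sizes** are lognormal(μ, σ) in cells, rounded and clipped to
  [1, n_cells]. Defaults μ = 1.0, σ = 1.0 (median ≈ 3 cells, heavy right
  tail). The defaults target the regime the surrogacy analysis actually
  operates in — threatened species with restricted ranges, where roughly
  half the landscape's cells hold no target species (the real analyses
  report 44–52% of cells without threatened freshwater species). Larger
  μ saturates the grid: nearly every cell becomes occupied, richness
  correlations flatten, and the co-distribution knob loses leverage.
  The true empirical range-size distribution of a Red List dataset is
  not characterized here; nothing downstream depends on the exact form.
- **Contiguity.** Ranges grow as 4-connected blobs by seeded random
  breadth-first accretion from a uniformly drawn start cell, emulating
  catchment-based range polygons without GIS machinery. A scatter mode
  (i.i.d. cells) exists for experiments that need exchangeable
  placement.
- **Co-distribution.** The `overlap ∈ [−1, 1]` knob maps linearly to the
  probability that a new range's start cell is drawn from the base
  group's occupied footprint: with f the occupied fraction,
  p = f + overlap·(1−f) for overlap ≥ 0 and p = f·(1+overlap) below
  zero. overlap = 0 is exact independence; ±1 are the all-inside /
  all-outside limits. Blob growth itself is unconstrained, so overlap
  shifts where ranges start, not their shape.
- **Assessments.** Categories are i.i.d. multinomial draws; only CR
  records receive possibly-extinct(-in-the-wild) tags (defaults 19% and
  1% of CR, matching the reported one-fifth of CR species so tagged).
  The default category mixture puts 18% of species in CR/EN/VU as
  assessed and 23% in DD, so the best-estimate proportion threatened
  lands near one-quarter with bounds near 18–42%. Threat codes attach
  only to non-LC/NT species (threat coding concentrates on at-risk
  species); habitat codes attach to all.
- **Abiotic layers** blend the tie-averaged ranks of target richness
  with Gaussian noise. The blend weight is 2·sin(π·ρ/6) for requested
  Spearman ρ (the Gaussian grade-correlation inverse), giving realized
  rank correlations within ±0.1 of the request at ≥2,500 cells despite
  the heavy ties among zero-richness cells; ±1 are noise-free and exact.
  Cells go missing independently at the configured rate (default 12%,
  the coverage gap of a global water-stress raster).

## Prioritization

Both rules are backward greedy elimination with dynamic remaining ranges
Q_j, read in reverse as a best-first ranking. Dynamic Q (rather than
static original range sizes) is what makes the ranking
complementarity-based; the static variant is available behind a flag for
sensitivity checks and changes results materially on landscapes with
strong range overlap. The ABF exponent is fixed at 1 (a pure sum of
remaining-range proportions); power transforms of representation are out
of scope. Ties in δ are broken uniformly at random from a named seed
stream; "iterations" of an algorithm are re-runs with different
tie-break seeds. Empty cells have δ = 0 and drop out first, so they sit
at the bottom of every ranking. The implementation updates δ only for
cells sharing a species with the removed cell; this is algebraically
identical to full recomputation, and the test suite pins it to an
independent naive reference implementation.

A caution recorded from the small-instance oracle experiments: greedy
marginal-loss rankings are *not* uniformly near-optimal in accumulation
area. On instances whose δ values tie heavily (duplicate cells,
singleton species), the tie lottery can leave the ranking below the top
decile of all orderings — CAZ especially, since its max rule is
indifferent to how many species a cell serves. Measured on random
4-species instances with 4–6 cells, CAZ falls below the decile on ~19%
of instances and ABF on ~2%. This is a property of the rules themselves
(verified against the naive reference), not of the implementation.

## Surrogacy estimation

Representation is coverage-of-one: a target species counts as included
once any of its occupied cells is selected, which makes the optimal
curve reach 1 whenever every species occupies at least one included
cell. Curve areas use the rectangle rule (mean of v_1..v_n on the
unit-normalized axis); the trapezoid alternative differs by O(1/n) and
is available via configuration.

`evaluate_surrogacy` runs n_runs (default 5) tie-break iterations of the
chosen algorithm on the targets (optimal) and on the surrogate, plus
n_random (default 100) uniform cell permutations. Optimal and surrogate
runs share seeds, so a surrogate identical to the targets reproduces the
optimal curves run-for-run and the SAI median is exactly 1 — the
self-surrogacy anchor. The confidence interval pairs each surrogate-run
area with each random-run area, holding o at its run median, and takes
the median and 2.5/97.5 percentiles over the n_runs × n_random SAI
samples; pairing o per run instead is available behind a flag. For an
abiotic surrogate the landscape is first restricted to non-missing cells
for all three curve families, and target species confined to excluded
cells are dropped from every denominator with a warning.

Degenerate cases are errors, not silent defaults: o = r makes the SAI
undefined, as does a landscape whose median optimal area equals the
median random area.

## What the synthetic experiments show — and don't

- Self-surrogacy = 1 and the monotone SAI response to the overlap knob
  validate the machinery, not any claim about real taxa.
- The zero-overlap null (SAI CI straddling 0) is exact only under
  exchangeable (scatter) placement. With contiguous ranges, *any*
  spatially smooth target-independent ordering is systematically worse
  than uniform random: a blob's cells have correlated ranks under a
  smooth ordering, so its earliest cell arrives later than the minimum
  of independent uniform ranks. This is the same mechanism that drives
  environmental-layer surrogates below random, and it means contiguous
  independent surrogates legitimately score slightly negative. A
  genuinely uninformative surrogate ordering (constant layer, hence pure
  random permutations) straddles 0 regardless of target structure.
- Synthetic landscapes lack latitudinal richness gradients, coastlines,
  realistic river networks and range-size/threat correlations; SAI
  magnitudes here are not comparable to published values for real taxa.

## Numerical conventions

- Coverage percentages round half-up to integers; headline proportions
  are reported to one decimal as percentages.
- Chi-squared comparisons are Pearson 2×2 without continuity correction
  (configurable); degenerate tables (a zero row or column total) are
  errors.
- All randomness flows from `numpy.random.default_rng` seeded via a
  master seed plus stable named streams (CRC32 of the stream name mixed
  into a `SeedSequence`), so every stage is independently reproducible
  and derived seeds stay below 2³¹.
- Problem sizes: the standard synthetic study uses a 30 × 30 grid with
  200 species per group, 5 prioritization iterations and 100 random
  sequences; the whole analysis chain completes in seconds, and the
  small-instance oracles enumerate all orderings of up to 6 cells.
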