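# Methods

## The statistic

For one spatial unit (a state, a city, or a whole synthetic grid) with `n`
valid cells and exposure values `x_j`, the local Getis-Ord Gi\* score of cell
`i` is

```
Gi* = [ Σ_j w_ij x_j − X̄ Σ_j w_ij ] / ( S · sqrt( [ n Σ_j w_ij² − (Σ_j w_ij)² ] / (n−1) ) )
X̄ = Σ_j x_j / n        S = sqrt( Σ_j x_j² / n − X̄² )
```

where the sums run over **all** cells of the unit and `w_ij` are binary queen
weights: 1 if cells i and j share an edge or corner, else 0, with `w_ii = 1`
by default.  Self-inclusion is what makes the statistic the *star* variant;
it is exposed as a flag (`include_self`) because contiguity descriptions in
the literature often mention only border-sharing neighbors, but Gi\* is only
Gi\* with the focal cell included.  `S` is the population (divide-by-n)
standard deviation; the same convention is used for every SD the package
reports, so summary SDs and the denominator of the statistic agree.

Interpretation: Gi\* is a z-like score for the weighted neighborhood sum.
Positive values mean cell plus neighbors jointly exceed the unit mean.  Both
the numerator and `S` scale linearly under `x → a + b·x` (b > 0), so scores,
p-values and all downstream labels are affine-invariant — the analysis does
not care about the exposure unit's origin or scale.

Degenerate cases are flagged, never silently dropped: a constant field
(`S = 0`) makes every cell degenerate, and a cell whose neighborhood covers
the whole unit (`Σ_j w_ij = n`, e.g. the center of a full 3×3 grid with
self-inclusion) zeroes the denominator radical.  Degenerate cells are
labeled `ns`.

## Permutation inference

Analytic Gaussian p-values are not used.  Significance comes from
**conditional randomization**: the focal value `x_i` is held fixed and, for
each of `nsim` simulations, the values of i's neighborhood are replaced by a
without-replacement sample from the remaining `n − 1` cells; the statistic is
recomputed (only the neighborhood sum changes — `X̄`, `S` and the weights are
permutation-invariant, so comparing numerators is comparing scores).  The
one-sided pseudo p-value on the observed side is

```
p = (1 + #{sim: Gi*_sim ≥ Gi*_obs}) / (1 + nsim)     if Gi*_obs ≥ 0
p = (1 + #{sim: Gi*_sim ≤ Gi*_obs}) / (1 + nsim)     otherwise
```

With the default `nsim = 99`, every p is a multiple of 1/100, the smallest
attainable p is 0.01, and the strict rule `p < 0.05` admits p ∈
{0.01, …, 0.04} — hence an exact null hotspot rate of 4% per year, which the
calibration test verifies on an iid field.

Two design choices deserve emphasis:

* **Per-cell independent draws.**  Each cell's `nsim` samples are drawn
  independently (rejection sampling of duplicate indices makes every draw
  uniform over distinct k-tuples).  Sharing one permutation matrix across
  cells — a common implementation shortcut — correlates all cells' null
  draws within a simulation and inflates the variance of aggregate false
  positive rates; independence keeps the hotspot-count distribution close to
  binomial on exchangeable fields.
* **Seeding.**  A master seed spawns one sub-seed per year via
  `SeedSequence([master, year_index])`, so per-year results do not depend on
  execution order and any year can be recomputed in isolation.

No multiple-testing correction is applied across cells or years; the method
is a descriptive screen, and the downstream trend taxonomy (which requires
repeated flags) is itself a guard against one-off false positives.

## Trend taxonomy

The window splits into halves T1/T2 (for 12 years: years 1–6 vs 7–12).  With
hotspot-year counts (c1, c2):

| category | rule (6+6 window) | reading |
|---|---|---|
| consistent | c1 ≥ 5 and c2 ≥ 3 | almost always hot early, at least half late |
| declining | c1 ≥ 3 and c2 ≤ 2 | at least half early, at most a third late |
| emerging | c1 ≤ 3 and c2 ≥ 4 | at most half early, at least two thirds late |
| inconsistent | anything else | |

The three named rules are mutually exclusive (consistent vs emerging split on
c1; the other pairs split on c2) and with the fallback the map is total — the
test suite verifies this exhaustively over all 49 pairs.  For windows whose
halves are not 6 years, thresholds scale proportionally (5/6 and 3/6 of |T1|,
2/6 and 4/6 of |T2|), rounded half-up; they are also directly configurable.
Coldspot years simply count as non-hotspot years; no coldspot trend classes
are defined.

## Synthetic study design

`synthetic.SimulationConfig` generates, per year,

```
field = base_level + gradient·(row, col) + correlated_noise + Σ active bumps
```

* **Correlated noise**: white noise convolved with a Gaussian kernel of
  scale `spatial_corr_length` (periodic boundaries for stationarity), then
  rescaled so the empirical SD equals `noise_sd` exactly.  Chosen over
  spectral synthesis for simplicity and exact seeding.
* **Sources**: Gaussian bumps of scale `decay` (default 1.5 cells),
  truncated at 3·decay, switched on per `active_years`.  Cells within
  `radius` (default 2) of the center are the source's *core*; the core's
  planted regime is the trend category its active-year pattern would earn,
  which makes "did the pipeline recover the planted structure?" a
  well-posed question with a purely geometric answer.
* **Masking**: exactly `round(mask_fraction · n_rows · n_cols)` cells are
  removed uniformly at random outside source cores, so planted truths
  survive pruning.
* **Population**: independent log-normal draws per cell (defaults
  log-mean 5, log-sd 1 — median ≈ 150 persons/cell with a heavy right
  tail), independent of exposure so population-weighted summaries can be
  checked against direct tallies.

The planted-recovery study used by the tests and the acceptance script is a
60×60 grid over 12 years, base level 40, iid noise of SD 5, and three
non-overlapping amplitude-15 sources: always-on (plants a consistent core),
active years 7–12 (emerging), and active years 1–6 (declining).  Two
deliberate choices: **no regional gradient**, because a strong gradient makes
one whole flank of the unit a genuine hotspot, which is a property of the
statistic's unit-relative definition rather than of source recovery; and
**iid rather than correlated noise**, because the conditional-randomization
null assumes exchangeability of the background — under spatially correlated
noise the test over-rejects (see limitations), and the recovery experiment is
meant to measure regime recovery, not that separate calibration effect.
Amplitude 3× the noise SD puts per-year detection of core cells in the
high-power regime without being trivial at the core edge.

What the generator does **not** emulate: real-world exposure distributions
(skewness, seasonal structure), meteorology-driven interannual correlation,
population–exposure correlation (a real population is denser exactly where
sources are), and irregular administrative boundaries.  Passing recovery
tests therefore demonstrate correctness of the machinery under the stated
model, not field performance on any particular real surface.

## Numerical and I/O choices

* Weights are stored as a sparse CSR adjacency over valid-cell positions;
  memory is linear in the number of adjacencies.  Pruning of empty-neighbor
  cells iterates to a fixed point (a removal can orphan a neighbor) and is
  idempotent.
* Coordinates are (row, col), 0-based, row 0 at the top; `cell_id =
  row · n_cols + col` is stable across all operations.  Point gazetteers use
  ground coordinates with y increasing downward from the top edge.
* Interchange is plain CSV plus small JSON sidecars (lattice shape, weight
  flags, run manifest).  Floats are serialized with 10 significant digits
  and fixed column order, which is what makes byte-level reproducibility of
  a rerun achievable and testable.
* Exceedance uses a strict `>` at the threshold (default 40 μg/m³-like
  units).  Exposure-bin tables use half-open bins `[lo, hi)` with edges at
  multiples of the bin width (default 10).
* Point overlay with a positive Chebyshev radius resolves multiple
  categories by the priority consistent > emerging > declining >
  inconsistent; radius 0 is plain containment.

## Problem sizes

Default test and acceptance runs use 10×10 formula-check lattices (against a
scalar reference implementation), a 50×50 field for null calibration
(2,500 cells, nsim = 99), and the 60×60 × 12-year recovery study
(3,600 cells, 43,200 cell-years).  These sizes give the calibration and
recovery checks comfortable statistical resolution (binomial SE of the null
rate ≈ 0.4 percentage points) while keeping a full suite run in well under a
minute; the implementation itself is vectorized and has no problem-size
constants baked in.

## Known limitations

* **Autocorrelated nulls.**  Conditional randomization assumes the
  non-focal values are exchangeable.  On fields with strong background
  autocorrelation the test over-rejects (neighborhoods of correlated cells
  have higher-variance sums than permutation resampling produces), inflating
  yearly hotspot rates and, downstream, the declining/emerging counts.  This
  is a property of the standard method, shared by its common
  implementations; interpret hotspot maps on smooth fields accordingly.
* **Unit-relative hotspots.**  Scores compare each neighborhood to the mean
  and SD of its own spatial unit, so hotspot status changes with the
  partition, and cells near a unit border ignore across-border neighbors of
  other units if the units are analysed separately.
* **Threshold brittleness.**  The taxonomy's count thresholds make cells
  with (c1, c2) near rule boundaries sensitive to single-year label flips;
  the permutation p-granularity (multiples of 1/100) bounds, but does not
  remove, this effect.
* The pipeline is single-process; very large national lattices (millions of
  cells) are feasible memory-wise (sparse weights, per-year vectorized
  permutation draws) but would benefit from chunking by spatial unit, which
  is the natural parallel axis.
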