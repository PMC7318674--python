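# Methods

## The decision problem

Given *n* threatened species with range areas *R_i* (km²), binary
threat profiles *T_ik* over *m* threatening processes, pairwise overlap
fractions *O_ij* and weights *W_i* (default 1), the package selects a
set of species to manage — each for all of its manageable threats,
across its entire range — maximizing the total accrued benefit subject
to a budget on summed action costs. The greedy solver picks, at every
iteration, the unselected species with the largest marginal
benefit-to-cost ratio E_i, recomputed against the current accrual
ledger, until the budget blocks further selection.

## Overlap convention

`O[i, j]` is the fraction of the **recipient** j's range intersected by
i's range: `O[i, j] = area(range_i ∩ range_j) / area(range_j)`. The
matrix is asymmetric; both orientations encode the same intersection
area, so `O[i, j]·area_j = O[j, i]·area_i` holds exactly for matrices
built from grid geometry and to 1e-9 relative tolerance for user-
supplied matrices (with an extra allowance for the 6-decimal
quantization of CSV files). The recipient-normalized reading is a
modelling commitment of this package: benefit statements like "15% of
its distribution" refer to the receiving species' range.

Geometry is a set of unit cells on a shared rectangular grid rather
than vector polygons. That makes intersections and multi-umbrella union
coverage exact rational numbers and all results bit-reproducible;
GeoJSON/shapefile ingestion is deliberately out of scope (precomputed
overlap CSVs cover the vector-GIS case).

## Benefit accounting

**Threat ratio.** The fraction of threats shared between umbrella i and
recipient j, divided by a denominator threat count. Two conventions
ship, selected by `benefit_denominator`:

- `umbrella` (default): divide by i's threat count. A single-threat
  umbrella passes its full overlap fraction to each recipient sharing
  that threat. The published three-species example (koala receiving
  0.15 + 0.15 + 1.0 = 1.30) reproduces exactly under this convention.
- `recipient`: divide by j's threat count. Reading the benefit formula
  literally suggests this form; under it each species' lifetime accrued
  benefit is bounded by its weight. The two conventions disagree and
  the source material is ambiguous; both are first-class and the
  default merely favours the reproducible worked example.

**Accrual ledger.** A species may benefit from a threat-specific action
only once per unit of its range. The ledger tracks `coverage[j, k]`,
the fraction of j's range over which threat k is managed, capped at 1
and nondecreasing over a run. Marginal benefit of managing i is
`W_i · Δ_jk / D` summed over recipients j and shared threats k, where
Δ_jk is the *newly* managed fraction. Re-evaluating an already-managed
species yields 0, so the greedy never reselects.

Two ledger modes:

- `matrix` (default): Δ_jk = min(1, coverage + O[i, j]) − coverage.
  When several umbrellas' ranges overlap *each other* inside a
  recipient, the capped sum over-counts the true union — the pairwise
  overlap matrix alone cannot resolve triple intersections. Matrix-mode
  coverage is therefore an upper bound on geometry-mode coverage, with
  equality when umbrellas are pairwise disjoint within the recipient
  (tests quantify the gap).
- `geometry`: exact union of managed cells per threat; requires cell
  geometry for every species.

Final coverage is order-invariant in both modes (capped sums and set
unions commute). The *split* of benefit between umbrellas is
order-dependent in umbrella-denominator mode when the cap binds
(whichever umbrella arrives first claims the larger increment), which
is why subset values in the exhaustive oracle are evaluated in a
canonical ascending-index order, and why the oracle-vs-greedy
comparisons in the test suite run in recipient mode with unit weights,
where the total is provably order-invariant.

**Static accumulated benefit vs. ledger accounting.** The worked
example's arithmetic (0.15 + 0.15 + 1.0 = 1.30) sums each umbrella's
static contribution, counting the koala's full self-benefit even though
fox management for the bilby already covers 15% of the koala's range —
each umbrella's own management is capped at 100% of its own
distribution, but contributions from distinct actions add without a
recipient-side union. `accumulated_benefit` implements exactly this
convention and is what the acceptance script reports. The ledger-based
marginal accounting used inside the greedy applies the recipient-side
cap as well (the same trio yields 1.15 for the koala when accrued
bilby → orchid → koala) — the two accountings answer different
questions and both are exposed; they coincide whenever managed areas
within each recipient are disjoint across umbrellas.

**Scenarios.** `baseline` accrues proportional per-threat coverage as
above. `optimistic` grants a recipient W_i times the increment of its
*maximum* per-threat coverage — one managed shared threat is enough.
`pessimistic` grants W_i only when every one of the recipient's threats
reaches full coverage of its entire range. Both are one-sentence
reconstructions of scenario descriptions whose full specification is
not public; each is isolated in one code branch for easy revision. For
any fixed selection, benefitting counts satisfy optimistic ≥ baseline ≥
pessimistic (verified in the acceptance suite).

**Categorization.** After a run, selected species whose accrued
contribution to at least one *other* species exceeds
`benefit_threshold` (default 0) are *umbrella* species; selected
species without such a contribution are *additional*; unselected
species with accrued benefit above the threshold are *benefitting*.
`total_benefitting` counts all distinct species above the threshold.
Note the three categories need not sum to `total_benefitting`:
additional species benefit themselves and are counted in the total.

## Costs and budget

`C = q · R^z` with q > 0 (cost units per km^{2z} per yr) and
0 < z ≤ 1, concave for z < 1 so per-area cost falls with managed area.
q carries all currency information and has no default tied to any
particular fit — the generator emits q = 1. Species are always costed
over their full range; partial-range management is not costed. Threats
listed as `unmanageable_threats` are zeroed out of the threat matrix
before benefit computation (their benefit is 0) but do not reduce R or
C. The assumed-budget operation is simply the portfolio cost of a
reference list, used as the budget of an optimized run in
`efficiency_comparison`.

## Greedy details

- Candidates with positive marginal benefit are ranked by E_i; ties
  break by lower cost, then lexicographic species id (determinism
  requires a rule; this one is the package's choice).
- When no remaining species has positive marginal benefit, ranking
  falls back to 1/cost, so cheap self-benefit-exhausted species can
  still fill the budget as additional picks.
- `skip_and_continue` (default, standard greedy-knapsack practice)
  skips unaffordable candidates and keeps scanning; `stop_at_first`
  ends the run at the first unaffordable best candidate. Both are
  exposed because the stopping rule in the source description is
  ambiguous.
- Species with zero (manageable) threats are excluded from selection
  and accrual, with a logged warning.
- The exhaustive oracle enumerates all within-budget subsets and
  refuses instances above `max_n = 15` (≈ 32k subsets) rather than
  silently subsampling.
- The z-sensitivity consistency metric is the Jaccard overlap of list
  membership in percent (order ignored; 100 for two empty lists). The
  "percent consistent" metric it mirrors is not precisely specified in
  the source material; Jaccard is this package's interpretation.

## Synthetic assemblages

The generator stands in for real national datasets (range maps,
species-profile threat listings, cost fits), which are not
redistributable. It emulates: broad, right-skewed range-size variation
(log-uniform in cells between configurable bounds; default 16–4096 on
a 256 × 256 grid of nominal 1 km² cells), spatial aggregation of
species into hotspots (a species' block is placed around one of 3
Gaussian kernels, sd = grid/12, with probability `clustering`, else
uniformly), and independent per-threat prevalence (default 10 threats
at 0.2 each ≈ 2 threats/species, resampled to a floor of 1, matching
the stylized fact that every listed species has at least one documented
threat). Ranges are contiguous axis-aligned rectangles — adequate to
exercise every downstream formula while keeping set arithmetic exact.

It does **not** emulate: realistic biogeography or range shapes, threat
co-occurrence structure, spatial threat gradients, or any particular
country's species list. Passing tests therefore demonstrate the
correctness and internal consistency of the accounting and optimization
on controllable inputs, not the field accuracy of any specific
prioritization.

Because species must have ≥ 1 threat, empirical threat frequencies are
conditioned draws and sit slightly above the nominal prevalence; the
statistical recovery test uses a prevalence (0.3 with 10 threats) at
which this conditioning bias is far inside the Monte-Carlo error band.

Two deterministic fixtures support the examples and tests: the
three-species koala/bilby/orchid configuration (15% disjoint overlaps
inside a 100-cell koala range), and a 40-species two-list assemblage
whose 8 isolated, uniquely-threatened reference species are strictly
beaten — more species benefitting under the same assumed budget — by
the greedy's preference for four clusters of overlapping,
threat-sharing species.

## Numerical choices

- Benefit totals below 1e-12 are treated as zero when testing whether a
  candidate still yields benefit.
- "Full coverage" in the pessimistic scenario means ≥ 1 − 1e-9;
  geometry-mode fractions are exact, the tolerance absorbs float
  summation in matrix mode.
- Problem sizes in the test and acceptance suites (ensembles of 200
  instances with 6–8 species, grids ≤ 128²) were chosen so the
  exhaustive oracle stays exact and the whole suite runs in seconds;
  the algorithms themselves have no such limits (the greedy is
  O(n² · m) per run at matrix mode).
- Output CSVs print floats at 6 decimals; summary JSON rounds to 9.

## Known limitations

- Matrix-mode coverage over-counts union area when umbrella ranges
  overlap each other inside a recipient (bounded above by the capped
  sum; use geometry mode when cell data are available).
- Benefit is time-independent and deterministic: no persistence
  probability, management feasibility or action scheduling.
- Costs depend only on area, not on how many threats are managed.
- The greedy is a heuristic; constructed instances exist where two
  cheap complementary species jointly beat its first pick (the test
  suite contains one), though on random small instances its empirical
  approximation ratio is high.
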