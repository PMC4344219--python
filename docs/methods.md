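# Methods

This note documents the statistical model, the algorithmic choices made
where the design was genuinely open, the synthetic data the tests rely on,
and the package's known limitations.

## Uncertainty model

Every input cell is an (estimate, MOE) pair, with the MOE interpreted as the
half-width of a 90% normal interval. One constant, 1.645, converts between
MOE and SE throughout; the older 1.65 convention used by some pre-2006
products is deliberately not supported — mixing divisors inside one analysis
is a worse failure mode than a 0.3% scale difference.

CV conventions at the edges:

- estimate 0, MOE 0 → CV 0 (a perfectly known zero satisfies any target);
- estimate 0, MOE > 0 → CV +∞, so feasibility fails loudly rather than a
  zero estimate silently passing;
- published MOEs on zero estimates are a statewide placeholder, not a
  measurement, so preprocessing resets them to zero before any CV is taken.

Region aggregation uses the Census Bureau approximation formulas (counts:
root-sum-of-squares; proportions: the subtractive subset form; means/ratios:
the additive form). The subtractive form's radicand can go negative when the
denominator is relatively noisier than the numerator; the standard remedy —
switching to the additive ratio form — is applied automatically and every
switch is counted (`proportion_fallbacks` in the run manifest). No
finite-population corrections, design effects, or between-variable
covariances are modeled: the published MOEs are taken as the complete
uncertainty description, which is all a public-data user has.

## Preprocessing

Fixed order, enforced by the pipeline object: (1) drop zero-household areas
(parks, water, institutions — they break ratio denominators), (2) reset
zero-estimate MOEs, (3) z-score the attribute values (the estimate for
counts, the ratio for derived variables) with the sample (n−1) sd —
immaterial to optima, documented for reproducibility, (4) PCA.

The PCA weighting needed a concrete functional form: every component is
kept (100% of the variance), each score column is whitened to unit variance
and multiplied by its explained-variance share w_c = λ_c/Σλ. A component's
maximum possible contribution to squared deviations is then proportional to
the variance it explains, which is the stated intent — use all the
information, weight by contribution — in its simplest exact form. Numerically
null components (λ ≤ 1e−10, e.g. perfectly collinear inputs) are dropped
with a warning and the weights renormalized. Features are computed once on
the full retained table, never per candidate region, so all regions are
compared in a common space. Manual variable weighting is exposed only as a
config hook, not a supported workflow.

The 5% exemption is evaluated on the **candidate region's aggregated
estimate**, not on member areas: an area-level rule would let an infeasible
region hide behind one small tract. Only `proportion`-kind variables are
ever exempt; means of dollar amounts and counts are not, since their scale
makes the "small proportion" rationale meaningless.

## The search

Phase 1 constructs feasible partitions from random seeds. Within-ring order
during concentric growth is uniform-random and each ring is consumed before
the next is computed — growth stays compact while restarts stay diverse. A
region that exhausts its frontier (or exceeds a population ceiling) without
reaching feasibility is dissolved; its members stay available to other
seeds. Leftovers are absorbed in random order into the adjacent region with
the smallest SSD increase among those that stay feasible; a leftover whose
neighbors are all still-unplaced leftovers is requeued, and an attempt with
no feasible placement is discarded whole — construction passes are cheap by
design, so backtracking buys little.

Phase 2 is tabu search over single-area moves. A move donor must stay
nonempty, connected (checked by traversal after tentative removal) and
feasible; the recipient must stay feasible; region count never changes. Each
iteration applies the globally best admissible move — even a worsening one,
which is how tabu search escapes local optima — and forbids the reverse
(area, source-region) pair for `tabu_length` iterations, with aspiration for
moves that beat the best solution ever seen. The incumbent best is returned,
so the reported SSD is monotone in effort. One RNG stream drives seeding,
growth and leftover order; the seed is recorded in the solution and the
manifest for exact replay.

Defaults: 100 restarts, tabu length 10, at most 10,000 swaps, stop after 500
non-improving iterations. Restart count matters far more than tabu depth: on
9-area instances where the exact optimum is known by enumeration, the rare
misses trace to the construction phase never sampling the optimal basin
(single-area moves cannot always reach it through feasible intermediates),
and raising restarts — the original design calls for thousands — closes the
gap, while raising tabu limits does not.

## Internal consistency

The optimizer evaluates regions from running sums (per-variable numerator /
denominator estimate and variance totals, feature sums for O(1) SSD deltas).
This fast path must agree exactly with the plain row-by-row reference
implementation (`uncertainty.region_cv_table`); a test compares the two on
random regions. Radicands computed from running sums may drift a few ulps
below zero and are clamped. The cached SSD of a returned solution is
asserted against a from-scratch recomputation at 1e−9.

The exact solver (`cvregion.exact`) enumerates every partition into
connected parts (bitmask recursion, infeasible parts pruned, per-subset
feasibility and SSD memoized) and is practical to roughly a dozen areas. It
shares only the per-region evaluator with the heuristic, not the search.

## Synthetic data

The generator emulates a rectangular lattice of unit-square tracts tiled by
planted zones (quadrants, horizontal bands, or an explicit label array).
Sample sizes are Poisson around 135 completed surveys (floor 10), the
realistic pooled-period tract scale. Every published cell is
truth + N(0, sd/√n) with MOE = 1.645·sd/√n, so MOE/SE consistency and
nominal 90% coverage hold exactly by construction. Proportions are emitted
as numerator/denominator count pairs against the population denominator
(per-person binomial sd for numerators; population unit sd 0.5, giving
tract-population CVs of a few percent), so the full derived-ratio error
path, including occasional radicand fallbacks, is exercised. Zone means are
separated by `effect` within-zone sds (default 3, within-zone sd 0.04 on
the proportion scale) with the level-to-zone mapping permuted per variable,
so variables disagree about which zones are high — the multivariate tension
the objective must balance. Base proportion levels span 0.25–0.75 across
variables; after zone offsets the lowest-level variable lands near 0.07,
which makes it the binding constraint almost everywhere, mirroring how one
poorly measured attribute drives real aggregations.

What the generator does **not** emulate: the real sampling design and
weighting, spatial autocorrelation beyond the planted blocks, irregular
tract geometry, and missing data. Passing tests therefore demonstrate the
estimator algebra, the constraint logic and the search — not performance on
any particular real survey product.

Test problem sizes are deliberately modest: exact-oracle studies on 6–9-area
lattices (where enumeration is the ground truth), recovery on 12×12, trend
sweeps on 10×10 with 25 restarts. The helper
`cv_target_for_region_size` picks CV targets from the data's own binding
CVs (median worst-variable CV divided by √m forces ≈ m-area regions), so
test conditions are stated in design terms rather than magic numbers.

## Design decisions that were open

- **Contiguity rule:** queen (a shared corner suffices) by default, rook
  available. Queen is the permissive convention for tract polygons and
  avoids spurious islands; corner-touching tracts are rare in real
  cartography but common on test lattices.
- **Geometry/attribute mismatch** is a hard error, not a silent drop — a
  silently truncated partition corrupts every downstream number.
- **Kind of a derived variable** (subset proportion vs ratio mean) is
  declared per variable; percent-type variables should declare `proportion`.
  The exemption applies only to CV targets, never to MOE-scale targets.
- **Information-loss convention:** the within-MOE comparison is strict
  (`|a_ij − a_kj| < e_ij`) as printed, except that an exactly zero
  difference counts as within even when the MOE is zero — otherwise a
  perfectly preserved singleton would be scored as information loss, which
  contradicts the statistic's meaning. Count variables are excluded from
  S_j and from the J in the global mean, since a region count always
  exceeds its members' counts.
- **Region attribute value** for the diagnostics is the re-aggregated ratio
  (summed numerators over summed denominators), not the mean of member
  ratios.
- **Region labels** are dense integers in first-seeded order; purely
  cosmetic.

## Limitations

- The heuristic offers no optimality certificate; use `cvregion.exact` to
  certify instances up to ~12 areas, and restarts for everything else.
- Tabu moves are single-area; optima separated from the incumbent by
  infeasible intermediates are unreachable in phase 2 (mitigated by
  restarts).
- MOEs enter feasibility but not the SSD objective, so an uncertain
  estimate pulls region shapes as strongly as a precise one.
- Run-to-run variation across seeds is inherent; the manifest records
  everything needed to replay a chosen solution, but no stability or
  consensus measure across solutions is computed.
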