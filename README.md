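# cvregion

**Uncertainty-constrained regionalization for survey small areas.**

Small-area survey estimates — census tracts reporting child poverty, housing
cost burden, transit use — often carry margins of error (MOE) as large as the
estimates themselves. `cvregion` repairs such data by merging contiguous
areas into the *maximum* number of composite regions whose estimates all meet
a user-chosen reliability target, expressed as a coefficient of variation
(CV), while keeping each region as internally homogeneous as possible.

It is aimed at analysts working with American Community Survey (ACS) tract or
block-group tables, or any survey product that publishes estimate + MOE
pairs, who need estimates reliable enough for policy or research use without
giving up more spatial detail than necessary.

## The model

Published MOEs are 90% half-widths, so `SE = MOE / 1.645` and
`CV = SE / estimate`. Aggregating areas i ∈ k follows the Census Bureau
rules: counts add with root-sum-of-squares SEs, and a derived proportion
p = num/den has

```
SE(p) = sqrt(SE_num² − p²·SE_den²) / den        (subset numerator)
SE(p) = sqrt(SE_num² + p²·SE_den²) / den        (ratio / mean; also the
                                                 fallback when the radicand
                                                 is negative)
```

A partition of n areas into p connected regions is **feasible** when every
variable in every region satisfies `CV ≤ c` (globally or per variable),
except proportions estimated below 5%, whose CVs are unstable and exempt,
and optional population bounds hold. Among feasible partitions the solver
maximizes p, then minimizes the within-region sum of squared deviations

```
SSD = Σ_k Σ_{i∈k} Σ_j (a_ij − ā_kj)²
```

computed on variance-weighted principal-component scores of the z-scored
attributes. The search is an adapted max-p heuristic: many randomized
construction passes (random seed areas grown concentrically until feasible,
leftovers absorbed where they raise SSD least), best partition by
(max regions, min SSD), then tabu-search refinement that moves single areas
between adjacent regions without breaking contiguity or feasibility.

Solution quality is reported as `S_j`: the share of areas whose region-level
estimate lies inside the area's own margin of error (no information lost by
aggregation), and `S`, the mean of `S_j` over proportion/mean variables.

## Worked example

Generate a synthetic 6×6 tract lattice with four planted neighborhood types,
then regionalize it at the commonly recommended CV target of 0.12:

```sh
cvregion synth demo --rows 6 --cols 6 --seed 3
python - <<'EOF'
import json
cfg = json.load(open("demo/variables.json"))
cfg.update({"cv": 0.12, "n_starts": 100, "seed": 0})
json.dump(cfg, open("demo/config.json", "w"), indent=2)
EOF
cvregion regionalize demo/areas.csv demo/areas.geojson demo/config.json demo/run
```

which logs

```
INFO regionalizing 36 areas, 6 variables, 100 starts, seed 0
INFO done: 7 regions, SSD 4.0879, S 0.489
```

The 36 tracts collapse into 7 contiguous regions (5.1 tracts per region) —
every region-level CV is now at or below 0.12, at the cost of spatial
detail: `S = 0.489` says that for about half of the (tract, variable) pairs
the regional estimate still falls inside the tract's own margin of error.
`demo/run/` contains the tract→region `assignment.csv`, a `regions.csv`
table of region estimates/MOEs/CVs, dissolved region polygons
(`regions.geojson`), the per-tract `diagnostics.csv` behind scatter-style
diagnostic plots, and a `manifest.json` (seed, configuration, preprocessing
report) sufficient to replay the run exactly. A looser target keeps more
tracts separate; a tighter one merges more aggressively — that trade-off is
the user's to steer.

The same machinery is importable as a library (`cvregion.regionalize`,
`cvregion.uncertainty`, `cvregion.evaluate`, ...), including an exact
enumeration solver (`cvregion.exact`) for instances small enough to verify
the heuristic against.

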