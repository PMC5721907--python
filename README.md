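# sdmtools

A GIS-engine-free Python toolkit for the computational core of species
distribution modelling (SDM) workflows in spatial ecology, biogeography and
landscape genetics. It covers the steps practitioners normally chain together
around a presence-background model such as MaxEnt:

* **occurrence curation** — CSV ingestion and spatial rarefaction (thinning
  records so no two retained points of a species lie closer than a filter
  distance, single-scale or stratified by up to five heterogeneity classes);
* **background/bias surfaces** — buffered minimum convex polygon, distance
  buffers, Gaussian kernel density of sampling localities, and a buffered
  local adaptive convex hull (single-linkage clusters at distance α, each
  contributing its own buffered hull);
* **spatial jackknifing and model tuning** — 3–5 geographically segregated
  occurrence groups, Voronoi-dissolved landscape regions, leave-one-group-out
  folds; candidate models over a regularization-multiplier (RM) grid × five
  feature-class combinations (L; L,Q; H; L,Q,H; L,Q,H,P,T, with the T class
  toggleable); selection by lowest omission error rate (OER), then highest
  AUC, then lowest complexity; MaxEnt java batch-file emission;
* **SDM post-processing** — thresholding (fixed / minimum training presence /
  percentile), splitting a binary SDM among 2–10 clades by nearest-occurrence
  Voronoi assignment, and dispersal-limited clipping of future projections;
* **biodiversity grids** — species richness, weighted endemism
  (WE = Σ 1/range size) and corrected weighted endemism (CWE = WE/richness)
  from binary range stacks; CANAPE neo/paleo/mixed/super endemism
  categorization and generic significance reclassification of externally
  produced randomization tables (Biodiverse exports);
* **landscape connectivity** — cost-distance surfaces, deterministic
  least-cost paths (LCPs), corridors, and pairwise along-path-cost /
  LCP-length matrices over friction rasters.

Everything operates on two plain data structures — a `Grid` (ESRI ASCII /
GeoTIFF raster lattice in projected map units) and an `OccurrenceSet`
(species, x, y, optional clade label) — so no proprietary GIS is required.
Seeded synthetic generators (`sdmtools.fixtures`) produce every scenario the
toolkit consumes, which makes the full pipeline testable offline.

## Key statistics

For test presences with suitability scores *s₁…sₙ* and threshold *t* (default:
minimum training presence),

```
OER = #{i : sᵢ < t} / n
```

is the omission error rate (false-negative rate), the overfitting signal; and
the rank-based AUC (Mann–Whitney) is

```
AUC = P(score(presence) > score(background)) + ½·P(tie)
```

the discrimination signal. Model selection is lexicographic:
min mean OER → max mean AUC → min feature-class complexity (combination
order 1–5) → min RM.

## Worked example

```python
from sdmtools import (ExtentSpec, FixtureSpec, TuningSpec, bias_buffered_mcp,
                      jackknife_evaluate, make_landscape, make_occurrences,
                      rarefy, tune_and_select)

spec = FixtureSpec(seed=1, extent=ExtentSpec(0, 0, 100, 100), cluster_spread=4.0)
env = make_landscape(spec)            # gradient + patchy layers
occ = make_occurrences(spec)          # 3 spatially clustered samples

thinned = rarefy(occ, 5.0)
print(f"occurrences: {len(occ)} -> {len(thinned)} after 5 map-unit rarefaction")

bias = bias_buffered_mcp(occ, 15.0, env["gradient"])
print(f"bias surface: {bias.cell_count()} background cells")

spatial = jackknife_evaluate(occ, env, k=3, mode="segregated", seed=1)
random_ = jackknife_evaluate(occ, env, k=3, mode="random", seed=1)
print(f"mean OER  spatial folds: {spatial.mean_oer:.3f}   random folds: {random_.mean_oer:.3f}")

best, evals = tune_and_select(occ, env, TuningSpec(rms=[0.5, 1.0, 2.0]),
                              k=3, seed=1, bias=bias, n_background=2000)
print(f"selected: RM={best.candidate.rm}, combo={''.join(best.candidate.combo)}, "
      f"mean OER={best.mean_oer:.3f}, mean AUC={best.mean_auc:.3f}")
```

prints

```
occurrences: 30 -> 12 after 5 map-unit rarefaction
bias surface: 6047 background cells
mean OER  spatial folds: 0.100   random folds: 0.000
selected: RM=0.5, combo=L, mean OER=0.033, mean AUC=0.284
```

The contrast in the third line is the point of spatial jackknifing: with
spatially clustered sampling, random folds let every training set span the
whole environmental range and report zero omission, while spatial folds force
extrapolation to a withheld region and reveal it. The low test AUC is also
expected here — background is drawn from the training regions only, where the
model fits well, so a geographically transferable model is hard to
distinguish from background on this deliberately biased fixture.

A command-line layer mirrors the library
(`sdmtools grid|occ|bias|sdm|biodiv|connect|fixtures …`); see
`sdmtools --help`.

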