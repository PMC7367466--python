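# Methods

## Scope and data model

All spatial objects live on a shared uniform planar lattice (`GridSpec`):
no reprojection, no geodesic cell areas. Area is the suitable-cell count,
which makes percent change resolution-free (refining every cell into four
leaves every percentage unchanged — this is asserted in the tests). Rows
are stored top-down; on-disk rasters use the ESRI ASCII grid text format,
occurrence sets and tables use CSV.

## Synthetic worlds

The generators emulate the statistical structure of a bioclim-based impact
study so the whole chain is testable without external downloads. Every
generator is a pure function of its parameters and a seed.

**Climate.** Each of the five predictor layers is white noise smoothed with
a Gaussian kernel (`smoothness`, default 6 cells — the correlation length),
standardized and scaled to a plausible eastern-Amazon mean and spatial sd:
bio1 26 ± 1.5 °C, bio3 85 ± 4, bio4 55 ± 12, bio12 2100 ± 350 mm,
bio13 320 ± 60 mm. A small rough component whose amplitude shrinks as
`1/(1+smoothness)` keeps cell-scale texture; when the kernel is much wider
than the domain the smoothed field is treated as constant rather than
standardizing float-precision residue.

**Futures.** A GCM ensemble is emulated by realizations
`current + (Δμ_v + σ_v·ε_r) + a_v·anomaly_r`, with ε_r standard normal per
realization and the anomaly a zero-mean smooth field (amplitude defaults to
half the inter-model spread). The rcp45 presets shift bio1 by +1.6 ± 0.5 °C
and dry bio12 by −120 ± 90 mm; rcp85 by +2.9 ± 0.7 °C and −240 ± 130 mm,
with matching signs for the remaining roles — mid-century warming-and-drying
magnitudes for the eastern Amazon lowlands. Eleven realizations per pathway
is the default ensemble size.

**Forest masks.** Current forest keeps the top fraction of a smooth habitat
field (default 0.24 — a landscape with ~76% already cleared). The 2050
scenarios carve cells out of the current mask in order of a shared smooth
clearing-pressure field, giving spatially contiguous fronts and exact
nesting BAU ⊆ GOV ⊆ current; defaults 0.17 (governance) and 0.08
(business-as-usual) continue the historical clearing trend under the two
outlooks. Counts hit their targets to the nearest cell.

**Virtual species.** A niche is Gaussian in predictor space:
s(v) = s_max·exp(−½(v−μ)ᵀΣ⁻¹(v−μ)). `niche_from_stack` anchors μ at
per-layer quantiles drawn from [0.35, 0.65] (so the optimum exists inside
the domain) and sets Σ diagonal with sd `breadth` (default 1.5) times each
layer's spatial sd — a species occupying roughly a third of the landscape
at half-maximum suitability. Occurrences are drawn without replacement at
cell granularity with weight ∝ suitability × exp(−bias·d_road/scale), where
d_road is the distance to a random line through the domain: a stand-in for
the accessibility bias of opportunistic databases, not an inference about
any particular dataset.

What the generator does **not** emulate: observation error in coordinates,
taxonomic misidentification, temporal bias, non-Gaussian or multimodal
niches, biotic interactions, and correlated predictor fields (layers are
generated independently; real bioclim variables are strongly collinear —
the screening step is therefore exercised separately via a packaged
synthetic 19-variable correlation matrix built from a seeded 5-factor
latent model). Passing tests demonstrate internal correctness and
recoverability under these idealized conditions, not performance on real
occurrence data.

## Occurrence cleaning

Deduplication keeps the first record per occupied cell. The Moran profile
computes I with binary weights (pair weight 1 iff distance ≤ lag) on the
first principal component of the column-standardized predictor values at
the records; the default lag ladder is ten equal steps from the cell size
to a quarter of the domain diagonal. Lags with no qualifying pair are
reported undefined and excluded. The thinning distance is the smallest lag
minimizing |I| — minimizing the absolute value, since negative
autocorrelation is still autocorrelation. Thinning is the randomized greedy
with restarts familiar from spThin: repeatedly discard a record from the
most crowded neighborhood (ties uniform at random), keep the best of
`n_restarts` runs. Exact maximum-independent-set search is NP-hard and is
used only as a test oracle on ≤ 12 points. In the pipeline, a chosen lag
that leaves fewer than `min_records_after_thinning` (default 8) records is
stepped down the lag ladder until enough records survive.

## Models

* `maxent_like` — logistic contrast of presences against a background cell
  sample (all cells up to 10 000) on linear + quadratic features with a
  mild ridge (C = 10); the fitted relative rate exp(η), normalized to mean
  1 over the background, is squashed to [0, 1) as 1 − exp(−rate),
  complementary-log-log style. Quadratic features are what lets a
  log-linear model express a unimodal niche.
* `margin_classifier` — RBF-kernel SVM (C = 10) with Platt sigmoid
  calibration (3-fold, so calibration stays feasible at the small presence
  counts of rare taxa).
* `tree_bag` — 200 bagged randomized trees voting a class-1 fraction.

Pseudo-absences are uniform over presence-free cells, as many as there are
presences, drawn once per taxon and then partitioned (five stratified
70/30 splits). Each fit is scored on its test fold with the Sørensen index
at the fold's best threshold; the binarization rule throughout is
"maximize Sørensen, ties toward the larger (more conservative) threshold".
The ensemble keeps fits scoring strictly above the mean Sørensen — if all
scores are equal, everyone enters, so the ensemble is never empty — and
averages them cellwise with weight equal to the score, the only
model-quality scalar the pipeline computes.

## Projection conventions

* **Consensus-then-binarize.** Realizations are averaged as continuous
  surfaces and thresholded once; voting binarized realizations is a
  different (noisier) estimator and is never used.
* **Threshold transfer.** The current-scenario threshold is reused for the
  future projections of the same taxon, so change estimates do not conflate
  threshold drift with climate change.
* **Dispersal.** Limited dispersal lives *inside* the fit via the
  cumulative-distance predictor, which is held at its current-occurrence
  value when projecting (a species cannot re-seed its own distance layer);
  the post-hoc intersection with the current range is reserved for the
  no-dispersal mode. A taxon whose limited-dispersal future area exceeds
  its unlimited area is flagged in the manifest, not dropped.
* **Baselines per framework.** The unlimited and no-dispersal columns
  divide by the unconstrained current range; the limited column divides by
  the dispersal-constrained fit's own current range. A published change
  table in which a taxon shows identical gains under unlimited and limited
  dispersal is only arithmetically possible with such per-framework
  baselines.
* Current ranges are masked with current forest; future ranges with the
  scenario's 2050 mask (masking and the no-dispersal intersection commute,
  so the order is immaterial).

## Impact accounting

Percent change is reported to two decimals with half-up rounding; summary
means are computed unrounded and rounded half-up only for presentation
(two decimals for table-style figures, integers for prose-style figures).
Taxa with zero current area have undefined percent change; they are
excluded from the table and reported separately in the manifest. Count
predicates are literal: "lost more than x" means change < −x, "gained"
means change > 0, applied over all selected columns.

## Virtual-species validation

`rangeshift.validation.recover_virtual_species` fits the full ensemble on
one world and scores the recovered range against the truth's half-maximum
contour. The headline score is a **matched-prevalence** Sørensen: the
ensemble range keeps the top-f fraction of cells by predicted suitability,
f being the truth range's own prevalence. The rationale: the
Sørensen-optimal threshold on a balanced presence/pseudo-absence sample
systematically sits below the half-maximum contour, so thresholded-range
overlap mixes calibration-level error into what should be a
where-is-the-habitat score. The no-skill reference is the identical harness
with labels permuted before fitting; under matched prevalence its expected
overlap approximates the truth prevalence itself. Recovery at realistic
sample sizes is information-limited: with few dozen presence records drawn
in proportion to a smooth suitability surface, even a correctly-specified
estimator of the truth's own family leaves substantial boundary error, and
overlap scores approach 1 only as the record count grows far beyond what
rare taxa provide. The validation study sizes (60 × 60 worlds, 80 records,
10 seeds) match the upper end of what such datasets offer.

## Problem sizes and determinism

The shipped test suite and examples run worlds between 20 × 20 and 60 × 60
cells with 2–11 GCM realizations and up to 80 records per taxon — sizes
chosen so a full validation sweep stays interactive on a laptop while every
statistic still has room to express its asymptotics. All randomness flows
from explicit seeds (numpy `default_rng` with fixed stream tags; estimator
seeds derived from the run seed), and two runs of the same configuration
produce byte-identical CSV outputs.

## Known limitations

* Planar geometry only; no support for real-world CRS metadata beyond a
  free-text label.
* The presence-background learner is a principled stand-in for the
  presence-background family, not a port of any particular software's
  feature classes or regularization path.
* The Moran profile is computed on the first climate principal component;
  multivariate alternatives (per-variable profiles, Mantel correlograms)
  are out of scope.
* Richness maps are plain stacked binaries; no richness calibration or
  macroecological constraint is applied.
* Protected-area overlays, IUCN criteria and map cartography are outside
  the package's scope.
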