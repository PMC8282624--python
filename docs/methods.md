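# Methods

## Scope and model

`pftshift` implements the analysis chain behind stacked species
distribution modelling of plant functional types (PFTs): per-species
correlative suitability models, their ensemble, community stacking, and
four derived analyses (dominance transitions, elevational shifts,
fragmentation, uncertainty partitioning). The statistical assumptions are
those of correlative SDMs generally: species occurrences are in
equilibrium with the training environment, pseudo-absences are an adequate
contrast class, and projected suitability is interpreted as environmental
favourability, not as predicted occupancy or a timeline of change.

## Coordinate and data conventions

Grids are geographic (degrees), north-up, row 0 northernmost, cell-center
registered, with half-open cell intervals (a point on an interior edge
belongs to the south/east cell). Missing data is NaN plus a shared boolean
mask. Rasters are written as multi-band float32 TIFF with the grid and
band names as JSON in the image description tag; occurrences as CSV
(`species,lon,lat`). Cell areas use spherical cos-latitude weighting,
since a fixed angular grid spans ~20° of latitude in the intended setting.

## Synthetic landscapes and virtual species

The generator emulates the statistical structure of gridded
climate/soil/topography predictors: spatially autocorrelated fields built
by Gaussian-filtering white noise (correlation length in cells; simpler
than variogram simulation and sufficient to create realistic spatial
structure), a non-negative elevation field (smooth field, optional
west-east ramp and/or a central ridge), temperature = sea-level field −
lapse_rate × elevation (default 0.0065 °C/m, the standard environmental
lapse rate), precipitation with a latitudinal gradient plus noise, slope
by finite differences, and three soil fields. Virtual species follow
independent Gaussian responses per variable — chosen because the ground
truth must stay analytically invertible for verification; niche
interactions are out of scope. Occurrences are drawn with cell probability
∝ suitability × optional bias and jittered uniformly within the cell, so
grid thinning is genuinely exercised. Scenario deltas are per-layer
offsets/factors restricted to climate layers.

What the synthetic data does *not* emulate: real observation processes
(taxonomic error, spatial clustering of collectors beyond a smooth bias
layer), niche interactions and dispersal limits, land-use masks, and
CRS/projection issues. Passing tests therefore demonstrate correctness of
the machinery and recoverability of known signal, not predictive skill on
real occurrence data.

## Data preparation

Thinning keeps the first record per species per cell in input order
(deterministic; the choice among duplicates is immaterial after cell
assignment). Species need ≥ 200 thinned records by default to be
modelled. Collinearity screening removes the predictor with the highest
variance inflation factor (VIF = 1/(1−R²), regression with intercept on
the remaining predictors) until all VIFs fall below 10; constant columns
are removed first (undefined VIF), and numerically infinite ties drop the
later variable in input order. The screening sample is pooled presences
plus a seeded random background. Training ranges are the per-layer min/max
over the whole study region; scenario layers are clamped to them, with
per-layer univariate novelty masks (multivariate novelty interactions are
not computed).

## Ensemble modelling

Defaults follow common practice for each learner family: 10,000 random
pseudo-absences for the regression-type and density-ratio learners;
presence-equal pseudo-absences from a distance annulus (d ≥ 2 cells) for
the bagged-tree learner. Pseudo-absences never fall on presence cells and
are down-weighted so presence and absence weight totals are equal. Each
learner runs `n_replicates` (default 100) independent 70/30 splits; a
failing replicate is skipped with a warning. For projection, a uniform
random subset of replicates per learner (default 10) is used. The learner
interface is pluggable; the concrete implementations (penalized spline
logistic, hinge-basis logistic, quadratic-feature presence/background
logistic, random forest) are deliberately standard components — algorithm
internals are not the contribution here.

## Evaluation

AUC uses the rank-sum formulation (ties ½). CBI uses 101 windows of width
0.1 × the suitability range (standard literature defaults); windows with
zero background expectation are dropped, and a perfectly flat P/E profile
is defined as CBI = 0 (no monotone habitat signal; the rank correlation is
otherwise undefined). The calibration statistic is
1 − Σ_b w_b |mean predicted_b − observed_b| over 10 equal-width bins with
occupancy weights w_b — a scalar summary of the calibration plot, stated
here as this package's definition. Filtering retains a learner iff every
applicable replicate-mean metric ≥ 0.7; the calibration statistic is
waived for presence-only learners whose scores are relative ranks.

## Stacking and dominance

maxSSS thresholds are computed per species × learner on holdout
predictions pooled across the selected replicates; comparison is ≥, and
objective ties resolve to the smallest threshold. Species presence
requires agreement of ≥ 3 learners; PFT presence requires bS-SDM ≥ 2 of
(typically) 4 members. Dominance restricts the argmax of richness to PFTs
passing presence (configurable to unrestricted); exact ties break by the
canonical PFT order and are flagged. Flow matrices are area-weighted and
conserve marginals by construction.

## Shifts

The "lower range boundary" is operationalized as the 5th altitude
percentile of presence cells — a density-contour reading is not
reproducible, a quantile is. Density clouds (2-D Gaussian KDE with
explicit per-axis bandwidths) are diagnostics only. Latitudinal divergence
is detected as ≥ 2 KDE modes with prominence ≥ 10% of the maximum; no
formal multimodality test is attempted. On a linear elevation ramp with a
temperature-limited species, a uniform +Δ warming moves the boundary by
Δ/lapse_rate; the test suite verifies recovery of 2/0.0065 ≈ 307.7 m
within ±25% at n = 1000 sampled presences.

## Fragmentation

Pf is the occupied fraction of in-window, in-map cells; Pff is estimated
as 2FF/(2FF+FN) over unordered cardinally adjacent in-window pairs (the
ordered-neighbour conditional frequency — the standard Riitters
formulation). Classes: interior (Pf = 1), patch (Pf < 0.4), transitional
(0.4 ≤ Pf ≤ 0.6; the boundary values, unclassified by strict
inequalities, are assigned here to keep classes exhaustive), perforated
(Pf > 0.6, Pf − Pff > 0), edge (Pf > 0.6 otherwise). Borders use
truncated windows so Pf remains a true proportion; ocean/no-data cells
count as outside the map. Exactly five in-type classes are attainable
over the complete focal-present 3×3 enumeration, verified against an
independent brute-force implementation.

## Uncertainty

Main-effects ANOVA per cell over algorithm × replicate × RCP × GCM;
fractions = SS_factor / SS_total, residual absorbs interactions. Balanced
designs use direct group-mean SS; unbalanced layouts fall back to
sequential (type I) SS in canonical factor order, which is then
order-dependent by construction. Zero-variance cells are flagged
degenerate with all fractions 0. The orchestrated pipeline evaluates the
partition on a seeded random subsample of cells (default 200) and ranks
factors by median fraction.

## Problem sizes and determinism

The bundled demo uses a 60×60 grid, 8 species in 2 PFTs, 12 replicates
per learner (6 selected for projection) and 4 scenarios — sizes chosen so
a laptop CPU runs the full chain in about a minute while every stage
still has non-trivial spatial structure. All randomness flows from one
run seed through CRC-derived sub-seeds per stage/species/learner, so
reruns reproduce all artifacts (the manifest records output digests).

## Known limitations

No CRS handling or reprojection; no multivariate extrapolation surfaces
(MESS/ExDet); no recalibration of projected probabilities; no
patch-level connectivity metrics beyond the 3×3 window classes; the
per-algorithm pseudo-absence settings are literature defaults, not tuned;
unbalanced ANOVA fractions depend on factor order.
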