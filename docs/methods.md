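# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## Grids, network and distances

All layers are square-cell rasters (default 2 m) with 0-based (row, col)
indices, origin top-left, and cell centres at (i + 0.5)·cellsize. The ditch
network is a graph whose nodes are network cells and whose edges join
8-neighbours with metric lengths (cellsize orthogonally, √2·cellsize
diagonally). A dendritic network is a tree rooted at its unique outlet;
masks with loops are accepted with a warning because all distances are
shortest-path distances. Network distances use Dijkstra; distances to
land-use classes are straight-line centre-to-centre (an exact Euclidean
distance transform), since natural and road cells are off-network and a
ditch-path metric to them is undefined. The land-use footprint may extend up
to 200 m beyond the scene to avoid edge truncation; if a class is absent
within that cap the cap value is returned and flagged.

## Terrain covariates

* **Stream burning.** The rasterized network is lowered by `burn_depth`
  (default 1 m) in the DTM so derived flow follows the mapped ditches.
  Exactly the masked cells change, by exactly the burn depth.
* **Hydrological conditioning.** Priority-flood depression filling with an
  epsilon gradient (1e-6 m per cell). Seeded from all boundary cells in the
  generic case; seeded from the outlet alone for single-outlet catchments,
  which guarantees a strictly descending path from every cell to that
  outlet.
* **D8 routing.** Each cell drains to its steepest-descent 8-neighbour
  (drop divided by distance); ties resolve to the first neighbour in a fixed
  clockwise order starting at east, for determinism. Flow leaves the grid
  only at a boundary cell with no lower in-grid neighbour, so on a conditioned
  single-outlet DEM the drained area at the outlet equals the catchment area
  exactly. Unresolved interior pits raise an error listing the cells.
* **Ditch slope** is |Δz between the two terminal nodes of a ditch polyline|
  divided by the polyline length, rasterized identically onto all of that
  ditch's cells; ditches are the unbranched chains between nodes of
  degree ≠ 2.
* **MRVBF** follows the classical multiresolution valley-bottom-flatness
  construction: per scale, flatness is a sigmoid of percent slope against a
  threshold (initial 16 %, halved per step, shape exponent 4), lowness a
  sigmoid of the elevation percentile in a 3-cell radius (threshold 0.4);
  their product maps through a second sigmoid to a valley-flatness score,
  and scales are combined with the standard weight
  w = 1/(1 + (vf/0.4)^(−p)), p = ln((L−0.5)/0.1)/ln 1.5, with threefold
  grid coarsening from the third step. Values < 0.5 mean non-valley,
  > 1.5 large valley floors; both limits are exercised in tests.
* **Northness** is the cosine of the downslope azimuth measured from north,
  computed on a DTM smoothed with a 9×9 mean window — a landscape-scale
  exposure index (+1 north-facing, −1 south-facing, 0 flat) — in contrast to
  the cell-scale gradients used for solar incidence.
* **Solar radiation** integrates direct-beam irradiance over March 1 –
  June 30, sampling every 5 days and hourly (finer sampling changes test
  scenes by well under 1 %). Solar position comes from the standard
  declination/hour-angle formulas; the beam is the configured solar constant
  (default 1360.7, recorded as printed in its source even though the value
  is dimensionally a fluence; it acts as a scale factor only, since all
  covariates are rescaled before modelling) attenuated by
  transmittance^airmass (default 0.701; airmass 1/sin α capped at 38). The
  beam projects on the DSM-derived cell slope/aspect; cells below the DSM
  horizon toward the sun (16 azimuth sectors, 200 m scan radius) receive
  nothing; cells under canopy (DSM − DTM ≥ 1.5 m) are forced to zero because
  the model cannot shade the shading pixel itself. The dust factor
  (100 ppm) is recorded metadata: the lumped transmittance already absorbs
  atmospheric attenuation.

## Spatial autocorrelation on the network

Moran's I is computed per half-open network-distance lag ring (d_prev, d],
default 2 m rings to 100 m, with binary symmetric weights; Z-scores use the
analytical randomization mean −1/(n−1) and variance. The critical distance
is the largest lag of the initial consecutive run with Z > 1.96 (0 if the
first ring is non-significant). Thinning visits cells of each class in
seeded random order and keeps a cell only if every kept cell of its class is
at least the critical distance away; classes are thinned independently.
SSB is the ratio of mean nearest-training-presence network distance of test
presences to that of test absences (1 = unbiased).

Two behaviours of this design are worth knowing:

* **Ring rings fade before a pattern's full diameter.** For presence
  clusters of diameter D, the ring at D contains mostly
  cluster-boundary-straddling pairs, so significance fades slightly before
  D. Likewise, for a random effect whose correlation decays linearly to
  zero at range R (the moving-average construction below), 2 m rings detect
  significance to ~0.8 R; 10 m rings recover R exactly. Recovery
  experiments therefore use 10 m rings and state recovery at the
  correlogram's resolution.
* **Class-wise thinning attenuates smooth-covariate signal and pushes
  SSB above 1.** Where occurrence probability is high, presences are dense
  and are thinned hard while the rare absences all survive (and vice
  versa), compressing the class balance toward 0.5 along any covariate that
  is smooth at scales larger than the critical distance. Because kept
  presences are mutually spaced but absences are not constrained against
  them, held-out presences are never closer than the critical distance to
  training presences while absences can be adjacent, so SSB lands above 1.
  Joint cross-class thinning would change both behaviours; the class-wise
  convention is kept and reported.

## Occurrence models

**GLM.** Binomial likelihood, logit link, fitted by IRLS with step-halving
(the deviance trace is monotone by construction), Wald standard errors and
p-values. All eight covariates enter; no stepwise selection. Coefficients
with p ≥ 0.05 are blanked in report tables. Because covariates are on
[0, 1], |coefficient| doubles as relative importance; a coefficient
magnitude above 15 on that scale triggers an explicit separation error
naming the variable. Agreement with an independent optimizer is checked in
tests to 1e-4.

**Maxent.** The model is the Gibbs distribution q(x) ∝ exp(λ·f(x)) over all
surveyed ditch cells (the background), with features per variable: linear,
quadratic, and — with at least 15 presences — forward/reverse hinges at 8
background quantiles. The fit maximizes the regularized training gain
(mean presence log-density relative to uniform) with per-feature L1
penalties β·sd_presence(f)/√m, where β interpolates (10, 1.0) (30, 0.2)
(100, 0.05) over presence count m for linear/quadratic features and is 0.5
for hinges. Optimization is cyclic coordinate descent: a soft-thresholded
Newton step per feature with backtracking, so the gain trace is
non-decreasing; it stops when a full cycle improves the gain by less than
1e-5 or at 5000 feature updates. Per-variable percent contribution
accumulates the gain improvement credited to each updated feature's
variable, normalized to 100. The logistic output is
expit(λ·f(x) − log Z + H), H the entropy of the fitted background
distribution, bounded in (0, 1). Product features are off by default
(desk-scale speed); all classes are configurable.

**Importance flags.** A variable is "important" when its importance value
(|significant GLM coefficient| or Maxent percent contribution) is strictly
above the median of the pooled value set — pooled across species when a
multi-species report is built, which reproduces the published medians of the
reference survey's tables (2 for GLM, 9 for Maxent).

## Evaluation

Stratified k-fold cross-validation (k = 4) with a floor of more than 10
presences per fold, redrawing the partition up to 100 times. AUC is the
midrank Mann–Whitney statistic; the binarization threshold maximizes
Cohen's kappa over the midpoints of sorted unique held-out scores (choosing
the threshold on training scores is available for leakage-sensitivity
checks); PPV/NPV/overall accuracy come from the resulting confusion matrix,
with undefined ratios reported as NaN, never as 0. Aggregates are mean and
sample sd (n−1) over folds; a failed fold is excluded with a warning.
FP/FN ratio maps divide the per-pixel count of species mispredicted there by
the total species count.

A caveat that matters at synthetic scale: fold-wise CV AUC has a negative
finite-sample bias of roughly p/(2·n_test) under weak signal (the chance
association in a held-out fold is anti-correlated with that in its training
complement), about −0.04 to −0.1 at the few hundred thinned cells a
0.26 km² scene yields, and negligible at real-survey sizes. Weak synthetic
species therefore evaluate at or slightly below 0.5, while a strongly
controlled species on unthinned data reaches AUC ≈ 0.94 under the same
harness.

## Synthetic catchment generator

The DEM is a radial profile away from an east-edge outlet — valley plain
(gentle), slope band (steep), plateau (gentle) — plus band-limited Gaussian
roughness (σ = 3 % of relief) and a raised watershed rim with a notch at the
outlet, rescaled to span [55, 128] m exactly; the outlet is the unique
lowest boundary cell. The network grows by tracing D8 paths from seed cells
(drawn preferentially on high ground) down to the existing network, which
yields a tree by construction; seeding stops when total length per hectare
reaches 119 m/ha (realized within a few percent; the last path is truncated
to the remaining length budget). Land use is {other, natural, road}:
natural patches from quantile-thresholded smooth noise (fractions accurate
to a few percent), roads as one-cell lines every 150 m; the DSM adds
1.5–8 m canopy on a configurable fraction of cells.

Occurrences are Bernoulli with logit = a + Σβx + u on the rescaled
covariates. The random effect u averages white node noise over network
neighbourhoods of radius sac_range/2 and is scaled to sac_sd, giving a
correlation that decays to exactly zero at sac_range (default 30 m,
emulating the 10–30 m critical distances reported for ditch vegetation).
With a prevalence target set, the intercept is solved by root finding.
A single seed forks per-stage generator streams, so scenes and occurrences
are bit-reproducible.

The default three-species community (a valley-bottom hydrophile driven by
Drain and Mrvbf, a road-avoiding heliophilous ruderal, and a slope-avoiding
generalist, with sac_sd 0.5–1.0 and prevalence 0.4–0.45) is chosen so that
realized critical distances fall in the reported 10–30 m regime and thinned
samples stay above the fold floor.

What the generator does **not** emulate: real soil development, management
practices, temporally varying hydrology, detection error, and — most
importantly — realistic spatial extent. A 256×256-cell scene carries ~25×
less network than a real 76 km catchment survey, so after thinning the
per-species sample is hundreds rather than thousands of cells, and
cross-validated discrimination of weakly controlled species is
correspondingly poor. Passing tests demonstrate the correctness and
calibration of the machinery (oracle equivalence, conservation laws,
parameter recovery, null calibration), not that field data of any
particular species would be predictable.

## Problem sizes used

Unit and property tests run on toy grids and path graphs (≤ 500 nodes) and
96×96 scenes; recovery experiments use a 256×256 scene (~1350 ditch cells),
GLM recovery n = 5000, the null cross-validation 50 seeds × 240 cells, and
the end-to-end demo a 256×256 scene with three species.
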