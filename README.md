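# ditchsdm

Species distribution modelling along agricultural drainage (ditch) networks.

Agricultural headwater catchments are drained by dense, tree-structured
networks of man-made ditches that host distinctive plant communities. Where a
species occurs along such a network is strongly shaped by geomorphology —
drained area, distance to the outlet, valley-bottom position, slope, sun
exposure — and by the distance to seed sources (natural land) and dispersal
vectors (roads). `ditchsdm` is a reusable pipeline for testing that
hypothesis at catchment scale. It is aimed at spatial ecologists and
agro-hydrologists who have (or want to simulate) presence/absence records
snapped to a rasterized ditch network plus terrain and land-use grids.

## What it computes

Given a 2 m DTM/DSM, a land-use grid and a rasterized single-outlet ditch
network, the pipeline:

1. **Derives eight covariates per ditch cell** — Doutlet (network distance to
   the outlet), Drain (D8 drained area on the stream-burned DTM, modelled as
   log(m² + 1)), Mrvbf (multiresolution valley-bottom flatness), Northness
   (cos aspect), Slope (per-ditch rise/run), Solar (potential direct beam
   over March–June, zeroed under ≥ 1.5 m canopy), Dnat and Droad (Euclidean
   distance to natural land and roads, footprint extended 200 m) — then
   min–max rescales each to [0, 1] and screens Pearson collinearity at
   |r| ≥ 0.6.
2. **Handles spatial autocorrelation on the network.** For each species it
   builds a Moran's I correlogram over network-distance lag rings
   (default 2–100 m), converts I to randomization Z-scores, finds the
   *critical distance* (end of the initial run of Z > 1.96), and thins
   presences and absences so retained cells are at least that far apart.
   The spatial sorting bias (SSB) of every train/test split is reported.
3. **Fits two occurrence models** per species on the rescaled covariates:
   a binomial-logit GLM (IRLS, Wald tests; coefficients with p ≥ 0.05 are
   blanked in reports) and a presence-background maximum-entropy model
   (linear/quadratic/hinge features, per-feature L1 penalties, coordinate
   descent stopping at a 1e-5 gain change or 5000 iterations; per-variable
   percent contributions summing to 100).
4. **Evaluates by stratified 4-fold cross-validation** — more than 10
   presences per fold — reporting mean ± sd of rank-based AUC (with the
   0.5/0.7/0.9 interpretation bands), the max-kappa threshold, PPV, NPV and
   overall accuracy, and compiles per-pixel false-positive / false-negative
   ratio maps across species.

Because real ditch surveys are rarely shared, the package ships a first-class
synthetic-catchment generator: a DEM with plateau / slope-band / valley-plain
structure (55–128 m relief) and a single outlet, a dendritic network grown to
a target density of 119 m/ha, land-use and canopy layers, and Bernoulli
occurrences whose logit is a known linear function of the covariates plus a
network-ranged random effect — so every estimator can be checked for
parameter recovery.

## Worked example

```sh
ditchsdm run --out demo --size 256 --seed 7
```

generates a 256×256-cell (0.26 km²) catchment with three synthetic species,
runs the full pipeline, and prints the cross-validation table. The SAC
summary (`demo/sac_summary.csv`) for this seed reads:

```
species,critical_distance_m,n_presence,n_absence,frequency_pct,ssb_mean
generalist,20.0,103,110,48.4,2.33
hydrophile,8.0,220,261,45.7,1.55
ruderal,6.0,267,314,46.0,1.72
```

i.e. occurrence autocorrelation dies out within 6–20 m of network distance,
and thinning at that spacing retains a few hundred cells per species. The
best-predicted species, `ruderal` (planted to avoid roads and favour sunlit
cells), scores a mean held-out AUC of 0.59 (GLM) and 0.56 (Maxent) — the
"low" predictive band — and its Maxent contribution row

```
species,Doutlet,Drain,Mrvbf,Northness,Slope,Solar,Dnat,Droad
ruderal,10.3,5.2,6.6,0.7,3.8,57.1,0.1,16.4
```

correctly ranks the two planted drivers (Solar, Droad) first; rows sum
to 100. The weaker species sit at or slightly below AUC 0.5: at a few
hundred thinned cells, fold-wise cross-validated AUC carries a pessimistic
finite-sample bias of roughly p/(2·n_test) (see `docs/methods.md`), which
real surveys an order of magnitude larger do not suffer. On unthinned data
with one dominant covariate the same harness reaches mean AUC ≈ 0.94 for
both models (see the acceptance script below).

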