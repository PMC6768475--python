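# Methods

## The problem

Nest registries for territorial raptors such as the golden eagle (*Aquila
chrysaetos*) are compiled opportunistically: records cluster where surveys
happened, a territory holds several alternate nests of which one is used
per season, and absences are not recorded. `nestdensity` implements a
workflow that turns such presence-only records into a *relative nest-site
density* (RND) surface whose binned values are proportional to nest-site
density, together with the area-adjusted-frequency machinery that
quantifies how many times denser one part of a region is than another.

## Model

The core model is a maximum-entropy presence-background density model.
Given presence feature vectors f(x_1..m) and a background sample
characterizing available environment, it fits the Gibbs distribution
q_λ(x) ∝ exp(λ·f(x)) over the background by maximizing

    G(λ) = (1/m) Σ_presence λ·f(x_i) − log( mean_bg exp(λ·f(x)) ) − Σ_j β_j |λ_j|.

This is equivalent to the likelihood of an inhomogeneous Poisson point
process for the nest locations, so exp(λ·f(x)) is proportional to nest
density — the property the whole evaluation rests on. Features per
covariate are linear, quadratic, and forward/reverse hinges
max(0, ±(x−k)) on covariates scaled to [0, 1] by their background range;
hinge knots sit at equally spaced background quantiles (20 per direction
by default). Per-feature penalties are
β_j = r · β_class(m) · s_j / √m with r the user regularization
multiplier (default 1.0), s_j the feature SD over the presence sample,
and β_class interpolated from the conventional sample-size-keyed default
tables (linear/quadratic: 1.0 at m=10, 0.8 at 30, 0.5 at 100; hinge: 0.5).

The optimizer is cyclic coordinate descent with a prox-Newton
soft-threshold step per coordinate and a step-halving guard; it stops
when the penalized gain changes by < 1e-7 (relative) over a full pass or
after 5,000 passes. Each accepted update's gain increment is traced;
positive increments pooled per covariate and normalized to 100 give the
percent contributions used to reduce models (covariates < 1% are dropped
and the model refitted once).

Two bounded outputs are available for binning: the logistic transform
p = raw·e^H / (1 + raw·e^H), with H the entropy of the raw distribution
over the background (default — the 0–1 equal-interval binning presumes a
bounded score), and a min–max rescaling of the raw output. All
evaluation operates on whichever transform is configured; because both
are strictly monotone in the raw output, bin *ranks* are transform-
invariant.

## Pipeline defaults and why

* **Cell size 120 m** (1.44 ha): the base resolution of the covariate
  rasters.
* **Thinning distance 3 km**: typical nearest-neighbour distance and
  core-use area of nesting golden eagles; collapses a territory's
  alternate nests to one site. The thinning order is status (in-use >
  occupied), then most recent observation, then lexicographic nest id —
  the id tie-break is our addition to make the greedy selection a total
  order, hence deterministic and input-order invariant.
* **Accuracy filter < 120 m**: a record must locate its nest to within
  one cell.
* **Modeled area = union of 20-km circles** on thinned nests, clipped to
  the modeling region: restricts the background to neighbourhoods a
  nesting pair can assess, damping opportunistic survey bias.
* **100,000 background points**, uniform over the modeled area.
* **Focal scales 120 m, 0.5, 1, 2, 3.2, 6.4 km**, mean and SD, circular
  windows by cell-centre membership (the 120-m window is the focal cell
  plus its four edge neighbours). Windows shrink at edges and around
  nodata; SD is the population form. Cell-centre membership and the
  population SD are conventions chosen here and flagged as configurable.
* **Scale selection** by the nest:random mean ratio at 1,000 random
  sites. We score scales by |log ratio| so a strong avoidance covariate
  (ratio ≪ 1, e.g. cropland) can win its family; a literal largest-ratio
  mode is available. A scale is ineligible when fewer than 20% of sample
  locations have non-zero values — we read the sparsity rule as an
  eligibility floor, since discarding dense layers would invert its
  evident anti-sparsity purpose. Both readings are configurable.
* **VIF < 4 within covariate categories**, worst-first iterative removal,
  computed on the pooled nest + random sample; constant layers removed
  first.
* **Regularization grid 0.1, 0.5, 0.75, 1, 2, 3, 4, 5**, tuned by the
  MSE between predicted (Eq. N_p(i) = N_t·p_A(i)·AAF_i) and observed
  held-out bin counts over 10 random 25% holdouts (100 replicate-by-bin
  pairs), ties to the smaller multiplier, with the grid extended by +1
  (up to twice) when the minimum lands on its top. The printed holdout
  rule "25% with replacement" is ambiguous; the default draws the test
  set with replacement and trains on the complement of the unique drawn
  records, and a without-replacement mode is provided.
* **K = 10 equal-interval bins** on [0, 1]; a value on an internal edge
  belongs to the upper bin, 1.0 to the top bin. Bins with zero area and
  zero nests carry an undefined (NaN) AAF and are excluded from MSE and
  the Boyce index. AAFs are reported to 3 decimals and density-ratio
  factors to 1 decimal at display time only; all computation keeps full
  precision (recomputing ratio factors from rounded AAFs reproduces only
  the low-accumulation cells of a rounded report — the rest differ in
  the final decimal).

## Synthetic data: what it emulates, what it does not

The generator produces smooth stationary Gaussian random fields
(white noise smoothed at a stated correlation length, standardized;
land-cover and development layers are rendered as thresholded-and-
smoothed proportions in [0, 1]) in the seven candidate-variable
categories; a log-linear inhomogeneous Poisson territory process
λ(s) = exp(α + Σβ_k z_k(s)); within-territory alternate nests uniform in
a cluster radius smaller than the thinning distance, with mixed status
labels and dates; and optional survey bias as independent thinning of
detections (the true intensity is untouched). Sub-regions are Voronoi
cells of random interior points, an exact partition of the region.

The true nest-generating process of any real population is unknown; the
log-linear Poisson form here is an assumption that makes parameter
recovery testable, not a claim about eagles. The generator does not
simulate dispersal or demography, temporally autocorrelated occupancy,
real terrain physics, or the heavy-tailed clustering of real survey
effort. Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes at realistic sizes — not that any particular
real landscape satisfies those assumptions.

## Numerical choices

* Feature matrices are kept in [0, 1]; the coordinate-descent Hessian is
  floored at 1e-12 and steps capped at ±2 with halving on non-increase.
* Presence-feature SDs are floored at 1e-4 when forming penalties so
  constant features stay penalized.
* Focal SD centres values on the global mean before convolution to avoid
  the catastrophic cancellation of Σx²/n − x̄².
* Random fields whose smoothed amplitude falls below 1e-3 (the
  infinite-correlation-length limit) are returned as constant zero
  rather than standardized numerical noise.
* Buffer circles are polygonized with 32 quadrant segments (area error
  ≈ 0.04%, well inside the 0.5% tolerance used in tests).
* Raster IO uses plain-text ESRI ASCII grids with a JSON manifest for
  layer metadata (category, statistic, scale); geometry is GeoJSON. All
  coordinates are planar metres; there is no geographic-CRS handling.

## Scaled-down study conditions

The suite and the acceptance benchmarks run desk-scale analogs of the
full study: unit tests use 80×80-cell landscapes with 4,000 background
points and proportionally reduced thinning distances; the strong-signal
benchmark uses a 400×400-cell (48×48 km) landscape with one dominant
covariate (coefficient 2.0 on a standardized field), a 1.2-km thinning
distance (a 48-km square cannot hold ~300 sites at 3-km spacing once
intensity concentrates), ~300 thinned nest sites, 10,000 background
points and regularization multiplier 1. The null-calibration benchmark
places 10,000 uniform-random nests on a 200×200-cell surface.

## Known limitations

* Percent contributions are path-dependent (they depend on the
  coordinate-descent update order), as in any gain-trace attribution;
  they are used only for coarse model reduction.
* RND and AAF values are comparable within a region only; the package
  deliberately provides no cross-region standardization.
* Only linear/quadratic/hinge features are implemented (no product,
  threshold or categorical features, no cloglog output, no bias-file
  weighting).
* `evaluate_independent` assumes the test records carry the same schema
  and planar CRS as training records.
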