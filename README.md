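# nestdensity

Relative nest-site density (RND) modelling from presence-only nest
records, for spatial ecologists and conservation planners working with
territorial raptors such as the golden eagle (*Aquila chrysaetos*).

Opportunistically collected nest registries cannot support
presence–absence designs: survey effort is uneven, territories hold
several alternate nests, and absences go unrecorded. `nestdensity`
implements a complete pipeline for such data:

1. **Preprocessing** — reclassify free-text nest status to
   in-use / occupied / unoccupied / unknown, filter to locational
   accuracy < 120 m, and thin records hierarchically (status, then
   recency) to nest *sites* ≥ 3 km apart; build the *modeled area* as the
   union of 20-km circles around thinned nests and sample 100,000
   uniform background points inside it.
2. **Multi-scale covariates** — focal mean and SD of every base raster
   in circular windows of radius 120 m and 0.5, 1, 2, 3.2, 6.4 km.
3. **Variable screening** — per variable, keep the scale with the
   strongest nest:random contrast (1,000 random sites), then remove
   collinear layers within covariate categories until all VIF < 4.
4. **Density model** — an L1-regularized maximum-entropy
   presence-background model with linear, quadratic and hinge features,
   equivalent to an inhomogeneous Poisson point process, so its raw
   output is proportional to nest density; covariates contributing < 1%
   are dropped and the model refitted.
5. **Evaluation** — partition the bounded output into 10 equal-interval
   bins and compute each bin's *area-adjusted frequency*

       AAF_i = p_N(i) / p_A(i),

   the proportion of nests in a bin over the proportion of area in it
   (1 everywhere under random placement, proportional to density in
   general). Predicted bin counts N_p(i) = N_t · p_A(i) · AAF_i drive
   cross-validated tuning of the regularization multiplier (10 × 25%
   holdouts, grid 0.1–5 with upward extension), the Boyce index
   (Spearman correlation of bin rank and AAF rank), sub-region
   evaluation via N_p(i)SR(j) = N_t · p_A(i) · p_SR(j) · AAF_i, and
   independent-data evaluation.
6. **Projection** — apply a fitted model to the rest of its region or to
   an environmentally similar external region, with out-of-range
   covariates clamped to the training range and the clamped fraction
   reported.

A synthetic-landscape module generates autocorrelated covariate fields,
log-linear Poisson nest processes with territory clusters and survey
bias, and sub-region partitions, so the whole pipeline is testable
without confidential nest databases or large raster downloads.

The model is exposed sklearn-style (`MaxentDensityEstimator` with
`fit(X, y)` / `predict`, `VIFFilter` as a feature-selection transformer),
so both compose with scikit-learn pipelines and model selection.

## Worked example

```python
import numpy as np, pandas as pd
import nestdensity as nd
from shapely.geometry import box

grid = nd.GridSpec(n_rows=200, n_cols=200)                      # 24 x 24 km
stack = nd.generate_covariate_grids(
    grid, {"topographic": 2, "landcover": 1}, correlation_length=3000.0, seed=7)
spec = nd.IntensitySpec(coefficients={"topographic_1": 2.0},
                        territory_cluster=(1.0, 400.0))
spec = nd.calibrate_intercept(spec, stack, 1800)
records = nd.simulate_nest_process(spec, stack, seed=8)

nest_set, report = nd.thin_nests(records, 1000.0, with_report=True)
print(f"{report.n_input} records -> {report.n_thinned} nest sites")
area = nd.build_modeled_area(nest_set, radius_m=8000.0, region=box(*grid.bounds))
background = nd.sample_background(area, 10_000, seed=9)

covs = ["topographic_1", "topographic_2", "landcover_1"]
pres = stack.extract_values(nest_set.xy[:, 0], nest_set.xy[:, 1], flag_nodata=False)[covs]
bg = stack.extract_values(background[:, 0], background[:, 1], flag_nodata=False)[covs]
X = pd.concat([pres, bg], ignore_index=True)
y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
est = nd.MaxentDensityEstimator(reg_multiplier=1.0).fit(X, y)
print("percent contributions:", {c: round(v, 1) for c, v in est.contributions_.items()})

surface = nd.predict_rnd(est, stack.subset(covs), mask=area.geometry)
bins = nd.area_adjusted_frequency(
    nd.count_nests_in_bins(nd.bin_rnd_surface(surface, K=10), surface, nest_set.xy))
table = bins.to_frame().round({"area_km2": 1, "p_A": 3, "p_N": 3, "AAF": 3})
table["factor_vs_lowest"] = np.round(nd.aaf_ratio_table(bins.aaf), 1)
print(table.to_string(index=False))
print(f"Boyce index: {nd.boyce_index(bins):.3f}")
```

Output:

```
3524 records -> 156 nest sites
percent contributions: {'topographic_1': 98.9, 'topographic_2': 0.1, 'landcover_1': 1.0}
 bin_low  bin_high  area_km2   p_A  n   p_N   AAF  factor_vs_lowest
     0.0       0.1      72.4 0.126  1 0.006 0.051               1.0
     0.1       0.2      45.9 0.080  1 0.006 0.080               1.6
     0.2       0.3      42.0 0.073  6 0.038 0.528              10.4
     0.3       0.4     140.6 0.244 29 0.186 0.762              14.9
     0.4       0.5     113.1 0.196 28 0.179 0.914              17.9
     0.5       0.6      65.6 0.114 29 0.186 1.632              32.0
     0.6       0.7      96.5 0.168 62 0.397 2.372              46.5
     0.7       0.8       0.0 0.000  0 0.000   NaN               NaN
     0.8       0.9       0.0 0.000  0 0.000   NaN               NaN
     0.9       1.0       0.0 0.000  0 0.000   NaN               NaN
Boyce index: 1.000
```

Reading the table: the model concentrates nests as intended — the
simulated driver (`topographic_1`) takes 98.9% of the fitted gain; the
0.6–0.7 RND bin covers 17% of the modeled area but holds 40% of the
nest sites, a nest density 46.5 times the lowest bin's; AAF rises
monotonically with bin rank (Boyce index 1.000). Bins with no area at
all carry an undefined (NaN) AAF rather than a fabricated zero.

A thin CLI wraps the common steps:

```bash
nestdensity simulate scenario/ --size 200 --expected-nests 300 --seed 1
nestdensity thin scenario/nests.csv --distance 3000
nestdensity fit scenario/ --reg-multiplier 1.0
nestdensity aaf scenario/rnd.asc scenario/nests_thinned.csv
```

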