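import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import nestdensity as nd


@pytest.fixture(scope="session")
def small_grid():
    return nd.GridSpec(n_rows=80, n_cols=80)


@pytest.fixture(scope="session")
def landscape(small_grid):
    """Small synthetic landscape: two topographic fields, one proportion
    layer, and nests driven by topographic_1."""
    stack = nd.generate_covariate_grids(
        small_grid, {"topographic": 2, "landcover": 1}, correlation_length=1500.0,
        seed=11,
    )
    spec = nd.IntensitySpec(coefficients={"topographic_1": 1.5},
                            territory_cluster=(1.5, 300.0))
    spec = nd.calibrate_intercept(spec, stack, 300)
    nests = nd.simulate_nest_process(spec, stack, seed=12)
    return {"grid": small_grid, "stack": stack, "spec": spec, "nests": nests}


@pytest.fixture(scope="session")
def fitted(landscape):
    """A fitted estimator plus its prediction surface, shared across tests."""
    stack = landscape["stack"]
    grid = landscape["grid"]
    nest_set = nd.thin_nests(landscape["nests"], 500.0)
    region = box(*grid.bounds)
    area = nd.build_modeled_area(nest_set, radius_m=5000.0, region=region)
    background = nd.sample_background(area, 4000, seed=13)
    covs = ["topographic_1", "topographic_2"]
    pres = stack.extract_values(nest_set.xy[:, 0], nest_set.xy[:, 1],
                                flag_nodata=False)[covs]
    bg = stack.extract_values(background[:, 0], background[:, 1],
                              flag_nodata=False)[covs]
    X = pd.concat([pres, bg], ignore_index=True)
    y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
    est = nd.MaxentDensityEstimator().fit(X, y)
    surface = nd.predict_rnd(est, stack.subset(covs), mask=area.geometry)
    return {
        "estimator": est,
        "surface": surface,
        "nest_set": nest_set,
        "area": area,
        "background": background,
        "X": X,
        "y": y,
        "covs": covs,
        "stack": stack,
    }
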