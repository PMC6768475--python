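"""End-to-end benchmark scenarios used for calibration checks.

These run the full pipeline on synthetic study conditions sized for a
desktop run:

* a null-calibration scenario — nests placed uniformly at random over a
  surface must yield area-adjusted frequencies of 1 in every bin;
* a strong-signal scenario — a 400x400-cell landscape whose nest
  intensity is driven by one dominant covariate (coefficient 2.0 on a
  standardized field), thinned to ~300 nest sites, fitted with 10,000
  background points at regularization multiplier 1, and evaluated by the
  Boyce index on a 25% held-out nest sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import box

from .evaluation import (
    area_adjusted_frequency,
    bin_rnd_surface,
    boyce_index,
    count_nests_in_bins,
)
from .grid import GridSpec
from .model import MaxentDensityEstimator, RNDSurface, predict_rnd
from .preprocess import build_modeled_area, sample_background, thin_nests
from .synthetic import (
    IntensitySpec,
    calibrate_intercept,
    generate_covariate_grids,
    simulate_nest_process,
)


def null_aaf_profile(seed: int, n_nests: int = 10_000, K: int = 10):
    """AAFs of uniform-random nests over a synthetic RND surface.

    Returns the fitted :class:`BinTable`; under the null every defined
    AAF is 1 up to Monte-Carlo noise.
    """
    rng = np.random.default_rng(seed)
    grid = GridSpec(n_rows=200, n_cols=200)
    stack = generate_covariate_grids(grid, {"topographic": 1},
                                     correlation_length=3000.0, seed=seed)
    vals = 1.0 / (1.0 + np.exp(-stack["topographic_1"]))
    surface = RNDSurface(grid, vals, vals, "logistic")
    b = grid.bounds
    xy = np.column_stack([
        rng.uniform(b[0], b[2], n_nests),
        rng.uniform(b[1] + 1e-9, b[3], n_nests),
    ])
    table = bin_rnd_surface(surface, K=K)
    table = count_nests_in_bins(table, surface, xy)
    return area_adjusted_frequency(table)


def null_aaf_worst_case(seed: int, n_nests: int = 10_000,
                        min_p_A: float = 0.02) -> tuple[float, int]:
    """Worst-case AAF (farthest from 1) among bins holding at least
    ``min_p_A`` of total area under the uniform null."""
    table = null_aaf_profile(seed, n_nests)
    qualifying = table.p_A >= min_p_A
    aafs = table.aaf[qualifying]
    worst = aafs[np.argmax(np.abs(aafs - 1.0))]
    return float(worst), int(n_nests)


def strong_signal_boyce(seed: int) -> tuple[float, int]:
    """One strong-signal replicate: simulate, thin, fit, hold-out Boyce.

    Returns (Boyce index on the 25% held-out nests, thinned nest count).
    """
    grid = GridSpec(n_rows=400, n_cols=400)
    stack = generate_covariate_grids(
        grid, {"topographic": 1, "landcover": 1, "climate": 1},
        correlation_length=4000.0, seed=seed,
    )
    spec = IntensitySpec(coefficients={"topographic_1": 2.0},
                         territory_cluster=(1.0, 600.0))
    spec = calibrate_intercept(spec, stack, 1800)
    nests = simulate_nest_process(spec, stack, seed=seed + 1000)
    nest_set = thin_nests(nests, 1200.0)
    area = build_modeled_area(nest_set, radius_m=20000.0,
                              region=box(*grid.bounds), quad_segs=16)
    rng = np.random.default_rng(seed + 2000)
    n = len(nest_set)
    test_idx = rng.choice(n, size=int(round(0.25 * n)), replace=False)
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    background = sample_background(area, 10_000, seed=seed + 3000)
    covs = ["topographic_1", "landcover_1", "climate_1"]
    xy = nest_set.xy
    pres = stack.extract_values(xy[train_idx, 0], xy[train_idx, 1],
                                flag_nodata=False)[covs]
    bg = stack.extract_values(background[:, 0], background[:, 1],
                              flag_nodata=False)[covs]
    X = pd.concat([pres, bg], ignore_index=True)
    y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
    est = MaxentDensityEstimator(reg_multiplier=1.0).fit(X, y)
    surface = predict_rnd(est, stack.subset(covs), mask=area.geometry)
    table = bin_rnd_surface(surface, K=10)
    table = count_nests_in_bins(table, surface, xy[test_idx])
    table = area_adjusted_frequency(table)
    return boyce_index(table), n


def single_effect_recovery(seed: int) -> float:
    """Spearman correlation between fitted raw intensity and the true
    simulating intensity for a single-linear-effect landscape with at
    least 300 presence records."""
    from scipy.stats import spearmanr

    from .synthetic import intensity_grid

    grid = GridSpec(n_rows=200, n_cols=200)
    stack = generate_covariate_grids(grid, {"topographic": 1},
                                     correlation_length=3000.0, seed=seed)
    spec = IntensitySpec(coefficients={"topographic_1": 1.5},
                         territory_cluster=(0.0, 100.0))
    spec = calibrate_intercept(spec, stack, 400)
    nests = simulate_nest_process(spec, stack, seed=seed + 500)
    if len(nests) < 300:  # Poisson fluctuation guard: top up deterministically
        nests = simulate_nest_process(
            calibrate_intercept(spec, stack, 500), stack, seed=seed + 500
        )
    region = box(*grid.bounds)
    background = sample_background(region, 5000, seed=seed + 600)
    covs = ["topographic_1"]
    pres = stack.extract_values(nests.x.values, nests.y.values,
                                flag_nodata=False)[covs]
    bg = stack.extract_values(background[:, 0], background[:, 1],
                              flag_nodata=False)[covs]
    X = pd.concat([pres, bg], ignore_index=True)
    y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
    est = MaxentDensityEstimator().fit(X, y)
    surface = predict_rnd(est, stack.subset(covs))
    lam = intensity_grid(spec, stack)
    ok = np.isfinite(surface.raw)
    return float(spearmanr(surface.raw[ok], lam[ok]).statistic)
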