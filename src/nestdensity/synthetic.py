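"""Synthetic landscapes and nest processes for testing the density pipeline.

Real nest registries for territorial raptors are confidential and the
continental covariate layers are large downloads, so every downstream stage
is exercised against synthetic data with the same statistical structure:

* smooth, spatially autocorrelated covariate fields organised into the
  seven environment categories used for candidate variables (climate,
  land cover, topographic indices, topographic landforms, vegetation,
  wind/uplift, development);
* a log-linear inhomogeneous Poisson point process for territory (primary
  nest) placement, lambda(s) = exp(intercept + sum_k beta_k * z_k(s));
* within-territory alternate nests scattered inside a cluster radius that
  is smaller than the 3-km thinning distance applied downstream, carrying
  mixed status labels and observation dates;
* optional opportunistic survey bias, implemented as independent thinning
  of detections so the true intensity is untouched.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Polygon, mapping
from shapely.ops import voronoi_diagram

from .grid import CovariateStack, GridSpec, LayerInfo, write_stack

#: candidate-variable categories
CATEGORIES = (
    "climate",
    "landcover",
    "topographic",
    "landform",
    "vegetation",
    "wind_uplift",
    "development",
)

#: categories rendered as "proportion of ..." layers in [0, 1]
_PROPORTION_CATEGORIES = {"landcover", "development"}

STATUS_LABELS = ("in-use", "occupied", "unoccupied", "unknown")


@dataclass
class IntensitySpec:
    """Log-linear intensity for the synthetic nest point process.

    ``coefficients`` maps covariate layer names to effect sizes on the log
    scale; ``intercept`` is the log expected count per cell at covariate
    value zero. ``territory_cluster`` = (mean alternates per territory,
    cluster radius m); the radius must stay below the thinning distance
    used downstream so a territory collapses to one nest site.
    ``bias_field`` is an optional detection-probability grid in [0, 1].
    """

    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    territory_cluster: tuple[float, float] = (2.0, 1500.0)
    bias_field: np.ndarray | None = None


class ConfigurationError(ValueError):
    pass


def _smooth_field(rng: np.random.Generator, grid: GridSpec,
                  correlation_length: float) -> np.ndarray:
    sigma = correlation_length / grid.cell_size
    z = rng.standard_normal(grid.shape)
    f = gaussian_filter(z, sigma=sigma, mode="reflect")
    sd = f.std()
    if sd < 1e-3:
        # infinite-correlation limit: the smoothed amplitude is numerical
        # noise; return the constant field instead of amplifying it
        return np.zeros(grid.shape)
    return (f - f.mean()) / sd


def generate_covariate_grids(
    grid: GridSpec,
    category_plan: Mapping[str, int],
    correlation_length: float = 2000.0,
    seed: int = 0,
) -> CovariateStack:
    """One standardized smooth random field per requested variable.

    Fields are white noise smoothed with a Gaussian kernel whose scale is
    ``correlation_length``, then standardized to mean 0, SD 1. Layers in
    the land-cover and development categories are additionally rendered as
    "proportion of ..." surfaces in [0, 1] by thresholding the field at its
    median and smoothing the indicator at the same correlation length.
    """
    unknown = [c for c in category_plan if c not in CATEGORIES]
    if unknown:
        raise ConfigurationError(
            f"unknown covariate categories {unknown}; known: {list(CATEGORIES)}"
        )
    if correlation_length <= grid.cell_size:
        raise ConfigurationError("correlation_length must exceed the cell size")
    rng = np.random.default_rng(seed)
    stack = CovariateStack(grid)
    for category in CATEGORIES:  # fixed order => seed-stable
        count = int(category_plan.get(category, 0))
        if category in category_plan and count < 1:
            raise ConfigurationError(f"category {category!r} needs count >= 1")
        for i in range(count):
            f = _smooth_field(rng, grid, correlation_length)
            if category in _PROPORTION_CATEGORIES:
                indicator = (f > np.median(f)).astype(float)
                f = gaussian_filter(
                    indicator, sigma=correlation_length / grid.cell_size,
                    mode="reflect",
                )
                f = np.clip(f, 0.0, 1.0)
            name = f"{category}_{i + 1}"
            stack.add(name, f, LayerInfo(base_variable=name, category=category))
    return stack


def intensity_grid(spec: IntensitySpec, stack: CovariateStack) -> np.ndarray:
    """Expected nests per cell, exp(intercept + sum beta_k z_k)."""
    eta = np.full(stack.grid.shape, spec.intercept, dtype=float)
    for name, beta in spec.coefficients.items():
        if name not in stack:
            raise ConfigurationError(f"covariate {name!r} not in stack")
        eta = eta + beta * stack[name]
    lam = np.exp(eta)
    if not np.all(np.isfinite(lam)):
        for name in spec.coefficients:
            if not np.all(np.isfinite(stack[name])):
                raise ConfigurationError(f"covariate {name!r} is non-finite")
        raise ConfigurationError("non-finite intensity (intercept/coefficients too large)")
    return lam


def calibrate_intercept(spec: IntensitySpec, stack: CovariateStack,
                        expected_total: float) -> IntensitySpec:
    """Return a copy of ``spec`` with the intercept set so sum(lambda) equals
    ``expected_total``."""
    base = IntensitySpec(0.0, spec.coefficients, spec.territory_cluster,
                         spec.bias_field)
    total = intensity_grid(base, stack).sum()
    return IntensitySpec(
        float(np.log(expected_total / total)),
        spec.coefficients,
        spec.territory_cluster,
        spec.bias_field,
    )


def simulate_nest_process(
    spec: IntensitySpec,
    stack: CovariateStack,
    grid: GridSpec | None = None,
    seed: int = 0,
    date_range: tuple[str, str] = ("1990-01-01", "2018-12-31"),
    accuracy_range_m: tuple[float, float] = (5.0, 100.0),
) -> pd.DataFrame:
    """Draw nest records from the inhomogeneous Poisson territory process.

    The number of territories (primary nests) is Poisson with mean
    ``sum(lambda)``; locations are cell draws weighted by lambda, jittered
    uniformly within the cell. Each territory gains a Poisson number of
    alternate nests uniformly inside the cluster radius with randomized
    statuses and dates (the primary always carries a breeding status so
    the territory survives status filtering). When ``spec.bias_field`` is
    set, each record is independently retained with the local detection
    probability — survey bias affects what is observed, not the process.

    Returns a DataFrame with columns nest_id, x, y, status, obs_date,
    accuracy_m plus bookkeeping columns territory_id and is_primary.
    """
    grid = grid or stack.grid
    rng = np.random.default_rng(seed)
    lam = intensity_grid(spec, stack)
    n_primary = rng.poisson(lam.sum())
    p = (lam / lam.sum()).ravel()
    cells = rng.choice(lam.size, size=n_primary, p=p)
    rows, cols = np.unravel_index(cells, lam.shape)
    x = grid.origin_x + (cols + rng.uniform(0, 1, n_primary)) * grid.cell_size
    y = grid.origin_y + (grid.n_rows - rows - rng.uniform(0, 1, n_primary)) * grid.cell_size

    t0, t1 = (pd.Timestamp(d) for d in date_range)
    span_days = max((t1 - t0).days, 1)
    mean_alt, radius = spec.territory_cluster

    records: list[dict] = []
    nid = 0
    for t in range(n_primary):
        nid += 1
        records.append(
            {
                "nest_id": f"N{nid:06d}",
                "x": x[t],
                "y": y[t],
                "status": STATUS_LABELS[rng.integers(0, 2)],  # in-use / occupied
                "obs_date": t0 + pd.Timedelta(days=int(rng.integers(0, span_days))),
                "accuracy_m": rng.uniform(*accuracy_range_m),
                "territory_id": t,
                "is_primary": True,
            }
        )
        for _ in range(rng.poisson(mean_alt)):
            nid += 1
            theta = rng.uniform(0, 2 * np.pi)
            r = radius * rng.uniform(0, 1)
            records.append(
                {
                    "nest_id": f"N{nid:06d}",
                    "x": x[t] + r * np.cos(theta),
                    "y": y[t] + r * np.sin(theta),
                    "status": STATUS_LABELS[rng.integers(0, 4)],
                    "obs_date": t0 + pd.Timedelta(days=int(rng.integers(0, span_days))),
                    "accuracy_m": rng.uniform(*accuracy_range_m),
                    "territory_id": t,
                    "is_primary": False,
                }
            )
    nests = pd.DataFrame.from_records(
        records,
        columns=[
            "nest_id", "x", "y", "status", "obs_date", "accuracy_m",
            "territory_id", "is_primary",
        ],
    )
    # alternates scattered past the landscape edge are unobservable
    xmin, ymin, xmax, ymax = grid.bounds
    if len(nests):
        nests = nests[
            (nests.x >= xmin) & (nests.x < xmax)
            & (nests.y > ymin) & (nests.y <= ymax)
        ].reset_index(drop=True)
    if spec.bias_field is not None and len(nests):
        inside = (
            (nests.x >= grid.bounds[0]) & (nests.x < grid.bounds[2])
            & (nests.y > grid.bounds[1]) & (nests.y <= grid.bounds[3])
        )
        keep = np.zeros(len(nests), dtype=bool)
        if inside.any():
            r, c = grid.index_of(nests.x[inside].values, nests.y[inside].values)
            detect = np.asarray(spec.bias_field, dtype=float)[r, c]
            keep[np.flatnonzero(inside.values)] = rng.uniform(0, 1, int(inside.sum())) < detect
        nests = nests[keep].reset_index(drop=True)
    return nests


def partition_subregions(region: Polygon, k: int, seed: int = 0) -> list[Polygon]:
    """Split ``region`` into ``k`` disjoint sub-regions (2 <= k <= 8).

    Voronoi cells of k random interior points, clipped to the region, give
    an exact partition (union = region, disjoint interiors).
    """
    if not 2 <= k <= 8:
        raise ConfigurationError(f"number of sub-regions must be in 2..8, got {k}")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = region.bounds
    pts: list[tuple[float, float]] = []
    while len(pts) < k:
        px, py = rng.uniform(minx, maxx), rng.uniform(miny, maxy)
        from shapely.geometry import Point

        if region.contains(Point(px, py)):
            pts.append((px, py))
    cells = voronoi_diagram(MultiPoint(pts), envelope=region)
    parts = [cell.intersection(region) for cell in cells.geoms]
    parts = [p for p in parts if not p.is_empty]
    return parts


def write_nests_csv(path: str | Path, nests: pd.DataFrame) -> None:
    out = nests[["nest_id", "x", "y", "status", "obs_date", "accuracy_m"]].copy()
    out["obs_date"] = pd.to_datetime(out["obs_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_region_geojson(path: str | Path, polygons: Sequence[Polygon],
                         names: Sequence[str] | None = None) -> None:
    names = names or [f"region_{i + 1}" for i in range(len(polygons))]
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": n},
                "geometry": mapping(p),
            }
            for n, p in zip(names, polygons)
        ],
    }
    Path(path).write_text(json.dumps(fc))


def write_scenario(directory: str | Path, stack: CovariateStack,
                   nests: pd.DataFrame, region: Polygon, seed: int,
                   spec: IntensitySpec) -> None:
    """Persist a full synthetic scenario (rasters, nests, region, manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_stack(
        directory,
        stack,
        manifest_extra={
            "seed": seed,
            "intensity": {
                "intercept": spec.intercept,
                "coefficients": dict(spec.coefficients),
                "territory_cluster": list(spec.territory_cluster),
            },
            "files": {"nests": "nests.csv", "region": "region.geojson"},
        },
    )
    write_nests_csv(directory / "nests.csv", nests)
    write_region_geojson(directory / "region.geojson", [region])
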