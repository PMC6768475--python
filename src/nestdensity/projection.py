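"""Projection of fitted models beyond the modeled area and bin-area reports.

A model trained inside the modeled area (union of 20-km nest buffers) can
be projected to the remaining modeling region, or to an external region
with similar environmental conditions. Covariate values outside the
training range are clamped to it (the model is never evaluated on feature
values it has not seen), and the fraction of clamped cells is reported so
the user can judge how far the projection extrapolates. All area
summaries are computed from cell counts of the projected surfaces, never
from polygon areas, so surfaces and summaries agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .evaluation import DEFAULT_K, DEFAULT_REG_GRID, bin_rnd_surface
from .grid import FOCAL_SCALES_M, CovariateStack
from .model import MaxentDensityEstimator, RNDSurface, predict_rnd


@dataclass(frozen=True)
class PipelineConfig:
    """Every pipeline default in one place."""

    cell_size_m: float = 120.0
    focal_scales_m: tuple = FOCAL_SCALES_M
    thin_distance_m: float = 3000.0
    buffer_radius_m: float = 20000.0
    n_background: int = 100_000
    n_random_sites: int = 1000
    vif_threshold: float = 4.0
    min_nonzero_fraction: float = 0.20
    contribution_cutoff_pct: float = 1.0
    reg_grid: tuple = DEFAULT_REG_GRID
    n_bins: int = DEFAULT_K
    n_cv_replicates: int = 10
    holdout_fraction: float = 0.25
    max_accuracy_m: float = 120.0


@dataclass
class ProjectionReport:
    """Percent of area per RND bin for each labeled surface, with pairwise
    per-bin percentage-point differences."""

    percent_by_bin: pd.DataFrame          # rows = bins, columns = labels
    differences: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    clamp_fractions: dict[str, float] = field(default_factory=dict)


def project_model(
    fit: MaxentDensityEstimator,
    stack: CovariateStack,
    target_mask=None,
    transform: str | None = None,
) -> tuple[RNDSurface, dict]:
    """Predict the RND surface on a target area with training scaling.

    Out-of-range covariates are clamped to the training [min, max]; the
    returned report dict carries the clamped-cell fraction. Restricted to
    the training mask this reproduces training predictions exactly, since
    clamping is already part of feature scaling.
    """
    report: dict = {}
    surface = predict_rnd(fit, stack, mask=target_mask, transform=transform,
                          clamp_report=report)
    return surface, report


def area_by_bin_summary(
    surfaces: Mapping[str, tuple[RNDSurface, object]],
    K: int = DEFAULT_K,
) -> ProjectionReport:
    """Percent of area in each RND bin per labeled (surface, mask) pair.

    ``mask`` may be None to use the surface's full valued extent. Each
    column sums to 100.
    """
    if not surfaces:
        raise ValueError("at least one surface is required")
    pct = {}
    for label, (surface, mask) in surfaces.items():
        bins = bin_rnd_surface(surface, mask=mask, K=K)
        pct[label] = 100.0 * bins.p_A
    edges = np.linspace(0, 1, K + 1)
    df = pd.DataFrame(pct, index=pd.IntervalIndex.from_breaks(np.round(edges, 3),
                                                              closed="left"))
    labels = list(pct)
    diffs = {
        (a, b): (df[a] - df[b]).to_numpy()
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }
    return ProjectionReport(percent_by_bin=df, differences=diffs)
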