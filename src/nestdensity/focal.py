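"""Multi-scale focal statistics over circular neighbourhoods.

Because the spatial scale at which nest-site selection responds to the
environment is unknown a priori, every base covariate is summarised by its
focal mean and focal standard deviation in circular windows at six radii:
120 m, 0.5, 1.0, 2.0, 3.2 and 6.4 km. A cell belongs to the window of a
focal cell when the distance between cell centres is at most the radius
(at 120-m resolution the 120-m window is the focal cell plus its four edge
neighbours). Windows shrink at the raster edge and around nodata cells —
statistics are computed over the valid cells actually in the window, so no
data is fabricated at region borders. The SD is the population form
(divide by the window count n).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve

from .grid import FOCAL_SCALES_M, CovariateStack, LayerInfo, layer_name

_VALID_STATS = ("mean", "sd")


def disk_kernel(radius_m: float, cell_size: float) -> np.ndarray:
    """0/1 kernel of cells whose centres are within ``radius_m`` of the
    focal cell centre."""
    if radius_m < cell_size / 2:
        raise ValueError(
            f"radius {radius_m} m is below half a cell ({cell_size / 2} m)"
        )
    r_cells = int(np.floor(radius_m / cell_size))
    offs = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return ((dx**2 + dy**2) * cell_size**2 <= radius_m**2 + 1e-9).astype(float)


def focal_statistic(
    values: np.ndarray,
    radius_m: float,
    stat: str,
    cell_size: float = 120.0,
) -> np.ndarray:
    """Per-cell mean or SD over the circular window; NaN treated as nodata
    and excluded; result NaN where the window holds no valid cell."""
    if stat not in _VALID_STATS:
        raise ValueError(f"stat must be one of {_VALID_STATS}, got {stat!r}")
    values = np.asarray(values, dtype=float)
    kernel = disk_kernel(radius_m, cell_size)
    valid = np.isfinite(values).astype(float)
    shift = 0.0
    if stat == "sd" and valid.any():
        # centre on the global mean: SD is shift-invariant and this kills
        # the catastrophic cancellation of sum(x^2)/n - mean^2
        shift = np.nanmean(values)
    v0 = np.where(np.isfinite(values), values - shift, 0.0)
    n = convolve(valid, kernel, mode="constant", cval=0.0)
    s = convolve(v0, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / n, np.nan)
        if stat == "mean":
            return mean
        s2 = convolve(v0**2, kernel, mode="constant", cval=0.0)
        var = np.where(n > 0, s2 / n - mean**2, np.nan)
    return np.sqrt(np.clip(var, 0.0, None))


def build_multiscale_stack(
    base: CovariateStack,
    radii: tuple[float, ...] = FOCAL_SCALES_M,
    stats: tuple[str, ...] = _VALID_STATS,
) -> CovariateStack:
    """Focal mean and SD of every base layer at every radius.

    Produces ``len(base) * len(radii) * len(stats)`` layers named
    ``{base}__{stat}__{radius}`` with metadata recording the base variable,
    category, statistic and scale.
    """
    if not radii:
        raise ValueError("at least one focal radius is required")
    out = CovariateStack(base.grid)
    for name, values, info in base.iter_layers():
        for radius in radii:
            for stat in stats:
                out.add(
                    layer_name(info.base_variable, stat, radius),
                    focal_statistic(values, radius, stat, base.grid.cell_size),
                    LayerInfo(
                        base_variable=info.base_variable,
                        category=info.category,
                        statistic=stat,
                        scale_radius_m=float(radius),
                    ),
                )
    return out


def extract_values(stack: CovariateStack, x, y, flag_nodata: bool = True):
    """Sample every layer of ``stack`` at point locations.

    Thin wrapper over :meth:`CovariateStack.extract_values`; errors when a
    point falls outside the grid extent.
    """
    return stack.extract_values(x, y, flag_nodata=flag_nodata)
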