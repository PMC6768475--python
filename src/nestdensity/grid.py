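"""Planar raster grids and the multi-layer covariate stack.

All geometry is in planar map units (metres); the base cell size is 120 m
(1.44 ha per cell), the resolution at which the density models operate.
Rasters are stored as dense ``float64`` arrays with ``NaN`` for nodata and
serialized as ESRI ASCII grids (plain text), one layer per file, with layer
metadata carried in a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

NODATA = -9999.0

#: the six circular-neighbourhood radii (m) used for focal statistics
FOCAL_SCALES_M = (120, 500, 1000, 2000, 3200, 6400)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid in a projected CRS.

    ``origin_x, origin_y`` locate the lower-left corner; row 0 of the data
    array is the northernmost row.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 120.0
    n_rows: int = 100
    n_cols: int = 100
    crs_label: str = "local-planar-m"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def cell_area_km2(self) -> float:
        return self.cell_area_m2 / 1e6

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of x and y cell-centre coordinates, shaped like the grid."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point.

        A cell owns the half-open interval [x0, x0 + cell) horizontally and
        (y0 - cell, y0] vertically (y0 the cell's upper edge), so points on
        internal edges resolve deterministically. Points outside the extent
        raise ``ValueError`` listing the offenders.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        fx = (x - self.origin_x) / self.cell_size
        fy = (y - self.origin_y) / self.cell_size
        col = np.floor(fx).astype(int)
        row = self.n_rows - np.ceil(fy).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            pts = list(zip(np.atleast_1d(x)[np.atleast_1d(bad)][:5],
                           np.atleast_1d(y)[np.atleast_1d(bad)][:5]))
            raise ValueError(
                f"{int(np.sum(bad))} point(s) outside grid extent {self.bounds}; "
                f"first offenders: {pts}"
            )
        return row, col


@dataclass(frozen=True)
class LayerInfo:
    """Provenance of one covariate layer."""

    base_variable: str
    category: str = "uncategorized"
    statistic: str = "base"  # "base", "mean" or "sd"
    scale_radius_m: float = 120.0


def layer_name(base: str, stat: str, radius_m: float) -> str:
    """Canonical ``{base}__{stat}__{radius_m}`` layer name."""
    return f"{base}__{stat}__{int(round(radius_m))}"


@dataclass
class CovariateStack:
    """Named raster layers sharing one :class:`GridSpec`."""

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    info: dict[str, LayerInfo] = field(default_factory=dict)

    def add(self, name: str, values: np.ndarray, info: LayerInfo) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} has shape {values.shape}, grid is {self.grid.shape}"
            )
        self.layers[name] = values
        self.info[name] = info

    def __len__(self) -> int:
        return len(self.layers)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def names(self) -> list[str]:
        return list(self.layers)

    def categories(self) -> set[str]:
        return {i.category for i in self.info.values()}

    def subset(self, names: list[str]) -> "CovariateStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return CovariateStack(
            self.grid,
            {n: self.layers[n] for n in names},
            {n: self.info[n] for n in names},
        )

    def iter_layers(self) -> Iterator[tuple[str, np.ndarray, LayerInfo]]:
        for n, v in self.layers.items():
            yield n, v, self.info[n]

    def extract_values(self, x, y, flag_nodata: bool = True):
        """Sample every layer at point locations (containing-cell lookup).

        Returns a pandas DataFrame (rows = points, columns = layers). Rows
        touching nodata cells keep NaN and are flagged in the boolean
        ``_nodata`` column when ``flag_nodata`` is set.
        """
        import pandas as pd

        row, col = self.grid.index_of(x, y)
        data = {n: v[row, col] for n, v in self.layers.items()}
        df = pd.DataFrame(data)
        if flag_nodata:
            df["_nodata"] = df.isna().any(axis=1)
        return df


# ---------------------------------------------------------------------------
# plain-text raster IO (ESRI ASCII grid)

def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = np.where(np.isfinite(values), values, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x}\n"
        f"yllcorner {grid.origin_y}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        hdr: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    grid = GridSpec(
        origin_x=hdr["xllcorner"],
        origin_y=hdr["yllcorner"],
        cell_size=hdr["cellsize"],
        n_rows=int(hdr["nrows"]),
        n_cols=int(hdr["ncols"]),
    )
    nod = hdr.get("nodata_value", NODATA)
    values = np.where(values == nod, np.nan, values)
    return grid, values


def write_stack(directory: str | Path, stack: CovariateStack,
                manifest_extra: Mapping | None = None) -> Path:
    """Write every layer as ``<name>.asc`` plus a ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, values, info in stack.iter_layers():
        fname = f"{name}.asc"
        write_ascii_grid(directory / fname, stack.grid, values)
        entries.append(
            {
                "name": name,
                "file": fname,
                "base_variable": info.base_variable,
                "category": info.category,
                "statistic": info.statistic,
                "scale_radius_m": info.scale_radius_m,
            }
        )
    manifest = {
        "grid": {
            "origin_x": stack.grid.origin_x,
            "origin_y": stack.grid.origin_y,
            "cell_size": stack.grid.cell_size,
            "n_rows": stack.grid.n_rows,
            "n_cols": stack.grid.n_cols,
            "crs_label": stack.grid.crs_label,
        },
        "layers": entries,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_stack(directory: str | Path) -> CovariateStack:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    grid = GridSpec(**manifest["grid"])
    stack = CovariateStack(grid)
    for entry in manifest["layers"]:
        _, values = read_ascii_grid(directory / entry["file"])
        stack.add(
            entry["name"],
            values,
            LayerInfo(
                base_variable=entry["base_variable"],
                category=entry["category"],
                statistic=entry["statistic"],
                scale_radius_m=entry["scale_radius_m"],
            ),
        )
    return stack
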