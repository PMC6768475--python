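"""Nest-record preprocessing: status reclassification, spatial thinning,
modeled-area construction and background sampling.

Opportunistic nest registries carry redundant records: territories hold
several alternate nests and the same nest is resurveyed across years. To
obtain (approximately) independent nest *sites*, records are reduced to
breeding-relevant statuses, filtered to locational accuracy better than the
raster resolution, and thinned so no two retained nests lie within 3 km of
each other, keeping for every cluster the most recent record of the highest
status. The model is then trained inside the *modeled area* — the union of
20-km circles around the thinned nests — which confines the background
sample to surveyed neighbourhoods and damps opportunistic survey bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, mapping
from shapely.ops import unary_union


class NestStatus(IntEnum):
    """Nest status; higher rank outranks lower during thinning."""

    UNKNOWN = 0
    UNOCCUPIED = 1
    OCCUPIED = 2
    IN_USE = 3


#: default synonym table for raw status labels (lower-cased, stripped)
DEFAULT_STATUS_SYNONYMS: dict[str, NestStatus] = {
    "in-use": NestStatus.IN_USE,
    "in use": NestStatus.IN_USE,
    "in_use": NestStatus.IN_USE,
    "active": NestStatus.IN_USE,
    "occupied": NestStatus.OCCUPIED,
    "pair present": NestStatus.OCCUPIED,
    "unoccupied": NestStatus.UNOCCUPIED,
    "inactive": NestStatus.UNOCCUPIED,
    "empty": NestStatus.UNOCCUPIED,
    "unknown": NestStatus.UNKNOWN,
}

MAX_ACCURACY_M = 120.0
DEFAULT_THIN_DISTANCE_M = 3000.0
DEFAULT_BUFFER_RADIUS_M = 20000.0


class EmptyNestSetError(ValueError):
    """No records survive the status/accuracy filters."""


def reclassify_status(raw_label: str,
                      synonyms: Mapping[str, NestStatus] | None = None) -> NestStatus:
    """Map a free-text status label onto the four-level status enum.

    Unmapped labels become ``UNKNOWN`` (total function). A user synonym
    table extends/overrides the defaults.
    """
    table = dict(DEFAULT_STATUS_SYNONYMS)
    if synonyms:
        table.update({k.strip().lower(): NestStatus(v) for k, v in synonyms.items()})
    if raw_label is None:
        return NestStatus.UNKNOWN
    return table.get(str(raw_label).strip().lower(), NestStatus.UNKNOWN)


@dataclass
class NestSet:
    """Thinned breeding nest sites: pairwise >= ``thin_distance_m`` apart."""

    records: pd.DataFrame
    thin_distance_m: float

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float)


@dataclass
class ThinningReport:
    n_input: int
    n_eligible: int
    n_thinned: int
    status_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _prepare(records: pd.DataFrame,
             synonyms: Mapping[str, NestStatus] | None = None) -> pd.DataFrame:
    df = records.copy()
    df["status_rank"] = [int(reclassify_status(s, synonyms)) for s in df["status"]]
    df["obs_date"] = pd.to_datetime(df["obs_date"])
    return df


def thin_nests(
    records: pd.DataFrame,
    d_thin_m: float = DEFAULT_THIN_DISTANCE_M,
    max_accuracy_m: float = MAX_ACCURACY_M,
    synonyms: Mapping[str, NestStatus] | None = None,
    with_report: bool = False,
) -> NestSet | tuple[NestSet, ThinningReport]:
    """Greedy hierarchical thinning of nest records to independent sites.

    Records are filtered to accuracy < ``max_accuracy_m`` and breeding
    statuses (in-use or occupied), ranked by status (in-use first), then
    observation date (most recent first), then nest_id (lexicographic
    tie-break for reproducibility), and kept greedily whenever at least
    ``d_thin_m`` from every already-kept record. The result is independent
    of the input row order and idempotent.
    """
    df = _prepare(records, synonyms)
    status_counts = (
        df["status_rank"].map(lambda r: NestStatus(r).name).value_counts().to_dict()
    )
    eligible = df[
        (df["accuracy_m"] < max_accuracy_m)
        & (df["status_rank"] >= NestStatus.OCCUPIED)
    ]
    if eligible.empty:
        raise EmptyNestSetError(
            f"no eligible records: {len(records)} input, status tally {status_counts}, "
            f"{int((df['accuracy_m'] >= max_accuracy_m).sum())} failed the "
            f"accuracy filter (<{max_accuracy_m} m)"
        )
    ranked = eligible.sort_values(
        ["status_rank", "obs_date", "nest_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    xy = ranked[["x", "y"]].to_numpy(dtype=float)
    kept_idx: list[int] = []
    kept_xy: list[np.ndarray] = []
    tree: cKDTree | None = None
    for i in range(len(ranked)):
        if tree is None:
            ok = True
        else:
            ok = not tree.query_ball_point(xy[i], r=d_thin_m * (1 - 1e-12))
        if ok:
            kept_idx.append(i)
            kept_xy.append(xy[i])
            tree = cKDTree(np.vstack(kept_xy))
    thinned = ranked.iloc[kept_idx].drop(columns=["status_rank"]).reset_index(drop=True)
    result = NestSet(thinned, d_thin_m)
    if with_report:
        return result, ThinningReport(
            n_input=len(records),
            n_eligible=len(eligible),
            n_thinned=len(thinned),
            status_counts=status_counts,
        )
    return result


@dataclass
class ModeledArea:
    """Union of buffer circles around thinned nests, clipped to the region."""

    geometry: Polygon
    buffer_radius_m: float
    area_km2: float
    pct_of_region: float | None = None

    def to_geojson(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "type": "Feature",
                    "properties": {
                        "buffer_radius_m": self.buffer_radius_m,
                        "area_km2": self.area_km2,
                        "pct_of_region": self.pct_of_region,
                    },
                    "geometry": mapping(self.geometry),
                }
            )
        )


def build_modeled_area(
    nests: NestSet | pd.DataFrame,
    radius_m: float = DEFAULT_BUFFER_RADIUS_M,
    region: Polygon | None = None,
    quad_segs: int = 32,
) -> ModeledArea:
    """Union of ``radius_m`` circles on nest sites, intersected with the
    modeling region when given; reports area and percent of region."""
    df = nests.records if isinstance(nests, NestSet) else nests
    if df.empty:
        raise EmptyNestSetError("cannot build a modeled area from zero nests")
    circles = [
        Point(x, y).buffer(radius_m, quad_segs=quad_segs)
        for x, y in df[["x", "y"]].to_numpy(dtype=float)
    ]
    geom = unary_union(circles)
    pct = None
    if region is not None:
        geom = geom.intersection(region)
        pct = 100.0 * geom.area / region.area
    return ModeledArea(geom, radius_m, geom.area / 1e6, pct)


def sample_background(
    area: ModeledArea | Polygon,
    n: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """``n`` points uniform over the modeled area (rejection sampling).

    Returns an (n, 2) array; deterministic for a fixed seed.
    """
    geom = area.geometry if isinstance(area, ModeledArea) else area
    if n < 1:
        raise ValueError("n must be >= 1")
    if geom.is_empty or geom.area == 0:
        raise ValueError("modeled area has zero extent")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = geom.bounds
    out = np.empty((0, 2))
    # expected acceptance rate; draw in batches
    rate = max(geom.area / ((maxx - minx) * (maxy - miny)), 1e-6)
    while len(out) < n:
        m = int((n - len(out)) / rate * 1.2) + 16
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(geom, xs, ys)
        out = np.vstack([out, np.column_stack([xs[keep], ys[keep]])])
    return out[:n]
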