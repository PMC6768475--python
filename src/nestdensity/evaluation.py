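"""Area-adjusted frequencies and density evaluation.

The bounded model output (RND) is partitioned into K equal-interval bins
(default 10: 0.0-0.1, ..., 0.9-1.0). With a_i the area in bin i,
A = sum a_i, n_i the nest count in bin i and N = sum n_i, the
area-adjusted frequency of a bin is

    AAF_i = p_N(i) / p_A(i),   p_A(i) = a_i / A,  p_N(i) = n_i / N.

AAF equals 1 for every bin when nests are placed at random (no relation to
the environment), and is proportional to nest-site density, so AAF ratios
between bins quantify how many times denser one bin is than another. The
expected number of nests from a test sample of size N_t falling in bin i is

    N_p(i) = N_t * p_A(i) * AAF_i,

and for a sub-region j holding a proportion p_SR(j) of the modeled area

    N_p(i)SR(j) = N_t * p_A(i) * p_SR(j) * AAF_i,

which marginalizes back over sub-regions to the whole-area prediction.

The same machinery drives regularization tuning: the multiplier is chosen
to minimize the mean squared error between predicted and observed held-out
bin counts over 10 random 25% holdouts, and the Boyce index (Spearman rank
correlation between bin rank and AAF rank) summarizes calibration.

Bins whose area and count are both zero have an undefined AAF (NaN); they
are excluded from MSE and the Boyce index. A value exactly on an internal
bin edge belongs to the upper bin; 1.0 belongs to the top bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.stats import spearmanr
from shapely.geometry import Point
from shapely.ops import unary_union

from .model import MaxentDensityEstimator, RNDSurface, predict_rnd
from .preprocess import (
    DEFAULT_BUFFER_RADIUS_M,
    DEFAULT_THIN_DISTANCE_M,
    NestSet,
    thin_nests,
)

DEFAULT_K = 10
DEFAULT_REG_GRID = (0.1, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_N_REPLICATES = 10
DEFAULT_HOLDOUT_FRACTION = 0.25


def bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin of each value: [e_i, e_{i+1}) with the top edge inclusive."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


@dataclass
class BinTable:
    """Per-bin areas, nest counts, proportions and AAFs."""

    edges: np.ndarray
    area: np.ndarray                   # a_i, km^2
    counts: np.ndarray | None = None   # n_i
    aaf: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.edges) - 1

    @property
    def A(self) -> float:
        return float(self.area.sum())

    @property
    def N(self) -> int:
        return int(self.counts.sum()) if self.counts is not None else 0

    @property
    def p_A(self) -> np.ndarray:
        return self.area / self.A

    @property
    def p_N(self) -> np.ndarray:
        if self.counts is None or self.counts.sum() == 0:
            raise ValueError("no nest counts in this bin table")
        return self.counts / self.counts.sum()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_low": self.edges[:-1],
                "bin_high": self.edges[1:],
                "area_km2": self.area,
                "p_A": self.p_A,
            }
        )
        if self.counts is not None:
            df["n"] = self.counts
            df["p_N"] = self.counts / max(self.counts.sum(), 1)
        if self.aaf is not None:
            df["AAF"] = self.aaf
        return df


def bin_rnd_surface(rnd: RNDSurface, mask=None, K: int = DEFAULT_K) -> BinTable:
    """Bin areas of an RND surface: a_i = in-bin cell count x cell area.

    ``mask`` optionally restricts to a polygon (cell-centre membership);
    by default all cells carrying values are used.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    values = rnd.values
    sel = np.isfinite(values)
    if mask is not None:
        xs, ys = rnd.grid.cell_centers()
        sel &= shapely.contains_xy(mask, xs.ravel(), ys.ravel()).reshape(rnd.grid.shape)
    vals = values[sel]
    if vals.size == 0:
        raise ValueError("mask selects no valued cells")
    edges = np.linspace(0.0, 1.0, K + 1)
    idx = bin_index(vals, edges)
    counts = np.bincount(idx, minlength=K)
    return BinTable(edges=edges, area=counts * rnd.grid.cell_area_km2)


def count_nests_in_bins(bins: BinTable, rnd: RNDSurface, xy: np.ndarray) -> BinTable:
    """Attach nest counts: each nest falls in the bin of its cell's RND."""
    xy = np.asarray(xy, dtype=float)
    row, col = rnd.grid.index_of(xy[:, 0], xy[:, 1])
    v = rnd.values[row, col]
    ok = np.isfinite(v)
    idx = bin_index(v[ok], bins.edges)
    counts = np.bincount(idx, minlength=bins.K)
    return BinTable(edges=bins.edges, area=bins.area, counts=counts,
                    flags={"n_outside_mask": int(np.sum(~ok))})


def area_adjusted_frequency(bins: BinTable) -> BinTable:
    """AAF_i = p_N(i)/p_A(i); NaN where a bin has neither area nor nests."""
    if bins.counts is None:
        raise ValueError("bin table has no nest counts")
    if bins.N == 0:
        raise ValueError("total nest count is zero")
    a, n = bins.area, bins.counts
    impossible = (a == 0) & (n > 0)
    if impossible.any():
        raise ValueError(
            f"nests recorded in zero-area bins {np.flatnonzero(impossible).tolist()}"
        )
    p_A = bins.p_A
    p_N = n / bins.N
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(a > 0, p_N / np.where(p_A > 0, p_A, np.nan), np.nan)
    return BinTable(edges=bins.edges, area=a, counts=n, aaf=aaf, flags=dict(bins.flags))


def predicted_bin_counts(N_t: float, p_A: np.ndarray, aaf: np.ndarray) -> pd.DataFrame:
    """Predicted test-sample counts per bin, N_p(i) = N_t p_A(i) AAF_i.

    Undefined-AAF bins contribute 0 and are flagged in the ``defined``
    column.
    """
    p_A = np.asarray(p_A, dtype=float)
    aaf = np.asarray(aaf, dtype=float)
    if p_A.shape != aaf.shape:
        raise ValueError("p_A and AAF must have the same length")
    if N_t < 0 or np.any(p_A < 0) or np.any(aaf[np.isfinite(aaf)] < 0):
        raise ValueError("negative inputs")
    defined = np.isfinite(aaf)
    Np = np.where(defined, N_t * p_A * np.where(defined, aaf, 0.0), 0.0)
    return pd.DataFrame({"N_p": Np, "defined": defined})


def subregion_predicted_counts(
    N_t: float, p_A: np.ndarray, p_SR: np.ndarray, aaf: np.ndarray
) -> pd.DataFrame:
    """Predicted counts per (bin i, sub-region j):
    N_p(i)SR(j) = N_t p_A(i) p_SR(j) AAF_i. Marginal over j recovers the
    whole-area prediction."""
    p_SR = np.asarray(p_SR, dtype=float)
    if abs(p_SR.sum() - 1.0) > 1e-9:
        raise ValueError(f"sub-region proportions sum to {p_SR.sum()}, not 1")
    base = predicted_bin_counts(N_t, p_A, aaf)["N_p"].to_numpy()
    mat = np.outer(base, p_SR)
    return pd.DataFrame(
        mat, columns=[f"SR{j + 1}" for j in range(len(p_SR))]
    ).rename_axis("bin")


def boyce_index(bins: BinTable) -> float:
    """Spearman rank correlation of bin rank vs AAF; NaN-AAF bins excluded;
    undefined (NaN) with fewer than 3 defined bins."""
    if bins.aaf is None:
        raise ValueError("bin table has no AAF column")
    defined = np.isfinite(bins.aaf)
    if defined.sum() < 3:
        return float("nan")
    rho, _ = spearmanr(np.arange(bins.K)[defined], bins.aaf[defined])
    return float(rho)


def aaf_ratio_table(aaf: Sequence[float]) -> np.ndarray:
    """Density of each bin as a multiple of the lowest bin: AAF_i / AAF_1.

    The lowest bin maps to 1.0 by construction; undefined when the lowest
    bin's AAF is missing or zero. Values are full precision — round only
    for display.
    """
    aaf = np.asarray(aaf, dtype=float)
    if not np.isfinite(aaf[0]) or aaf[0] == 0:
        return np.full_like(aaf, np.nan)
    return aaf / aaf[0]


# ---------------------------------------------------------------------------
# regularization tuning


@dataclass
class CVResult:
    """Per-multiplier cross-validated MSE and the selected value."""

    table: pd.DataFrame            # columns: reg_multiplier, mse, n_pairs
    selected: float
    n_replicates: int
    holdout_fraction: float
    extended: bool = False

    def mse_of(self, reg: float) -> float:
        row = self.table[self.table.reg_multiplier == reg]
        return float(row.mse.iloc[0])


def _holdout_split(rng: np.random.Generator, n: int, fraction: float,
                   with_replacement: bool) -> tuple[np.ndarray, np.ndarray]:
    k = max(int(round(fraction * n)), 1)
    if with_replacement:
        test = rng.integers(0, n, size=k)
        train = np.setdiff1d(np.arange(n), np.unique(test))
    else:
        test = rng.permutation(n)[:k]
        train = np.setdiff1d(np.arange(n), test)
    return train, test


def crossvalidate_regularization(
    fit_fn: Callable[[np.ndarray, float], RNDSurface],
    nest_xy: np.ndarray,
    reg_grid: Sequence[float] = DEFAULT_REG_GRID,
    n_rep: int = DEFAULT_N_REPLICATES,
    holdout: float = DEFAULT_HOLDOUT_FRACTION,
    seed: int = 0,
    K: int = DEFAULT_K,
    with_replacement: bool = True,
    max_extensions: int = 2,
) -> CVResult:
    """Tune the regularization multiplier by cross-validated bin-count MSE.

    ``fit_fn(train_xy, reg)`` must fit the model on the training nests and
    return the resulting :class:`RNDSurface`. For each multiplier and each
    of ``n_rep`` replicates, 25% of the nests are withheld (drawn with
    replacement by default; the training set is the complement of the
    unique drawn records), the surface is binned, AAFs come from the
    training nests, and held-out counts are predicted with N_t = held-out
    total. The MSE over all replicate-by-bin pairs selects the multiplier
    (ties to the smaller value). When the minimum lands on the largest grid
    value the grid is extended upward by +1 steps, up to
    ``max_extensions`` times.
    """
    nest_xy = np.asarray(nest_xy, dtype=float)
    n = len(nest_xy)
    if n < 40:
        raise ValueError(f"need >= 40 nests for stable holdout bins, got {n}")
    splits = []
    rng = np.random.default_rng(seed)
    for _ in range(n_rep):
        splits.append(_holdout_split(rng, n, holdout, with_replacement))

    def evaluate(reg: float) -> tuple[float, int]:
        sq_errors: list[float] = []
        for train, test in splits:
            surface = fit_fn(nest_xy[train], reg)
            bins = bin_rnd_surface(surface, K=K)
            bins = count_nests_in_bins(bins, surface, nest_xy[train])
            try:
                bins = area_adjusted_frequency(bins)
            except ValueError:
                warnings.warn("replicate skipped: no training nests binned")
                continue
            test_bins = count_nests_in_bins(
                BinTable(edges=bins.edges, area=bins.area), surface, nest_xy[test]
            )
            pred = predicted_bin_counts(len(test), bins.p_A, bins.aaf)
            defined = pred["defined"].to_numpy()
            obs = test_bins.counts
            err = (pred["N_p"].to_numpy()[defined] - obs[defined]) ** 2
            sq_errors.extend(err.tolist())
        if not sq_errors:
            return float("inf"), 0
        return float(np.mean(sq_errors)), len(sq_errors)

    grid = sorted(float(r) for r in reg_grid)
    rows = [(r, *evaluate(r)) for r in grid]
    extended = False
    extensions = 0
    while extensions < max_extensions:
        best = min(rows, key=lambda t: (t[1], t[0]))
        if best[0] != max(r for r, *_ in rows):
            break
        nxt = max(r for r, *_ in rows) + 1.0
        rows.append((nxt, *evaluate(nxt)))
        extended = True
        extensions += 1
    table = pd.DataFrame(rows, columns=["reg_multiplier", "mse", "n_pairs"])
    best = min(rows, key=lambda t: (t[1], t[0]))
    return CVResult(
        table=table,
        selected=best[0],
        n_replicates=n_rep,
        holdout_fraction=holdout,
        extended=extended,
    )


# ---------------------------------------------------------------------------
# independent evaluation


def evaluate_independent(
    test_nests: pd.DataFrame,
    training_nests: NestSet | pd.DataFrame,
    rnd: RNDSurface,
    training_aaf: BinTable,
    d_thin_m: float = DEFAULT_THIN_DISTANCE_M,
    buffer_m: float = DEFAULT_BUFFER_RADIUS_M,
) -> pd.DataFrame:
    """Evaluate a fitted surface against nests not used in training.

    Test records pass the usual status/accuracy filters, are thinned
    against themselves *and* the training nests, bin-area proportions are
    recomputed over the union of ``buffer_m`` circles on the surviving
    test nests, and predictions use the training AAFs with N_t = number of
    surviving test nests. Returns a per-bin frame with observed, predicted
    and observed-minus-predicted counts.
    """
    train_df = (training_nests.records if isinstance(training_nests, NestSet)
                else training_nests)
    thinned = thin_nests(test_nests, d_thin_m).records
    # cross-thin against training locations
    train_xy = train_df[["x", "y"]].to_numpy(dtype=float)
    keep = []
    for _, row in thinned.iterrows():
        d = np.hypot(train_xy[:, 0] - row.x, train_xy[:, 1] - row.y)
        keep.append(bool((d >= d_thin_m).all()))
    thinned = thinned[np.asarray(keep, dtype=bool)]
    if thinned.empty:
        raise ValueError("no test nests survive cross-thinning against training data")
    circles = [Point(x, y).buffer(buffer_m, quad_segs=16)
               for x, y in thinned[["x", "y"]].to_numpy(dtype=float)]
    test_area = unary_union(circles)
    area_bins = bin_rnd_surface(rnd, mask=test_area, K=training_aaf.K)
    obs_bins = count_nests_in_bins(area_bins, rnd,
                                   thinned[["x", "y"]].to_numpy(dtype=float))
    pred = predicted_bin_counts(len(thinned), area_bins.p_A, training_aaf.aaf)
    out = area_bins.to_frame()[["bin_low", "bin_high", "area_km2", "p_A"]]
    out["observed"] = obs_bins.counts
    out["predicted"] = pred["N_p"].to_numpy()
    out["defined"] = pred["defined"].to_numpy()
    out["obs_minus_pred"] = out["observed"] - out["predicted"]
    return out


def fit_surface_factory(
    stack,
    background_xy: np.ndarray,
    covariates: Sequence[str],
    mask=None,
    **estimator_params,
) -> Callable[[np.ndarray, float], RNDSurface]:
    """Convenience closure for :func:`crossvalidate_regularization`: fits a
    :class:`MaxentDensityEstimator` on given nests at a given multiplier and
    predicts the surface over ``stack`` (restricted to ``mask``)."""
    bg = stack.extract_values(background_xy[:, 0], background_xy[:, 1],
                              flag_nodata=False)[list(covariates)]

    def fit_fn(train_xy: np.ndarray, reg: float) -> RNDSurface:
        pres = stack.extract_values(train_xy[:, 0], train_xy[:, 1],
                                    flag_nodata=False)[list(covariates)]
        X = pd.concat([pres, bg], ignore_index=True)
        y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
        est = MaxentDensityEstimator(reg_multiplier=reg, **estimator_params)
        est.fit(X, y)
        return predict_rnd(est, stack.subset(list(covariates)), mask=mask)

    return fit_fn
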