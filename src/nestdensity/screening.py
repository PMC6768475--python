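"""Variable screening: per-variable scale selection and within-category
collinearity filtering.

Two steps reduce the multi-scale candidate stack to a model-ready set:

1. *Scale selection.* For every base variable, the nest:random ratio —
   mean covariate value at nest sites divided by the mean at 1,000 random
   sites — is computed at each focal scale, and the scale with the
   strongest contrast is retained. Contrast is measured by |log ratio| so
   that strong avoidance (ratio << 1, e.g. cropland) competes on equal
   footing with strong selection (ratio >> 1); a literal largest-ratio
   mode is available. Scales where fewer than 20% of sample locations have
   non-zero values are ineligible (too sparse to be informative).

2. *VIF filtering.* Within each covariate category, variance inflation
   factors are computed among the chosen-scale layers and the worst
   offender is removed iteratively until every remaining VIF < 4.
   Constant (zero-variance) layers are removed first. Surviving layers
   typically have pairwise correlations inside [-0.5, 0.5].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

DEFAULT_VIF_THRESHOLD = 4.0
DEFAULT_MIN_NONZERO_FRACTION = 0.20
DEFAULT_N_RANDOM_SITES = 1000


def nest_to_random_ratio(values_at_nests: Sequence[float],
                         values_at_random: Sequence[float]) -> float:
    """mean(nest values) / mean(random values); NaN when the random mean
    is zero (undefined marker — the scale becomes ineligible)."""
    nests = np.asarray(values_at_nests, dtype=float)
    rand = np.asarray(values_at_random, dtype=float)
    if nests.size == 0 or rand.size == 0:
        raise ValueError("ratio needs non-empty nest and random samples")
    denom = np.nanmean(rand)
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float(np.nanmean(nests) / denom)


def _contrast(ratio: float, mode: str) -> float:
    if not np.isfinite(ratio):
        return -np.inf
    if mode == "literal":
        return ratio
    if ratio <= 0:
        return -np.inf
    return abs(np.log(ratio))


def select_best_scale(
    ratios: Mapping[float, float],
    nonzero_fractions: Mapping[float, float],
    min_nonzero_fraction: float = DEFAULT_MIN_NONZERO_FRACTION,
    ratio_mode: str = "abslog",
) -> float | None:
    """Pick the focal scale with the strongest nest:random contrast.

    ``ratios`` and ``nonzero_fractions`` map scale radius -> value. Scales
    with an undefined ratio or a non-zero fraction below the floor are
    ineligible. Ties break toward the finer scale. Returns the chosen
    radius, or None when no scale is eligible.
    """
    if ratio_mode not in ("abslog", "literal"):
        raise ValueError("ratio_mode must be 'abslog' or 'literal'")
    best: float | None = None
    best_score = -np.inf
    for scale in sorted(ratios):
        if nonzero_fractions.get(scale, 0.0) < min_nonzero_fraction:
            continue
        score = _contrast(ratios[scale], ratio_mode)
        if score == -np.inf:
            continue
        if score > best_score:  # strict: ties keep the finer (earlier) scale
            best, best_score = scale, score
    return best


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j against the remaining columns, 1/(1-R^2)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    if others.shape[1] == 0:
        return 1.0
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return np.inf
    r2 = 1.0 - resid @ resid / sst
    return np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)


def vif_filter(
    samples: pd.DataFrame,
    category_of: Mapping[str, str] | None = None,
    threshold: float = DEFAULT_VIF_THRESHOLD,
) -> tuple[list[str], dict]:
    """Iteratively drop, within each category, the layer with the largest
    VIF until all remaining VIFs are below ``threshold``.

    Returns (retained layer names, diagnostics dict with per-category
    removal order and final VIFs).
    """
    category_of = category_of or {c: "all" for c in samples.columns}
    diagnostics: dict[str, dict] = {}
    retained: list[str] = []
    clean = samples.dropna()
    by_cat: dict[str, list[str]] = {}
    for col in samples.columns:
        by_cat.setdefault(category_of.get(col, "all"), []).append(col)
    for cat, cols in by_cat.items():
        cols = list(cols)
        removed: list[tuple[str, float]] = []
        # constant layers cannot enter a regression model; drop first
        for col in list(cols):
            if clean[col].nunique() <= 1:
                warnings.warn(f"removing constant layer {col!r} before VIF")
                cols.remove(col)
                removed.append((col, float("inf")))
        while len(cols) > 1:
            X = clean[cols].to_numpy(dtype=float)
            vifs = np.array([_vif_one(X, j) for j in range(len(cols))])
            worst = int(np.argmax(vifs))
            if vifs[worst] < threshold:
                break
            removed.append((cols[worst], float(vifs[worst])))
            cols.pop(worst)
        final_vifs = {}
        if cols:
            X = clean[cols].to_numpy(dtype=float)
            final_vifs = {c: float(_vif_one(X, j)) for j, c in enumerate(cols)}
        diagnostics[cat] = {"removed": removed, "final_vifs": final_vifs}
        retained.extend(cols)
    return retained, diagnostics


class VIFFilter(SelectorMixin, BaseEstimator):
    """Scikit-learn transformer removing collinear features by iterative VIF.

    Parameters
    ----------
    threshold : float, default 4.0
        Features are removed (worst first, within category) until every
        remaining VIF is below this value.
    categories : mapping or None
        Optional feature-name -> category map; filtering is performed
        within categories independently.
    """

    def __init__(self, threshold: float = DEFAULT_VIF_THRESHOLD,
                 categories: Mapping[str, str] | None = None):
        self.threshold = threshold
        self.categories = categories

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            df = X
        else:
            X = np.asarray(X, dtype=float)
            df = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        retained, diag = vif_filter(df, self.categories, self.threshold)
        self.retained_ = retained
        self.diagnostics_ = diag
        self.support_ = np.isin(self.feature_names_in_, retained)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


@dataclass
class ScreeningReport:
    """Outcome of the two-step screen."""

    ratios: pd.DataFrame              # rows = base variables, cols = scales
    nonzero_fractions: pd.DataFrame
    chosen_scale: dict[str, float | None]
    chosen_layers: list[str] = field(default_factory=list)
    retained_layers: list[str] = field(default_factory=list)
    vif_diagnostics: dict = field(default_factory=dict)
    correlation: pd.DataFrame | None = None

    def summary(self) -> dict:
        return {
            "n_base_variables": len(self.chosen_scale),
            "n_chosen_scale_layers": len(self.chosen_layers),
            "n_retained_after_vif": len(self.retained_layers),
            "retained_layers": self.retained_layers,
        }


def screen_variables(
    stack,
    nest_xy: np.ndarray,
    random_xy: np.ndarray,
    min_nonzero_fraction: float = DEFAULT_MIN_NONZERO_FRACTION,
    vif_threshold: float = DEFAULT_VIF_THRESHOLD,
    ratio_mode: str = "abslog",
) -> ScreeningReport:
    """Run scale selection then VIF filtering over a multi-scale stack.

    ``nest_xy`` are thinned nest sites; ``random_xy`` are the random sites
    for the ratio (1,000 by convention). VIF is computed on the pooled
    nest + random sample of the chosen-scale layers.
    """
    nest_vals = stack.extract_values(nest_xy[:, 0], nest_xy[:, 1], flag_nodata=False)
    rand_vals = stack.extract_values(random_xy[:, 0], random_xy[:, 1], flag_nodata=False)

    # a scale hosts two statistics (mean and sd); each (base, statistic)
    # pair is its own family competing across scales
    families: dict[str, dict[float, str]] = {}
    for name, _, info in stack.iter_layers():
        key = f"{info.base_variable}__{info.statistic}"
        families.setdefault(key, {})[info.scale_radius_m] = name

    all_scales = sorted({info.scale_radius_m for info in stack.info.values()})
    ratio_rows, nz_rows = {}, {}
    chosen_scale: dict[str, float | None] = {}
    chosen_layers: list[str] = []
    for fam, by_scale in families.items():
        ratios, nz = {}, {}
        pooled = {}
        for scale, lname in by_scale.items():
            nv = nest_vals[lname].to_numpy(dtype=float)
            rv = rand_vals[lname].to_numpy(dtype=float)
            ratios[scale] = nest_to_random_ratio(nv, rv)
            both = np.concatenate([nv, rv])
            nz[scale] = float(np.mean(both != 0))
            pooled[scale] = lname
        ratio_rows[fam] = {s: ratios.get(s, np.nan) for s in all_scales}
        nz_rows[fam] = {s: nz.get(s, np.nan) for s in all_scales}
        best = select_best_scale(ratios, nz, min_nonzero_fraction, ratio_mode)
        chosen_scale[fam] = best
        if best is not None:
            chosen_layers.append(by_scale[best])

    category_of = {n: stack.info[n].category for n in chosen_layers}
    pooled_samples = pd.concat(
        [nest_vals[chosen_layers], rand_vals[chosen_layers]], ignore_index=True
    )
    retained, diag = vif_filter(pooled_samples, category_of, vif_threshold)
    corr = pooled_samples[retained].corr() if retained else None
    return ScreeningReport(
        ratios=pd.DataFrame.from_dict(ratio_rows, orient="index"),
        nonzero_fractions=pd.DataFrame.from_dict(nz_rows, orient="index"),
        chosen_scale=chosen_scale,
        chosen_layers=chosen_layers,
        retained_layers=retained,
        vif_diagnostics=diag,
        correlation=corr,
    )
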