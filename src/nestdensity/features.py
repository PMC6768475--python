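"""Feature expansion for the maximum-entropy density model.

Each covariate is scaled to [0, 1] using its background minimum/maximum
(values outside the range are clamped) and expanded into:

* linear      x
* quadratic   x^2
* forward hinges   max(0, (x - k) / (1 - k))
* reverse hinges   max(0, (k - x) / k)

with hinge knots k placed at equally spaced quantiles of the background
distribution (20 per direction by default). Every derived column lies in
[0, 1], which keeps the L1 penalties comparable across feature classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("linear", "quadratic", "hinge")
DEFAULT_HINGE_KNOTS = 20


@dataclass
class CovariateFeatures:
    """Scaling range and knots for one covariate."""

    vmin: float
    vmax: float
    classes: tuple[str, ...]
    forward_knots: np.ndarray = field(default_factory=lambda: np.empty(0))
    reverse_knots: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def degenerate(self) -> bool:
        return not (self.vmax > self.vmin)

    def scale(self, x: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.zeros_like(np.asarray(x, dtype=float))
        z = (np.asarray(x, dtype=float) - self.vmin) / (self.vmax - self.vmin)
        return np.clip(z, 0.0, 1.0)


@dataclass
class FeatureSpec:
    """Per-covariate feature definitions, fixed from the background sample."""

    covariates: dict[str, CovariateFeatures]

    @classmethod
    def from_background(
        cls,
        background: pd.DataFrame,
        classes: Sequence[str] = FEATURE_CLASSES,
        n_hinge_knots: int = DEFAULT_HINGE_KNOTS,
    ) -> "FeatureSpec":
        bad = [c for c in classes if c not in FEATURE_CLASSES]
        if bad:
            raise ValueError(f"unknown feature classes {bad}")
        if not classes:
            raise ValueError("at least one feature class must be enabled")
        covs: dict[str, CovariateFeatures] = {}
        for col in background.columns:
            vals = background[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            vmin, vmax = (float(vals.min()), float(vals.max())) if vals.size else (0.0, 0.0)
            cf = CovariateFeatures(vmin, vmax, tuple(classes))
            if cf.degenerate:
                warnings.warn(
                    f"covariate {col!r} has zero background range; features dropped"
                )
            elif "hinge" in classes and n_hinge_knots > 0:
                z = cf.scale(vals)
                qs = np.linspace(0, 1, n_hinge_knots + 2)[1:-1]
                knots = np.unique(np.quantile(z, qs))
                knots = knots[(knots > 0.0) & (knots < 1.0)]
                cf.forward_knots = knots
                cf.reverse_knots = knots
            covs[col] = cf
        return cls(covs)

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for cov, cf in self.covariates.items():
            if cf.degenerate:
                continue
            if "linear" in cf.classes:
                names.append(f"{cov}::linear")
            if "quadratic" in cf.classes:
                names.append(f"{cov}::quadratic")
            if "hinge" in cf.classes:
                names += [f"{cov}::hinge_f@{k:.6g}" for k in cf.forward_knots]
                names += [f"{cov}::hinge_r@{k:.6g}" for k in cf.reverse_knots]
        return names

    def feature_covariates(self) -> list[str]:
        return [n.split("::", 1)[0] for n in self.feature_names()]

    def feature_classes(self) -> list[str]:
        out = []
        for n in self.feature_names():
            tail = n.split("::", 1)[1]
            out.append("hinge" if tail.startswith("hinge") else tail)
        return out

    def subset(self, covariate_names: Sequence[str]) -> "FeatureSpec":
        return FeatureSpec({c: self.covariates[c] for c in covariate_names})


def build_feature_matrix(samples: pd.DataFrame, spec: FeatureSpec) -> np.ndarray:
    """Expand covariate samples into the design matrix (columns ordered as
    :meth:`FeatureSpec.feature_names`); all entries in [0, 1]."""
    cols: list[np.ndarray] = []
    for cov, cf in spec.covariates.items():
        if cov not in samples.columns:
            raise KeyError(f"covariate {cov!r} missing from samples")
        if cf.degenerate:
            continue
        z = cf.scale(samples[cov].to_numpy(dtype=float))
        if "linear" in cf.classes:
            cols.append(z)
        if "quadratic" in cf.classes:
            cols.append(z**2)
        if "hinge" in cf.classes:
            for k in cf.forward_knots:
                cols.append(np.maximum(0.0, (z - k) / (1.0 - k)))
            for k in cf.reverse_knots:
                cols.append(np.maximum(0.0, (k - z) / k))
    if not cols:
        return np.empty((len(samples), 0))
    return np.column_stack(cols)
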