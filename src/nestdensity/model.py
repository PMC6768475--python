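"""Maximum-entropy presence-background density model.

The model is the Gibbs distribution over the background sample,

    q_lambda(x) = exp(lambda . f(x)) / Z,   Z = sum_background exp(lambda . f(x)),

fitted by maximizing the L1-penalized log gain

    G(lambda) = mean_presence[lambda . f(x)] - log mean_bg[exp(lambda . f(x))]
                - sum_j beta_j |lambda_j|,

which is the penalized likelihood of an inhomogeneous Poisson point
process for the presence locations given availability described by the
background. The raw output is therefore proportional to event (nest-site)
density. Per-feature penalties follow the conventional maximum-entropy
SDM defaults:

    beta_j = reg_multiplier * beta_class(m) * s_j / sqrt(m)

with m the presence sample size, s_j the feature's SD over the presence
sample, and beta_class interpolated from sample-size-keyed tables (one for
linear/quadratic features, one for hinges).

Optimization is cyclic coordinate descent with a prox-Newton
soft-threshold step per coordinate, run until the relative change of the
penalized gain over a full pass falls below ``tol`` (default 1e-7) or
5,000 passes. Each accepted update's gain increment is recorded in a
trace; positive increments pooled per covariate and normalized to 100
give the percent contributions used for model reduction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .features import (
    DEFAULT_HINGE_KNOTS,
    FEATURE_CLASSES,
    CovariateFeatures,
    FeatureSpec,
    build_feature_matrix,
)
from .grid import CovariateStack, GridSpec

# beta_class default tables, keyed on presence sample size (piecewise-linear
# interpolation, clamped at the ends) — the conventional defaults for
# presence-background maximum-entropy SDMs.
BETA_TABLE_LINEAR_QUADRATIC = ((10, 1.0), (30, 0.8), (100, 0.5))
BETA_TABLE_HINGE = ((0, 0.5),)

DEFAULT_REG_MULTIPLIER = 1.0
DEFAULT_TOL = 1e-7
DEFAULT_MAX_PASSES = 5000


def _beta_class(feature_class: str, m: int) -> float:
    table = BETA_TABLE_HINGE if feature_class == "hinge" else BETA_TABLE_LINEAR_QUADRATIC
    sizes = np.array([t[0] for t in table], dtype=float)
    vals = np.array([t[1] for t in table], dtype=float)
    return float(np.interp(m, sizes, vals))


def default_betas(presence_features: np.ndarray,
                  feature_classes: Sequence[str],
                  reg_multiplier: float) -> np.ndarray:
    """Per-feature L1 penalties beta_j = reg * beta_class(m) * s_j / sqrt(m)."""
    m = presence_features.shape[0]
    s = presence_features.std(axis=0)
    # features constant over the presences still need a finite penalty
    s = np.maximum(s, 1e-4)
    cls = np.array([_beta_class(c, m) for c in feature_classes])
    return reg_multiplier * cls * s / np.sqrt(m)


@dataclass
class MaxentFit:
    """Fitted coefficients and bookkeeping of one maximum-entropy fit."""

    feature_names: list[str]
    feature_covariates: list[str]
    coef: np.ndarray
    log_normalizer: float          # log mean_bg exp(score)
    reg_multiplier: float
    betas: np.ndarray
    gain_trace: list[tuple[str, float]] = field(default_factory=list)
    training_gain: float = 0.0
    n_presence: int = 0
    n_background: int = 0
    n_passes: int = 0
    converged: bool = True

    @property
    def contributions_pct(self) -> dict[str, float]:
        return percent_contributions(self)

    def scores(self, features: np.ndarray) -> np.ndarray:
        return features @ self.coef

    def raw(self, features: np.ndarray) -> np.ndarray:
        """exp(score)/Z with Z over the training background; sums to 1 over
        the training background sample."""
        return np.exp(
            self.scores(features) - self.log_normalizer - np.log(self.n_background)
        )

    def entropy(self, background_features: np.ndarray) -> float:
        q = self.raw(background_features)
        q = q / q.sum()
        return float(-np.sum(q * np.log(np.maximum(q, 1e-300))))


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    reg_multiplier: float = DEFAULT_REG_MULTIPLIER,
    feature_names: Sequence[str] | None = None,
    feature_covariates: Sequence[str] | None = None,
    feature_classes: Sequence[str] | None = None,
    betas: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_passes: int = DEFAULT_MAX_PASSES,
) -> MaxentFit:
    """Cyclic coordinate descent for the L1-penalized maximum-entropy model.

    ``presence_features`` (m x p) and ``background_features`` (n x p) are
    pre-built design matrices with columns in [0, 1]. ``betas`` overrides
    the default per-feature penalties.
    """
    Fp = np.asarray(presence_features, dtype=float)
    Fb = np.asarray(background_features, dtype=float)
    if Fp.ndim != 2 or Fp.shape[0] < 1:
        raise ValueError("at least one presence row is required")
    if Fb.shape[0] < Fp.shape[0]:
        raise ValueError("background must hold at least as many rows as presence")
    m, p = Fp.shape
    n = Fb.shape[0]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    if feature_covariates is None:
        feature_covariates = list(feature_names)
    if feature_classes is None:
        feature_classes = ["linear"] * p
    if betas is None:
        betas = default_betas(Fp, feature_classes, reg_multiplier)
    betas = np.asarray(betas, dtype=float)

    coef = np.zeros(p)
    pbar = Fp.mean(axis=0)
    s_b = np.zeros(n)  # background scores

    def penalized_gain(scores_b: np.ndarray, c: np.ndarray) -> float:
        return float(pbar @ c - (logsumexp(scores_b) - np.log(n)) - betas @ np.abs(c))

    gain = 0.0
    trace: list[tuple[str, float]] = []
    n_passes = 0
    converged = False
    for n_passes in range(1, max_passes + 1):
        gain_at_pass_start = gain
        for j in range(p):
            col = Fb[:, j]
            logw = s_b - logsumexp(s_b)
            w = np.exp(logw)
            Ej = w @ col
            Hj = max(w @ col**2 - Ej**2, 1e-12)
            grad = pbar[j] - Ej
            target = coef[j] + grad / Hj
            new = np.sign(target) * max(abs(target) - betas[j] / Hj, 0.0)
            # cap the Newton step; the quadratic model is only local
            step = np.clip(new - coef[j], -2.0, 2.0)
            if step == 0.0:
                continue
            coef[j] += step
            s_b = s_b + step * col
            new_gain = penalized_gain(s_b, coef)
            if new_gain < gain - 1e-12:
                # step overshot a flat region: halve until non-decreasing
                ok = False
                for _ in range(20):
                    step /= 2.0
                    coef[j] -= step
                    s_b = s_b - step * col
                    new_gain = penalized_gain(s_b, coef)
                    if new_gain >= gain - 1e-12:
                        ok = True
                        break
                if not ok:
                    # revert entirely
                    s_b = s_b - step * col
                    coef[j] -= step
                    continue
            if new_gain != gain:
                trace.append((str(feature_names[j]), new_gain - gain))
            gain = new_gain
        denom = max(abs(gain), 1e-12)
        if abs(gain - gain_at_pass_start) / denom < tol:
            converged = True
            break
    if not converged:
        logw = s_b - logsumexp(s_b)
        w = np.exp(logw)
        grad = pbar - Fb.T @ w
        gnorm = float(np.max(np.abs(grad) - betas, initial=0.0))
        warnings.warn(
            f"maximum-entropy fit did not converge in {max_passes} passes; "
            f"max excess gradient {gnorm:.3g}"
        )
    return MaxentFit(
        feature_names=list(feature_names),
        feature_covariates=list(feature_covariates),
        coef=coef,
        log_normalizer=float(logsumexp(s_b) - np.log(n)),
        reg_multiplier=reg_multiplier,
        betas=betas,
        gain_trace=trace,
        training_gain=float(pbar @ coef - (logsumexp(s_b) - np.log(n))),
        n_presence=m,
        n_background=n,
        n_passes=n_passes,
        converged=converged,
    )


def percent_contributions(fit: MaxentFit) -> dict[str, float]:
    """Positive gain increments pooled per covariate, normalized to 100."""
    by_cov: dict[str, float] = {c: 0.0 for c in dict.fromkeys(fit.feature_covariates)}
    name_to_cov = dict(zip(fit.feature_names, fit.feature_covariates))
    for fname, dg in fit.gain_trace:
        if dg > 0:
            by_cov[name_to_cov[fname]] += dg
    total = sum(by_cov.values())
    if total <= 0:
        warnings.warn("empty gain trace: all contributions zero")
        return {c: 0.0 for c in by_cov}
    return {c: 100.0 * v / total for c, v in by_cov.items()}


# ---------------------------------------------------------------------------
# scikit-learn estimator


class MaxentDensityEstimator(BaseEstimator):
    """Presence-background maximum-entropy density model (sklearn API).

    ``fit(X, y)`` takes covariate samples ``X`` (DataFrame or array) and a
    binary indicator ``y`` (1 = presence/nest, 0 = background). The model
    output is a relative density: ``predict_raw`` is proportional to
    point-process intensity and sums to 1 over the training background;
    ``predict`` returns the bounded [0, 1] output used for density binning
    (logistic by default).

    Parameters
    ----------
    feature_classes : tuple of {"linear", "quadratic", "hinge"}
    n_hinge_knots : int, default 20
        Knots per hinge direction, at background quantiles.
    reg_multiplier : float, default 1.0
        Scales every per-feature L1 penalty; larger = smoother model.
    transform : {"logistic", "minmax_raw"}, default "logistic"
        Output transform of :meth:`predict`.
    tol, max_passes : optimizer stopping rules.

    Attributes
    ----------
    fit_ : MaxentFit
    feature_spec_ : FeatureSpec (scaling ranges and knots from background)
    coef_ : per-expanded-feature coefficients
    contributions_ : percent contribution per covariate
    entropy_ : entropy of the raw distribution over the training background
    """

    def __init__(
        self,
        feature_classes: tuple[str, ...] = FEATURE_CLASSES,
        n_hinge_knots: int = DEFAULT_HINGE_KNOTS,
        reg_multiplier: float = DEFAULT_REG_MULTIPLIER,
        transform: str = "logistic",
        tol: float = DEFAULT_TOL,
        max_passes: int = DEFAULT_MAX_PASSES,
    ):
        self.feature_classes = feature_classes
        self.n_hinge_knots = n_hinge_knots
        self.reg_multiplier = reg_multiplier
        self.transform = transform
        self.tol = tol
        self.max_passes = max_passes

    # -- helpers ----------------------------------------------------------
    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        cols = getattr(self, "feature_names_in_", None)
        if cols is not None and len(cols) == X.shape[1]:
            return pd.DataFrame(X, columns=list(cols))
        return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])

    def fit(self, X, y, feature_spec: FeatureSpec | None = None):
        df = self._as_frame(X)
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary: 1 = presence, 0 = background")
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        presence = df[y == 1]
        background = df[y == 0]
        if len(presence) < 1:
            raise ValueError("no presence rows (y == 1)")
        spec = feature_spec or FeatureSpec.from_background(
            background, self.feature_classes, self.n_hinge_knots
        )
        Fp = build_feature_matrix(presence, spec)
        Fb = build_feature_matrix(background, spec)
        self.fit_ = fit_maxent(
            Fp,
            Fb,
            reg_multiplier=self.reg_multiplier,
            feature_names=spec.feature_names(),
            feature_covariates=spec.feature_covariates(),
            feature_classes=spec.feature_classes(),
            tol=self.tol,
            max_passes=self.max_passes,
        )
        self.feature_spec_ = spec
        self.coef_ = self.fit_.coef
        self.contributions_ = percent_contributions(self.fit_)
        self.training_gain_ = self.fit_.training_gain
        self.entropy_ = self.fit_.entropy(Fb)
        self._raw_minmax_ = None
        raw_b = self.fit_.raw(Fb)
        self._raw_minmax_ = (float(raw_b.min()), float(raw_b.max()))
        return self

    def predict_raw(self, X) -> np.ndarray:
        """Relative density, normalized over the training background."""
        check_is_fitted(self, "fit_")
        F = build_feature_matrix(self._as_frame(X), self.feature_spec_)
        return self.fit_.raw(F)

    def predict(self, X, transform: str | None = None) -> np.ndarray:
        """[0, 1]-bounded relative nest-site density."""
        check_is_fitted(self, "fit_")
        transform = transform or self.transform
        raw = self.predict_raw(X)
        if transform == "logistic":
            z = raw * np.exp(self.entropy_)
            return z / (1.0 + z)
        if transform == "minmax_raw":
            lo, hi = self._raw_minmax_
            if hi <= lo:
                return np.full_like(raw, 0.5)
            return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
        raise ValueError(f"unknown transform {transform!r}")

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "fit_")
        doc = {
            "format": "nestdensity-maxent",
            "version": 1,
            "params": self.get_params(),
            "covariates": {
                c: {
                    "vmin": cf.vmin,
                    "vmax": cf.vmax,
                    "classes": list(cf.classes),
                    "forward_knots": cf.forward_knots.tolist(),
                    "reverse_knots": cf.reverse_knots.tolist(),
                }
                for c, cf in self.feature_spec_.covariates.items()
            },
            "coef": self.fit_.coef.tolist(),
            "feature_names": self.fit_.feature_names,
            "log_normalizer": self.fit_.log_normalizer,
            "n_background": self.fit_.n_background,
            "n_presence": self.fit_.n_presence,
            "entropy": self.entropy_,
            "raw_minmax": list(self._raw_minmax_),
            "contributions_pct": self.contributions_,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaxentDensityEstimator":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        est = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in doc["params"].items()})
        covs = {
            c: CovariateFeatures(
                d["vmin"], d["vmax"], tuple(d["classes"]),
                np.asarray(d["forward_knots"]), np.asarray(d["reverse_knots"]),
            )
            for c, d in doc["covariates"].items()
        }
        spec = FeatureSpec(covs)
        est.feature_spec_ = spec
        est.feature_names_in_ = np.asarray(list(covs), dtype=object)
        est.n_features_in_ = len(covs)
        est.fit_ = MaxentFit(
            feature_names=doc["feature_names"],
            feature_covariates=[n.split("::", 1)[0] for n in doc["feature_names"]],
            coef=np.asarray(doc["coef"], dtype=float),
            log_normalizer=doc["log_normalizer"],
            reg_multiplier=doc["params"].get("reg_multiplier", 1.0),
            betas=np.zeros(len(doc["coef"])),
            n_presence=doc["n_presence"],
            n_background=doc["n_background"],
        )
        est.coef_ = est.fit_.coef
        est.entropy_ = doc["entropy"]
        est._raw_minmax_ = tuple(doc["raw_minmax"])
        est.contributions_ = doc["contributions_pct"]
        est.training_gain_ = 0.0
        return est


def reduce_and_refit(
    estimator: MaxentDensityEstimator,
    X,
    y,
    threshold_pct: float = 1.0,
) -> MaxentDensityEstimator:
    """Drop covariates contributing < ``threshold_pct`` percent and refit once.

    When every covariate falls below the threshold the single largest
    contributor is kept (with a warning). Returns a new fitted estimator.
    """
    check_is_fitted(estimator, "fit_")
    contrib = estimator.contributions_
    keep = [c for c, v in contrib.items() if v >= threshold_pct]
    if not keep:
        best = max(contrib, key=contrib.get)
        warnings.warn(
            f"all covariates below {threshold_pct}% contribution; keeping {best!r}"
        )
        keep = [best]
    df = estimator._as_frame(X)
    reduced = MaxentDensityEstimator(**estimator.get_params())
    spec = estimator.feature_spec_.subset(keep)
    reduced.fit(df[keep], y, feature_spec=spec)
    return reduced


# ---------------------------------------------------------------------------
# surfaces


@dataclass
class RNDSurface:
    """Relative nest-site density over a grid: bounded values plus the raw
    relative-intensity grid (NaN outside the mask)."""

    grid: GridSpec
    values: np.ndarray
    raw: np.ndarray
    transform_label: str

    def in_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def predict_rnd(
    estimator: MaxentDensityEstimator,
    stack: CovariateStack,
    mask=None,
    transform: str | None = None,
    clamp_report: dict | None = None,
) -> RNDSurface:
    """Evaluate the fitted model over grid cells (optionally inside a mask
    polygon); returns the bounded surface and the raw grid.

    ``clamp_report`` (a dict, filled in place) receives the fraction of
    in-mask cells with any covariate outside its training range.
    """
    check_is_fitted(estimator, "fit_")
    missing = [c for c in estimator.feature_spec_.covariates if c not in stack]
    if missing:
        raise KeyError(f"covariates missing from stack: {missing}")
    grid = stack.grid
    xs, ys = grid.cell_centers()
    if mask is not None:
        inside = shapely.contains_xy(mask, xs.ravel(), ys.ravel()).reshape(grid.shape)
    else:
        inside = np.ones(grid.shape, dtype=bool)
    cols = {c: stack[c][inside] for c in estimator.feature_spec_.covariates}
    samples = pd.DataFrame(cols)
    valid = ~samples.isna().any(axis=1).to_numpy()
    if clamp_report is not None:
        clamped = np.zeros(len(samples), dtype=bool)
        for c, cf in estimator.feature_spec_.covariates.items():
            v = samples[c].to_numpy(dtype=float)
            clamped |= (v < cf.vmin) | (v > cf.vmax)
        clamp_report["clamped_fraction"] = float(np.mean(clamped[valid])) if valid.any() else 0.0
    raw_vals = np.full(len(samples), np.nan)
    bnd_vals = np.full(len(samples), np.nan)
    if valid.any():
        sub = samples[valid]
        raw_vals[valid] = estimator.predict_raw(sub)
        bnd_vals[valid] = estimator.predict(sub, transform=transform)
    raw = np.full(grid.shape, np.nan)
    val = np.full(grid.shape, np.nan)
    raw[inside] = raw_vals
    val[inside] = bnd_vals
    return RNDSurface(grid, val, raw, transform or estimator.transform)
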