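"""Rejection sampling plus weighted local linear regression on Box–Cox Ne.

Given the input sample's summary-statistic vector and a simulated reference
table, the engine

1. centers and scales every statistic by the reference table's median and
   median absolute deviation (raw MAD, so a standardized column has MAD 1) —
   an unscaled Euclidean distance would be dominated by whichever statistic
   happens to have the largest units;
2. accepts the ``acceptance_fraction`` of records closest to the target in
   standardized Euclidean distance (delta = that distance quantile, ties
   included);
3. regresses Box–Cox-transformed Ne (lambda = -0.2) on the standardized
   statistics among accepted records with Epanechnikov weights
   ``1 - (d/delta)^2``, and projects each record's residual onto the target
   (Beaumont-style local-linear adjustment);
4. back-transforms, clamps into the prior support, and summarizes by the
   weighted median and 2.5%/97.5% weighted quantiles (inverted-CDF rule on
   cumulative weights).

A rank-deficient regression design falls back to pure rejection with a
warning, so rejection and regression modes agree whenever the accepted
records carry identical statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.special
import statsmodels.api as sm
from scipy.stats import median_abs_deviation

_EPS = 1e-12


class AbcError(ValueError):
    """The ABC step cannot proceed on the given inputs."""


@dataclass
class AbcConfig:
    """Acceptance and adjustment settings.

    ``acceptance_fraction`` is the proportion of reference records kept
    (delta is the corresponding distance quantile).  At least 20 accepted
    records are required for the 5-covariate regression; fewer than 100
    draws a warning.
    """

    acceptance_fraction: float = 0.02
    boxcox_lambda: float = -0.2
    standardization: str = "mad"
    adjust: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.acceptance_fraction <= 1.0:
            raise ValueError("acceptance_fraction must lie in (0, 1]")
        if self.standardization not in ("mad", "none"):
            raise ValueError("standardization must be 'mad' or 'none'")


@dataclass
class NeEstimate:
    """Posterior summary of Ne with acceptance diagnostics."""

    median: float
    ci_low: float
    ci_high: float
    posterior_samples: np.ndarray
    weights: np.ndarray
    n_accepted: int
    delta_used: float
    mode: str  # "regression" or "rejection"
    diagnostics: dict = field(default_factory=dict)
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_accepted": self.n_accepted,
            "delta_used": self.delta_used,
            "mode": self.mode,
            "seed": self.seed,
            "config": self.config,
            "posterior_samples": [float(x) for x in self.posterior_samples],
            "weights": [float(x) for x in self.weights],
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
        }


# ---------------------------------------------------------------------------
# standardization and selection


def standardize_stats(
    table_stats: np.ndarray,
    target: np.ndarray,
    method: str = "mad",
    names: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale table and target by the table's robust location and scale.

    Returns ``(standardized_table, standardized_target, kept_mask)``.
    Statistics whose scale is zero over the table carry no distance
    information and are dropped with a warning.
    """
    table_stats = np.asarray(table_stats, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if table_stats.ndim != 2 or table_stats.shape[1] != target.size:
        raise AbcError("table and target statistic dimensions do not match")
    if table_stats.shape[0] == 0:
        raise AbcError("empty reference table")
    if method == "none":
        kept = np.ones(target.size, dtype=bool)
        return table_stats.copy(), target.copy(), kept
    center = np.median(table_stats, axis=0)
    scale = median_abs_deviation(table_stats, axis=0)
    kept = scale > _EPS
    if not kept.any():
        raise AbcError("every summary statistic is constant over the reference table")
    if not kept.all():
        dropped = (
            [names[k] for k in np.flatnonzero(~kept)]
            if names is not None
            else np.flatnonzero(~kept).tolist()
        )
        warnings.warn(
            f"statistics {dropped} have zero spread in the reference table "
            "and were dropped from the distance",
            stacklevel=2,
        )
    z_table = (table_stats[:, kept] - center[kept]) / scale[kept]
    z_target = (target[kept] - center[kept]) / scale[kept]
    return z_table, z_target, kept


def select_accepted(
    z_table: np.ndarray,
    z_target: np.ndarray,
    acceptance_fraction: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Indices and distances of records within the acceptance quantile.

    delta is the ``acceptance_fraction`` quantile of all distances; every
    record with distance <= delta is accepted (ties included).
    """
    dist = np.linalg.norm(z_table - z_target[None, :], axis=1)
    delta = float(np.quantile(dist, acceptance_fraction))
    accepted = np.flatnonzero(dist <= delta)
    if accepted.size < 20:
        raise AbcError(
            f"only {accepted.size} records accepted; increase the number of "
            "simulation trials or the acceptance fraction"
        )
    if accepted.size < 100:
        warnings.warn(
            f"only {accepted.size} accepted records; posterior quantiles will "
            "be coarse (consider a larger reference table)",
            stacklevel=2,
        )
    return accepted, dist[accepted], delta


# ---------------------------------------------------------------------------
# Box–Cox


def boxcox(x, lam: float):
    """Box–Cox transform ``(x^lam - 1)/lam`` (log for lambda = 0); x must be > 0."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("Box-Cox transform requires strictly positive input")
    return scipy.special.boxcox(x, lam)


def inv_boxcox(y, lam: float):
    """Exact inverse of :func:`boxcox` on its range (requires 1 + lam*y > 0)."""
    y = np.asarray(y, dtype=np.float64)
    if lam != 0.0 and np.any(1.0 + lam * y <= 0):
        raise ValueError("inverse Box-Cox input outside the transform's range")
    return scipy.special.inv_boxcox(y, lam)


# ---------------------------------------------------------------------------
# local linear adjustment


def epanechnikov_weights(dist: np.ndarray, delta: float) -> np.ndarray:
    """Smooth kernel weights on accepted records; uniform when delta is 0."""
    if delta <= _EPS:
        return np.ones_like(dist)
    w = 1.0 - (dist / delta) ** 2
    w = np.clip(w, 0.0, None)
    if w.sum() <= _EPS:
        return np.ones_like(dist)
    return w


def local_linear_adjust(
    ne_accepted: np.ndarray,
    z_accepted: np.ndarray,
    z_target: np.ndarray,
    dist: np.ndarray,
    delta: float,
    cfg: AbcConfig,
    ne_bounds: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Beaumont-style regression adjustment of accepted Ne values.

    Returns ``(posterior_samples, weights, diagnostics)``; samples are
    clamped into the prior support.  Falls back to unadjusted rejection when
    adjustment is disabled or the weighted design is rank-deficient.
    """
    ne_accepted = np.asarray(ne_accepted, dtype=np.float64)
    lo, hi = ne_bounds
    weights = epanechnikov_weights(dist, delta)
    diagnostics: dict = {"distances": dist}

    def rejection(reason: Optional[str]) -> tuple[np.ndarray, np.ndarray, dict]:
        if reason:
            warnings.warn(reason, stacklevel=3)
        diagnostics["mode"] = "rejection"
        return np.clip(ne_accepted, lo, hi), weights, diagnostics

    if not cfg.adjust:
        return rejection(None)

    design = np.column_stack([np.ones(z_accepted.shape[0]), z_accepted])
    weighted_design = design * np.sqrt(weights)[:, None]
    if np.linalg.matrix_rank(weighted_design) < design.shape[1]:
        return rejection(
            "regression design is rank-deficient; falling back to pure rejection"
        )

    lam = cfg.boxcox_lambda
    y = boxcox(ne_accepted, lam)
    fit = sm.WLS(y, design, weights=weights).fit()
    beta = fit.params
    y_adj = y - (z_accepted - z_target[None, :]) @ beta[1:]
    # keep the back-transform inside the image of the prior support
    y_lo, y_hi = float(boxcox(lo, lam)), float(boxcox(hi, lam))
    y_adj = np.clip(y_adj, min(y_lo, y_hi), max(y_lo, y_hi))
    samples = np.clip(inv_boxcox(y_adj, lam), lo, hi)
    diagnostics["mode"] = "regression"
    diagnostics["coefficients"] = beta
    diagnostics["r_squared"] = float(fit.rsquared) if y.std() > _EPS else np.nan
    return samples, weights, diagnostics


# ---------------------------------------------------------------------------
# posterior summary


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Inverted-CDF weighted quantile: smallest x with cumulative weight >= q."""
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if values.size == 0:
        raise AbcError("no posterior samples to summarize")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= _EPS:
        weights = np.ones_like(weights)
        total = weights.sum()
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order]) / total
    idx = np.searchsorted(cum, np.atleast_1d(q), side="left")
    idx = np.minimum(idx, values.size - 1)
    out = values[order][idx]
    return out if np.ndim(q) else float(out[0])


def summarize_posterior(
    posterior_samples: np.ndarray,
    weights: np.ndarray,
    *,
    n_accepted: Optional[int] = None,
    delta_used: float = np.nan,
    mode: str = "regression",
    diagnostics: Optional[dict] = None,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> NeEstimate:
    """Weighted median and 95% interval of the posterior samples."""
    qs = weighted_quantile(posterior_samples, weights, [0.025, 0.5, 0.975])
    return NeEstimate(
        median=float(qs[1]),
        ci_low=float(qs[0]),
        ci_high=float(qs[2]),
        posterior_samples=np.asarray(posterior_samples, dtype=np.float64),
        weights=np.asarray(weights, dtype=np.float64),
        n_accepted=len(posterior_samples) if n_accepted is None else n_accepted,
        delta_used=float(delta_used),
        mode=mode,
        diagnostics=diagnostics or {},
        seed=seed,
        config=config or {},
    )
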