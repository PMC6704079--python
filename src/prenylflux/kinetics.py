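"""Logistic labeling kinetics and half-times.

Time-course mean 13C enrichments E(t) after a tracer switch are fitted
with the logistic model

    E(t) = k * y0 * exp(t*T) / (k + y0 * exp(t*T) - y0)

with plateau k, initial enrichment y0 and rate parameter T (1/min). The
half-time, the time needed to exchange half of a pool's 12C atoms,

    T50 = (1/T) * ln((k - y0) / y0)

satisfies E(T50) = k/2 exactly under the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "EnrichmentSeries",
    "LogisticFit",
    "logistic_enrichment",
    "fit_logistic",
    "t50",
    "fit_table",
]

#: series spanning less total enrichment change than this are flagged
#: degenerate (mirrors the exclusion of pools with low, variable signal)
FLAT_SERIES_THRESHOLD = 0.05


@dataclass(frozen=True)
class EnrichmentSeries:
    """One metabolite's enrichment time course in one strain/replicate."""

    metabolite: str
    strain: str
    times_min: np.ndarray
    enrichment: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        e = np.asarray(self.enrichment, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "enrichment", e)
        if t.shape != e.shape:
            raise ValueError("times and enrichment must have equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(e < -1e-9) or np.any(e > 1 + 1e-9):
            raise ValueError("enrichment values must lie in [0, 1]")


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters and derived half-time."""

    k: float
    y0: float
    T: float
    t50_min: float | None
    rss: float
    converged: bool
    degenerate: bool = False


def logistic_enrichment(t, k: float, y0: float, T: float):
    """Evaluate the logistic model (overflow-safe form)."""
    t = np.asarray(t, dtype=float)
    return k / (1.0 + ((k - y0) / y0) * np.exp(-np.clip(t * T, None, 700.0)))


def t50(fit: LogisticFit | tuple[float, float, float]) -> float:
    """Closed-form half-time (1/T) * ln((k - y0)/y0).

    A y0 already at or above k/2 yields a non-positive half-time; it is
    returned as-is with a warning rather than clamped.
    """
    k, y0, T = (fit.k, fit.y0, fit.T) if isinstance(fit, LogisticFit) else fit
    if not (0 < y0 < k):
        raise ValueError(f"t50 requires 0 < y0 < k (got y0={y0}, k={k})")
    if T <= 0:
        raise ValueError("t50 requires T > 0")
    value = float(np.log((k - y0) / y0) / T)
    if value <= 0:
        warnings.warn(
            f"T50 = {value:.4g} min <= 0: initial enrichment already at or above "
            "half the plateau",
            stacklevel=2,
        )
    return value


def _initial_guess(t: np.ndarray, e: np.ndarray) -> tuple[float, float, float]:
    """Deterministic initialization: y0 from the first point (floored,
    since the model is undefined at y0 = 0), k from the maximum, T from
    a log-linear regression of the early phase."""
    y0 = max(float(e[0]), 1e-4)
    k = min(max(float(e.max()), y0 * 1.01 + 1e-6), 1.0)
    mask = (e > y0) & (e < k)
    if mask.sum() >= 2:
        z = np.log(e[mask] * (k - y0) / (y0 * (k - e[mask])))
        slope = float(np.polyfit(t[mask], z, 1)[0])
        T = min(max(slope, 1e-3), 10.0)
    else:
        T = 0.1
    return k, y0, T


def fit_logistic(series: EnrichmentSeries, weights: np.ndarray | None = None) -> LogisticFit:
    """Bounded least-squares fit of the logistic model to one series.

    Deterministic given the data (fixed initialization rule). A series
    whose total enrichment change is below ``FLAT_SERIES_THRESHOLD`` is
    flagged degenerate and gets no half-time.
    """
    t = series.times_min
    e = series.enrichment
    if len(t) < 4:
        raise ValueError("logistic fit requires at least 4 points")
    span = float(e.max() - e.min())
    if span < FLAT_SERIES_THRESHOLD:
        return LogisticFit(
            k=float(e.mean()), y0=float(e.mean()), T=0.0, t50_min=None,
            rss=float(np.sum((e - e.mean()) ** 2)), converged=True, degenerate=True,
        )
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != e.shape or np.any(weights <= 0):
            raise ValueError("weights must be positive and match the series length")
        sqrt_w = np.sqrt(weights)
    else:
        sqrt_w = np.ones_like(e)

    def residuals(params: np.ndarray) -> np.ndarray:
        k, y0, T = params
        return sqrt_w * (logistic_enrichment(t, k, y0, T) - e)

    x0 = np.array(_initial_guess(t, e))
    lb = np.array([1e-6, 1e-6, 1e-6])
    ub = np.array([1.0, 1.0, 10.0])
    result = least_squares(
        residuals, np.clip(x0, lb, ub), bounds=(lb, ub),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    k, y0, T = (float(v) for v in result.x)
    converged = bool(result.success)
    if not converged:
        warnings.warn(f"logistic fit did not converge: {result.message}", stacklevel=2)
    if y0 >= k:
        return LogisticFit(k=k, y0=y0, T=T, t50_min=None,
                           rss=float(2 * result.cost), converged=converged, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        half_time = t50((k, y0, T))
    return LogisticFit(k=k, y0=y0, T=T, t50_min=half_time,
                       rss=float(2 * result.cost), converged=converged)


def fit_table(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Fit every (strain, replicate, metabolite) series in a long table.

    Expects columns strain, replicate, metabolite, time_min,
    mean_enrichment; returns one row per series with the fitted
    parameters, half-time and diagnostics.
    """
    required = {"strain", "replicate", "metabolite", "time_min", "mean_enrichment"}
    missing = required - set(enrichment.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    rows = []
    for (strain, replicate, metabolite), group in enrichment.groupby(
        ["strain", "replicate", "metabolite"], sort=False
    ):
        group = group.sort_values("time_min")
        series = EnrichmentSeries(
            metabolite=metabolite,
            strain=strain,
            times_min=group["time_min"].to_numpy(),
            enrichment=group["mean_enrichment"].to_numpy(),
        )
        fit = fit_logistic(series)
        rows.append(
            {
                "strain": strain,
                "replicate": replicate,
                "metabolite": metabolite,
                "k": fit.k,
                "y0": fit.y0,
                "T": fit.T,
                "t50_min": fit.t50_min,
                "rss": fit.rss,
                "converged": fit.converged,
                "degenerate": fit.degenerate,
            }
        )
    return pd.DataFrame(rows)
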