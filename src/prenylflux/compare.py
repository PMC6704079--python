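"""Strain comparison statistics and turnover-based relative flux inference.

Concentrations and half-times are compared between strains with
two-sided Welch's t tests (fractional Welch-Satterthwaite degrees of
freedom, no integer rounding). Under constant turnover - the regime the
labeling data support when T50 values do not differ between strains -
the relative biosynthetic flux change equals the pool-size ratio; its
uncertainty is propagated by the first-order delta method from the
independent group standard deviations, with a parametric bootstrap as an
alternative estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "WelchResult",
    "FluxRatio",
    "StrainComparison",
    "welch_test",
    "welch_test_samples",
    "flux_ratio",
    "bootstrap_flux_ratio_sd",
    "compare_labeling_dynamics",
]


@dataclass(frozen=True)
class GroupSummary:
    """Replicate summary (mean, SD, n) of one quantity in one strain."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")

    @classmethod
    def from_samples(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(mean=float(arr.mean()),
                   sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                   n=len(arr))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float


@dataclass(frozen=True)
class FluxRatio:
    ratio: float
    sd: float


@dataclass(frozen=True)
class StrainComparison:
    metabolite: str
    group_a: GroupSummary
    group_b: GroupSummary
    welch: WelchResult
    flux: FluxRatio


def welch_test(a: GroupSummary, b: GroupSummary) -> WelchResult:
    """Two-sided Welch's t test from group summaries.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and p from the central t
    distribution.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("Welch's test requires n >= 2 in both groups")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        if a.mean == b.mean:
            return WelchResult(t=0.0, df=float(a.n + b.n - 2), p_value=1.0)
        raise ValueError("both groups have zero variance but different means")
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p_value=min(p, 1.0))


def welch_test_samples(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    return welch_test(GroupSummary.from_samples(x), GroupSummary.from_samples(y))


def flux_ratio(
    pool_a: GroupSummary,
    pool_b: GroupSummary,
    t50_a: float | None = None,
    t50_b: float | None = None,
) -> FluxRatio:
    """Relative flux of strain a vs. strain b.

    Constant-turnover mode (default): the flux ratio equals the pool
    ratio mean_a/mean_b, with first-order delta-method SD assuming
    independent groups,

        sd = ratio * sqrt((sd_a/mean_a)^2 + (sd_b/mean_b)^2).

    When both half-times are supplied the turnover-adjusted ratio
    (mean_a/T50_a)/(mean_b/T50_b) is returned instead (same relative SD;
    half-time uncertainty is not propagated).
    """
    if pool_a.mean <= 0 or pool_b.mean <= 0:
        raise ValueError("flux ratio requires positive pool means")
    ratio = pool_a.mean / pool_b.mean
    if t50_a is not None and t50_b is not None:
        if t50_a <= 0 or t50_b <= 0:
            raise ValueError("half-times must be positive for turnover adjustment")
        ratio = (pool_a.mean / t50_a) / (pool_b.mean / t50_b)
    elif (t50_a is None) != (t50_b is None):
        raise ValueError("supply both half-times or neither")
    rel = np.sqrt((pool_a.sd / pool_a.mean) ** 2 + (pool_b.sd / pool_b.mean) ** 2)
    return FluxRatio(ratio=float(ratio), sd=float(ratio * rel))


def bootstrap_flux_ratio_sd(
    pool_a: GroupSummary,
    pool_b: GroupSummary,
    n_boot: int = 10000,
    rng: np.random.Generator | None = None,
) -> float:
    """Parametric bootstrap SD of the pool ratio (normal groups)."""
    if rng is None:
        rng = np.random.default_rng(0)
    a = rng.normal(pool_a.mean, pool_a.sd, n_boot)
    b = rng.normal(pool_b.mean, pool_b.sd, n_boot)
    keep = b != 0
    return float(np.std(a[keep] / b[keep], ddof=1))


def compare_labeling_dynamics(
    t50_a: Mapping[str, Sequence[float]],
    t50_b: Mapping[str, Sequence[float]],
    alpha: float = 0.10,
) -> pd.DataFrame:
    """Per-metabolite Welch test on replicate-level half-times.

    Returns one row per metabolite present in both groups with the test
    statistic, fractional degrees of freedom, two-sided p-value and a
    flag for p > alpha (the 'labeling dynamics indistinguishable'
    outcome). Metabolites with fewer than 2 replicates in either group
    raise an error.
    """
    rows = []
    for metabolite in sorted(set(t50_a) & set(t50_b)):
        xs, ys = list(t50_a[metabolite]), list(t50_b[metabolite])
        if len(xs) < 2 or len(ys) < 2:
            raise ValueError(f"{metabolite}: need >= 2 replicate half-times per group")
        result = welch_test_samples(xs, ys)
        rows.append(
            {
                "metabolite": metabolite,
                "t": result.t,
                "df": result.df,
                "p_value": result.p_value,
                "n_a": len(xs),
                "n_b": len(ys),
                "not_significant": result.p_value > alpha,
            }
        )
    return pd.DataFrame(rows)
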