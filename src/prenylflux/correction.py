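"""Isotopologue correction and mean enrichment.

Measured mass fractions of a compound with n carbons mix the biological
labeling signal with (i) natural 13C on carbons not derived from the
tracer and (ii) the finite isotopic purity of the tracer itself (99% for
the U-13C-glucose used here). Working at high resolution, non-carbon
isotopes are resolved away, so the correction operates on carbon only:
``observed = C @ true`` where the column of C for a species with j
tracer carbons is the purity binomial over those j positions convolved
with the natural-abundance binomial over the remaining n-j carbons.
:func:`correct_spectrum` inverts this under a
non-negativity constraint; :func:`mean_enrichment` reduces a corrected
distribution to the mean fraction of 13C-occupied carbon positions,

    E = (sum_i i * M_i) / n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "DEFAULT_TRACER_PURITY",
    "IsotopologueDistribution",
    "CorrectionModel",
    "CorrectionResult",
    "binomial_pattern",
    "build_correction_model",
    "correct_spectrum",
    "mean_enrichment",
    "correct_table",
]

#: Natural abundance of 13C (fraction).
NATURAL_13C_ABUNDANCE = 0.0107
#: Isotopic purity of the U-13C-glucose tracer (fraction).
DEFAULT_TRACER_PURITY = 0.99


def binomial_pattern(n: int, p: float) -> np.ndarray:
    """Binomial(n, p) pmf over 0..n successes as a dense vector."""
    return stats.binom.pmf(np.arange(n + 1), n, p)


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Normalized vector M0..Mn of 13C mass-isotopologue fractions."""

    n: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", frac)
        if self.n < 0:
            raise ValueError("carbon count must be non-negative")
        if frac.shape != (self.n + 1,):
            raise ValueError(f"expected {self.n + 1} fractions for n={self.n}, got shape {frac.shape}")
        if np.any(frac < -1e-12):
            raise ValueError("isotopologue fractions must be non-negative")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError(f"isotopologue fractions must sum to 1 (got {frac.sum():.12f})")

    @classmethod
    def from_fractions(cls, fractions, normalize: bool = False) -> "IsotopologueDistribution":
        frac = np.asarray(fractions, dtype=float)
        if normalize:
            total = frac.sum()
            if total <= 0:
                raise ValueError("cannot normalize an all-zero vector")
            frac = np.clip(frac, 0.0, None) / np.clip(frac, 0.0, None).sum()
        return cls(n=len(frac) - 1, fractions=frac)


def mean_enrichment(dist: IsotopologueDistribution | np.ndarray) -> float:
    """Mean 13C enrichment E = (sum_i i*M_i)/n, a fraction in [0, 1]."""
    if isinstance(dist, IsotopologueDistribution):
        n, frac = dist.n, dist.fractions
    else:
        frac = np.asarray(dist, dtype=float)
        n = len(frac) - 1
    if n == 0:
        raise ValueError("mean enrichment is undefined for a carbon-free species")
    return float(np.arange(n + 1) @ frac / n)


@dataclass(frozen=True)
class CorrectionModel:
    """Forward measurement operator for one carbon count.

    ``matrix = N @ P`` maps a true (tracer-space) distribution to the
    observed mass-fraction pattern; columns of each factor sum to 1.
    """

    n: int
    natural_13c_abundance: float
    tracer_purity: float
    matrix: np.ndarray

    def forward(self, true_fractions: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(true_fractions, dtype=float)


def build_correction_model(
    n: int,
    natural_13c_abundance: float = NATURAL_13C_ABUNDANCE,
    tracer_purity: float = DEFAULT_TRACER_PURITY,
) -> CorrectionModel:
    """Build the combined natural-abundance x tracer-purity operator.

    The n-j non-tracer carbons of a nominally j-labeled species each
    carry 13C with probability a (binomial(n-j, a) pattern shifted by j
    when purity is 1); the j tracer positions are 13C with probability
    equal to the tracer purity. The two binomials convolve into column j.
    """
    if not (0.0 < natural_13c_abundance < 1.0):
        raise ValueError("natural 13C abundance must be in (0, 1)")
    if not (0.0 < tracer_purity <= 1.0):
        raise ValueError("tracer purity must be in (0, 1]")
    size = n + 1
    matrix = np.zeros((size, size))
    for j in range(size):
        # j tracer carbons at the tracer's purity, convolved with the
        # natural-abundance pattern of the n-j non-tracer carbons
        matrix[:, j] = np.convolve(
            binomial_pattern(j, tracer_purity),
            binomial_pattern(n - j, natural_13c_abundance),
        )
    return CorrectionModel(
        n=n,
        natural_13c_abundance=natural_13c_abundance,
        tracer_purity=tracer_purity,
        matrix=matrix,
    )


@dataclass(frozen=True)
class CorrectionResult:
    distribution: IsotopologueDistribution
    residual: float  #: relative L2 residual of the constrained solution


def correct_spectrum(
    raw: np.ndarray,
    model: CorrectionModel,
    residual_warn: float = 0.05,
) -> CorrectionResult:
    """Invert ``observed = matrix @ true`` under non-negativity.

    The raw vector may be on any intensity scale; the result is
    renormalized to sum 1. A relative residual above ``residual_warn``
    (noise or model mismatch) triggers a warning, never a failure.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (model.n + 1,):
        raise ValueError(f"raw vector length {raw.shape} does not match n={model.n}")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero raw spectrum cannot be corrected")
    scaled = raw / total
    x, rnorm = optimize.nnls(model.matrix, scaled)
    residual = float(rnorm)  # ||Ax - b||, with ||b|| ~ O(1)
    if residual > residual_warn:
        warnings.warn(
            f"correction residual {residual:.3g} exceeds {residual_warn:.3g}; "
            "spectrum poorly explained by the correction model",
            stacklevel=2,
        )
    dist = IsotopologueDistribution.from_fractions(x, normalize=True)
    return CorrectionResult(distribution=dist, residual=residual)


def correct_table(
    raw: pd.DataFrame,
    natural_13c_abundance: float = NATURAL_13C_ABUNDANCE,
    tracer_purity: float = DEFAULT_TRACER_PURITY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct a long-format measurement table.

    ``raw`` must carry columns strain, replicate, time_min, metabolite,
    m_index, intensity (extra columns pass through). Returns the table
    with an added ``corrected_fraction`` column and a per-spectrum
    summary with ``mean_enrichment`` and the correction residual.
    """
    required = {"strain", "replicate", "time_min", "metabolite", "m_index", "intensity"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    models: dict[int, CorrectionModel] = {}
    keys = ["strain", "replicate", "time_min", "metabolite"]
    corrected_parts: list[pd.DataFrame] = []
    summaries: list[dict] = []
    for key, group in raw.groupby(keys, sort=False, dropna=False):
        group = group.sort_values("m_index")
        m_index = group["m_index"].to_numpy()
        n = int(m_index.max())
        if not np.array_equal(m_index, np.arange(n + 1)):
            raise ValueError(f"incomplete isotopologue ladder for {key}: m_index {m_index.tolist()}")
        if n not in models:
            models[n] = build_correction_model(n, natural_13c_abundance, tracer_purity)
        result = correct_spectrum(group["intensity"].to_numpy(), models[n])
        part = group.copy()
        part["corrected_fraction"] = result.distribution.fractions
        corrected_parts.append(part)
        summaries.append(
            dict(
                zip(keys, key),
                mean_enrichment=mean_enrichment(result.distribution),
                residual=result.residual,
            )
        )
    return pd.concat(corrected_parts, ignore_index=True), pd.DataFrame(summaries)
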