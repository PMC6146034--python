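"""Cumulative sum scaling (CSS) normalization.

CSS divides each sample's counts by the cumulative sum of its counts up to
a data-chosen quantile of the nonzero count distribution, then rescales by
a fixed constant N so abundances are comparable across samples ("CSS
units").  Unlike total-sum scaling it is robust to the heavy right tail of
amplicon count distributions, because reads in dominant OTUs beyond the
quantile do not inflate the scaling factor.

Conventions: for sample j with m nonzero counts and quantile level l, the
reference quantile q_j is the ceil(l*m)-th order statistic of the nonzero
counts, and the scaling factor s_j is the sum of ALL counts of sample j
that are <= q_j.  The quantile level can be fixed or chosen adaptively by
:func:`select_css_quantile`, which scans a grid for the smallest level at
which sample quantiles start to disagree (relative median absolute
deviation from the across-sample median exceeding a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np

from cecofec.core_tables import OtuTable, TableError

__all__ = [
    "CssFactors",
    "NormalizedTable",
    "css_scaling_factors",
    "css_normalize",
    "select_css_quantile",
    "DEFAULT_SCALE",
]

DEFAULT_SCALE = 1000.0


@dataclass(frozen=True)
class CssFactors:
    """Per-sample CSS scaling factors at quantile level ``quantile``."""

    factors: np.ndarray  # s_j, reads
    sample_ids: tuple[str, ...]
    quantile: float  # l
    scale: float  # N

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile <= 1.0:
            raise TableError("quantile level must be in (0, 1]")
        if np.any(np.asarray(self.factors) <= 0):
            raise TableError("all scaling factors must be positive")


@dataclass(frozen=True)
class NormalizedTable:
    """CSS-normalized abundances (samples x OTUs, non-negative reals)."""

    abundances: np.ndarray
    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    factors: CssFactors
    log_transformed: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.abundances, index=list(self.sample_ids), columns=list(self.otu_ids)
        )


def _sample_quantile(nonzero_sorted: np.ndarray, level: float) -> float:
    """ceil(level*m)-th order statistic of the sorted nonzero counts."""
    m = len(nonzero_sorted)
    k = max(1, ceil(level * m))
    return float(nonzero_sorted[k - 1])


def css_scaling_factors(table: OtuTable, quantile: float, scale: float = DEFAULT_SCALE) -> CssFactors:
    """Compute per-sample CSS factors s_j at quantile level ``quantile``."""
    if not 0.0 < quantile <= 1.0:
        raise TableError("quantile level must be in (0, 1]")
    factors = np.empty(table.n_samples)
    for j in range(table.n_samples):
        row = table.counts[j]
        nonzero = np.sort(row[row > 0])
        if nonzero.size == 0:
            raise TableError(f"sample {table.sample_ids[j]!r} has no nonzero counts")
        q = _sample_quantile(nonzero, quantile)
        factors[j] = row[row <= q].sum()
    return CssFactors(factors, table.sample_ids, quantile, float(scale))


def css_normalize(
    table: OtuTable,
    quantile: float | None = None,
    scale: float = DEFAULT_SCALE,
    log2_transform: bool = False,
) -> NormalizedTable:
    """CSS-normalize: abundance_ij = count_ij / s_j * N.

    ``quantile=None`` selects the level adaptively via
    :func:`select_css_quantile`.  With ``log2_transform`` the stored
    abundances are log2(x + 1); the flag is recorded on the result.
    """
    if quantile is None:
        quantile = select_css_quantile(table)
    factors = css_scaling_factors(table, quantile, scale)
    abundances = table.counts / factors.factors[:, None] * factors.scale
    if log2_transform:
        abundances = np.log2(abundances + 1.0)
    return NormalizedTable(
        abundances, table.sample_ids, table.otu_ids, factors, log2_transform
    )


def select_css_quantile(
    table: OtuTable,
    grid: np.ndarray | None = None,
    instability_threshold: float = 0.1,
    fallback: float = 0.5,
) -> float:
    """Adaptive CSS quantile level.

    Scans levels 0.01..0.99 and finds the smallest level at which the
    per-sample reference quantiles become unstable across samples: the
    median absolute deviation of sample quantiles from their across-sample
    median, relative to that median, first exceeds
    ``instability_threshold``.  If no level on the grid is unstable the
    conventional median level ``fallback`` is returned.

    Like the reference CSS implementation, the selected level is floored
    at the median level (0.5, with a warning): count quantiles are
    integer-granular at the low tail, where the instability criterion can
    trigger spuriously on a handful of singleton reads.
    """
    if table.n_samples < 2:
        raise TableError("adaptive quantile selection needs at least 2 samples")
    if grid is None:
        grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
    sorted_nonzero = []
    for j in range(table.n_samples):
        row = table.counts[j]
        nz = np.sort(row[row > 0])
        if nz.size == 0:
            raise TableError(f"sample {table.sample_ids[j]!r} has no nonzero counts")
        sorted_nonzero.append(nz)
    for level in grid:
        q = np.array([_sample_quantile(nz, float(level)) for nz in sorted_nonzero])
        ref = float(np.median(q))
        if ref <= 0:
            continue
        rel_mad = float(np.median(np.abs(q - ref))) / ref
        if rel_mad > instability_threshold:
            if level < 0.5:
                warnings.warn(
                    f"adaptive CSS level {level:.2f} below the median level; using 0.50",
                    stacklevel=2,
                )
                return 0.5
            return float(level)
    return float(fallback)
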