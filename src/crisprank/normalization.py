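"""Median-ratio normalization of read counts across samples.

Sequencing depth differs between samples, so raw counts are scaled by a
per-sample size factor before any statistics are computed.  The size
factor of sample j is the median over sgRNAs of x_ij / x̂_i, where x̂_i is
the geometric mean of sgRNA i's counts across all samples.  sgRNAs with a
zero count in any sample have x̂_i = 0 and are excluded from the median
(they are still normalized).  Normalized counts are rounded half-away-
from-zero back to integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError
from .io import CountTable

__all__ = [
    "SizeFactors",
    "compute_size_factors",
    "normalize",
    "median_normalize",
    "total_count_normalize",
]


@dataclass
class SizeFactors:
    """Per-sample scale factors s_j and the per-sgRNA geometric means x̂_i.

    ``n_used`` counts the sgRNAs that contributed to the median, i.e. those
    with strictly positive counts in every sample.
    """

    factors: np.ndarray
    geometric_means: np.ndarray
    n_used: int

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.geometric_means = np.asarray(self.geometric_means, dtype=float)
        if not np.all(np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise NormalizationError("size factors must be positive and finite")


def compute_size_factors(table: CountTable) -> SizeFactors:
    """Median-of-ratios size factors, one per sample.

    Raises :class:`NormalizationError` when no sgRNA has positive counts in
    every sample (the median would be over an empty set); total-count
    normalization is the fallback in that case.
    """
    counts = table.counts.astype(float)
    positive = (counts > 0).all(axis=1)
    geo = np.zeros(table.n_sgrnas)
    if positive.any():
        geo[positive] = np.exp(np.log(counts[positive]).mean(axis=1))
    else:
        raise NormalizationError(
            "no sgRNA has positive counts in every sample; median-ratio size "
            "factors are undefined — use total_count_normalize instead"
        )
    ratios = counts[positive] / geo[positive, None]
    factors = np.median(ratios, axis=0)
    return SizeFactors(factors=factors, geometric_means=geo, n_used=int(positive.sum()))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # counts are non-negative, so half-away-from-zero == floor(x + 0.5)
    return np.floor(x + 0.5).astype(np.int64)


def normalize(table: CountTable, sf: SizeFactors) -> CountTable:
    """Divide each sample's counts by its size factor and round to integers."""
    if sf.factors.shape[0] != table.n_samples:
        raise NormalizationError("size factors do not match the table's samples")
    scaled = table.counts / sf.factors[None, :]
    return CountTable(
        sgrna_ids=list(table.sgrna_ids),
        gene_ids=list(table.gene_ids),
        sample_names=list(table.sample_names),
        counts=_round_half_away(scaled),
    )


def median_normalize(table: CountTable) -> tuple[CountTable, SizeFactors]:
    """Convenience wrapper: compute size factors and normalize in one step."""
    sf = compute_size_factors(table)
    return normalize(table, sf), sf


def total_count_normalize(table: CountTable) -> CountTable:
    """Scale every sample to the mean library size, then round.

    Simpler than median-ratio and robust to all-zero rows, but sensitive to
    a handful of sgRNAs dominating a library.
    """
    totals = table.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        j = int(np.argmax(totals <= 0))
        raise NormalizationError(
            f"sample {table.sample_names[j]!r} has zero total reads"
        )
    factors = totals / totals.mean()
    scaled = table.counts / factors[None, :]
    return CountTable(
        sgrna_ids=list(table.sgrna_ids),
        gene_ids=list(table.gene_ids),
        sample_names=list(table.sample_names),
        counts=_round_half_away(scaled),
    )
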