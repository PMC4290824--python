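"""Gene ranking by α-RRA: modified robust rank aggregation.

Under the null a gene's sgRNAs are scattered uniformly through the ranked
sgRNA list, so their rank percentiles u_(1) ≤ … ≤ u_(n) behave like sorted
uniforms and the k-th smallest follows Beta(k, n+1−k).  Classic RRA scores
a gene by the minimum of the Beta CDF p-values over all n order statistics;
that also rewards genes whose sgRNAs cluster in the *middle* of the list.
The α modification restricts the minimum to the j "good" sgRNAs — those in
the significant top fraction of the list (directional NB p-value below a
threshold and rank within the top α fraction) — so insignificant sgRNAs
cannot drive the score:

    ρ = min(p_1, …, p_j),   ρ = 1 when j = 0.

Significance of ρ is assessed by permutation: sgRNAs are reassigned to
genes at random keeping each gene's sgRNA count, the null ρ distribution
is collected per gene size, and the empirical p-value uses the +1/(N+1)
estimator.  FDR across genes is Benjamini-Hochberg.

The same machinery scores pathways over the ranked gene list (see
:mod:`crisprank.pathway`); the engine :func:`aggregate_groups` is generic
over "items" (sgRNAs or genes) and "groups" (genes or pathways).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AlphaConfig",
    "beta_order_pvalues",
    "alpha_select",
    "rho_score",
    "permutation_null",
    "gene_pvalues",
    "bh_fdr",
    "aggregate_groups",
    "gene_test",
]


@dataclass(frozen=True)
class AlphaConfig:
    """Tuning knobs of α-RRA.

    ``alpha_percent=None`` uses the realized fraction of items passing
    ``p_threshold``, which makes the two goodness criteria coincide.
    ``num_permutations=None`` defaults to 100 × (number of groups tested).
    """

    p_threshold: float = 0.05
    alpha_percent: float | None = None
    num_permutations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.alpha_percent is not None and not (0 <= self.alpha_percent <= 1):
            raise ValueError("alpha_percent must be in [0, 1]")
        if self.num_permutations is not None and self.num_permutations < 1:
            raise ValueError("num_permutations must be >= 1")


def beta_order_pvalues(u: np.ndarray) -> np.ndarray:
    """Beta order-statistic p-values of sorted percentiles.

    p_k = P(Beta(k, n+1−k) ≤ u_(k)): how surprisingly small the k-th
    smallest of n uniform percentiles is.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError("u must be 1-D")
    if np.any(np.diff(u) < 0):
        raise ValueError("percentiles must be sorted ascending")
    if np.any((u <= 0) | (u > 1)):
        raise ValueError("percentiles must lie in (0, 1]")
    n = u.size
    k = np.arange(1, n + 1)
    return stats.beta.cdf(u, k, n + 1 - k)


def alpha_select(
    pvalues: np.ndarray, ranks: np.ndarray, m: int, cfg: AlphaConfig
) -> np.ndarray:
    """Goodness flags: p below threshold AND rank within the top α fraction.

    ``pvalues`` and ``ranks`` are aligned per item; ranks are 1..m for the
    direction under test.  Because items are ranked by ascending p, both
    criteria are rank prefixes and so is their intersection.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    ranks = np.asarray(ranks)
    good = pvalues < cfg.p_threshold
    if cfg.alpha_percent is not None:
        good &= ranks <= cfg.alpha_percent * m
    return good


def good_prefix_length(good: np.ndarray, ranks: np.ndarray) -> int:
    """Length of the rank prefix formed by the goodness flags.

    The α-selection must pick a contiguous top slice of the ranking; this
    validates that and returns its length.
    """
    good = np.asarray(good, dtype=bool)
    n_good = int(good.sum())
    if n_good and int(np.asarray(ranks)[good].max()) != n_good:
        raise ValueError("goodness flags do not form a rank prefix")
    return n_good


def rho_score(u: np.ndarray, j: int) -> float:
    """ρ = min of the first j beta order p-values; 1 when nothing is good."""
    u = np.asarray(u, dtype=float)
    if j > u.size:
        raise ValueError(f"j={j} exceeds number of percentiles n={u.size}")
    if j == 0:
        return 1.0
    return float(beta_order_pvalues(u)[:j].min())


def _sample_rank_rows(
    rng: np.random.Generator, n_rows: int, n: int, m: int
) -> np.ndarray:
    """n_rows draws of n distinct ranks from 1..m."""
    if n > m:
        raise ValueError(f"cannot draw {n} distinct ranks from 1..{m}")
    if n * n * 4 >= m:  # collisions likely; draw row-wise without replacement
        out = np.empty((n_rows, n), dtype=np.int64)
        for i in range(n_rows):
            out[i] = rng.choice(m, size=n, replace=False) + 1
        return out
    # rejection sampling: i.i.d. draws, rows with duplicates redrawn, which
    # leaves the uniform without-replacement law on the accepted rows
    ranks = rng.integers(1, m + 1, size=(n_rows, n))
    while True:
        s = np.sort(ranks, axis=1)
        bad = (np.diff(s, axis=1) == 0).any(axis=1)
        if not bad.any():
            return ranks
        ranks[bad] = rng.integers(1, m + 1, size=(int(bad.sum()), n))


def _rho_rows(ranks: np.ndarray, m: int, n_good_prefix: int) -> np.ndarray:
    """Vectorized ρ for many rank rows of equal size.

    Goodness is inherited from the drawn positions; since the good items
    form the prefix of the ranking, an item is good iff its rank is at most
    ``n_good_prefix``.
    """
    s = np.sort(ranks, axis=1)
    n = s.shape[1]
    u = s / m
    k = np.arange(1, n + 1)
    pvals = stats.beta.cdf(u, k[None, :], (n + 1 - k)[None, :])
    j = (s <= n_good_prefix).sum(axis=1)
    masked = np.where(k[None, :] <= j[:, None], pvals, np.inf)
    return np.where(j > 0, masked.min(axis=1, initial=np.inf), 1.0)


def permutation_null(
    gene_sizes: Sequence[int],
    m: int,
    cfg: AlphaConfig,
    n_good_prefix: int,
    n_groups: int | None = None,
) -> dict[int, np.ndarray]:
    """Null ρ samples per gene size under random item-to-group assignment.

    One shared pool of ``num_permutations`` draws is generated per distinct
    size; under the permutation scheme (ranks drawn without replacement,
    sizes kept) the null is identical for groups of equal size, so sharing
    the pool loses nothing and the total number of draws is at least the
    configured count.  Pools are returned sorted.
    """
    rng = np.random.default_rng(cfg.seed)
    if n_groups is None:
        n_groups = len(gene_sizes)
    n_null = cfg.num_permutations or 100 * max(n_groups, 1)
    null: dict[int, np.ndarray] = {}
    for n in sorted(set(int(s) for s in gene_sizes)):
        ranks = _sample_rank_rows(rng, n_null, n, m)
        rhos = _rho_rows(ranks, m, n_good_prefix)
        null[n] = np.sort(rhos)
    return null


def gene_pvalues(
    observed: Mapping[str, tuple[int, float]], null: Mapping[int, np.ndarray]
) -> dict[str, float]:
    """Empirical permutation p-values, size-matched against the null pools.

    ``observed`` maps group id → (size n, ρ); p = (#{null ρ ≤ ρ_obs} + 1) /
    (N_null + 1), which can never be zero.  Null pools must be sorted.
    """
    out: dict[str, float] = {}
    for key, (n, rho) in observed.items():
        if n not in null:
            raise KeyError(f"no null stratum for size n={n}")
        pool = null[n]
        n_leq = int(np.searchsorted(pool, rho, side="right"))
        out[key] = (n_leq + 1) / (pool.size + 1)
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def aggregate_groups(
    group_ranks: Mapping[str, Sequence[int]],
    m: int,
    n_good_prefix: int,
    cfg: AlphaConfig,
) -> pd.DataFrame:
    """α-RRA scoring of groups of ranked items (the shared engine).

    ``group_ranks`` maps each group to the ranks (1..m, distinct) of its
    member items within the full ranking; ``n_good_prefix`` is the number
    of top-ranked items that passed α-selection.  Returns a DataFrame with
    columns group, n, j, rho, p, fdr, rank, ranked ascending by
    (p, ρ, group id).
    """
    observed: dict[str, tuple[int, float]] = {}
    rows = []
    for grp, ranks in group_ranks.items():
        r = np.sort(np.asarray(ranks, dtype=int))
        if r.size == 0:
            raise ValueError(f"group {grp!r} has no ranked items")
        u = r / m
        j = int((r <= n_good_prefix).sum())
        rho = rho_score(u, j)
        observed[grp] = (r.size, rho)
        rows.append({"group": grp, "n": r.size, "j": j, "rho": rho})

    sizes = [n for n, _ in observed.values()]
    null = permutation_null(sizes, m, cfg, n_good_prefix, n_groups=len(rows))
    pvals = gene_pvalues(observed, null)

    df = pd.DataFrame(rows)
    df["p"] = df["group"].map(pvals)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    order = np.lexsort(
        (df["group"].to_numpy(), df["rho"].to_numpy(), df["p"].to_numpy())
    )
    rank = np.empty(len(df), dtype=np.int64)
    rank[order] = np.arange(1, len(df) + 1)
    df["rank"] = rank
    return df.sort_values("rank", kind="mergesort").reset_index(drop=True)


def gene_test(
    sgrna_results: pd.DataFrame, cfg: AlphaConfig, direction: str
) -> pd.DataFrame:
    """α-RRA over genes for one selection direction.

    ``sgrna_results`` is the table produced by
    :func:`~crisprank.sgrna_test.sgrna_test`; ``direction`` is 'neg'
    (depletion, uses p_low/rank_neg) or 'pos' (enrichment).  Genes are
    ranked ascending by (permutation p, ρ, gene id).
    """
    if direction not in ("neg", "pos"):
        raise ValueError(f"direction must be 'neg' or 'pos', got {direction!r}")
    pcol = "p_low" if direction == "neg" else "p_high"
    rcol = "rank_neg" if direction == "neg" else "rank_pos"
    m = len(sgrna_results)
    # all-zero sgRNAs sit at the bottom of the ranking by construction; give
    # them a p-value of 1 for the goodness test so they can never be "good"
    # even when the pseudo-mean path produced a tiny nominal p.
    pvals = np.where(
        sgrna_results["all_zero"].to_numpy(), 1.0, sgrna_results[pcol].to_numpy()
    )
    ranks = sgrna_results[rcol].to_numpy()
    good = alpha_select(pvals, ranks, m, cfg)
    n_good = good_prefix_length(good, ranks)

    group_ranks: dict[str, list[int]] = {}
    for gene, rank in zip(sgrna_results["gene"], ranks):
        group_ranks.setdefault(gene, []).append(int(rank))

    df = aggregate_groups(group_ranks, m, n_good, cfg)
    return df.rename(columns={"group": "gene"})
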