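"""Pathway-level α-RRA applied to the ranked gene list.

Genes play the role that sgRNAs play at the gene level: each pathway's
member genes present in the screen contribute rank percentiles over the
n_g tested genes, a gene is "good" when its permutation p-value is below
the threshold and its rank lies within the top α fraction of the gene
ranking, and pathway ρ scores are calibrated by permutation (100 × number
of pathways by default) with BH FDR across pathways.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import PathwayDB
from .rra import AlphaConfig, aggregate_groups, alpha_select, good_prefix_length

__all__ = ["pathway_test"]


def pathway_test(
    gene_results: pd.DataFrame, db: PathwayDB, cfg: AlphaConfig, direction: str
) -> pd.DataFrame:
    """Rank pathways by the consistency of their genes' selection.

    ``gene_results`` is a single-direction gene table from
    :func:`~crisprank.rra.gene_test`.  Pathway membership for genes absent
    from the screen is ignored; pathways with no screened gene are dropped
    with a warning.  Overlapping pathways are tested independently.
    """
    if direction not in ("neg", "pos"):
        raise ValueError(f"direction must be 'neg' or 'pos', got {direction!r}")
    genes = gene_results["gene"].tolist()
    ranks = gene_results["rank"].to_numpy()
    pvals = gene_results["p"].to_numpy()
    n_g = len(genes)
    gene_rank = dict(zip(genes, (int(r) for r in ranks)))
    present = set(genes)

    group_ranks: dict[str, list[int]] = {}
    for name, members in db.pathways.items():
        screened = sorted(members & present)
        if not screened:
            warnings.warn(
                f"pathway {name!r} has no genes in the screen; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        group_ranks[name] = [gene_rank[g] for g in screened]
    if not group_ranks:
        return pd.DataFrame(columns=["pathway", "n", "j", "rho", "p", "fdr", "rank"])

    good = alpha_select(pvals, ranks, n_g, cfg)
    n_good = good_prefix_length(good, ranks)

    cfg_pw = AlphaConfig(
        p_threshold=cfg.p_threshold,
        alpha_percent=cfg.alpha_percent,
        num_permutations=cfg.num_permutations or 100 * len(group_ranks),
        seed=cfg.seed,
    )
    df = aggregate_groups(group_ranks, n_g, n_good, cfg_pw)
    return df.rename(columns={"group": "pathway"})
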