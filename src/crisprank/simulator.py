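"""Synthetic pooled-screen generator for calibration and recovery studies.

Counts are drawn from the same generative family the test assumes:
baseline sgRNA abundances are log-normal across the library, and each
replicate count is negative-binomial with variance following the
overdispersion law σ² = μ + k·μ^b (Poisson when k = 0).  A chosen
fraction of genes is negatively or positively selected; in treatment
samples the mean of every sgRNA of a selected gene is multiplied or
divided by the effect size, optionally jittered per sgRNA to mimic
unequal knockout efficiencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable

__all__ = ["SimConfig", "simulate_screen", "evaluate_recovery"]


@dataclass(frozen=True)
class SimConfig:
    """Study design of a simulated screen.

    Defaults describe a small but realistic knockout library: 1,000 genes
    with 4 sgRNAs each, two replicates per condition, a median baseline of
    ~300 reads per sgRNA spread over roughly two orders of magnitude, and
    mild overdispersion (k=0.2, b=1.5).  ``effect_size`` is the fold
    change of selected genes (4 ⇒ 4-fold depletion for 'neg' genes,
    4-fold enrichment for 'pos' genes).
    """

    n_genes: int = 1000
    sgrnas_per_gene: int = 4
    n_control: int = 2
    n_treatment: int = 2
    baseline_log_mean: float = math.log(300.0)
    baseline_log_sd: float = 1.0
    k: float = 0.2
    b: float = 1.5
    fraction_neg: float = 0.0
    fraction_pos: float = 0.0
    effect_size: float = 4.0
    efficiency_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_neg <= 1 and 0 <= self.fraction_pos <= 1):
            raise ValueError("selected fractions must lie in [0, 1]")
        if self.fraction_neg + self.fraction_pos > 1:
            raise ValueError("selected fractions must sum to at most 1")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.k < 0 or self.b < 0:
            raise ValueError("k and b must be non-negative")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, k: float, b: float) -> np.ndarray:
    """One replicate of NB counts with var = mean + k·mean^b (Poisson if k=0)."""
    mean = np.maximum(mean, 1e-8)
    if k == 0:
        return rng.poisson(mean)
    var = mean + k * mean**b
    r = mean**2 / (var - mean)
    p_success = mean / var
    return rng.negative_binomial(r, p_success)


def simulate_screen(cfg: SimConfig) -> tuple[CountTable, pd.DataFrame]:
    """Generate a count table plus the ground-truth gene labels.

    Returns ``(table, truth)`` where ``truth`` has columns gene, label
    ('neg'/'pos'/'null') and fold (treatment-to-control mean ratio).
    """
    rng = np.random.default_rng(cfg.seed)
    n_genes, spg = cfg.n_genes, cfg.sgrnas_per_gene
    m = n_genes * spg
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]

    n_neg = round(cfg.fraction_neg * n_genes)
    n_pos = round(cfg.fraction_pos * n_genes)
    labels = np.array(["null"] * n_genes, dtype=object)
    chosen = rng.permutation(n_genes)
    labels[chosen[:n_neg]] = "neg"
    labels[chosen[n_neg : n_neg + n_pos]] = "pos"
    fold = np.where(
        labels == "neg", 1.0 / cfg.effect_size, np.where(labels == "pos", cfg.effect_size, 1.0)
    )

    gene_ids = np.repeat(genes, spg).tolist()
    sgrna_ids = [f"{g}_sg{s + 1}" for g in genes for s in range(spg)]
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=m)

    lfc = np.repeat(np.log(fold), spg)
    if cfg.efficiency_jitter_sd > 0:
        # knockout efficiency scales the magnitude of the per-sgRNA effect
        lfc = lfc * np.exp(rng.normal(0.0, cfg.efficiency_jitter_sd, size=m))
    treat_mean = baseline * np.exp(lfc)

    samples = [f"control_{j + 1}" for j in range(cfg.n_control)] + [
        f"treatment_{j + 1}" for j in range(cfg.n_treatment)
    ]
    counts = np.empty((m, len(samples)), dtype=np.int64)
    for j in range(cfg.n_control):
        counts[:, j] = _nb_draw(rng, baseline, cfg.k, cfg.b)
    for j in range(cfg.n_treatment):
        counts[:, cfg.n_control + j] = _nb_draw(rng, treat_mean, cfg.k, cfg.b)

    table = CountTable(sgrna_ids, gene_ids, samples, counts)
    truth = pd.DataFrame({"gene": genes, "label": labels, "fold": fold})
    return table, truth


def evaluate_recovery(
    gene_results: pd.DataFrame, truth: pd.DataFrame, top_k: int, label: str = "neg"
) -> float:
    """Fraction of truly selected genes ranked within the top ``top_k``.

    ``gene_results`` is a single-direction table from gene_test; ``label``
    picks which truth stratum ('neg' or 'pos') counts as a hit.
    """
    selected = set(truth.loc[truth["label"] == label, "gene"])
    if not selected:
        raise ValueError(f"truth table has no genes labelled {label!r}")
    top = set(gene_results.loc[gene_results["rank"] <= top_k, "gene"])
    return len(selected & top) / len(selected)
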