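"""Per-sgRNA negative-binomial tests between two conditions.

For each sgRNA the null model is NB(μ_iA, σ²_iA): the control mean with
the model-adjusted variance from the fitted mean-variance law.  The
treatment mean μ_iB is compared against that null by two one-sided tail
probabilities,

    p_high = P(X > μ_iB)   (positive selection / enrichment)
    p_low  = P(X < μ_iB)   (negative selection / depletion),

with the strict inequalities read on integer support: "x > μ_iB" means
x ≥ ⌊μ_iB⌋ + 1 and "x < μ_iB" means x ≤ ⌈μ_iB⌉ − 1.  sgRNAs are then
ranked per direction by ascending p-value.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .io import CountTable, DesignSpec
from .variance_model import MeanVarModel, NBParams, VARIANCE_EPS, predict_variance

__all__ = ["sgrna_test", "nb_tail", "rank_sgrnas", "P_FLOOR", "PSEUDO_MEAN"]

#: p-values are floored here to stay strictly positive for downstream logs
P_FLOOR = 1e-300

#: control mean substituted when every control replicate is zero
PSEUDO_MEAN = 0.5


def nb_tail(params: NBParams, threshold: float, direction: str) -> float:
    """One-sided NB tail probability at a (possibly non-integral) threshold.

    ``direction='greater'`` returns P(X > threshold), ``'less'`` returns
    P(X < threshold), both exact for real-valued size r via the regularized
    incomplete beta function underlying scipy's nbinom.
    """
    dist = stats.nbinom(params.r, 1.0 - params.p)  # scipy wants P(success)
    if direction == "greater":
        p = float(dist.sf(math.floor(threshold)))
    elif direction == "less":
        p = float(dist.cdf(math.ceil(threshold) - 1))
    else:
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    return max(p, P_FLOOR)


def sgrna_test(
    norm_table: CountTable, design: DesignSpec, model: MeanVarModel
) -> pd.DataFrame:
    """Test every sgRNA for enrichment/depletion of treatment vs control.

    Returns a DataFrame with one row per sgRNA in table order: sgRNA, gene,
    control_mean, treat_mean, adj_var, p_low, p_high, rank_neg, rank_pos.
    All-zero sgRNAs (no reads anywhere) are kept but forced to the bottom
    of both rankings.
    """
    design.validate(norm_table)
    ctrl = norm_table.sample_index(list(design.control_samples))
    trt = norm_table.sample_index(list(design.treatment_samples))
    if ctrl.size == 0 or trt.size == 0:
        raise DesignError("both conditions need at least one sample")

    counts = norm_table.counts.astype(float)
    mu_a_raw = counts[:, ctrl].mean(axis=1)
    mu_b = counts[:, trt].mean(axis=1)
    mu_a = np.where(mu_a_raw > 0, mu_a_raw, PSEUDO_MEAN)
    var_a = predict_variance(model, mu_a)
    # NB parameterization needs strict overdispersion (Poisson-fit models
    # give var == mu exactly); inflate by the documented epsilon.
    var_a = np.maximum(var_a, mu_a * (1.0 + VARIANCE_EPS))

    r = mu_a * mu_a / (var_a - mu_a)
    p_success = mu_a / var_a
    # P(X > mu_b) on integer support: X >= floor(mu_b) + 1
    p_high = stats.nbinom.sf(np.floor(mu_b), r, p_success)
    # P(X < mu_b): X <= ceil(mu_b) - 1
    p_low = stats.nbinom.cdf(np.ceil(mu_b) - 1.0, r, p_success)
    p_high = np.maximum(p_high, P_FLOOR)
    p_low = np.maximum(p_low, P_FLOOR)

    out = pd.DataFrame(
        {
            "sgRNA": norm_table.sgrna_ids,
            "gene": norm_table.gene_ids,
            "control_mean": mu_a_raw,
            "treat_mean": mu_b,
            "adj_var": var_a,
            "p_low": p_low,
            "p_high": p_high,
            "all_zero": norm_table.all_zero,
        }
    )
    out["rank_neg"] = _ranks(out, "p_low")
    out["rank_pos"] = _ranks(out, "p_high")
    return out


def _ranks(results: pd.DataFrame, pcol: str) -> np.ndarray:
    """1..M ranks: ascending p, ties by larger |μ_B − μ_A|, then sgRNA id.

    All-zero sgRNAs sort after everything else regardless of their p-value.
    """
    absdiff = (results["treat_mean"] - results["control_mean"]).abs()
    order = np.lexsort(
        (
            results["sgRNA"].to_numpy(),
            -absdiff.to_numpy(),
            results[pcol].to_numpy(),
            results["all_zero"].to_numpy(),
        )
    )
    ranks = np.empty(len(results), dtype=np.int64)
    ranks[order] = np.arange(1, len(results) + 1)
    return ranks


def rank_sgrnas(results: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Results sorted by the direction's ranking ('neg' uses p_low)."""
    if direction not in ("neg", "pos"):
        raise ValueError(f"direction must be 'neg' or 'pos', got {direction!r}")
    col = "rank_neg" if direction == "neg" else "rank_pos"
    return results.sort_values(col, kind="mergesort").reset_index(drop=True)
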