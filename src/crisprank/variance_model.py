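"""Empirical mean-variance modeling and negative-binomial parameterization.

Replicate counts of pooled screens are overdispersed: the sample variance
σ̂² exceeds the sample mean μ̂.  With few replicates, per-sgRNA variance
estimates are too noisy to use directly, so information is shared across
sgRNAs through the smooth law

    σ² = μ + k·μ^b,      k ≥ 0, b ≥ 0,

fit by ordinary least squares of log(σ̂² − μ̂) on log(μ̂) over sgRNAs with
μ̂ > 0 and σ̂² > μ̂.  A (mean, variance) pair is converted to the
negative-binomial parameters by the method of moments:

    p = 1 − μ/σ²,   r = μ² / (σ² − μ),

where r may be non-integral (gamma-extended NB).  Note that in this
parameterization the NB mean is r·p/(1 − p); the size/success-probability
convention used by scipy and numpy is obtained with p_success = 1 − p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import DispersionError, MomentsError, VarianceModelError
from .io import CountTable

__all__ = [
    "MomentPair",
    "MeanVarModel",
    "NBParams",
    "sample_moments",
    "fit_mean_variance",
    "predict_variance",
    "nb_params",
]

#: relative inflation applied when a predicted variance is not above the mean
VARIANCE_EPS = 1e-2


class MomentPair(NamedTuple):
    """Sample mean and unbiased sample variance of one sgRNA's replicates."""

    mean: float
    var: float


@dataclass
class MeanVarModel:
    """Fitted parameters of the variance law σ² = μ + k·μ^b."""

    k: float
    b: float
    n_points: int
    r2: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.k < 0 or self.b < 0:
            raise VarianceModelError("k and b must be non-negative")


class NBParams(NamedTuple):
    """Moment-matched NB parameters; mean = r·p/(1−p), so p here is the
    complement of the scipy/numpy success probability."""

    r: float
    p: float
    mean: float
    var: float


def sample_moments(
    norm_table: CountTable, samples: Sequence[str]
) -> list[MomentPair]:
    """Per-sgRNA mean and unbiased (n−1) variance over the given samples."""
    if len(samples) < 2:
        raise MomentsError(
            "sample moments need at least two replicates; pool both conditions "
            "when the controls have no replicates"
        )
    cols = norm_table.sample_index(list(samples))
    x = norm_table.counts[:, cols].astype(float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    return [MomentPair(float(m), float(v)) for m, v in zip(mean, var)]


def fit_mean_variance(moments: Sequence[MomentPair]) -> MeanVarModel:
    """OLS regression in log space to estimate (k, b).

    Only points with μ̂ > 0 and σ̂² > μ̂ enter the regression (the response
    log(σ̂² − μ̂) is undefined otherwise); their number is reported as
    ``n_points`` and the discarded count as ``n_excluded``.  A negative
    fitted exponent is clamped to 0 with a warning.
    """
    mu = np.array([m.mean for m in moments], dtype=float)
    var = np.array([m.var for m in moments], dtype=float)
    usable = (mu > 0) & (var > mu)
    n_points = int(usable.sum())
    if n_points < 2:
        raise VarianceModelError(
            f"only {n_points} sgRNA(s) with variance above mean; cannot fit "
            "the overdispersion law — fall back to the Poisson model (k=0)"
        )
    x = np.log(mu[usable])
    y = np.log(var[usable] - mu[usable])
    fit = stats.linregress(x, y)
    b = float(fit.slope)
    k = float(np.exp(fit.intercept))
    if b < 0:
        warnings.warn(
            f"fitted exponent b={b:.4g} is negative; clamping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        b = 0.0
    return MeanVarModel(
        k=k,
        b=b,
        n_points=n_points,
        r2=float(fit.rvalue**2),
        n_excluded=len(moments) - n_points,
    )


def predict_variance(model: MeanVarModel, mean):
    """Model variance μ + k·μ^b at the given mean(s).

    If k > 0 but k·μ^b underflows to zero for a positive mean, the result
    is inflated to μ·(1 + 1e-2) so that downstream NB parameterization
    (which needs σ² > μ) stays defined.
    """
    mu = np.asarray(mean, dtype=float)
    if (mu < 0).any():
        raise ValueError("mean must be non-negative")
    var = mu + model.k * mu**model.b
    if model.k > 0:
        degenerate = (var <= mu) & (mu > 0)
        var = np.where(degenerate, mu * (1.0 + VARIANCE_EPS), var)
    return float(var) if np.isscalar(mean) else var


def nb_params(mean: float, var: float) -> NBParams:
    """Method-of-moments NB parameters for an overdispersed (μ, σ²) pair."""
    if mean <= 0:
        raise DispersionError(f"NB mean must be positive, got {mean}")
    if var <= mean:
        raise DispersionError(
            f"NB needs variance above mean (mu={mean}, var={var}); inflate the "
            "variance before parameterizing"
        )
    p = 1.0 - mean / var
    r = mean * mean / (var - mean)
    return NBParams(r=r, p=p, mean=mean, var=var)
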