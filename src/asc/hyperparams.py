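"""Empirical-Bayes hyperparameter estimation.

Two hyperparameters drive the hierarchical model:

* ``alpha`` -- decay rate (per log10 unit) of the shifted exponential prior
  on the expression level lambda.  Estimated by matching two empirical
  quantiles of the average log10 rpm distribution to the exponential CDF,
  or by a conditional-moment (memorylessness) estimator.
* ``tau`` -- standard deviation (log10 units) of the Gaussian prior on the
  log fold change delta, representing ordinary biological variation between
  replicates.  Estimated from the spread of log-ratio differences among
  high-count genes, where binomial noise is negligible; the interquartile
  range is used instead of the sample SD so genes with genuinely extreme
  differential expression do not inflate the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .count_data import CountTable

__all__ = [
    "GAUSSIAN_IQR",
    "Hyperparameters",
    "empirical_quantile",
    "estimate_alpha_quantile",
    "estimate_alpha_moment",
    "estimate_tau",
    "estimate_hyperparameters",
]

#: Interquartile range of the standard Gaussian, 2 * Phi^{-1}(0.75).
GAUSSIAN_IQR = 1.3489795003921634


@dataclass
class Hyperparameters:
    """Prior hyperparameters and the settings used to estimate them.

    ``lambda0`` (the shift of the exponential prior) is recorded for
    completeness but never enters the posterior: shifted exponentials with
    the same rate have proportional densities (memorylessness), so the shift
    cancels on normalization.
    """

    alpha: float
    tau: float
    q1: float = 0.8
    q2: float = 0.9
    min_total: int = 1000
    lambda0: float | None = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not (0.0 < self.q1 < self.q2 < 1.0):
            raise ValueError(f"need 0 < q1 < q2 < 1, got q1={self.q1}, q2={self.q2}")
        if self.min_total < 1:
            raise ValueError(f"min_total must be >= 1, got {self.min_total}")


def empirical_quantile(values, q: float) -> float:
    """Inverse empirical CDF with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError(f"need at least 2 finite values, got {v.size}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {q}")
    return float(np.quantile(v, q, method="linear"))


def estimate_alpha_quantile(avg_log_rpm, q1: float = 0.8, q2: float = 0.9):
    """Estimate (alpha, lambda0) of the shifted exponential prior by quantile matching.

    Solving ``q_i = 1 - exp(-alpha (l_i - lambda0))`` at the two empirical
    quantiles ``l_i = F^{-1}(q_i)`` gives::

        alpha   = -[log(1-q1) - log(1-q2)] / (l1 - l2)
        lambda0 = l1 + log(1-q1) / alpha

    alpha is invariant under adding a constant to all inputs; the shift is
    absorbed by lambda0.
    """
    if not q1 < q2:
        raise ValueError(f"need q1 < q2, got {q1} >= {q2}")
    l1 = empirical_quantile(avg_log_rpm, q1)
    l2 = empirical_quantile(avg_log_rpm, q2)
    if l1 >= l2:
        raise ValueError(
            f"empirical quantiles are tied (F^-1({q1}) = {l1:g}, F^-1({q2}) = {l2:g}); "
            "choose more separated quantile levels"
        )
    alpha = -(math.log1p(-q1) - math.log1p(-q2)) / (l1 - l2)
    lambda0 = l1 + math.log1p(-q1) / alpha
    return alpha, lambda0


def estimate_alpha_moment(avg_log_rpm, q: float = 0.8) -> float:
    """Estimate alpha from the conditional mean above a quantile threshold.

    For an exponential, ``E[lambda | lambda > F^{-1}(q)] = F^{-1}(q) + 1/alpha``
    regardless of the shift (lack of memory), so
    ``alpha = 1 / (mean excess above the threshold)``.
    """
    v = np.asarray(avg_log_rpm, dtype=float)
    thr = empirical_quantile(v, q)
    above = v[np.isfinite(v) & (v > thr)]
    if above.size < 2:
        raise ValueError(f"only {above.size} values above F^-1({q}) = {thr:g}; need >= 2")
    excess = float(above.mean() - thr)
    if excess <= 0:
        raise ValueError("mean excess above the threshold is not positive")
    return 1.0 / excess


def estimate_tau(table: CountTable, min_total: int = 1000, min_genes: int = 20) -> float:
    """Estimate the biological-variation SD tau from high-count genes.

    Restricted to genes with ``x1 + x2 > min_total``, where binomial noise on
    the log proportions is small, tau is the IQR of
    ``log10(p1) - log10(p2)`` divided by the IQR of the standard Gaussian
    (1.34898).  A zero count in a qualifying gene uses the 0.5 floor; the
    IQR makes such genes numerically irrelevant.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    total = table.x1 + table.x2
    mask = total > min_total
    n_ok = int(mask.sum())
    if n_ok < min_genes:
        raise ValueError(
            f"only {n_ok} genes have x1+x2 > {min_total}; need at least {min_genes} "
            "for tau estimation (lower min_total or provide deeper data)"
        )
    x1 = np.maximum(table.x1[mask].astype(float), 0.5)
    x2 = np.maximum(table.x2[mask].astype(float), 0.5)
    d = np.log10(x1 / table.N1) - np.log10(x2 / table.N2)
    q25, q75 = np.quantile(d, [0.25, 0.75])
    iqr = float(q75 - q25)
    if iqr <= 0:
        raise ValueError("log-ratio differences of qualifying genes are degenerate")
    return iqr / GAUSSIAN_IQR


def estimate_hyperparameters(
    table: CountTable,
    q1: float = 0.8,
    q2: float = 0.9,
    min_total: int = 1000,
    include_zero_floored: bool = True,
) -> Hyperparameters:
    """Estimate both hyperparameters from a count table.

    ``include_zero_floored`` controls whether genes with a zero count in
    both samples (whose average log rpm sits at the 0.5 display floor)
    participate in the alpha quantile matching; at the default upper
    quantiles (0.8, 0.9) this rarely matters.
    """
    from .count_data import average_log_rpm

    avg = average_log_rpm(table.x1, table.x2, table.N1, table.N2)
    if not include_zero_floored:
        avg = avg[(table.x1 + table.x2) > 0]
    alpha, lambda0 = estimate_alpha_quantile(avg, q1, q2)
    tau = estimate_tau(table, min_total=min_total)
    return Hyperparameters(
        alpha=alpha, tau=tau, q1=q1, q2=q2, min_total=min_total, lambda0=lambda0
    )
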