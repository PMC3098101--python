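"""Classical two-sample tests on count proportions, and ranked-list overlap.

These are the comparison methods for the shrinkage estimator: the pooled
two-proportion Z-test (Gaussian approximation to the binomial) with
Bonferroni correction, and Fisher's exact test on the 2x2 table
``(x1, N1-x1; x2, N2-x2)``.  Two-sided Fisher p-values follow the
minimum-likelihood convention (sum of all tables with probability at most
that of the observed one), as in R and SciPy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .count_data import CountTable

__all__ = [
    "TestResult",
    "z_test_equal_proportions",
    "fisher_exact_test",
    "bonferroni",
    "top_k_overlap",
    "z_test_table",
    "fisher_table",
]


@dataclass
class TestResult:
    gene_id: str
    statistic: float | None  # Z value; None for Fisher
    p_value: float
    p_adjusted: float | None = None


def z_test_equal_proportions(x1, x2, N1, N2, gene_id: str = "") -> TestResult:
    """Pooled two-proportion Z-test of pi1 = pi2.

    ``Z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/N1 + 1/N2))`` with the pooled
    ``pbar = (x1 + x2)/(N1 + N2)``; two-sided p from the standard Gaussian.
    A gene absent from both libraries carries no evidence: Z = 0, p = 1.
    """
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    if x1 + x2 == 0:
        return TestResult(gene_id, 0.0, 1.0)
    p1, p2 = x1 / N1, x2 / N2
    pbar = (x1 + x2) / (N1 + N2)
    se = np.sqrt(pbar * (1.0 - pbar) * (1.0 / N1 + 1.0 / N2))
    z = float((p1 - p2) / se)
    p = float(2.0 * st.norm.sf(abs(z)))
    return TestResult(gene_id, z, min(p, 1.0))


def fisher_exact_test(x1, x2, N1, N2, gene_id: str = "") -> TestResult:
    """Two-sided Fisher's exact test on the 2x2 table (x1, N1-x1; x2, N2-x2)."""
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    table = [[int(x1), int(N1 - x1)], [int(x2), int(N2 - x2)]]
    _, p = st.fisher_exact(table, alternative="two-sided")
    return TestResult(gene_id, None, float(min(p, 1.0)))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: each p replaced by min(1, m*p); m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def top_k_overlap(ranking_a, ranking_b, k: int) -> int:
    """Size of the intersection of the two length-k ranking prefixes."""
    a = list(ranking_a)
    b = list(ranking_b)
    for name, r in (("ranking_a", a), ("ranking_b", b)):
        if len(set(r)) != len(r):
            raise ValueError(f"{name} contains duplicate ids")
    if k > len(a) or k > len(b):
        raise ValueError(f"k = {k} exceeds a ranking length ({len(a)}, {len(b)})")
    return len(set(a[:k]) & set(b[:k]))


def z_test_table(table: CountTable, correct: bool = True) -> pd.DataFrame:
    """Vectorized Z-test for every gene, with optional Bonferroni adjustment."""
    x1 = table.x1.astype(float)
    x2 = table.x2.astype(float)
    p1, p2 = x1 / table.N1, x2 / table.N2
    pbar = (x1 + x2) / (table.N1 + table.N2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pbar * (1.0 - pbar) * (1.0 / table.N1 + 1.0 / table.N2))
        z = np.where(x1 + x2 > 0, (p1 - p2) / np.where(se > 0, se, 1.0), 0.0)
    p = np.minimum(2.0 * st.norm.sf(np.abs(z)), 1.0)
    p = np.where(x1 + x2 > 0, p, 1.0)
    out = pd.DataFrame(
        {"gene_id": table.gene_id, "statistic": z, "p_value": p}
    )
    out["p_adjusted"] = bonferroni(p) if correct else p
    return out


def fisher_table(table: CountTable, correct: bool = True) -> pd.DataFrame:
    """Fisher's exact test for every gene (per-gene SciPy calls; exact but slower)."""
    p = np.empty(table.n_genes)
    for i in range(table.n_genes):
        p[i] = fisher_exact_test(
            int(table.x1[i]), int(table.x2[i]), table.N1, table.N2
        ).p_value
    out = pd.DataFrame({"gene_id": table.gene_id, "p_value": p})
    out["p_adjusted"] = bonferroni(p) if correct else p
    return out
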