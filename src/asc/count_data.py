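"""Two-sample tag/gene count tables and their descriptive statistics.

The data model for a replicate-free comparison is minimal: per gene, the
observed tag counts ``x1`` and ``x2`` in the two libraries, plus the two
library sizes ``N1`` and ``N2`` (total sequenced tags).  Sample proportions
are ``p_i = x_i / N_i`` and "reads per million" is ``p_i * 1e6``.

Descriptive statistics use base-10 logarithms throughout and floor counts at
0.5 so that genes with a zero count in one sample can still be displayed on
a log scale.  The floor is purely cosmetic: the posterior model in
:mod:`asc.posterior` consumes raw counts and needs no zero handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "read_count_table",
    "apparent_log_ratio",
    "average_log_rpm",
]


@dataclass
class CountTable:
    """Per-gene counts for two sequencing libraries.

    Parameters
    ----------
    gene_id
        Unique text identifier per row.
    x1, x2
        Non-negative integer tag counts in samples 1 and 2.
    N1, N2
        Positive library sizes (total sequenced tags per sample).  These may
        exceed the column sums when the table was filtered after sequencing.
    """

    gene_id: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    N1: int
    N2: int

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        for name in ("x1", "x2"):
            arr = np.asarray(getattr(self, name))
            if arr.size and not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError(f"{name} contains non-integer counts")
            arr = arr.astype(np.int64)
            if np.any(arr < 0):
                bad = int(np.argmax(arr < 0))
                raise ValueError(f"{name} contains a negative count at row {bad + 1}")
            setattr(self, name, arr)
        if not (len(self.gene_id) == len(self.x1) == len(self.x2)):
            raise ValueError("gene_id, x1 and x2 must have equal length")
        for name in ("N1", "N2"):
            val = getattr(self, name)
            if int(val) != val or val <= 0:
                raise ValueError(f"{name} must be a positive integer, got {val!r}")
            setattr(self, name, int(val))
        if np.any(self.x1 > self.N1) or np.any(self.x2 > self.N2):
            raise ValueError("counts may not exceed the library size")
        uniq, counts = np.unique(self.gene_id.astype(str), return_counts=True)
        if np.any(counts > 1):
            raise ValueError(f"duplicate gene_id: {uniq[np.argmax(counts > 1)]!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_id)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame with columns gene_id, count_1, count_2."""
        return pd.DataFrame(
            {"gene_id": self.gene_id, "count_1": self.x1, "count_2": self.x2}
        )


def read_count_table(
    path,
    n1_override: int | None = None,
    n2_override: int | None = None,
) -> CountTable:
    """Read a tab-separated count table.

    The file must have at least three columns: identifier, count in sample 1,
    count in sample 2.  An optional single header line is detected by a
    non-numeric second field.  Library sizes default to the column sums;
    overrides exist because the true total of sequenced tags can exceed the
    sum over tabulated tags (e.g. after filtering).

    Raises
    ------
    ValueError
        On a malformed row, negative or non-integer count, or duplicate
        identifier; the message names the offending (1-based) file row.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, dtype=str, keep_default_na=False, comment=None
    )
    if df.shape[1] < 3:
        raise ValueError(f"expected >=3 tab-separated columns, found {df.shape[1]}")
    offset = 1  # 1-based file rows
    first = str(df.iloc[0, 1])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
        offset = 2
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    if len(ids) == 0:
        raise ValueError("count table contains no data rows")

    def _parse_counts(col: int, label: str) -> np.ndarray:
        raw = df.iloc[:, col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna().to_numpy()
        if bad.any():
            row = int(np.argmax(bad)) + offset
            raise ValueError(f"row {row}: {label} {raw.iloc[int(np.argmax(bad))]!r} is not a number")
        arr = vals.to_numpy(dtype=float)
        nonint = (arr < 0) | (np.mod(arr, 1) != 0)
        if nonint.any():
            row = int(np.argmax(nonint)) + offset
            raise ValueError(
                f"row {row}: {label} {arr[int(np.argmax(nonint))]!r} is not a non-negative integer"
            )
        return arr.astype(np.int64)

    x1 = _parse_counts(1, "count_1")
    x2 = _parse_counts(2, "count_2")
    seen: dict[str, int] = {}
    for i, g in enumerate(ids):
        if g in seen:
            raise ValueError(
                f"row {i + offset}: duplicate gene_id {g!r} (first seen at row {seen[g] + offset})"
            )
        seen[g] = i
    N1 = int(n1_override) if n1_override is not None else int(x1.sum())
    N2 = int(n2_override) if n2_override is not None else int(x2.sum())
    return CountTable(gene_id=ids, x1=x1, x2=x2, N1=N1, N2=N2)


def apparent_log_ratio(x1, x2, N1, N2):
    """Apparent log10 fold change between the two sample proportions.

    Counts are floored at 0.5 (``x* = max(x, 0.5)``) so the ratio is finite
    for zero counts: ``log10{(x1*/N1) / (x2*/N2)}``.  For counts >= 1 the
    floor is inert.  Accepts scalars or arrays.
    """
    x1f = np.maximum(np.asarray(x1, dtype=float), 0.5)
    x2f = np.maximum(np.asarray(x2, dtype=float), 0.5)
    return np.log10(x1f / np.asarray(N1, dtype=float)) - np.log10(
        x2f / np.asarray(N2, dtype=float)
    )


def average_log_rpm(x1, x2, N1, N2):
    """Mean of the two per-sample log10 reads-per-million, with the 0.5 floor.

    ``[log10(max(x1,0.5)*1e6/N1) + log10(max(x2,0.5)*1e6/N2)] / 2`` -- the
    log of the geometric mean of the two rpm values.  This is the empirical
    expression-level summary whose distribution motivates the shifted
    exponential prior on lambda.
    """
    x1f = np.maximum(np.asarray(x1, dtype=float), 0.5)
    x2f = np.maximum(np.asarray(x2, dtype=float), 0.5)
    r1 = np.log10(x1f * 1e6 / np.asarray(N1, dtype=float))
    r2 = np.log10(x2f * 1e6 / np.asarray(N2, dtype=float))
    return (r1 + r2) / 2.0
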