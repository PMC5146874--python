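"""RPKM expression summaries and descriptive read-distribution statistics.

RPKM (reads per kilobase of expressed sequence per million mapped reads)
normalizes a raw read count by transcript length and sequencing depth:
``RPKM = count / ((length/1000) * (library_size/1e6))``. The library size is
the per-sample total of mapped reads supplied by the caller — typically a
superset of the counted reads, so it need not equal the column sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "rpkm",
    "expressed_flag",
    "top_share",
    "de_direction_summary",
]


@dataclass
class ExpressionMatrix:
    """Gene × sample read counts with gene lengths and library sizes."""

    counts: pd.DataFrame          # genes × samples, nonnegative integers
    gene_length: pd.Series        # bp, aligned to counts.index
    library_size: pd.Series       # total mapped reads, aligned to columns

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.gene_length = self.gene_length.reindex(self.counts.index)
        self.library_size = self.library_size.reindex(self.counts.columns)
        if self.gene_length.isna().any():
            raise ValueError("genes without a length")
        if self.library_size.isna().any():
            raise ValueError("samples without a library size")


def rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene, per-sample RPKM values."""
    if (matrix.gene_length <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (matrix.library_size <= 0).any():
        raise ValueError("library sizes must be positive")
    kb = matrix.gene_length / 1000.0
    millions = matrix.library_size / 1e6
    return matrix.counts.div(kb, axis=0).div(millions, axis=1)


def expressed_flag(matrix: ExpressionMatrix, min_total: int = 20) -> pd.Series:
    """Flag a gene as expressed when its read total across all samples
    reaches ``min_total`` (default 20 reads)."""
    return matrix.counts.sum(axis=1) >= min_total


def top_share(
    matrix: ExpressionMatrix, sample: str, quantile: float = 0.10
) -> float:
    """Fraction of a sample's reads mapping to its top-``quantile`` most
    highly expressed genes (by raw count; ties broken by gene_id so the
    result is deterministic)."""
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    col = matrix.counts[sample]
    total = col.sum()
    if total == 0:
        raise ValueError(f"sample {sample!r} has no reads")
    n_top = math.ceil(quantile * len(col))
    # stable sort over a lexicographically ordered index -> deterministic ties
    ranked = col.loc[sorted(col.index)].sort_values(
        ascending=False, kind="mergesort"
    )
    return float(ranked.iloc[:n_top].sum() / total)


def de_direction_summary(de_table) -> dict[str, float]:
    """Up/down counts and fractions for a DE table (sign of log2fc)."""
    log2fc = de_table.data["log2fc"] if hasattr(de_table, "data") else de_table["log2fc"]
    n_up = int((log2fc > 0).sum())
    n_down = int((log2fc < 0).sum())
    n = len(log2fc)
    return {
        "n": n,
        "n_up": n_up,
        "n_down": n_down,
        "frac_up": n_up / n if n else 0.0,
        "frac_down": n_down / n if n else 0.0,
    }
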