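"""Normalization, the log2 expression floor, and gene detection.

Counts are normalized to each sample's total sequenced fragments (not just
exonic reads) and scaled to per-million; expression is log2 of the
normalized value with a hard floor (default 5 on the log2 scale) so that
downstream fold changes and correlations are defined for every gene while
sub-threshold differences vanish. Comparisons are within-gene across
samples only, so no transcript-length correction is applied.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .models import CountMatrix, ExpressionMatrix


def normalize(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million total fragments: counts(g, s) / library_size(s) * 1e6."""
    if (counts.library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.counts.div(counts.library_sizes, axis=1) * 1e6


def log_floor(normalized: pd.DataFrame, floor: float = 5.0) -> ExpressionMatrix:
    """log2 with a hard floor; zeros map to the floor (no pseudocount)."""
    values = np.asarray(normalized, dtype=float)
    if (values < 0).any():
        raise ValueError("normalized expression must be non-negative")
    with np.errstate(divide="ignore"):
        logged = np.log2(values, out=np.full_like(values, -np.inf), where=values > 0)
    floored = pd.DataFrame(
        np.maximum(logged, floor), index=normalized.index, columns=normalized.columns
    )
    return ExpressionMatrix(values=floored, floor=floor)


def expression_matrix(counts: CountMatrix, floor: float = 5.0) -> ExpressionMatrix:
    """Convenience: normalize then apply the log2 floor."""
    return log_floor(normalize(counts), floor=floor)


def detected_genes(counts_column, min_reads: int = 1) -> int:
    """Number of genes with at least ``min_reads`` exonic reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return int((np.asarray(counts_column) >= min_reads).sum())
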