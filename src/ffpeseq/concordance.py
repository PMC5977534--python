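"""Agreement statistics between matched samples and protocols.

Pearson correlation of floored log2 expression (optionally restricted to a
gene set, with genes floored in *both* compared samples excluded), per-pair
log2 fold changes, the fold-change sign-agreement statistic with a
threshold sweep, and two-group differential-expression selection (Welch
t-test with Benjamini-Hochberg control) for defining gene panels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ExpressionMatrix, FCAgreement


def pairwise_cc(
    expr_a: pd.Series,
    expr_b: pd.Series,
    floor: float,
    gene_subset: Iterable[str] | None = None,
) -> tuple[float, int]:
    """Pearson correlation over genes above the floor in at least one sample.

    Returns ``(cc, n_genes_used)``. Genes floored in both samples carry no
    information (their values are identical by construction) and are
    excluded; fewer than 3 usable genes is an error.
    """
    if not expr_a.index.equals(expr_b.index):
        expr_b = expr_b.reindex(expr_a.index)
        if expr_b.isna().any():
            raise ValueError("mismatched gene universes")
    if gene_subset is not None:
        subset = pd.Index(gene_subset)
        missing = subset.difference(expr_a.index)
        if len(missing):
            raise ValueError(f"gene subset contains unknown genes, e.g. {missing[0]!r}")
        expr_a = expr_a.loc[subset]
        expr_b = expr_b.loc[subset]
    usable = (expr_a > floor) | (expr_b > floor)
    n = int(usable.sum())
    if n < 3:
        raise ValueError(f"only {n} genes above the floor in either sample; need >= 3")
    cc = float(np.corrcoef(expr_a[usable], expr_b[usable])[0, 1])
    return cc, n


def correlation_matrix(
    expr: ExpressionMatrix,
    sample_ids: Sequence[str] | None = None,
    gene_subset: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson correlation over a set of samples.

    Returns ``(cc, n_used)`` DataFrames, symmetric with unit diagonal.
    Pairs with too few usable genes become NaN with a warning.
    """
    ids = list(sample_ids) if sample_ids is not None else list(expr.sample_ids)
    cc = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    n_used = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, a in enumerate(ids):
        n_used.loc[a, a] = int((expr.column(a) > expr.floor).sum())
        for b in ids[i + 1 :]:
            try:
                r, n = pairwise_cc(expr.column(a), expr.column(b), expr.floor, gene_subset)
            except ValueError as err:
                warnings.warn(f"correlation {a} vs {b} undefined: {err}")
                r, n = np.nan, 0
            cc.loc[a, b] = cc.loc[b, a] = r
            n_used.loc[a, b] = n_used.loc[b, a] = n
    return cc, n_used


def fold_changes(expr_a: pd.Series, expr_b: pd.Series) -> pd.Series:
    """Per-gene log2 fold change of floored expression, A minus B.

    Genes floored in both samples yield exactly 0 by construction.
    """
    if not expr_a.index.equals(expr_b.index):
        raise ValueError("mismatched gene universes")
    return expr_a - expr_b


def fc_agreement(
    fc_ffpe: pd.Series,
    fc_ff: pd.Series,
    threshold: float = 2.0,
    pair_labels: tuple[str, str] = ("FFPE", "FF"),
) -> FCAgreement:
    """Sign agreement of matched fold changes above a linear-scale FC threshold.

    Selects genes with |log2 FC| >= log2(threshold) in the FFPE pair and
    counts those whose FF fold change has the same strict sign. At
    threshold 1 the magnitude cut is vacuous, so genes with FC exactly 0
    (both-floored) are excluded explicitly. An FF fold change of exactly 0
    counts as disagreement.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1 (linear scale)")
    if not fc_ffpe.index.equals(fc_ff.index):
        raise ValueError("mismatched gene universes")
    cut = np.log2(threshold)
    selected = np.abs(fc_ffpe) >= cut
    selected &= fc_ffpe != 0  # only binding at threshold 1
    agree = selected & (np.sign(fc_ff) == np.sign(fc_ffpe)) & (fc_ff != 0)
    return FCAgreement(
        threshold=float(threshold),
        n_selected=int(selected.sum()),
        n_agree=int(agree.sum()),
        pair_labels=pair_labels,
    )


def agreement_sweep(
    fc_ffpe: pd.Series,
    fc_ff: pd.Series,
    thresholds: Sequence[float] = tuple(range(1, 11)),
    pair_labels: tuple[str, str] = ("FFPE", "FF"),
) -> list[FCAgreement]:
    """``fc_agreement`` at each threshold of an ascending ladder."""
    thresholds = list(thresholds)
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly ascending")
    return [fc_agreement(fc_ffpe, fc_ff, t, pair_labels) for t in thresholds]


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values (delegates to statsmodels)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGeneSet:
    """Differential-expression result table and the selected gene set."""

    table: pd.DataFrame  # index gene_id; columns t, p, q
    fdr_threshold: float

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index[self.table["q"] <= self.fdr_threshold]


def de_genes(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    fdr: float = 0.001,
    floor: float | None = None,
) -> DEGeneSet:
    """Two-group differential expression on log2 values.

    Welch (unequal-variance) two-sample t-test per gene, BH adjustment,
    membership at ``q <= fdr``. Genes must be expressed (above ``floor``)
    in at least half the samples of one group; genes with zero variance in
    both groups get p = 1. Requires >= 2 samples per group.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    if not group_a.index.equals(group_b.index):
        raise ValueError("mismatched gene universes")
    if floor is not None:
        expressed = ((group_a > floor).mean(axis=1) >= 0.5) | (
            (group_b > floor).mean(axis=1) >= 0.5
        )
        group_a = group_a[expressed]
        group_b = group_b[expressed]
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant genes trigger a harmless precision warning; they get p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)  # zero variance in both groups
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    q = benjamini_hochberg(p)
    table = pd.DataFrame({"t": t, "p": p, "q": q}, index=group_a.index)
    return DEGeneSet(table=table, fdr_threshold=fdr)
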