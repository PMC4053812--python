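"""TSS-window methylation, differential expression, and DMR-expression
enrichment.

TSS methylation is the count-weighted methylation of the window
[tss - flank, tss + flank). A gene is scoreable only when its window holds
enough "CpG data-points" in *every* compared methylome; a data-point is one
read observation at a window CpG (sum of coverage), with an alternative
distinct-CpG reading available behind ``datapoint_mode``.

Differential expression on log2-scale replicate intensities is either a
fold-change rule (|log2FC| >= 1 means two-fold) or a two-sample Student
t-test (equal variance), or both. The DMR-expression association is tested
with a label permutation: the observed number of differentially expressed
genes among DMR-associated genes is compared against random gene sets of the
same size.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneTable
from .methylome import Methylome

__all__ = [
    "tss_methylation",
    "differential_tss",
    "de_genes",
    "dmr_expression_enrichment",
    "GeneTable",
]


def tss_methylation(
    m: Methylome,
    genes: GeneTable,
    flank: int = 1000,
    min_datapoints: int = 80,
    datapoint_mode: Literal["coverage", "cpgs"] = "coverage",
) -> pd.DataFrame:
    """Per-gene TSS-window methylation with a data-point filter.

    Returns a frame indexed by gene_id with columns ``level`` (weighted
    methylation, NaN when the window has no coverage), ``n_datapoints`` and
    ``passed`` (n_datapoints >= min_datapoints, boundary inclusive). Genes
    failing the filter are flagged, never dropped.
    """
    if len(genes) == 0:
        raise ValueError("empty gene table")
    levels = np.full(len(genes), np.nan)
    ndp = np.zeros(len(genes), dtype=np.int64)
    for i, g in enumerate(genes.df.itertuples(index=False)):
        win = m.region(g.chrom, max(0, g.tss - flank), g.tss + flank)
        total = int(win["total"].sum())
        if total > 0:
            levels[i] = win["meth"].sum() / total
        if datapoint_mode == "coverage":
            ndp[i] = total
        else:
            ndp[i] = int((win["total"] > 0).sum())
    return pd.DataFrame(
        {
            "level": levels,
            "n_datapoints": ndp,
            "passed": ndp >= min_datapoints,
        },
        index=pd.Index(genes.gene_ids, name="gene_id"),
    )


def differential_tss(
    table_a: pd.DataFrame, table_b: pd.DataFrame, min_diff: float = 0.50
) -> pd.DataFrame:
    """Genes whose TSS methylation differs by strictly more than ``min_diff``.

    Only genes passing the data-point filter in *both* tables are compared.
    Returns a frame with the two levels, ``diff = level_a − level_b`` and
    ``direction`` ("higher_in_a"/"higher_in_b"). The comparison is strict
    (a difference of exactly ``min_diff`` is not called).
    """
    shared = table_a.index.intersection(table_b.index)
    if len(shared) == 0:
        raise ValueError("tables share no genes")
    a = table_a.loc[shared]
    b = table_b.loc[shared]
    ok = a["passed"] & b["passed"] & a["level"].notna() & b["level"].notna()
    diff = a.loc[ok, "level"] - b.loc[ok, "level"]
    hit = diff.abs() > min_diff
    out = pd.DataFrame(
        {
            "level_a": a.loc[ok, "level"][hit],
            "level_b": b.loc[ok, "level"][hit],
            "diff": diff[hit],
        }
    )
    out["direction"] = np.where(out["diff"] > 0, "higher_in_a", "higher_in_b")
    return out


def de_genes(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fold_log2: float = 1.0,
    alpha: float = 0.01,
    mode: Literal["fold", "ttest", "both"] = "fold",
    fdr: bool = False,
) -> pd.DataFrame:
    """Differential-expression calls on a log2 expression matrix.

    ``log2fc = mean(group_b) − mean(group_a)``; the fold rule flags
    |log2fc| >= fold_log2 (>= 1 is "two-fold" on the log2 scale); the t-test
    rule uses an equal-variance two-sample Student t at level ``alpha`` on
    per-gene p-values (set ``fdr=True`` to threshold Benjamini-Hochberg
    adjusted p-values instead). When both groups are constant and identical
    the t-test p is 1 by convention (no evidence of change).
    """
    for col in list(group_a) + list(group_b):
        if col not in expr.columns:
            raise ValueError(f"sample {col!r} not in expression matrix")
    if mode in ("ttest", "both") and (len(group_a) < 2 or len(group_b) < 2):
        raise ValueError("t-test mode requires >= 2 replicates per group")
    a = expr[list(group_a)].to_numpy(float)
    b = expr[list(group_b)].to_numpy(float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("expression matrix contains non-finite values")
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    if len(group_a) >= 2 and len(group_b) >= 2:
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # zero-variance genes are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        degenerate = np.isnan(p)
        p = np.where(degenerate & (log2fc == 0), 1.0, p)
        p = np.where(degenerate & (log2fc != 0), 0.0, p)
    else:
        p = np.full(len(expr), np.nan)
    fold_de = np.abs(log2fc) >= fold_log2
    p_thresh = p
    if fdr and not np.isnan(p).all():
        p_thresh = stats.false_discovery_control(np.nan_to_num(p, nan=1.0))
    ttest_de = p_thresh < alpha
    if mode == "fold":
        de = fold_de
    elif mode == "ttest":
        de = ttest_de
    else:
        de = fold_de & ttest_de
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "de": de}, index=expr.index.rename("gene_id")
    )


def dmr_expression_enrichment(
    dmr_genes: Iterable[str],
    de_flags: pd.Series,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Permutation test: are DMR-associated genes enriched for DE genes?

    The null draws ``n_perm`` uniform random gene sets of size
    ``len(dmr_genes)`` from the gene universe (the index of ``de_flags``)
    and counts DE genes in each. The one-sided empirical p-value uses the
    add-one correction ``p = (1 + #{perm >= observed}) / (n_perm + 1)`` so
    it can never be zero.
    """
    dmr_genes = list(dict.fromkeys(dmr_genes))
    if len(dmr_genes) == 0:
        raise ValueError("empty DMR gene set")
    missing = set(dmr_genes) - set(de_flags.index)
    if missing:
        raise ValueError(f"genes outside universe: {sorted(missing)[:5]}")
    flags = de_flags.astype(bool)
    observed = int(flags.loc[dmr_genes].sum())
    rng = np.random.default_rng(seed)
    arr = flags.to_numpy()
    k = len(dmr_genes)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        null[i] = arr[rng.choice(len(arr), size=k, replace=False)].sum()
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return {
        "observed": observed,
        "n_set": k,
        "p": float(p),
        "null_mean": float(null.mean()),
    }
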