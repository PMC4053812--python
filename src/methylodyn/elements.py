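"""Per-genomic-element methylation dynamics and the rank-sum primitive.

Elements (TSS windows, UTRs, exons, introns, repeat classes) are compared
between two methylomes by the change in count-weighted methylation per
element, averaged per class with one vote per element. The Wilcoxon/
Mann-Whitney rank-sum test implemented here is also the core statistic of
the 4C window-vs-flanks enrichment caller.
"""

from __future__ import annotations

from math import comb
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .genes import GeneTable
from .methylome import NO_DATA, Methylome

ELEMENT_CLASSES = ("TSS", "5'UTR", "exon", "intron", "3'UTR", "SINE", "LINE", "LTR")

EXACT_MAX_N = 12  # exact rank-sum enumeration limit (no ties)


class RankSumResult(NamedTuple):
    u: float
    p: float
    exact: bool


def _rank_sum_counts(N: int, n: int) -> np.ndarray:
    """Null distribution of the rank sum of n items among ranks 1..N.

    counts[r] = number of n-subsets of {1..N} with rank sum r. Dynamic
    programme over (subset size, sum); exact for the small-sample branch.
    """
    max_sum = N * (N + 1) // 2
    dp = np.zeros((n + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for rank in range(1, N + 1):
        for j in range(min(rank, n), 0, -1):
            dp[j, rank:] += dp[j - 1, : max_sum + 1 - rank]
    return dp[n]


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["two-sided", "greater"] = "two-sided",
) -> RankSumResult:
    """Wilcoxon/Mann-Whitney rank-sum test of x versus y.

    Uses exact enumeration of the rank-sum null distribution when the
    pooled sample has at most 12 observations and no ties; otherwise a
    normal approximation with midranks, tie-corrected variance and
    continuity correction. When every pooled value is identical the test
    carries no information and p = 1 by convention.

    Returns the Mann-Whitney U statistic for x (number of (x, y) pairs with
    x ahead, counting ties as 1/2) and the p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    N = n + m
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = float(ranks[:n].sum())
    u = rx - n * (n + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and N <= EXACT_MAX_N:
        counts = _rank_sum_counts(N, n)
        total = comb(N, n)
        r_obs = int(round(rx))
        p_ge = counts[r_obs:].sum() / total
        p_le = counts[: r_obs + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return RankSumResult(u=float(u), p=float(p), exact=True)

    mu = n * m / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return RankSumResult(u=float(u), p=1.0, exact=False)
    sd = np.sqrt(var)
    d = u - mu
    # continuity correction shrinks |d| by 1/2
    if alternative == "greater":
        z = (d - 0.5) / sd
        p = float(norm.sf(z))
    else:
        z = (abs(d) - 0.5) / sd if abs(d) > 0.5 else 0.0
        p = float(min(1.0, 2.0 * norm.sf(z)))
    return RankSumResult(u=float(u), p=p, exact=False)


# -- genomic elements --------------------------------------------------------


class ElementSet:
    """Labelled intervals; one class label each, addresses may repeat."""

    def __init__(self, df: pd.DataFrame) -> None:
        required = {"chrom", "start", "end", "klass"}
        if required - set(df.columns):
            raise ValueError(f"element table needs columns {sorted(required)}")
        if "gene_id" not in df.columns:
            df = df.assign(gene_id=None)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def by_class(self, klass: str) -> pd.DataFrame:
        return self.df[self.df["klass"] == klass]


def build_elements(genes: GeneTable, repeats: pd.DataFrame | None = None,
                   tss_flank: int = 1000) -> ElementSet:
    """Derive the element catalogue from gene structure plus repeat annotation.

    Genic classes come from exon/CDS structure: TSS windows (tss +/- flank),
    exons, introns, and the 5'/3' UTRs as the exonic sequence outside the
    CDS on the appropriate side. Repeat intervals (BED-like frame with a
    ``klass`` column in {SINE, LINE, LTR}) pass through unchanged. An
    address overlapped by several classes is listed under each.
    """
    rows: list[dict] = []
    for g in genes.df.itertuples(index=False):
        rows.append(dict(chrom=g.chrom, start=max(0, g.tss - tss_flank),
                         end=g.tss + tss_flank, klass="TSS", gene_id=g.gene_id))
        for s, e in zip(g.exon_starts, g.exon_ends):
            rows.append(dict(chrom=g.chrom, start=s, end=e, klass="exon",
                             gene_id=g.gene_id))
        for e_prev, s_next in zip(g.exon_ends[:-1], g.exon_starts[1:]):
            if e_prev < s_next:
                rows.append(dict(chrom=g.chrom, start=e_prev, end=s_next,
                                 klass="intron", gene_id=g.gene_id))
        if not (pd.isna(g.cds_start) or pd.isna(g.cds_end)) and g.cds_start < g.cds_end:
            left, right = [], []
            for s, e in zip(g.exon_starts, g.exon_ends):
                ls, le = s, min(e, int(g.cds_start))
                if ls < le:
                    left.append((ls, le))
                rs, re = max(s, int(g.cds_end)), e
                if rs < re:
                    right.append((rs, re))
            five, three = (left, right) if g.strand == "+" else (right, left)
            for s, e in five:
                rows.append(dict(chrom=g.chrom, start=s, end=e, klass="5'UTR",
                                 gene_id=g.gene_id))
            for s, e in three:
                rows.append(dict(chrom=g.chrom, start=s, end=e, klass="3'UTR",
                                 gene_id=g.gene_id))
    if repeats is not None and len(repeats):
        bad = set(repeats["klass"]) - {"SINE", "LINE", "LTR"}
        if bad:
            raise ValueError(f"unknown repeat classes: {sorted(bad)}")
        for r in repeats.itertuples(index=False):
            rows.append(dict(chrom=r.chrom, start=int(r.start), end=int(r.end),
                             klass=r.klass, gene_id=None))
    return ElementSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                  "klass", "gene_id"]))


def element_change(a: Methylome, b: Methylome, elements: ElementSet) -> dict:
    """Mean per-element methylation change (%) per class, b relative to a.

    Per element: 100 * (weighted level in b − weighted level in a); elements
    without coverage in either sample are excluded. Per class: unweighted
    mean over elements (each element one vote). Classes with no scoreable
    element map to :data:`NO_DATA`. Also returns the per-element table.
    """
    if not a.same_manifest(b):
        raise ValueError("methylomes are on different genome manifests")
    changes = np.full(len(elements), np.nan)
    for i, el in enumerate(elements.df.itertuples(index=False)):
        ra = a.region(el.chrom, int(el.start), int(el.end))
        rb = b.region(el.chrom, int(el.start), int(el.end))
        ta, tb = int(ra["total"].sum()), int(rb["total"].sum())
        if ta == 0 or tb == 0:
            continue
        changes[i] = 100.0 * (rb["meth"].sum() / tb - ra["meth"].sum() / ta)
    table = elements.df.assign(change_pct=changes)
    per_class: dict[str, float | None] = {}
    for klass in table["klass"].unique():
        vals = table.loc[table["klass"] == klass, "change_pct"].dropna()
        per_class[klass] = float(vals.mean()) if len(vals) else NO_DATA
    return {"per_class": per_class, "per_element": table}


def expressed_vs_silent(
    changes: Sequence[float], expressed_flags: Sequence[bool]
) -> RankSumResult | None:
    """Two-sided rank-sum comparison of expressed vs silent element values.

    Returns :data:`NO_DATA` when either group is empty (after dropping NaNs).
    """
    vals = np.asarray(changes, float)
    flags = np.asarray(expressed_flags, bool)
    if len(vals) != len(flags):
        raise ValueError("changes and flags must align")
    ok = ~np.isnan(vals)
    x = vals[ok & flags]
    y = vals[ok & ~flags]
    if len(x) == 0 or len(y) == 0:
        return NO_DATA
    return rank_sum_test(x, y, alternative="two-sided")
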