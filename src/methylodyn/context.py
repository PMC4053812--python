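"""Genomic context of DMRs, TF-peak proximity, and TF-site metaprofiles.

A DMR is labelled "TSS" when it lies within 2 kb of an annotated
transcription start, "intergenic" when it is more than 2 kb from every gene,
and "exon"/"intron" by overlap with gene structure; a DMR overlapping
several genomic elements is counted in every category it touches (TSS and
intergenic remain mutually exclusive by construction). Distances are
edge-to-edge between intervals; a TF peak's position is its summit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import GeneTable
from .hmr_dmr import DMR
from .intervals import gap_distance
from .methylome import NO_DATA, Methylome


@dataclass(frozen=True)
class TFPeak:
    chrom: str
    start: int
    end: int
    summit: int
    name: str = "peak"

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside [{self.start}, {self.end})")


@dataclass
class DmrContext:
    dmr: DMR
    labels: frozenset[str]
    nearest_gene: str | None
    tss_distance: int | None
    nearby_peaks: tuple[str, ...] = ()


def _point(p: int) -> tuple[int, int]:
    return (p, p + 1)


def annotate_dmrs(
    dmrs: Sequence[DMR],
    genes: GeneTable,
    tss_dist: int = 2000,
    gene_dist: int = 2000,
) -> dict:
    """Label DMRs by genomic context and count labels per direction.

    Labels: "TSS" iff within ``tss_dist`` of a TSS (boundary inclusive);
    "intergenic" iff farther than ``gene_dist`` from every gene's transcript
    interval; "exon"/"intron" by overlap. Returns ``{"contexts": [...],
    "counts": DataFrame(label x direction)}``.
    """
    contexts: list[DmrContext] = []
    for d in dmrs:
        labels: set[str] = set()
        nearest_gene, nearest_tss_dist, min_gene_dist = None, None, None
        gdf = genes.df[genes.df["chrom"] == d.chrom]
        for g in gdf.itertuples(index=False):
            td = gap_distance(d.interval, _point(int(g.tss)))
            if nearest_tss_dist is None or td < nearest_tss_dist:
                nearest_gene, nearest_tss_dist = g.gene_id, td
            gd = gap_distance(d.interval, (int(g.tx_start), int(g.tx_end)))
            min_gene_dist = gd if min_gene_dist is None else min(min_gene_dist, gd)
            if gd == 0:
                for s, e in zip(g.exon_starts, g.exon_ends):
                    if gap_distance(d.interval, (s, e)) == 0:
                        labels.add("exon")
                for s, e in zip(g.exon_ends[:-1], g.exon_starts[1:]):
                    if s < e and gap_distance(d.interval, (s, e)) == 0:
                        labels.add("intron")
        if nearest_tss_dist is not None and nearest_tss_dist <= tss_dist:
            labels.add("TSS")
        if min_gene_dist is None or min_gene_dist > gene_dist:
            labels.add("intergenic")
        if not labels:
            # gene-flanking DMR: within gene_dist of a gene but overlapping
            # nothing and away from the TSS; label it by the nearest genic
            # element so every DMR carries at least one label
            best_lab, best_d = "exon", None
            for g in gdf.itertuples(index=False):
                for s, e in zip(g.exon_starts, g.exon_ends):
                    dd = gap_distance(d.interval, (s, e))
                    if best_d is None or dd < best_d:
                        best_lab, best_d = "exon", dd
                for s, e in zip(g.exon_ends[:-1], g.exon_starts[1:]):
                    if s < e:
                        dd = gap_distance(d.interval, (s, e))
                        if best_d is None or dd < best_d:
                            best_lab, best_d = "intron", dd
            labels.add(best_lab)
        contexts.append(
            DmrContext(
                dmr=d,
                labels=frozenset(labels),
                nearest_gene=nearest_gene,
                tss_distance=nearest_tss_dist,
            )
        )
    rows = []
    for label in ("TSS", "exon", "intron", "intergenic"):
        row = {}
        for direction in ("loss", "gain"):
            row[direction] = sum(
                1
                for c in contexts
                if label in c.labels and c.dmr.direction == direction
            )
        rows.append(pd.Series(row, name=label))
    return {"contexts": contexts, "counts": pd.DataFrame(rows)}


def peaks_near_dmrs(
    dmrs: Sequence[DMR], peaks: Sequence[TFPeak], max_dist: int = 1000
) -> list[tuple[DMR, TFPeak, int]]:
    """All (DMR, peak) pairs within ``max_dist`` bp edge-to-edge.

    Distance is 0 for any overlap; the boundary is inclusive (a pair at
    exactly ``max_dist`` is reported).
    """
    out = []
    for d in dmrs:
        for p in peaks:
            if p.chrom != d.chrom:
                continue
            dist = gap_distance(d.interval, (p.start, p.end))
            if dist <= max_dist:
                out.append((d, p, dist))
    return out


def tf_metaprofile(
    m: Methylome,
    peaks: Sequence[TFPeak],
    genes: GeneTable,
    min_tss_dist: int = 5000,
    flank: int = 2000,
    bin_bp: int = 50,
) -> dict | None:
    """Mean methylation around TF-peak summits, away from promoters.

    Peaks whose summit lies closer than ``min_tss_dist`` to any TSS are
    excluded ("at least 5 kb away" keeps a peak at exactly the boundary).
    The remaining summits' +/-``flank`` windows are cut into ``bin_bp`` bins
    and each bin's value is the read-count-weighted methylation pooled
    across peaks. Returns ``{"offsets", "profile", "n_peaks"}`` or
    :data:`NO_DATA` when no peak survives the filter.
    """
    if flank % bin_bp:
        raise ValueError("flank must be a multiple of bin_bp")
    tss_by_chrom: dict[str, np.ndarray] = {
        str(c): np.sort(grp["tss"].to_numpy())
        for c, grp in genes.df.groupby("chrom")
    }
    kept: list[TFPeak] = []
    for p in peaks:
        tss = tss_by_chrom.get(p.chrom)
        if tss is not None and len(tss):
            d = np.abs(tss - p.summit).min()
            if d < min_tss_dist:
                continue
        kept.append(p)
    if not kept:
        return NO_DATA
    n_bins = 2 * flank // bin_bp
    meth = np.zeros(n_bins)
    total = np.zeros(n_bins)
    for p in kept:
        win = m.region(p.chrom, p.summit - flank, p.summit + flank)
        if len(win) == 0:
            continue
        offsets = win["pos"].to_numpy() - (p.summit - flank)
        bins = offsets // bin_bp
        np.add.at(meth, bins, win["meth"].to_numpy())
        np.add.at(total, bins, win["total"].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(total > 0, meth / total, np.nan)
    centers = np.arange(n_bins) * bin_bp + bin_bp // 2 - flank
    return {"offsets": centers, "profile": profile, "n_peaks": len(kept)}
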