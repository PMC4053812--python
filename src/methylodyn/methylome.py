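"""Single-CpG methylome data model, I/O and elementary summaries.

A methylome is an ordered table of per-CpG methylated/total read counts for
one cell population, typically produced by a bisulfite-sequencing methylation
caller. Files follow the methcounts-style six-column TSV convention
(chrom, pos, strand, context, level, coverage); in memory, both strands are
collapsed onto the position of the C on the plus strand and coordinates are
0-based.

The central scalar summary is *weighted methylation*: the ratio of methylated
read observations to total read observations over a region. It is
count-weighted, so low-coverage CpGs do not get an equal vote with
high-coverage ones, and it is exactly additive over a partition of the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel returned by summaries evaluated over regions with no covered CpGs.
#: Distinct from 0.0: "no data" is not "unmethylated".
NO_DATA = None

_METHCOUNTS_COLUMNS = ["chrom", "pos", "strand", "context", "level", "coverage"]


class MethylomeError(ValueError):
    """Malformed methylome input (unsorted, duplicated, or invalid counts)."""


@dataclass(frozen=True)
class CpGSite:
    """One CpG with its methylated/total read counts.

    ``level`` is ``meth_reads / total_reads`` and is undefined (None) when
    the site has no coverage.
    """

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.meth_reads <= self.total_reads):
            raise MethylomeError(
                f"invalid counts at {self.chrom}:{self.pos}: "
                f"meth={self.meth_reads}, total={self.total_reads}"
            )

    @property
    def level(self) -> float | None:
        if self.total_reads == 0:
            return None
        return self.meth_reads / self.total_reads


class Methylome:
    """Ordered per-CpG counts for one sample.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, meth, total`` (ints), strictly
        sorted by (chrom, pos), no duplicate positions within a chromosome.
    sample_name
        Label carried through outputs.
    chrom_sizes
        Genome manifest mapping chromosome name to length in bp. Two
        methylomes are comparable only if their manifests agree.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        sample_name: str = "sample",
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        required = {"chrom", "pos", "meth", "total"}
        missing = required - set(sites.columns)
        if missing:
            raise MethylomeError(f"missing columns: {sorted(missing)}")
        sites = sites.reset_index(drop=True)
        if (sites["meth"] < 0).any() or (sites["meth"] > sites["total"]).any():
            bad = sites.index[(sites["meth"] < 0) | (sites["meth"] > sites["total"])][0]
            raise MethylomeError(
                f"invalid counts at row {bad}: meth must be in [0, total]"
            )
        _check_sorted_unique(sites)
        self.sites = sites
        self.sample_name = sample_name
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else _infer_manifest(sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __repr__(self) -> str:
        return (
            f"Methylome({self.sample_name!r}, {len(self)} CpGs, "
            f"{len(self.chrom_sizes)} chromosomes)"
        )

    @property
    def levels(self) -> np.ndarray:
        """Per-site methylation level; NaN where coverage is zero."""
        total = self.sites["total"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.sites["meth"].to_numpy(float) / total, np.nan)

    def region(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Sites in the half-open interval [start, end) of ``chrom``."""
        block = self.sites[self.sites["chrom"] == chrom]
        pos = block["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end])
        return block.iloc[lo:hi]

    def same_manifest(self, other: "Methylome") -> bool:
        return self.chrom_sizes == other.chrom_sizes


def _infer_manifest(sites: pd.DataFrame) -> dict[str, int]:
    if len(sites) == 0:
        return {}
    ends = sites.groupby("chrom", sort=False)["pos"].max() + 2
    return {str(c): int(e) for c, e in ends.items()}


def _check_sorted_unique(sites: pd.DataFrame) -> None:
    if len(sites) <= 1:
        return
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    same = chrom[1:] == chrom[:-1]
    backwards = same & (pos[1:] <= pos[:-1])
    if backwards.any():
        i = int(np.argmax(backwards)) + 1
        if pos[i] == pos[i - 1]:
            raise MethylomeError(
                f"duplicate CpG position {chrom[i]}:{pos[i]} (rows {i - 1}, {i})"
            )
        raise MethylomeError(
            f"input not sorted: {chrom[i]}:{pos[i]} after {chrom[i - 1]}:{pos[i - 1]} "
            f"(row {i})"
        )
    # chromosomes must form contiguous blocks
    seen: set[str] = set()
    last = None
    for c in chrom:
        if c != last:
            if c in seen:
                raise MethylomeError(f"chromosome {c} appears in non-contiguous blocks")
            seen.add(c)
            last = c


def read_methcounts(
    path: str | Path,
    sample_name: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> Methylome:
    """Read a methcounts-style TSV into a :class:`Methylome`.

    Columns: chrom, pos, strand, context, level, coverage (no header).
    Methylated read counts are reconstructed as ``round(level * coverage)``;
    this is lossless when the file was written from integer counts. Non-CpG
    contexts (CHH/CHG/...) are skipped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        names=_METHCOUNTS_COLUMNS,
        header=None,
        dtype={"chrom": str, "pos": np.int64, "level": float, "coverage": np.int64},
        comment="#",
    )
    if len(df) == 0:
        return Methylome(
            pd.DataFrame(columns=["chrom", "pos", "meth", "total"]),
            sample_name or path.stem,
            chrom_sizes,
        )
    if (df["coverage"] < 0).any():
        row = int(df.index[df["coverage"] < 0][0])
        raise MethylomeError(f"{path}: negative coverage at line {row + 1}")
    is_cpg = df["context"].str.upper().str.startswith("CPG")
    n_skipped = int((~is_cpg).sum())
    if n_skipped:
        logger.info("%s: skipped %d non-CpG context lines", path, n_skipped)
    df = df[is_cpg]
    meth = np.rint(df["level"].to_numpy() * df["coverage"].to_numpy()).astype(np.int64)
    sites = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "meth": meth,
            "total": df["coverage"].to_numpy(),
        }
    )
    return Methylome(sites, sample_name or path.stem, chrom_sizes)


def write_methcounts(m: Methylome, path: str | Path) -> None:
    """Write a :class:`Methylome` as methcounts-style TSV (round-trip safe)."""
    total = m.sites["total"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, m.sites["meth"].to_numpy(float) / total, 0.0)
    out = pd.DataFrame(
        {
            "chrom": m.sites["chrom"],
            "pos": m.sites["pos"],
            "strand": "+",
            "context": "CpG",
            "level": level,
            "coverage": m.sites["total"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def weighted_methylation(
    m: Methylome,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> float | None:
    """Count-weighted methylation over a region (or the whole genome).

    Returns sum(meth) / sum(total) over covered CpGs, or :data:`NO_DATA`
    when the region holds no read observations.
    """
    if chrom is None:
        block = m.sites
    else:
        block = m.region(chrom, 0 if start is None else start,
                         np.iinfo(np.int64).max if end is None else end)
    total = int(block["total"].sum())
    if total == 0:
        return NO_DATA
    return float(block["meth"].sum()) / total


def level_histogram(
    m: Methylome, n_bins: int = 10, min_coverage: int = 1
) -> np.ndarray | None:
    """Fraction of CpGs per methylation-level bin.

    Sites with coverage >= ``min_coverage`` are binned by level into
    ``n_bins`` equal-width bins on [0, 1], the last bin closed at 1.
    Returns :data:`NO_DATA` when no site qualifies.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    keep = m.sites["total"] >= max(min_coverage, 1)
    if not keep.any():
        return NO_DATA
    lv = m.sites.loc[keep, "meth"].to_numpy(float) / m.sites.loc[keep, "total"].to_numpy(float)
    counts, _ = np.histogram(lv, bins=n_bins, range=(0.0, 1.0))
    return counts / counts.sum()


# -- per-read co-methylation patterns ---------------------------------------

PATTERNS = tuple(
    (a, b, c) for a in ("C", "mC") for b in ("C", "mC") for c in ("C", "mC")
)


@dataclass
class ReadPatternSet:
    """Per-read methylation calls at the first three CpGs of each read.

    ``patterns`` is an (n_reads, 3) boolean array (True = methylated);
    ``anchors`` gives the index of the first covered CpG of each read.
    """

    patterns: np.ndarray
    anchors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=bool)
        if self.patterns.ndim != 2 or self.patterns.shape[1] != 3:
            raise ValueError("patterns must be an (n_reads, 3) array")
        if self.anchors is None:
            self.anchors = np.zeros(len(self.patterns), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.patterns)


def pattern_fractions(r: ReadPatternSet) -> dict | None:
    """Fractions of reads per three-CpG methylation pattern.

    Returns a dict with two tables: ``by_pattern`` maps each of the 8 ordered
    (call1, call2, call3) patterns to its fraction, and ``by_class`` maps the
    number of methylated calls (0..3) to its fraction. Returns
    :data:`NO_DATA` on an empty read set.
    """
    if len(r) == 0:
        return NO_DATA
    n = len(r)
    codes = r.patterns @ np.array([4, 2, 1])  # lexicographic pattern index
    counts = np.bincount(codes, minlength=8)
    by_pattern = {}
    for code in range(8):
        bits = ((code >> 2) & 1, (code >> 1) & 1, code & 1)
        key = tuple("mC" if b else "C" for b in bits)
        by_pattern[key] = counts[code] / n
    n_meth = r.patterns.sum(axis=1)
    by_class = {k: float((n_meth == k).mean()) for k in range(4)}
    return {"by_pattern": by_pattern, "by_class": by_class}
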