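"""4C-seq interaction calling via multiscale window-vs-flanks domainograms.

A 4C fragment-end track records, for every restriction-fragment end along
the chromosome of the viewpoint, how often it was captured in ligation with
the viewpoint. Fragment ends flanked by two primary-cutter sites without an
internal secondary-cutter site ("blind" fragments) have a systematically
different count distribution from regular fragments, so the two classes are
quantile-normalized onto a common reference before testing.

Enrichment is scored by sliding a window of w fragment ends along the track
and comparing its normalized counts against the directly flanking windows of
the same size on either side (the window at fragment indices i..i+w-1 versus
i-w..i-1 and i+w..i+2w-1 pooled) with a one-sided Wilcoxon rank-sum test.
Doing this over a range of window sizes yields the domainogram: the matrix
of -log10 p over (window size x start index), a multiscale picture of which
loci contact the viewpoint more than their local background. Significant
cells are merged across positions and scales into interaction calls, which
can then be linked to nearby transcription start sites and their expression
behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import rank_sum_test
from .genes import GeneTable
from .intervals import gap_distance

logger = logging.getLogger(__name__)

UNTESTABLE = None  # window_test result where a full flank is missing

DEFAULT_WINDOW_SIZES = (2, 5, 10, 20, 50, 100)
P_FLOOR = 1e-16


@dataclass
class FragmentTrack:
    """Ordered fragment-end counts around one viewpoint.

    ``fragments`` columns: chrom, pos, klass ("blind"/"regular"), count and,
    after normalization, norm. Positions must be strictly increasing within
    a chromosome.
    """

    fragments: pd.DataFrame
    viewpoint_chrom: str
    viewpoint_pos: int
    viewpoint_name: str = "viewpoint"

    def __post_init__(self) -> None:
        df = self.fragments.reset_index(drop=True)
        required = {"chrom", "pos", "klass", "count"}
        if required - set(df.columns):
            raise ValueError(f"fragment table needs columns {sorted(required)}")
        if (df["count"] < 0).any():
            raise ValueError("fragment counts must be non-negative")
        pos = df["pos"].to_numpy()
        chrom = df["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1] if len(df) > 1 else np.array([], bool)
        if bool((same & (np.diff(pos) <= 0)).any()):
            raise ValueError("fragment positions must be strictly increasing")
        bad = set(df["klass"]) - {"blind", "regular"}
        if bad:
            raise ValueError(f"unknown fragment classes: {sorted(bad)}")
        self.fragments = df

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def values(self) -> np.ndarray:
        """Normalized counts when available, raw counts otherwise."""
        if "norm" in self.fragments.columns:
            return self.fragments["norm"].to_numpy(float)
        return self.fragments["count"].to_numpy(float)


@dataclass(frozen=True)
class DomainogramConfig:
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    p_floor: float = P_FLOOR
    alternative: str = "greater"

    def __post_init__(self) -> None:
        ws = tuple(sorted(int(w) for w in self.window_sizes))
        if not ws or ws[0] < 2:
            raise ValueError("window sizes must be >= 2 fragments")
        object.__setattr__(self, "window_sizes", ws)


@dataclass
class Domainogram:
    """-log10 p over (window size x start index); NaN marks untestable cells."""

    matrix: np.ndarray  # shape (n_window_sizes, n_fragments)
    window_sizes: tuple[int, ...]
    positions: np.ndarray  # bp of each fragment end
    chrom: str
    p_floor: float = P_FLOOR


@dataclass(frozen=True)
class InteractionCall:
    chrom: str
    start: int
    end: int
    frag_start: int  # fragment index range [frag_start, frag_end)
    frag_end: int
    best_p: float
    window_sizes: tuple[int, ...]
    linked_gene: str | None = None
    linked_log2fc: float = float("nan")
    linked_p: float = float("nan")
    tss_distance: int | None = None


def _midrank_quantiles(values: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return (rankdata(values) - 0.5) / len(values)


def normalize_classes(track: FragmentTrack) -> FragmentTrack:
    """Quantile-normalize blind and regular fragment counts onto a shared
    reference.

    The reference quantile function is the mean of the two classes'
    empirical (inverted-CDF) quantile functions; each value is mapped to the
    reference at its midrank quantile. For equal class sizes this reproduces
    the classic two-vector quantile normalization (sort each class, average
    the sorted vectors, assign back by rank), so the two normalized
    distributions coincide exactly; tied raw counts within a class receive
    equal normalized values and within-class ranking is preserved. If either
    class is empty the track is returned unchanged (norm = raw count).
    """
    df = track.fragments.copy()
    blind = (df["klass"] == "blind").to_numpy()
    x = df.loc[blind, "count"].to_numpy(float)
    y = df.loc[~blind, "count"].to_numpy(float)
    if len(x) == 0 or len(y) == 0:
        df["norm"] = df["count"].astype(float)
        return replace(track, fragments=df)

    def ref(p: np.ndarray) -> np.ndarray:
        return 0.5 * (
            np.quantile(x, p, method="inverted_cdf")
            + np.quantile(y, p, method="inverted_cdf")
        )

    norm = np.empty(len(df))
    norm[blind] = ref(_midrank_quantiles(x))
    norm[~blind] = ref(_midrank_quantiles(y))
    df["norm"] = norm
    return replace(track, fragments=df)


def window_test(
    values: np.ndarray, i: int, w: int, alternative: str = "greater"
) -> float | None:
    """One window-vs-flanks rank-sum test.

    Compares values[i : i+w] against the pooled flanking windows
    values[i-w : i] and values[i+w : i+2w]. Returns the p-value, or
    :data:`UNTESTABLE` when either flank is not fully inside the track.
    """
    values = np.asarray(values, float)
    if i < w or i + 2 * w > len(values):
        return UNTESTABLE
    window = values[i : i + w]
    flanks = np.concatenate([values[i - w : i], values[i + w : i + 2 * w]])
    if np.all(window == window[0]) and np.all(flanks == window[0]):
        return 1.0
    return rank_sum_test(window, flanks, alternative=alternative).p


def build_domainogram(track: FragmentTrack, config: DomainogramConfig | None = None) -> Domainogram:
    """Multiscale -log10 p matrix over (window size x start index).

    p-values are floored at ``config.p_floor`` so the matrix stays finite;
    cells whose flanks fall off the track are NaN. The track must span at
    least three times the smallest window.
    """
    config = config or DomainogramConfig()
    values = track.values
    if len(values) < 3 * config.window_sizes[0]:
        raise ValueError(
            f"track of {len(values)} fragments is shorter than three times the "
            f"smallest window ({config.window_sizes[0]})"
        )
    mat = np.full((len(config.window_sizes), len(values)), np.nan)
    for wi, w in enumerate(config.window_sizes):
        if len(values) < 3 * w:
            continue
        for i in range(w, len(values) - 2 * w + 1):
            p = window_test(values, i, w, config.alternative)
            mat[wi, i] = -np.log10(max(p, config.p_floor))
    return Domainogram(
        matrix=mat,
        window_sizes=config.window_sizes,
        positions=track.fragments["pos"].to_numpy(),
        chrom=str(track.fragments["chrom"].iloc[0]) if len(track) else track.viewpoint_chrom,
        p_floor=config.p_floor,
    )


def call_interactions(
    d: Domainogram, p_threshold: float = 1e-3
) -> list[InteractionCall]:
    """Merge significant domainogram cells into interaction calls.

    Every cell (w, i) with p < ``p_threshold`` claims the fragment-index
    interval [i, i+w); overlapping or touching claims are merged across
    positions and window scales into maximal intervals. Each call records
    its best (smallest) p and the window sizes supporting it.
    """
    score = -np.log10(p_threshold)
    claims: list[tuple[int, int, float, int]] = []
    for wi, w in enumerate(d.window_sizes):
        hits = np.nonzero(d.matrix[wi] > score)[0]
        for i in hits:
            claims.append((int(i), int(i) + w, float(d.matrix[wi, i]), w))
    if not claims:
        return []
    claims.sort()
    merged: list[list] = []  # [start, end, best_score, {window sizes}]
    for s, e, sc, w in claims:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], sc)
            merged[-1][3].add(w)
        else:
            merged.append([s, e, sc, {w}])
    out = []
    for s, e, sc, ws in merged:
        out.append(
            InteractionCall(
                chrom=d.chrom,
                start=int(d.positions[s]),
                end=int(d.positions[e - 1]) + 1,
                frag_start=s,
                frag_end=e,
                best_p=float(10.0 ** (-sc)),
                window_sizes=tuple(sorted(ws)),
            )
        )
    return out


def link_viewpoint(
    calls: list[InteractionCall],
    genes: GeneTable,
    expr_de: pd.DataFrame | None = None,
    viewpoint_pos: int | None = None,
    range_bp: int = 750_000,
    tss_window: int = 5_000,
) -> list[InteractionCall]:
    """Restrict calls to the viewpoint neighbourhood and link them to TSSs.

    Calls whose interval lies more than ``range_bp`` from the viewpoint
    (edge-to-edge) are discarded. A retained call within ``tss_window`` of a
    TSS (boundary inclusive) is linked to the nearest TSS's gene and, when an
    expression table (index gene_id, columns log2fc and p) is supplied,
    annotated with that gene's expression change.
    """
    if viewpoint_pos is None:
        raise ValueError("viewpoint_pos is required")
    out: list[InteractionCall] = []
    for call in calls:
        dist_vp = gap_distance((call.start, call.end), (viewpoint_pos, viewpoint_pos + 1))
        if dist_vp > range_bp:
            continue
        gdf = genes.df[genes.df["chrom"] == call.chrom]
        best_gene, best_dist = None, None
        for g in gdf.itertuples(index=False):
            dist = gap_distance((call.start, call.end), (int(g.tss), int(g.tss) + 1))
            if best_dist is None or dist < best_dist:
                best_gene, best_dist = g.gene_id, dist
        if best_gene is not None and best_dist <= tss_window:
            log2fc, p = float("nan"), float("nan")
            if expr_de is not None and best_gene in expr_de.index:
                log2fc = float(expr_de.loc[best_gene, "log2fc"])
                p = float(expr_de.loc[best_gene, "p"])
            out.append(
                replace(
                    call,
                    linked_gene=best_gene,
                    linked_log2fc=log2fc,
                    linked_p=p,
                    tss_distance=int(best_dist),
                )
            )
        else:
            out.append(call)
    return out


# -- I/O ---------------------------------------------------------------------


def read_track(path: str | Path) -> FragmentTrack:
    """Read a fragment track TSV (chrom, pos, klass, count).

    The viewpoint is declared in a leading comment line:
    ``# viewpoint=<chrom>:<pos>:<name>``.
    """
    path = Path(path)
    vp_chrom, vp_pos, vp_name = None, None, "viewpoint"
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("# viewpoint="):
        spec = first.split("=", 1)[1]
        parts = spec.split(":")
        vp_chrom, vp_pos = parts[0], int(parts[1])
        if len(parts) > 2:
            vp_name = parts[2]
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "pos", "klass", "count"],
                     dtype={"chrom": str})
    if vp_chrom is None:
        raise ValueError(f"{path}: missing '# viewpoint=chrom:pos[:name]' header")
    return FragmentTrack(df, vp_chrom, vp_pos, vp_name)


def write_track(track: FragmentTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# viewpoint={track.viewpoint_chrom}:{track.viewpoint_pos}:"
            f"{track.viewpoint_name}\n"
        )
        track.fragments[["chrom", "pos", "klass", "count"]].to_csv(
            fh, sep="\t", header=False, index=False
        )
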