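"""Planted-truth generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure of a whole-genome bisulfite
study of an adult stem-cell differentiation system at desk scale: per-CpG
beta-binomial read counts over a two-state (hypo/hyper) methylation
landscape with planted hypo-methylated regions; stem/differentiated pairs
with planted DMRs (mostly methylation losses) and a small global methylation
loss (defaults emulate roughly 78% genome-wide methylation dropping to
roughly 74%); correlated per-read CpG calls; 4C fragment-end tracks with a
distance-decaying heavy-tailed background, a distinct blind-fragment count
distribution and multiplicative contact peaks; replicate log2 expression
with planted fold changes; and gene/repeat/TF-peak annotations.

Every generator is a pure function of its parameters and seed, and each
emits a machine-readable truth table describing exactly what was planted,
so downstream callers can be scored against known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fourc import FragmentTrack
from .genes import GeneTable
from .methylome import Methylome, ReadPatternSet

logger = logging.getLogger(__name__)

CHROM = "chr1"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic methylome landscape.

    The defaults are the study conditions the pipeline targets: ~10-fold
    Poisson coverage per CpG, a hyper-methylated baseline near 0.85 broken
    by planted hypo-methylated regions near 0.10 occupying ~9% of CpGs
    (genome-wide weighted methylation ~0.78), 50 planted DMRs of which 43
    lose methylation upon differentiation (delta 0.5, 15 CpGs each), and a
    global methylation loss of 0.04. Beta-binomial dispersion is
    parameterized as (mean, precision): alpha = mean * precision,
    beta = (1 - mean) * precision.
    """

    genome_length: int = 2_000_000
    cpg_density: float = 8.0  # expected CpGs per kb
    coverage_mean: float = 10.0
    hypo_level: float = 0.10
    hyper_level: float = 0.85
    betabin_dispersion: float = 30.0  # precision; np.inf = plain binomial
    n_hmrs: int = 50
    hmr_cpg_range: tuple[int, int] = (20, 40)
    n_hypo_dmrs: int = 43
    n_hyper_dmrs: int = 7
    dmr_delta: float = 0.5
    cpgs_per_dmr: int = 15
    global_loss: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not (0 <= self.hypo_level < self.hyper_level <= 1):
            raise ValueError("need 0 <= hypo_level < hyper_level <= 1")
        if not (0 < self.dmr_delta <= 1):
            raise ValueError("dmr_delta must be in (0, 1]")
        if min(self.cpg_density, self.betabin_dispersion) <= 0:
            raise ValueError("cpg_density and dispersion must be positive")
        if min(self.n_hmrs, self.n_hypo_dmrs, self.n_hyper_dmrs,
               self.cpgs_per_dmr) < 0:
            raise ValueError("counts must be non-negative")
        if not (0 <= self.global_loss < 1):
            raise ValueError("global_loss must be in [0, 1)")


def _cpg_positions(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    mean_gap = 1000.0 / spec.cpg_density
    n_expect = int(spec.genome_length / mean_gap * 1.3) + 16
    gaps = rng.geometric(1.0 / mean_gap, size=n_expect)
    pos = np.cumsum(gaps) + 50
    pos = pos[pos < spec.genome_length - 50]
    while len(pos) and pos[-1] < spec.genome_length - 50 - 10 * mean_gap:
        extra = np.cumsum(rng.geometric(1.0 / mean_gap, size=n_expect)) + pos[-1]
        pos = np.concatenate([pos, extra[extra < spec.genome_length - 50]])
    return pos.astype(np.int64)


def _place_blocks(
    n_sites: int,
    n_blocks: int,
    lengths: np.ndarray,
    rng: np.random.Generator,
    margin: int = 5,
    occupied: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Non-overlapping CpG-index blocks [start, end), margin sites apart."""
    taken = np.zeros(n_sites, dtype=bool)
    if occupied is not None:
        taken |= occupied
    blocks: list[tuple[int, int]] = []
    attempts = 0
    for L in lengths:
        placed = False
        while not placed:
            attempts += 1
            if attempts > 200 * n_blocks + 1000:
                raise ValueError(
                    "could not place requested blocks: genome too small for "
                    "the requested features"
                )
            s = int(rng.integers(margin, max(n_sites - L - margin, margin + 1)))
            lo, hi = max(0, s - margin), min(n_sites, s + L + margin)
            if not taken[lo:hi].any():
                taken[s : s + L] = True
                blocks.append((s, s + int(L)))
                placed = True
    return sorted(blocks)


def _draw_counts(
    means: np.ndarray,
    coverage_mean: float,
    precision: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = rng.poisson(coverage_mean, size=len(means))
    if np.isinf(precision):
        p = means
    else:
        a = np.clip(means, 1e-12, 1 - 1e-12) * precision
        b = (1 - np.clip(means, 1e-12, 1 - 1e-12)) * precision
        p = rng.beta(a, b)
        p = np.where((means <= 0) | (means >= 1), means, p)
    k = rng.binomial(n, p)
    return k, n


def _sites_frame(pos: np.ndarray, k: np.ndarray, n: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"chrom": CHROM, "pos": pos, "meth": k, "total": n})


def simulate_methylome(
    spec: SimulationSpec, sample_name: str = "sim"
) -> tuple[Methylome, pd.DataFrame]:
    """One methylome over a two-state landscape with planted HMRs.

    Returns the methylome and a truth table of planted hypo-methylated
    intervals (chrom, start, end, cpg_start, cpg_end, n_cpgs; CpG indices
    are half-open into the site array).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pos = _cpg_positions(spec, rng)
    lengths = rng.integers(spec.hmr_cpg_range[0], spec.hmr_cpg_range[1] + 1,
                           size=spec.n_hmrs)
    blocks = _place_blocks(len(pos), spec.n_hmrs, lengths, rng)
    means = np.full(len(pos), spec.hyper_level)
    for s, e in blocks:
        means[s:e] = spec.hypo_level
    k, n = _draw_counts(means, spec.coverage_mean, spec.betabin_dispersion, rng)
    m = Methylome(
        _sites_frame(pos, k, n),
        sample_name,
        {CHROM: spec.genome_length},
    )
    truth = pd.DataFrame(
        [
            {
                "chrom": CHROM,
                "start": int(pos[s]),
                "end": int(pos[e - 1]) + 1,
                "cpg_start": s,
                "cpg_end": e,
                "n_cpgs": e - s,
            }
            for s, e in blocks
        ],
        columns=["chrom", "start", "end", "cpg_start", "cpg_end", "n_cpgs"],
    )
    return m, truth


def simulate_differentiation_pair(
    spec: SimulationSpec,
) -> tuple[Methylome, Methylome, pd.DataFrame]:
    """A stem/differentiated methylome pair with planted DMRs.

    Both methylomes share CpG positions and planted HMRs. Loss-DMRs sit in
    the hyper background: stem at hyper_level, differentiated at
    hyper_level - delta. Gain-DMRs are the mirror image (stem at
    hyper_level - delta). All non-DMR sites additionally drop by
    ``global_loss`` in the differentiated sample, emulating passive
    genome-wide demethylation. Counts are drawn independently per sample.

    Returns (stem, villus, truth) where truth lists chrom, start, end,
    direction ("loss"/"gain"), delta and n_cpgs per planted DMR.
    """
    spec.validate()
    if spec.dmr_delta * spec.coverage_mean < 1:
        logger.warning(
            "planted delta %.3f is below the sampling noise floor at coverage %.1f",
            spec.dmr_delta,
            spec.coverage_mean,
        )
    rng = np.random.default_rng(spec.seed)
    pos = _cpg_positions(spec, rng)
    hmr_lengths = rng.integers(spec.hmr_cpg_range[0], spec.hmr_cpg_range[1] + 1,
                               size=spec.n_hmrs)
    hmr_blocks = _place_blocks(len(pos), spec.n_hmrs, hmr_lengths, rng)
    occupied = np.zeros(len(pos), dtype=bool)
    for s, e in hmr_blocks:
        occupied[max(0, s - 5) : e + 5] = True
    n_dmrs = spec.n_hypo_dmrs + spec.n_hyper_dmrs
    dmr_blocks = _place_blocks(
        len(pos),
        n_dmrs,
        np.full(n_dmrs, spec.cpgs_per_dmr),
        rng,
        occupied=occupied,
    )
    directions = ["loss"] * spec.n_hypo_dmrs + ["gain"] * spec.n_hyper_dmrs
    order = rng.permutation(n_dmrs)
    assignment = [directions[i] for i in order]

    stem_means = np.full(len(pos), spec.hyper_level)
    for s, e in hmr_blocks:
        stem_means[s:e] = spec.hypo_level
    villus_means = np.clip(stem_means - spec.global_loss, 0.0, 1.0)

    rows = []
    for (s, e), direction in zip(dmr_blocks, assignment):
        if direction == "loss":
            stem_means[s:e] = spec.hyper_level
            villus_means[s:e] = spec.hyper_level - spec.dmr_delta
        else:
            stem_means[s:e] = spec.hyper_level - spec.dmr_delta
            villus_means[s:e] = spec.hyper_level
        rows.append(
            {
                "chrom": CHROM,
                "start": int(pos[s]),
                "end": int(pos[e - 1]) + 1,
                "direction": direction,
                "delta": spec.dmr_delta if direction == "loss" else -spec.dmr_delta,
                "n_cpgs": e - s,
            }
        )
    ks, ns = _draw_counts(stem_means, spec.coverage_mean,
                          spec.betabin_dispersion, rng)
    kv, nv = _draw_counts(villus_means, spec.coverage_mean,
                          spec.betabin_dispersion, rng)
    manifest = {CHROM: spec.genome_length}
    stem = Methylome(_sites_frame(pos, ks, ns), "stem", manifest)
    villus = Methylome(_sites_frame(pos, kv, nv), "villus", manifest)
    truth = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "delta", "n_cpgs"]
    )
    return stem, villus, truth


def simulate_read_patterns(
    m: Methylome, rho: float, n_reads: int, seed: int | None = None
) -> ReadPatternSet:
    """Reads covering three consecutive CpGs with co-methylation rho.

    Each read anchors at a uniform CpG index i and calls sites i, i+1, i+2.
    With probability ``rho`` the read is coherent: a single Bernoulli draw at
    the mean of the three site levels decides all three calls (rho = 1 gives
    only fully methylated or fully unmethylated reads); otherwise the three
    calls are independent Bernoullis at the per-site levels (rho = 0 gives
    the independence product for the all-methylated fraction). Site levels
    are the underlying per-CpG methylation fractions; uncovered sites count
    as the sample-wide weighted mean.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    if len(m) < 3:
        raise ValueError("methylome must have at least 3 CpGs")
    rng = np.random.default_rng(seed)
    if n_reads == 0:
        return ReadPatternSet(np.zeros((0, 3), dtype=bool),
                              np.zeros(0, dtype=np.int64))
    levels = m.levels
    fallback = np.nanmean(levels) if np.isnan(levels).any() else 0.0
    levels = np.nan_to_num(levels, nan=fallback)
    anchors = rng.integers(0, len(m) - 2, size=n_reads)
    trip = np.stack([levels[anchors], levels[anchors + 1], levels[anchors + 2]],
                    axis=1)
    coherent = rng.random(n_reads) < rho
    shared = rng.random(n_reads)[:, None] < trip.mean(axis=1)[:, None]
    indep = rng.random((n_reads, 3)) < trip
    patterns = np.where(coherent[:, None], shared, indep)
    return ReadPatternSet(patterns, anchors.astype(np.int64))


def simulate_4c_track(
    n_fragments: int,
    blind_fraction: float = 0.3,
    background_scale: float = 5.0,
    peaks: list[tuple[int, int, float]] | None = None,
    seed: int | None = None,
    chrom: str = "chr4",
    viewpoint_name: str = "viewpoint",
    frag_spacing: float = 1000.0,
    decay_halfdist: float = 50_000.0,
    blind_ratio: float = 0.35,
) -> tuple[FragmentTrack, pd.DataFrame]:
    """A 4C fragment-end track with planted contact peaks.

    Fragment ends are spaced by geometric gaps (mean ``frag_spacing`` bp)
    with the viewpoint at the central fragment. Regular counts follow a
    geometric ("heavy-tailed") background whose mean decays with distance d
    from the viewpoint as background_scale / (1 + d / decay_halfdist);
    blind-fragment counts come from the same family with mean scaled by
    ``blind_ratio``, giving the two classes systematically different
    distributions. Peaks are (center_bp, width_fragments, enrichment)
    triples that multiply the background mean over ``width`` fragments
    centred on the fragment nearest center_bp.

    Returns the track plus a truth table (chrom, start, end, frag_start,
    frag_end, enrichment).
    """
    if n_fragments < 3:
        raise ValueError("need at least 3 fragments")
    if not (0.0 <= blind_fraction <= 1.0):
        raise ValueError("blind_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gaps = rng.geometric(1.0 / frag_spacing, size=n_fragments)
    pos = np.cumsum(gaps) + 1000
    vp_pos = int(pos[n_fragments // 2])
    dist = np.abs(pos - vp_pos).astype(float)
    mu = background_scale / (1.0 + dist / decay_halfdist)
    enrich = np.ones(n_fragments)
    rows = []
    for center, width, enrichment in peaks or []:
        if enrichment <= 1:
            logger.warning("peak at %d has enrichment %.2f <= 1: undetectable",
                           center, enrichment)
        if not (pos[0] <= center <= pos[-1]):
            raise ValueError(f"peak center {center} outside track")
        c = int(np.searchsorted(pos, center))
        c = min(max(c, 0), n_fragments - 1)
        s = max(0, c - width // 2)
        e = min(n_fragments, s + width)
        enrich[s:e] *= enrichment
        rows.append(
            {
                "chrom": chrom,
                "start": int(pos[s]),
                "end": int(pos[e - 1]) + 1,
                "frag_start": s,
                "frag_end": e,
                "enrichment": enrichment,
            }
        )
    blind = rng.random(n_fragments) < blind_fraction
    mu_eff = mu * enrich * np.where(blind, blind_ratio, 1.0)
    counts = rng.geometric(1.0 / (1.0 + mu_eff)) - 1
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "klass": np.where(blind, "blind", "regular"),
            "count": counts,
        }
    )
    track = FragmentTrack(df, chrom, vp_pos, viewpoint_name)
    truth = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "frag_start", "frag_end", "enrichment"],
    )
    return track, truth


def simulate_expression(
    genes: GeneTable,
    n_up: int = 0,
    n_down: int = 0,
    log2fc: float = 2.0,
    sigma: float = 0.25,
    n_replicates: int = 3,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Replicate log2 expression for two conditions with planted DE genes.

    Per gene, replicate values are Normal(baseline, sigma) on the log2
    scale; the first ``n_up`` planted genes are shifted by +log2fc in
    condition B, the next ``n_down`` by −log2fc. Returns (matrix, groups,
    truth) where groups maps "A"/"B" to sample column names and truth lists
    gene_id and planted label in {"up", "down", "null"}.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    ids = genes.gene_ids
    if n_up + n_down > len(ids):
        raise ValueError("more planted DE genes than genes")
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(4.0, 12.0, size=len(ids))
    chosen = rng.choice(len(ids), size=n_up + n_down, replace=False)
    shift = np.zeros(len(ids))
    shift[chosen[:n_up]] = log2fc
    shift[chosen[n_up:]] = -log2fc
    cols_a = [f"A_{i + 1}" for i in range(n_replicates)]
    cols_b = [f"B_{i + 1}" for i in range(n_replicates)]
    data = {}
    for c in cols_a:
        data[c] = rng.normal(baseline, sigma)
    for c in cols_b:
        data[c] = rng.normal(baseline + shift, sigma)
    expr = pd.DataFrame(data, index=pd.Index(ids, name="gene_id"))
    label = np.full(len(ids), "null", dtype=object)
    label[chosen[:n_up]] = "up"
    label[chosen[n_up:]] = "down"
    truth = pd.DataFrame({"gene_id": ids, "label": label})
    return expr, {"A": cols_a, "B": cols_b}, truth


def simulate_annotations(
    genome_length: int = 2_000_000,
    n_genes: int = 30,
    exons_per_gene: int = 3,
    gene_length: int = 12_000,
    n_repeats_per_class: int = 20,
    repeat_length: int = 300,
    n_tf_peaks: int = 0,
    peak_width: int = 200,
    min_tss_distance: int = 0,
    peak_centers: list[int] | None = None,
    chrom: str = CHROM,
    seed: int | None = None,
) -> tuple[GeneTable, pd.DataFrame, pd.DataFrame]:
    """Gene, repeat and TF-peak annotation over one synthetic chromosome.

    Gene bodies are non-overlapping, evenly tiled, alternating strand, with
    ``exons_per_gene`` equal exons and a CDS trimming the outer exon halves
    (so both UTR classes exist). Repeats are uniform intervals labelled
    SINE/LINE/LTR. TF peaks are centred on ``peak_centers`` when given,
    otherwise placed uniformly; every peak centre is constrained to lie at
    least ``min_tss_distance`` bp from every TSS.
    """
    rng = np.random.default_rng(seed)
    span_per_gene = genome_length // max(n_genes, 1)
    if gene_length + 2000 > span_per_gene:
        raise ValueError("requested genes exceed genome length")
    gene_rows = []
    for i in range(n_genes):
        tx_start = i * span_per_gene + 1000
        tx_end = tx_start + gene_length
        exon_len = gene_length // (2 * exons_per_gene - 1)
        starts, ends = [], []
        for j in range(exons_per_gene):
            s = tx_start + 2 * j * exon_len
            starts.append(s)
            ends.append(min(s + exon_len, tx_end))
        ends[-1] = tx_end
        cds_start = starts[0] + exon_len // 2
        cds_end = ends[-1] - exon_len // 2
        gene_rows.append(
            {
                "gene_id": f"gene{i + 1}",
                "chrom": chrom,
                "strand": "+" if i % 2 == 0 else "-",
                "tx_start": tx_start,
                "tx_end": tx_end,
                "cds_start": cds_start,
                "cds_end": cds_end,
                "exon_starts": tuple(starts),
                "exon_ends": tuple(ends),
            }
        )
    genes = GeneTable(pd.DataFrame(gene_rows))
    repeat_rows = []
    for klass in ("SINE", "LINE", "LTR"):
        for _ in range(n_repeats_per_class):
            s = int(rng.integers(0, genome_length - repeat_length))
            repeat_rows.append(
                {"chrom": chrom, "start": s, "end": s + repeat_length,
                 "klass": klass}
            )
    repeats = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "klass"]
    )
    tss = genes.df["tss"].to_numpy()
    peak_rows = []
    centers: list[int] = list(peak_centers) if peak_centers is not None else []
    if peak_centers is None and n_tf_peaks > 0:
        attempts = 0
        while len(centers) < n_tf_peaks:
            attempts += 1
            if attempts > 1000 * n_tf_peaks:
                raise ValueError("cannot place TF peaks under the TSS-distance "
                                 "constraint")
            c = int(rng.integers(peak_width, genome_length - peak_width))
            if len(tss) == 0 or np.abs(tss - c).min() >= min_tss_distance:
                centers.append(c)
    for i, c in enumerate(centers):
        if len(tss) and np.abs(tss - c).min() < min_tss_distance:
            raise ValueError(f"peak centre {c} violates min_tss_distance")
        peak_rows.append(
            {
                "chrom": chrom,
                "start": c - peak_width // 2,
                "end": c + peak_width // 2,
                "summit": c,
                "name": f"peak{i + 1}",
            }
        )
    peaks = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "summit", "name"]
    )
    return genes, repeats, peaks
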