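# Methods

## Methylome model

A methylome is an ordered table of per-CpG (methylated reads, total reads)
pairs for one cell population, 0-based, both strands collapsed onto the
plus-strand C. The scalar summary used throughout is *weighted methylation*,
Σ meth / Σ total over a region: it is count-weighted, exactly additive over
a partition of the region, and robust to low-coverage CpGs. A region with no
read observations yields a distinguished "no data" result, never 0. Files
use the methcounts-style six-column TSV (chrom, pos, strand, context, level,
coverage); methylated counts are reconstructed as round(level × coverage),
which is lossless when the file was written from integer counts.

## HMR segmentation

Two-state HMM over the CpG sequence. Emissions are beta-binomial,
parameterized per state as (mean, precision) with α = mean·precision,
β = (1 − mean)·precision — two orthogonal, interpretable knobs. The
beta-binomial absorbs the biological and technical overdispersion of
bisulfite counts relative to a plain binomial; a zero-coverage CpG emits
with probability one in both states and therefore carries no information but
keeps the chain's positional structure. Inter-CpG gaps larger than
`desert_size` (default 1,000 bp) reset the chain to its initial
distribution, so state information never crosses long unassayed stretches.

Fitting is Baum–Welch EM: an exact scaled forward–backward E-step and an
M-step that updates transitions/initial probabilities in closed form and the
emission parameters by numerical maximisation (L-BFGS on log-parameters with
analytic digamma gradients, sites aggregated by unique (k, n) pairs). The
M-step keeps the previous parameters whenever the optimiser fails to improve
the expected complete-data log-likelihood, so the data log-likelihood is
non-decreasing by construction — an asserted invariant. States are
relabelled after fitting so state 0 is always the lower-mean (hypo) state.
Convergence: absolute log-likelihood gain < `tol` (default 1e-4), cap
`max_iter` = 100; a non-converged fit returns best parameters with a flag.

HMRs are maximal runs of CpGs with posterior P(hypo) > 0.5 (posterior
decoding), never spanning deserts or chromosome boundaries. A posterior of
exactly 0.5 is assigned to the hyper state — the conservative tie-break
(fewer HMRs).

## DMR calling

Candidates are the symmetric difference of two samples' HMR interval sets:
regions hypo-methylated in exactly one sample. A candidate is emitted when
(i) it contains at least 10 CpGs covered in both samples and (ii) the
absolute weighted-methylation difference is at least 0.40; both boundaries
are inclusive, and the delta filter is applied on count-weighted region
methylation rather than the mean of per-CpG levels (the robust choice at
low coverage). Per-CpG Fisher exact tests on the (meth, unmeth) × (sample)
tables are summarised per emitted DMR (minimum p, fraction below 0.05) but
are not used as a filter by default, since the exact scoring rule of the
original HMR/DMR software is not recoverable. Direction: with arguments
(a, b) = (stem, differentiated), Δ = level(a) − level(b) > 0 is "loss" upon
differentiation. Swapping the arguments provably yields identical intervals
with flipped signs.

## TSS, elements and expression

TSS methylation is weighted methylation of [tss − 1 kb, tss + 1 kb). The
"CpG data-point" filter is interpreted as the summed read coverage of the
window's CpGs (default thresholds 80 or 50 depending on the comparison);
the alternative reading — number of distinct covered CpGs — is available via
`datapoint_mode="cpgs"`, but 80 distinct CpGs in 2 kb is near the biological
ceiling, which makes summed coverage the more plausible convention. A gene
passes only if it meets the threshold in *every* compared methylome; failing
genes are flagged, never dropped. Differential TSSs require a strictly
greater than 0.50 level difference.

Genomic elements: TSS windows, exons, introns, and UTRs derived as exonic
sequence outside the CDS on the strand-appropriate side, plus repeat
intervals by class. Per-element change is 100 × (level_b − level_a); the
class summary is the unweighted mean over elements (one element, one vote).
Elements lacking coverage in either sample are excluded from their class
mean. Expression flags on genic elements inherit the host gene's status.

DE calling on log2 replicate intensities: log2FC = mean(B) − mean(A);
"two-fold" means |log2FC| ≥ 1 (boundary inclusive); the t-test is two-sample
Student with equal variances at per-gene p < 0.01 with no multiple-testing
correction by default, matching per-gene usage in the study design this
emulates; a Benjamini–Hochberg option sits behind the ``fdr`` flag.
Identical constant groups get p = 1 by convention. The DMR–DE association
uses a label permutation: null sets are uniform random gene sets of the same
size, and the one-sided empirical p carries the add-one correction
(1 + #{null ≥ obs}) / (n_perm + 1), so p ∈ [1/(n_perm+1), 1].

## Rank-sum test

The Wilcoxon/Mann–Whitney implementation is shared by the element
comparisons and the 4C window statistic. With at most 12 pooled observations
and no ties it uses the exact null distribution of the rank sum (dynamic
programme over n-subsets of ranks); otherwise a normal approximation with
midranks, tie-corrected variance and a 0.5 continuity correction. If every
pooled value is identical the test is uninformative and p = 1. The exact
branch is validated against full enumeration of all C(n+m, n) rank
assignments; the approximate branch against a 10^5-draw permutation oracle.

## 4C domainograms

Blind fragment ends (no secondary-cutter site between two primary-cutter
sites) have a systematically different count distribution from regular ends,
so the two classes are quantile-normalized before testing: each value maps
to the mean of the two classes' empirical quantile functions at its midrank
quantile. For equal class sizes this reproduces the classic two-vector
quantile normalization exactly (the two normalized distributions coincide;
KS distance 0); with unequal sizes the KS distance is bounded by
1/min(n_blind, n_regular). Tied raw counts receive equal normalized values,
so the exact-coincidence property is asserted on continuous counts.

The window statistic compares values[i..i+w−1] against the pooled flanks
values[i−w..i−1] and values[i+w..i+2w−1], one-sided ("window greater") —
the enrichment question the assay asks. Cells whose flanks leave the track are
"untestable" (NaN in the matrix), and p is floored at 1e-16 for a finite
−log10 display. Window sizes default to {2, 5, 10, 20, 50, 100} fragments
(there is no canonical range). Cells with p below the
calling threshold (default 1e-3) claim their fragment interval; claims are
merged across positions and scales by interval union into maximal calls,
each carrying its best p and supporting scales. Calls farther than 750 kb
from the viewpoint are discarded; a retained call within 5 kb of a TSS
(boundary inclusive, edge-to-edge) is linked to the nearest TSS and
annotated with that gene's log2FC and DE p. The "within 5 kb of a TSS" rule
is read as *selecting* the TSS-proximal loops for linking — the opposite
(discarding) reading would leave nothing to link expression to.

Null calibration of the window test is asserted at w = 10 with α = 0.05 on
block-spaced (disjoint) cells: for small w the rank-sum null is too discrete
for the false-positive rate to sit on α (e.g. w = 2 cannot produce p < 1/15),
so the calibration band is checked in the asymptotic regime while small-w
cells are covered by the exactness check instead.

## DMR context and TF metaprofiles

Context labels use edge-to-edge distances: "TSS" within 2 kb of a TSS,
"intergenic" farther than 2 kb from every transcript, exon/intron by
overlap; a DMR overlapping several elements is counted in each category
(TSS and intergenic stay mutually exclusive). A DMR within 2 kb of a gene
but overlapping nothing and away from the TSS — a configuration the
standard rules leave unlabelled — receives the label of its nearest genic
element so that every DMR is counted somewhere. DMR–peak proximity is
edge-to-edge with a 1 kb inclusive boundary. Metaprofiles pool read counts
per bin across peaks (count-weighted, not mean-of-means), ±2 kb around
summits in 50 bp bins by default, after excluding peaks whose summit is
closer than 5 kb to any TSS ("at least 5 kb away" keeps the exact boundary);
flank width and bin size have no canonical values and are
exposed as configuration.

## Synthetic data generator

The generators emulate the study conditions, not the mouse genome. Defaults:
2 Mb single-chromosome genome, 8 CpGs/kb (geometric gaps), Poisson 10×
coverage, hyper state 0.85 and hypo state 0.10 with beta-binomial precision
30, 50 planted HMRs of 20–40 CpGs (~9% of CpGs hypo, genome-wide weighted
methylation ≈ 0.78), 50 planted DMRs (43 loss / 7 gain, Δ = 0.5, 15 CpGs
each) and a global loss of 0.04 applied to all non-DMR state means in the
differentiated sample. Loss-DMRs sit in the hyper background (stem 0.85 →
villus 0.35); gain-DMRs are the mirror image. Counts are drawn independently
per sample; every generator is a pure function of its parameters and seed
and emits a truth table.

Read-level patterns use a coherence mixture: with probability ρ a read's
three CpG calls share a single Bernoulli draw at the mean of the three site
levels, otherwise they are independent per-site draws. This reproduces the
two anchor cases exactly (ρ = 1 → only fully methylated/unmethylated reads;
ρ = 0 → independence products) at the cost of slightly distorted per-site
marginals for intermediate ρ — adequate for testing the pattern summaries,
not a mechanistic model of processive (de)methylation.

4C tracks: fragment ends at geometric spacings (mean 1 kb), viewpoint at the
central fragment, geometric ("heavy-tailed") background counts whose mean
decays with distance d as scale/(1 + d/50 kb) — a smooth power-law-style
proximity bias, since the source data show but do not parameterize it.
Blind fragments draw from the same family with mean scaled by 0.35. Peaks
multiply the background mean over a stated width of fragments.

What the generator does **not** emulate: CpG islands and local density
structure, strand asymmetries, mapping artefacts, copy-number effects,
replicate library structure, trans-chromosomal 4C contacts, and microarray
probe effects. Passing benchmarks therefore demonstrate correctness of the
statistics and callers under the assumed generative families, not
performance on real tissue data.

## Problem sizes and runtime choices

The test and acceptance runs use scaled-down instances chosen to keep the
full suite fast while leaving the assertions statistically meaningful:
5,000–16,000 CpGs per methylome, 600-fragment 4C tracks, 3,000-gene
expression universes, 100-seed calibration loops, 10,000 permutations.
Assertion tolerances are derived from the sampling noise of those sizes
(binomial/Monte-Carlo standard errors), not tuned. On the default study-size
simulation the villus global methylation lands near 72% rather than the
~74% a genome-scale run would give, because the 50 planted DMRs occupy a
visibly larger fraction of a 2 Mb toy genome than of a real one — the
acceptance script reports what it measures.

## Known limitations

- The HMR/DMR procedure follows the cited methodology family (two-state
  beta-binomial HMM, posterior decoding, symmetric-difference candidates)
  but is not a bit-for-bit reimplementation of any particular software.
- Fisher per-CpG summaries are reported, not used for filtering; the
  candidate scoring used by earlier implementations of this methodology
  is not standardised.
- The exact rank-sum branch is disabled in the presence of ties (midranks +
  corrected normal approximation are used instead).
- Interaction-call merging across scales is by interval union; other
  reasonable merge rules (e.g. scale-weighted) would change call boundaries
  but not the planted-truth recovery asserted here.
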