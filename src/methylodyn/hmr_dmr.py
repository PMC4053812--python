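"""Hypo-methylated region (HMR) segmentation and DMR calling.

Methylomes are segmented with a two-state hidden Markov model over the
ordered CpG sequence. Emissions are beta-binomial: at a CpG with ``n`` reads
of which ``k`` are methylated, state ``s`` emits ``k`` with probability
BetaBinomial(k; n, alpha_s, beta_s). The beta-binomial absorbs the
overdispersion of bisulfite counts relative to a plain binomial. State 0 is
always the lower-mean ("hypo") state; large gaps between consecutive CpGs
("deserts") reset the chain, so no state information is carried across
unassayed stretches.

Fitting is Baum-Welch EM (exact E-step via scaled forward-backward; M-step
for the emission parameters by numerical maximisation of the expected
complete-data log-likelihood). HMRs are maximal runs of CpGs whose posterior
probability of the hypo state exceeds 0.5 (posterior decoding).

DMRs between two methylomes are candidate intervals hypo-methylated in
exactly one of the two (symmetric difference of the HMR sets), kept when
they span at least ``min_cpgs`` CpGs covered in both samples and the
count-weighted methylation difference is at least ``min_delta`` (defaults
10 CpGs and 0.40, i.e. a 40% difference). The sign convention is
``delta = level(a) - level(b)``; with a = stem and b = differentiated,
positive delta means methylation was *lost* upon differentiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, digamma, gammaln
from scipy.stats import fisher_exact

from . import intervals as iv
from .methylome import Methylome, weighted_methylation

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationModel",
    "FitResult",
    "HMR",
    "DMR",
    "betabin_logpmf",
    "default_model",
    "fit_segmentation",
    "posterior_hypo",
    "call_hmrs",
    "call_dmrs",
    "dmr_direction_summary",
]


def betabin_logpmf(k, n, alpha, beta):
    """Exact log PMF of the beta-binomial distribution.

    log P(K = k | n, alpha, beta) with K the number of methylated reads out
    of n. Vectorised over all arguments; k must lie in [0, n] and
    alpha, beta must be positive. n = 0 yields log(1) = 0.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("k must satisfy 0 <= k <= n")
    if np.any(np.asarray(alpha) <= 0) or np.any(np.asarray(beta) <= 0):
        raise ValueError("alpha and beta must be positive")
    out = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + alpha, n - k + beta)
        - betaln(alpha, beta)
    )
    return out if out.shape else float(out)


@dataclass
class SegmentationModel:
    """Two-state HMM with beta-binomial emissions.

    State 0 is the hypo-methylated state, state 1 the hyper-methylated one
    (enforced after fitting by relabelling). ``desert_size`` is the inter-CpG
    gap in bp beyond which the chain is reset to its initial distribution.
    """

    alpha: np.ndarray  # shape (2,)
    beta: np.ndarray  # shape (2,)
    trans: np.ndarray  # shape (2, 2), rows sum to 1
    start: np.ndarray  # shape (2,)
    desert_size: int = 1000

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, float)
        self.beta = np.asarray(self.beta, float)
        self.trans = np.asarray(self.trans, float)
        self.start = np.asarray(self.start, float)
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("emission parameters must be positive")
        if not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def emission_means(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)

    def relabelled(self) -> "SegmentationModel":
        """Return a copy with state 0 as the lower-mean state."""
        if self.emission_means[0] <= self.emission_means[1]:
            return self
        perm = [1, 0]
        return SegmentationModel(
            self.alpha[perm],
            self.beta[perm],
            self.trans[np.ix_(perm, perm)],
            self.start[perm],
            self.desert_size,
        )


@dataclass
class FitResult:
    model: SegmentationModel
    log_likelihoods: list[float]
    converged: bool

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihoods[-1]


@dataclass(frozen=True)
class HMR:
    """A maximal hypo-methylated run of CpGs."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_level: float
    score: float  # mean posterior probability of the hypo state

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class DMR:
    """An interval differentially methylated between two methylomes."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    delta: float  # weighted level(a) - weighted level(b)
    direction: str  # "loss" (delta > 0) or "gain"
    fisher_min_p: float = float("nan")
    fisher_frac_sig: float = float("nan")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def default_model(desert_size: int = 1000) -> SegmentationModel:
    """Generic initialisation: well-separated states, sticky transitions."""
    return SegmentationModel(
        alpha=np.array([2.0, 15.0]),
        beta=np.array([8.0, 5.0]),
        trans=np.array([[0.9, 0.1], [0.1, 0.9]]),
        start=np.array([0.5, 0.5]),
        desert_size=desert_size,
    )


def _blocks(m: Methylome, desert_size: int) -> list[np.ndarray]:
    """Index arrays of desert-delimited runs of consecutive CpGs."""
    out: list[np.ndarray] = []
    for _, grp in m.sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        g = grp.index.to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.nonzero(np.diff(pos) > desert_size)[0] + 1
        for blk in np.split(g, breaks):
            if len(blk):
                out.append(blk)
    return out


def _forward_backward(logB: np.ndarray, start: np.ndarray, trans: np.ndarray):
    """Scaled forward-backward for one block.

    Returns (gamma, xi_sum, loglik): per-site posteriors, summed two-slice
    posteriors, and the block log-likelihood.
    """
    T = logB.shape[0]
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    scale_log = logB.max(axis=1)
    alpha = np.empty((T, 2))
    c = np.empty(T)
    alpha[0] = start * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta_ = np.empty((T, 2))
    beta_[-1] = 1.0
    xi_sum = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta_[t + 1]
        beta_[t] = (trans @ bb) / c[t + 1]
        xi = (alpha[t][:, None] * trans) * bb[None, :] / c[t + 1]
        xi_sum += xi
    gamma = alpha * beta_
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + scale_log.sum())
    return gamma, xi_sum, loglik


def _emission_loglik_matrix(k, n, model: SegmentationModel) -> np.ndarray:
    logB = np.empty((len(k), 2))
    for s in range(2):
        logB[:, s] = betabin_logpmf(k, n, model.alpha[s], model.beta[s])
    return logB


def _weighted_betabin_mle(k, n, w, alpha0, beta0):
    """Maximise sum_i w_i log BetaBinomial(k_i; n_i, alpha, beta).

    Sites are aggregated by unique (k, n) pairs so the objective cost is
    independent of the number of CpGs. Optimised over log-parameters with
    an analytic gradient; falls back to the starting point if the optimiser
    fails to improve.
    """
    pairs = k.astype(np.int64) * (n.max() + 1) + n.astype(np.int64)
    uniq, inv = np.unique(pairs, return_inverse=True)
    wagg = np.bincount(inv, weights=w)
    ku = (uniq // (n.max() + 1)).astype(float)
    nu = (uniq % (n.max() + 1)).astype(float)

    def negQ(theta):
        a, b = np.exp(theta)
        ll = betaln(ku + a, nu - ku + b) - betaln(a, b)
        val = -float(wagg @ ll)
        da = digamma(ku + a) - digamma(nu + a + b) - digamma(a) + digamma(a + b)
        db = digamma(nu - ku + b) - digamma(nu + a + b) - digamma(b) + digamma(a + b)
        grad = -np.array([float(wagg @ da) * a, float(wagg @ db) * b])
        return val, grad

    x0 = np.log([alpha0, beta0])
    res = minimize(negQ, x0, jac=True, method="L-BFGS-B",
                   bounds=[(-7, 9)] * 2, options={"maxiter": 60})
    if res.fun <= negQ(x0)[0]:
        a, b = np.exp(res.x)
        return float(a), float(b)
    return float(alpha0), float(beta0)


def fit_segmentation(
    m: Methylome,
    init: SegmentationModel | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    seed: int | None = None,
) -> FitResult:
    """Fit the two-state segmentation model by Baum-Welch EM.

    The log-likelihood is non-decreasing across iterations (a monotonicity
    guard keeps the previous emission parameters whenever the numerical
    M-step fails to improve the expected complete-data log-likelihood).
    Convergence is declared when the log-likelihood gain falls below ``tol``.
    The fit is deterministic given the data and initialisation; ``seed`` is
    accepted for interface symmetry with the stochastic generators.

    Raises ``ValueError`` when no CpG has coverage. A non-converged fit
    returns the best parameters with ``converged=False`` and a logged
    warning.
    """
    model = (init or default_model()).relabelled()
    k = m.sites["meth"].to_numpy(float)
    n = m.sites["total"].to_numpy(float)
    if len(k) == 0 or n.sum() == 0:
        raise ValueError("cannot fit segmentation: no covered CpGs")
    blocks = _blocks(m, model.desert_size)
    lls: list[float] = []
    converged = False
    for _ in range(max_iter):
        logB = _emission_loglik_matrix(k, n, model)
        gamma = np.empty_like(logB)
        xi_sum = np.zeros((2, 2))
        start_acc = np.zeros(2)
        ll = 0.0
        for blk in blocks:
            g, x, l = _forward_backward(logB[blk], model.start, model.trans)
            gamma[blk] = g
            xi_sum += x
            start_acc += g[0]
            ll += l
        lls.append(ll)
        if len(lls) > 1 and abs(lls[-1] - lls[-2]) < tol:
            converged = True
            break
        trans = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
        # keep rows stochastic even if a state received no mass
        for s in range(2):
            if xi_sum[s].sum() == 0:
                trans[s] = model.trans[s]
        start = start_acc / start_acc.sum()
        new_ab = [
            _weighted_betabin_mle(k, n, gamma[:, s], model.alpha[s], model.beta[s])
            for s in range(2)
        ]
        model = SegmentationModel(
            alpha=np.array([ab[0] for ab in new_ab]),
            beta=np.array([ab[1] for ab in new_ab]),
            trans=trans,
            start=start,
            desert_size=model.desert_size,
        )
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return FitResult(model.relabelled(), lls, converged)


def posterior_hypo(m: Methylome, model: SegmentationModel) -> np.ndarray:
    """Posterior probability of the hypo state at every CpG."""
    model = model.relabelled()
    k = m.sites["meth"].to_numpy(float)
    n = m.sites["total"].to_numpy(float)
    logB = _emission_loglik_matrix(k, n, model)
    post = np.empty(len(k))
    for blk in _blocks(m, model.desert_size):
        g, _, _ = _forward_backward(logB[blk], model.start, model.trans)
        post[blk] = g[:, 0]
    return post


def call_hmrs(m: Methylome, model: SegmentationModel) -> list[HMR]:
    """Posterior-decode HMRs: maximal runs with P(hypo) > 0.5.

    Runs never span deserts or chromosome boundaries. A posterior of exactly
    0.5 is assigned to the hyper state (conservative: fewer HMRs).
    """
    post = posterior_hypo(m, model)
    chroms = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    meth = m.sites["meth"].to_numpy()
    total = m.sites["total"].to_numpy()
    out: list[HMR] = []
    for blk in _blocks(m, model.desert_size):
        hypo = post[blk] > 0.5
        if not hypo.any():
            continue
        edges = np.nonzero(np.diff(hypo.astype(int)))[0] + 1
        for run in np.split(np.arange(len(blk)), edges):
            if not hypo[run[0]]:
                continue
            g = blk[run]
            tot = total[g].sum()
            lvl = float(meth[g].sum() / tot) if tot > 0 else float("nan")
            out.append(
                HMR(
                    chrom=str(chroms[g[0]]),
                    start=int(pos[g[0]]),
                    end=int(pos[g[-1]]) + 1,
                    n_cpgs=len(g),
                    mean_level=lvl,
                    score=float(post[g].mean()),
                )
            )
    return out


def _hmrs_by_chrom(hmrs: list[HMR]) -> dict[str, list[tuple[int, int]]]:
    d: dict[str, list[tuple[int, int]]] = {}
    for h in hmrs:
        d.setdefault(h.chrom, []).append(h.interval)
    return d


def _fisher_summary(sa: pd.DataFrame, sb: pd.DataFrame) -> tuple[float, float]:
    """Per-CpG Fisher exact tests at positions covered in both samples."""
    merged = sa.merge(sb, on="pos", suffixes=("_a", "_b"))
    ps = []
    for row in merged.itertuples(index=False):
        table = [
            [row.meth_a, row.total_a - row.meth_a],
            [row.meth_b, row.total_b - row.meth_b],
        ]
        ps.append(fisher_exact(table)[1])
    if not ps:
        return float("nan"), float("nan")
    ps = np.asarray(ps)
    return float(ps.min()), float((ps < 0.05).mean())


def call_dmrs(
    a: Methylome,
    b: Methylome,
    hmrs_a: list[HMR],
    hmrs_b: list[HMR],
    min_cpgs: int = 10,
    min_delta: float = 0.40,
) -> list[DMR]:
    """Call DMRs between two methylomes from their HMR segmentations.

    Candidates are the symmetric difference of the HMR interval sets —
    regions hypo-methylated in exactly one sample. A candidate is emitted
    when it contains at least ``min_cpgs`` CpGs covered in both samples
    (boundary inclusive) and the absolute count-weighted methylation
    difference is at least ``min_delta`` (boundary inclusive). Direction is
    "loss" when a is more methylated than b, "gain" otherwise.
    """
    if not a.same_manifest(b):
        raise ValueError("methylomes are on different genome manifests")
    iva = _hmrs_by_chrom(hmrs_a)
    ivb = _hmrs_by_chrom(hmrs_b)
    out: list[DMR] = []
    for chrom in sorted(set(iva) | set(ivb)):
        cands = iv.symmetric_difference(iva.get(chrom, []), ivb.get(chrom, []))
        for s, e in cands:
            sa = a.region(chrom, s, e)
            sb = b.region(chrom, s, e)
            sa = sa[sa["total"] > 0]
            sb = sb[sb["total"] > 0]
            shared = np.intersect1d(sa["pos"].to_numpy(), sb["pos"].to_numpy())
            if len(shared) < min_cpgs:
                continue
            ta, tb = int(sa["total"].sum()), int(sb["total"].sum())
            if ta == 0 or tb == 0:
                continue
            delta = float(sa["meth"].sum() / ta - sb["meth"].sum() / tb)
            if abs(delta) < min_delta - 1e-12:
                continue
            min_p, frac_sig = _fisher_summary(sa, sb)
            out.append(
                DMR(
                    chrom=chrom,
                    start=int(s),
                    end=int(e),
                    n_cpgs=int(len(shared)),
                    delta=delta,
                    direction="loss" if delta > 0 else "gain",
                    fisher_min_p=min_p,
                    fisher_frac_sig=frac_sig,
                )
            )
    return out


def dmr_direction_summary(
    dmrs: list[DMR], methylomes: list[Methylome] | None = None
) -> dict:
    """Direction counts plus per-DMR methylation trajectory across samples.

    Returns ``{"counts": {"loss": ..., "gain": ...}, "trajectory": DataFrame}``
    where the trajectory table holds one row per DMR and one column of
    weighted methylation per supplied methylome.
    """
    if not dmrs:
        raise ValueError("no DMRs supplied")
    counts = {
        "loss": sum(1 for d in dmrs if d.direction == "loss"),
        "gain": sum(1 for d in dmrs if d.direction == "gain"),
    }
    rows = {}
    for m in methylomes or []:
        rows[m.sample_name] = [
            weighted_methylation(m, d.chrom, d.start, d.end) for d in dmrs
        ]
    traj = pd.DataFrame(
        rows, index=[f"{d.chrom}:{d.start}-{d.end}" for d in dmrs]
    )
    return {"counts": counts, "trajectory": traj}
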