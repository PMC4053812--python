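"""Beta-binomial emissions, HMM segmentation and DMR calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import betabinom

from methylodyn import (
    SegmentationModel,
    SimulationSpec,
    betabin_logpmf,
    call_dmrs,
    call_hmrs,
    default_model,
    dmr_direction_summary,
    fit_segmentation,
    posterior_hypo,
    simulate_methylome,
)
from methylodyn.hmr_dmr import DMR, HMR

from conftest import make_methylome


class TestBetaBinomial:
    def test_zero_trials_is_certain(self):
        assert betabin_logpmf(0, 0, 2.0, 3.0) == 0.0

    def test_uniform_case(self):
        # alpha = beta = 1 makes every k in 0..n equally likely
        assert betabin_logpmf(2, 4, 1.0, 1.0) == pytest.approx(np.log(1 / 5))

    def test_against_scipy_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            a, b = rng.uniform(0.1, 20, size=2)
            assert betabin_logpmf(k, n, a, b) == pytest.approx(
                betabinom.logpmf(k, n, a, b), abs=1e-10
            )

    def test_against_integration_oracle(self):
        # brute-force: integrate Binomial(k; n, p) over Beta(p; a, b)
        from scipy.integrate import quad
        from scipy.stats import beta as beta_dist, binom

        k, n, a, b = 3, 10, 2.0, 5.0
        val, _ = quad(
            lambda p: binom.pmf(k, n, p) * beta_dist.pdf(p, a, b), 0, 1
        )
        assert betabin_logpmf(k, n, a, b) == pytest.approx(np.log(val), abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            betabin_logpmf(5, 4, 1.0, 1.0)
        with pytest.raises(ValueError):
            betabin_logpmf(1, 4, -1.0, 1.0)

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(0, 60))
            a, b = rng.uniform(0.05, 50, size=2)
            total = np.exp(betabin_logpmf(np.arange(n + 1), n, a, b)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)


def _enumeration_posteriors(k, n, model):
    """Exhaustive oracle: per-site posterior of state 0 over all 2^T paths."""
    T = len(k)
    logB = np.array(
        [
            [betabin_logpmf(k[t], n[t], model.alpha[s], model.beta[s]) for s in (0, 1)]
            for t in range(T)
        ]
    )
    log_trans = np.log(model.trans)
    log_start = np.log(model.start)
    weights = np.zeros(T)
    total = 0.0
    joint = []
    for path in itertools.product((0, 1), repeat=T):
        lp = log_start[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += log_trans[path[t - 1], path[t]] + logB[t, path[t]]
        joint.append((path, lp))
    mx = max(lp for _, lp in joint)
    z = sum(np.exp(lp - mx) for _, lp in joint)
    post = np.zeros(T)
    for path, lp in joint:
        w = np.exp(lp - mx) / z
        for t in range(T):
            if path[t] == 0:
                post[t] += w
    return post


class TestSegmentation:
    def test_posterior_matches_path_enumeration(self):
        rng = np.random.default_rng(7)
        model = default_model()
        for T in (1, 2, 5, 12):
            n = rng.poisson(10, T) + 1
            k = rng.binomial(n, rng.uniform(0, 1, T))
            m = make_methylome(
                [("chr1", int(50 * t), int(k[t]), int(n[t])) for t in range(T)]
            )
            post = posterior_hypo(m, model)
            oracle = _enumeration_posteriors(k, n, model)
            np.testing.assert_allclose(post, oracle, atol=1e-9)

    def test_em_loglik_nondecreasing_and_deterministic(self):
        m, _ = simulate_methylome(
            SimulationSpec(seed=4, genome_length=150_000, n_hmrs=5,
                           hmr_cpg_range=(15, 25))
        )
        fit1 = fit_segmentation(m, max_iter=40)
        fit2 = fit_segmentation(m, max_iter=40)
        ll = np.array(fit1.log_likelihoods)
        assert np.all(np.diff(ll) >= -1e-6)
        assert fit1.log_likelihoods == fit2.log_likelihoods
        np.testing.assert_array_equal(fit1.model.alpha, fit2.model.alpha)

    def test_parameter_recovery_on_planted_landscape(self):
        spec = SimulationSpec(seed=2, genome_length=650_000, cpg_density=8,
                              n_hmrs=10, hmr_cpg_range=(30, 30))
        m, _ = simulate_methylome(spec)
        assert len(m) >= 4500
        fit = fit_segmentation(m)
        means = fit.model.emission_means
        assert means[0] == pytest.approx(spec.hypo_level, abs=0.05)
        assert means[1] == pytest.approx(spec.hyper_level, abs=0.05)

    def test_single_state_data_concentrates(self):
        # all-hyper data: the hypo state receives (almost) no stationary mass
        spec = SimulationSpec(seed=9, genome_length=200_000, n_hmrs=0)
        m, _ = simulate_methylome(spec)
        fit = fit_segmentation(m)
        post = posterior_hypo(m, fit.model)
        assert (post > 0.5).mean() <= 0.01

    def test_zero_coverage_everywhere_raises(self):
        m = make_methylome([("chr1", i * 10, 0, 0) for i in range(60)])
        with pytest.raises(ValueError, match="no covered"):
            fit_segmentation(m)


class TestCallHmrs:
    def test_fully_methylated_yields_none(self):
        spec = SimulationSpec(seed=1, genome_length=100_000, n_hmrs=0,
                              hyper_level=1.0, betabin_dispersion=np.inf)
        m, _ = simulate_methylome(spec)
        hmrs = call_hmrs(m, default_model())
        assert hmrs == []

    def test_fully_unmethylated_yields_one_per_desert_block(self):
        sites = [("chr1", p, 0, 10) for p in range(0, 500, 50)]
        sites += [("chr1", p, 0, 10) for p in range(5000, 5500, 50)]  # desert gap
        m = make_methylome(sites)
        hmrs = call_hmrs(m, default_model(desert_size=1000))
        assert len(hmrs) == 2
        assert all(h.n_cpgs == 10 for h in hmrs)

    def test_planted_blocks_recovered(self):
        spec = SimulationSpec(seed=2, genome_length=650_000, cpg_density=8,
                              n_hmrs=10, hmr_cpg_range=(30, 30))
        m, truth = simulate_methylome(spec)
        fit = fit_segmentation(m)
        hmrs = call_hmrs(m, fit.model)
        # CpG-level F1
        pos = m.sites["pos"].to_numpy()
        truth_mask = np.zeros(len(pos), bool)
        for r in truth.itertuples(index=False):
            truth_mask[r.cpg_start : r.cpg_end] = True
        call_mask = np.zeros(len(pos), bool)
        for h in hmrs:
            lo, hi = np.searchsorted(pos, [h.start, h.end])
            call_mask[lo:hi] = True
        tp = (truth_mask & call_mask).sum()
        f1 = 2 * tp / (truth_mask.sum() + call_mask.sum())
        assert f1 >= 0.9
        # every planted block matched with boundary error <= 2 CpGs
        for r in truth.itertuples(index=False):
            best = None
            for h in hmrs:
                if h.start < r.end and h.end > r.start:
                    lo_err = abs(np.searchsorted(pos, h.start) - r.cpg_start)
                    hi_err = abs(np.searchsorted(pos, h.end) - r.cpg_end)
                    best = max(lo_err, hi_err) if best is None else min(best, max(lo_err, hi_err))
            assert best is not None and best <= 2


def _pair_with_planted_dmr(n_cpgs, level_a, level_b, coverage=20):
    """Two methylomes with exact per-site counts differing on one interval."""
    sites_a, sites_b = [], []
    for i in range(60):
        pos = i * 50
        in_dmr = 20 <= i < 20 + n_cpgs
        la = level_a if in_dmr else 0.9
        lb = level_b if in_dmr else 0.9
        sites_a.append(("chr1", pos, int(round(la * coverage)), coverage))
        sites_b.append(("chr1", pos, int(round(lb * coverage)), coverage))
    manifest = {"chr1": 4000}
    return (
        make_methylome(sites_a, "a", manifest),
        make_methylome(sites_b, "b", manifest),
    )


def _hmr(chrom, start, end, n):
    return HMR(chrom, start, end, n, 0.1, 0.99)


class TestCallDmrs:
    def test_identical_methylomes_yield_none(self):
        a, b = _pair_with_planted_dmr(12, 0.9, 0.9)
        hmrs = [_hmr("chr1", 1000, 1600, 12)]
        assert call_dmrs(a, b, hmrs, hmrs) == []
        assert call_dmrs(a, b, [], []) == []

    def test_planted_dmr_called_with_direction(self):
        a, b = _pair_with_planted_dmr(12, 0.9, 0.3)
        # interval hypo in b only: CpG indices 20..31 -> bp 1000..1551
        hmrs_b = [_hmr("chr1", 1000, 1551, 12)]
        dmrs = call_dmrs(a, b, [], hmrs_b)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "loss"
        assert d.n_cpgs == 12
        assert d.delta == pytest.approx(0.6)

    @pytest.mark.parametrize(
        "n_cpgs,level_b,accepted",
        [
            (9, 0.30, False),   # enough delta, one CpG short
            (12, 0.501, False), # enough CpGs, delta 0.399 short
            (10, 0.50, True),   # both boundaries exactly met
        ],
    )
    def test_filter_boundaries_exact(self, n_cpgs, level_b, accepted):
        a, b = _pair_with_planted_dmr(n_cpgs, 0.9, level_b, coverage=1000)
        end = 1000 + (n_cpgs - 1) * 50 + 1
        hmrs_b = [_hmr("chr1", 1000, end, n_cpgs)]
        dmrs = call_dmrs(a, b, [], hmrs_b)
        assert (len(dmrs) == 1) is accepted

    def test_symmetry_under_argument_swap(self):
        a, b = _pair_with_planted_dmr(12, 0.9, 0.3)
        hmrs_b = [_hmr("chr1", 1000, 1551, 12)]
        fwd = call_dmrs(a, b, [], hmrs_b)
        rev = call_dmrs(b, a, hmrs_b, [])
        assert [(d.chrom, d.start, d.end) for d in fwd] == [
            (d.chrom, d.start, d.end) for d in rev
        ]
        assert fwd[0].delta == pytest.approx(-rev[0].delta)
        assert {fwd[0].direction, rev[0].direction} == {"loss", "gain"}

    def test_mismatched_manifests_rejected(self):
        a, _ = _pair_with_planted_dmr(12, 0.9, 0.3)
        c = make_methylome([("chr1", 0, 1, 2)], "c", {"chr1": 99})
        with pytest.raises(ValueError, match="manifest"):
            call_dmrs(a, c, [], [])


class TestDirectionSummary:
    def test_counts_and_trajectory(self):
        a, b = _pair_with_planted_dmr(12, 0.9, 0.3)
        dmrs = [
            DMR("chr1", 1000, 1551, 12, 0.6, "loss"),
            DMR("chr1", 2000, 2100, 10, -0.5, "gain"),
        ]
        res = dmr_direction_summary(dmrs, [a, b])
        assert res["counts"] == {"loss": 1, "gain": 1}
        assert res["trajectory"].shape == (2, 2)
        # the loss DMR sits at 0.9 in a and 0.3 in b
        assert res["trajectory"].iloc[0]["a"] == pytest.approx(0.9)
        assert res["trajectory"].iloc[0]["b"] == pytest.approx(0.3)

    def test_single_gain(self):
        res = dmr_direction_summary([DMR("chr1", 0, 10, 10, -0.5, "gain")])
        assert res["counts"] == {"loss": 0, "gain": 1}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dmr_direction_summary([])
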