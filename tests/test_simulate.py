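"""Planted-truth generators: determinism, bookkeeping and derived moments."""

import numpy as np
import pandas as pd
import pytest

from methylodyn import (
    SimulationSpec,
    pattern_fractions,
    simulate_4c_track,
    simulate_annotations,
    simulate_differentiation_pair,
    simulate_expression,
    simulate_methylome,
    simulate_read_patterns,
    weighted_methylation,
    write_methcounts,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"genome_length": 0},
            {"coverage_mean": -1},
            {"hypo_level": 0.9, "hyper_level": 0.5},
            {"dmr_delta": 0.0},
            {"global_loss": 1.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationSpec(**kwargs).validate()


class TestSimulateMethylome:
    def test_determinism(self, tmp_path):
        spec = SimulationSpec(seed=7, genome_length=100_000, n_hmrs=3)
        m1, t1 = simulate_methylome(spec)
        m2, t2 = simulate_methylome(spec)
        pd.testing.assert_frame_equal(m1.sites, m2.sites)
        pd.testing.assert_frame_equal(t1, t2)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_methcounts(m1, p1)
        write_methcounts(m2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_degenerate_emission_fully_methylated(self):
        spec = SimulationSpec(seed=1, genome_length=50_000, n_hmrs=0,
                              hyper_level=1.0, betabin_dispersion=np.inf)
        m, truth = simulate_methylome(spec)
        assert len(truth) == 0
        covered = m.sites[m.sites["total"] > 0]
        assert (covered["meth"] == covered["total"]).all()

    def test_positions_strictly_increasing(self):
        m, _ = simulate_methylome(SimulationSpec(seed=3, genome_length=80_000, n_hmrs=2))
        assert (np.diff(m.sites["pos"].to_numpy()) > 0).all()

    def test_mixture_mean_matches_planted_fractions(self):
        # genome-wide weighted methylation ~ hypo_frac*hypo + (1-f)*hyper
        spec = SimulationSpec(seed=2, genome_length=650_000, cpg_density=8,
                              n_hmrs=10, hmr_cpg_range=(30, 30),
                              hypo_level=0.1, hyper_level=0.85)
        m, truth = simulate_methylome(spec)
        assert len(m) >= 4500
        frac_hypo = truth["n_cpgs"].sum() / len(m)
        expected = frac_hypo * 0.1 + (1 - frac_hypo) * 0.85
        assert weighted_methylation(m) == pytest.approx(expected, abs=0.02)

    def test_invalid_spec_raises(self):
        with pytest.raises(ValueError):
            simulate_methylome(SimulationSpec(genome_length=-5))


class TestDifferentiationPair:
    def test_null_pair_is_exchangeable(self):
        from scipy.stats import mannwhitneyu

        spec = SimulationSpec(seed=5, genome_length=300_000, n_hmrs=5,
                              n_hypo_dmrs=0, n_hyper_dmrs=0, global_loss=0.0)
        a, b, truth = simulate_differentiation_pair(spec)
        assert len(truth) == 0
        la, lb = a.levels, b.levels
        ok = ~(np.isnan(la) | np.isnan(lb))
        assert mannwhitneyu(la[ok], lb[ok]).pvalue > 0.01

    def test_truth_bookkeeping(self):
        spec = SimulationSpec(seed=6, genome_length=1_500_000,
                              n_hypo_dmrs=43, n_hyper_dmrs=7)
        _, _, truth = simulate_differentiation_pair(spec)
        assert len(truth) == 50
        assert (truth["direction"] == "loss").sum() == 43
        assert (truth["direction"] == "gain").sum() == 7

    def test_global_loss_recovered_from_counts(self):
        spec = SimulationSpec(seed=8, genome_length=800_000, n_hmrs=20,
                              n_hypo_dmrs=0, n_hyper_dmrs=0, global_loss=0.04)
        stem, villus, _ = simulate_differentiation_pair(spec)
        wm_stem = weighted_methylation(stem)
        wm_villus = weighted_methylation(villus)
        assert wm_stem == pytest.approx(0.78, abs=0.01)
        assert wm_villus == pytest.approx(wm_stem - 0.04, abs=0.01)

    def test_planted_deltas_present_in_counts(self):
        spec = SimulationSpec(seed=9, genome_length=1_500_000)
        stem, villus, truth = simulate_differentiation_pair(spec)
        for r in truth.itertuples(index=False):
            da = weighted_methylation(stem, r.chrom, r.start, r.end)
            db = weighted_methylation(villus, r.chrom, r.start, r.end)
            assert (da - db) == pytest.approx(r.delta, abs=0.15)

    def test_noise_floor_warning(self, caplog):
        spec = SimulationSpec(seed=1, genome_length=400_000, dmr_delta=0.05,
                              coverage_mean=10, n_hypo_dmrs=1, n_hyper_dmrs=0)
        with caplog.at_level("WARNING"):
            simulate_differentiation_pair(spec)
        assert any("noise floor" in r.message for r in caplog.records)


class TestReadPatterns:
    def _uniform_methylome(self, level, n=50):
        from conftest import make_methylome

        cov = 1000
        return make_methylome(
            [("chr1", i * 40, int(level * cov), cov) for i in range(n)]
        )

    def test_rho_one_full_methylation(self):
        m = self._uniform_methylome(1.0)
        r = simulate_read_patterns(m, rho=1.0, n_reads=500, seed=0)
        res = pattern_fractions(r)
        assert res["by_class"][3] == 1.0

    def test_rho_one_only_extreme_patterns(self):
        m = self._uniform_methylome(0.6)
        r = simulate_read_patterns(m, rho=1.0, n_reads=2000, seed=1)
        res = pattern_fractions(r)
        assert res["by_class"][1] == 0.0
        assert res["by_class"][2] == 0.0

    def test_rho_zero_independence_product(self):
        level = 0.7
        m = self._uniform_methylome(level)
        n_reads = 20_000
        r = simulate_read_patterns(m, rho=0.0, n_reads=n_reads, seed=2)
        frac = pattern_fractions(r)["by_class"][3]
        p = level**3
        se = np.sqrt(p * (1 - p) / n_reads)
        assert frac == pytest.approx(p, abs=3 * se)

    def test_empty_and_errors(self):
        m = self._uniform_methylome(0.5, n=5)
        assert len(simulate_read_patterns(m, 0.5, 0, seed=0)) == 0
        with pytest.raises(ValueError):
            simulate_read_patterns(m, 1.5, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_read_patterns(self._uniform_methylome(0.5, n=2), 0.5, 10, 0)


class TestFourCTrack:
    def test_blind_fraction_zero(self):
        track, _ = simulate_4c_track(100, blind_fraction=0.0, seed=0)
        assert (track.fragments["klass"] == "regular").all()

    def test_planted_peak_attains_max_mean(self):
        track, truth = simulate_4c_track(
            500, blind_fraction=0.0, background_scale=5.0,
            peaks=[(250_000, 20, 10.0)], seed=3,
        )
        counts = track.fragments["count"].to_numpy(float)
        s, e = int(truth.frag_start[0]), int(truth.frag_end[0])
        peak_mean = counts[s:e].mean()
        # compare against every other window of the same width
        best_other = max(
            counts[i : i + 20].mean()
            for i in range(0, len(counts) - 20)
            if i + 20 <= s or i >= e
        )
        assert peak_mean > best_other

    def test_undetectable_peak_warns(self, caplog):
        with caplog.at_level("WARNING"):
            simulate_4c_track(100, peaks=[(50_000, 5, 0.5)], seed=0)
        assert any("undetectable" in r.message for r in caplog.records)

    def test_positions_increasing_and_deterministic(self):
        t1, _ = simulate_4c_track(200, seed=11)
        t2, _ = simulate_4c_track(200, seed=11)
        pd.testing.assert_frame_equal(t1.fragments, t2.fragments)
        assert (np.diff(t1.fragments["pos"].to_numpy()) > 0).all()


class TestExpression:
    @pytest.fixture
    def genes(self):
        g, _, _ = simulate_annotations(n_genes=200, genome_length=10_000_000,
                                       seed=0)
        return g

    def test_null_false_positive_rate_matches_gaussian_tail(self, genes):
        from scipy.stats import norm

        sigma, n = 0.4, 3
        expr, groups, _ = simulate_expression(genes, 0, 0, sigma=sigma,
                                              n_replicates=n, seed=4)
        from methylodyn import de_genes

        res = de_genes(expr, groups["A"], groups["B"], fold_log2=1.0, mode="fold")
        # difference of two means of n replicates: sd = sigma*sqrt(2/n)
        p_fp = 2 * norm.sf(1.0 / (sigma * np.sqrt(2 / n)))
        expected = p_fp * len(genes)
        se = np.sqrt(len(genes) * p_fp * (1 - p_fp))
        assert abs(res["de"].sum() - expected) <= max(3 * se, 3)

    def test_strong_effect_fully_recovered(self, genes):
        from methylodyn import de_genes

        expr, groups, truth = simulate_expression(
            genes, n_up=10, n_down=10, log2fc=3.0, sigma=0.1, n_replicates=3,
            seed=5,
        )
        res = de_genes(expr, groups["A"], groups["B"], fold_log2=1.0, mode="fold")
        planted = truth.loc[truth["label"] != "null", "gene_id"]
        assert res.loc[planted, "de"].all()

    def test_zero_noise_exact_fold_change(self, genes):
        from methylodyn import de_genes

        expr, groups, truth = simulate_expression(
            genes, n_up=1, n_down=0, log2fc=2.5, sigma=0.0, n_replicates=2,
            seed=6,
        )
        gene = truth.loc[truth["label"] == "up", "gene_id"].iloc[0]
        res = de_genes(expr, groups["A"], groups["B"])
        assert res.loc[gene, "log2fc"] == pytest.approx(2.5, abs=1e-12)

    def test_replicate_floor(self, genes):
        with pytest.raises(ValueError):
            simulate_expression(genes, n_replicates=1, seed=0)


class TestAnnotations:
    def test_intron_arithmetic(self):
        genes, _, _ = simulate_annotations(n_genes=10, exons_per_gene=3,
                                           genome_length=1_000_000, seed=0)
        n_introns = sum(len(genes.introns(g)) for g in genes.gene_ids)
        assert n_introns == 20

    def test_peak_tss_distance_constraint(self):
        genes, _, peaks = simulate_annotations(
            n_genes=10, genome_length=2_000_000, n_tf_peaks=15,
            min_tss_distance=5000, seed=1,
        )
        tss = genes.df["tss"].to_numpy()
        for s in peaks["summit"]:
            assert np.abs(tss - s).min() >= 5000

    def test_determinism(self):
        a = simulate_annotations(n_genes=8, genome_length=500_000,
                                 n_tf_peaks=4, seed=9)
        b = simulate_annotations(n_genes=8, genome_length=500_000,
                                 n_tf_peaks=4, seed=9)
        pd.testing.assert_frame_equal(a[0].df, b[0].df)
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_too_many_features_rejected(self):
        with pytest.raises(ValueError, match="exceed genome"):
            simulate_annotations(n_genes=100, gene_length=50_000,
                                 genome_length=100_000, seed=0)
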