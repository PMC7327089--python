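"""Synthetic cohort generator: count model, truth assignment, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

from aeipipe import SimulationConfig, simulate_cohort, write_cohort
from aeipipe.simulate import assign_gene_truth, draw_allele_counts, _zero_truncated_poisson
from aeipipe.exceptions import ValidationError
from aeipipe import analyze_cohort
from aeipipe.io import read_counts, read_table


class TestDrawAlleleCounts:
    def test_binomial_limit_moments(self):
        rng = np.random.default_rng(0)
        n, draws = 50, 100_000
        major, minor = draw_allele_counts(
            np.full(draws, 0.5), np.full(draws, n), 0.0, rng
        )
        assert np.all(major + minor == n)
        se = math.sqrt(n * 0.25 / draws)
        assert abs(major.mean() - n / 2) < 3 * se

    def test_overdispersion_inflates_variance(self):
        # Var = n theta (1-theta) (1 + (n-1) rho) for the beta-binomial.
        rng = np.random.default_rng(1)
        n, rho, draws = 50, 0.05, 100_000
        major, _ = draw_allele_counts(np.full(draws, 0.5), np.full(draws, n), rho, rng)
        expected = n * 0.25 * (1 + (n - 1) * rho)
        # SE of a sample variance ~ sqrt(2/draws) * Var for near-normal counts
        assert abs(major.var() - expected) < 3 * expected * math.sqrt(2 / draws)
        assert major.var() > n * 0.25  # strictly above the binomial variance

    def test_variance_monotone_in_rho_mean_preserved(self):
        rng = np.random.default_rng(2)
        draws, n = 100_000, 40
        variances, means = [], []
        for rho in (0.0, 0.02, 0.05, 0.1):
            major, _ = draw_allele_counts(np.full(draws, 0.6), np.full(draws, n), rho, rng)
            variances.append(major.var())
            means.append(major.mean())
        assert all(a < b for a, b in zip(variances, variances[1:]))
        se = math.sqrt(n * 0.24 * (1 + 39 * 0.1) / draws)
        assert all(abs(m - n * 0.6) < 4 * se for m in means)

    def test_rho_zero_is_exactly_binomial(self):
        # chi-square goodness of fit against Binomial(20, 0.5) masses
        rng = np.random.default_rng(3)
        n, draws = 20, 100_000
        major, _ = draw_allele_counts(np.full(draws, 0.5), np.full(draws, n), 0.0, rng)
        observed = np.bincount(major, minlength=n + 1)
        expected = stats.binom.pmf(np.arange(n + 1), n, 0.5) * draws
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.001

    def test_seed_reproducibility(self):
        a = draw_allele_counts(0.7, 30, 0.05, np.random.default_rng(5))
        b = draw_allele_counts(0.7, 30, 0.05, np.random.default_rng(5))
        assert a == b

    @pytest.mark.parametrize("theta,rho,depth", [(0.0, 0.1, 10), (1.0, 0.1, 10), (0.5, 1.0, 10), (0.5, 0.1, 0)])
    def test_parameter_errors(self, theta, rho, depth):
        with pytest.raises(ValidationError):
            draw_allele_counts(theta, depth, rho, np.random.default_rng(0))


class TestGeneTruth:
    def test_marginal_aei_fraction(self):
        config = SimulationConfig(
            n_genes=10_000, alpha_aei=float(logit(0.3)), beta_cons=0.0, beta_nonsyn=0.0
        )
        truth = assign_gene_truth(config, np.random.default_rng(7))
        se = math.sqrt(0.3 * 0.7 / 10_000)
        assert abs(truth["is_aei_truth"].mean() - 0.3) < 3 * se

    def test_minus_infinity_intercept_gives_no_aei(self):
        config = SimulationConfig(n_genes=500, alpha_aei=-np.inf, beta_cons=0.0, beta_nonsyn=0.0)
        truth = assign_gene_truth(config, np.random.default_rng(8))
        assert not truth["is_aei_truth"].any()
        assert (truth["theta"] == 0.5).all()

    def test_conserved_genes_less_often_aei(self):
        config = SimulationConfig(n_genes=10_000, alpha_aei=0.0, beta_cons=-4.0, beta_nonsyn=0.0)
        truth = assign_gene_truth(config, np.random.default_rng(9))
        lo = truth.loc[truth["conservation"] < 0.2, "is_aei_truth"].mean()
        hi = truth.loc[truth["conservation"] > 0.8, "is_aei_truth"].mean()
        assert hi < lo

    def test_theta_half_iff_not_aei(self):
        truth = assign_gene_truth(SimulationConfig(n_genes=2000), np.random.default_rng(10))
        aei = truth["is_aei_truth"]
        assert (truth.loc[~aei, "theta"] == 0.5).all()
        assert (truth.loc[aei, "theta"].between(0.65, 0.90)).all()
        assert (truth.loc[aei, "theta"] != 0.5).all()

    def test_dnds_tracks_conservation(self):
        truth = assign_gene_truth(SimulationConfig(n_genes=5000), np.random.default_rng(11))
        r = stats.pearsonr(truth["conservation"], np.log(truth["dnds"]))[0]
        assert r < -0.8


class TestZeroTruncatedPoisson:
    def test_truncated_mean_matches_request(self):
        k = _zero_truncated_poisson(1.2, 100_000, np.random.default_rng(12))
        assert k.min() >= 1
        assert 1.15 < k.mean() < 1.25

    def test_degenerate_mean_one(self):
        k = _zero_truncated_poisson(1.0, 100, np.random.default_rng(13))
        assert (k == 1).all()


class TestSimulateCohort:
    def test_determinism(self):
        config = SimulationConfig(n_pairs=10, n_genes=100, seed=7, frac_dna_bias=0.1)
        a, b = simulate_cohort(config), simulate_cohort(config)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.dna_counts, b.dna_counts)

    def test_mean_snps_per_gene_under_one_point_five(self):
        cohort = simulate_cohort(SimulationConfig(n_pairs=1, n_genes=10_000, seed=1))
        per_gene = cohort.snp_annotation.groupby("gene_id")["snp_id"].size()
        assert 1.0 < per_gene.mean() < 1.5

    def test_paired_structure_and_count_conservation(self, small_cohort):
        counts = small_cohort.counts
        per_patient = counts.groupby("patient_id")["tissue"].nunique()
        assert (per_patient == 2).all()
        assert (counts["ref_count"] + counts["alt_count"] >= 1).all()
        # identical SNP layout in both tissues
        by_tissue = counts.groupby("tissue")["snp_id"].nunique()
        assert by_tissue["tumor"] == by_tissue["adjacent"]

    def test_artifact_sites_flagged_and_filterable(self):
        cohort = simulate_cohort(
            SimulationConfig(n_pairs=2, n_genes=200, seed=3, frac_artifact=0.2)
        )
        ann = cohort.snp_annotation
        assert (ann["known_variant"] == 0).sum() > 0
        from aeipipe.calling import drop_unknown_variants

        kept = drop_unknown_variants(cohort.counts, ann)
        known_ids = set(ann.loc[ann["known_variant"] == 1, "snp_id"])
        assert set(kept["snp_id"]) <= known_ids

    def test_equal_noise_null_has_no_tissue_difference(self):
        # With rho_tumor = rho_adjacent and no DNA bias the tissues are
        # exchangeable, so the paired proportion test should rarely reject.
        nonsig = 0
        for seed in range(20):
            config = SimulationConfig(
                n_pairs=15, n_genes=200, seed=seed,
                rho_tumor=0.01, rho_adjacent=0.01, frac_dna_bias=0.0,
            )
            cohort = simulate_cohort(config)
            res = analyze_cohort(
                cohort.counts, cohort.snp_annotation, cohort.gene_annotation
            )
            prop = next(r for r in res.report if r.test_name == "aei_proportion_tumor_vs_adjacent")
            nonsig += prop.p_value > 0.05
        assert nonsig >= 16  # >= 80% of replicates


class TestWriteCohort:
    def test_round_trip(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        counts = read_counts(tmp_path / "counts.tsv")
        pd.testing.assert_frame_equal(counts, small_cohort.counts)
        dna = read_counts(tmp_path / "dna_counts.tsv")
        pd.testing.assert_frame_equal(dna, small_cohort.dna_counts)
        ann = read_table(tmp_path / "snp_annotation.tsv")
        pd.testing.assert_frame_equal(ann, small_cohort.snp_annotation)

    def test_empty_cohort_writes_headers(self, tmp_path):
        cohort = simulate_cohort(SimulationConfig(n_pairs=1, n_genes=0, seed=0))
        write_cohort(cohort, tmp_path)
        lines = (tmp_path / "counts.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("sample_id\t")

    def test_dna_file_only_when_present(self, tmp_path):
        no_dna = simulate_cohort(SimulationConfig(n_pairs=2, n_genes=10, seed=0))
        write_cohort(no_dna, tmp_path / "a")
        assert not (tmp_path / "a" / "dna_counts.tsv").exists()
        with_dna = simulate_cohort(
            SimulationConfig(n_pairs=2, n_genes=10, seed=0, include_dna=True)
        )
        write_cohort(with_dna, tmp_path / "b")
        assert (tmp_path / "b" / "dna_counts.tsv").exists()

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SimulationConfig(rho_tumor=1.0)
        with pytest.raises(ValidationError):
            SimulationConfig(theta_lo=0.4)
        with pytest.raises(ValidationError):
            SimulationConfig(theta_lo=0.9, theta_hi=0.8)
        with pytest.raises(ValidationError):
            SimulationConfig(frac_nonsyn=1.5)
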