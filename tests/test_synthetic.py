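"""Generator correctness: exact LD scores, point-normal architectures,
summary-statistic calibration, cohort construction, and item aggregation."""

import numpy as np
import pandas as pd
import pytest

from sfactor import synthetic
from sfactor.synthetic import (
    ParameterError,
    TrueModel,
    aggregate_suicidality,
    aggregate_suicidality_frame,
    simulate_factor_architecture,
    simulate_ld_blocks,
    simulate_ld_panel,
    simulate_sumstats,
    simulate_target_cohort,
)


class TestLDBlocks:
    def test_no_ld_gives_unit_ld_scores(self):
        ld = simulate_ld_blocks(100, 1, 0.0)
        assert np.allclose(ld.ld_score, 1.0)

    def test_two_snp_block_ld_score_is_one_plus_r2(self):
        # 2-SNP AR(1) block at rho=0.5: l_j = 1 + 0.5^2 for both variants
        ld = simulate_ld_blocks(4, 2, 0.5)
        assert np.allclose(ld.ld_score, 1.25)

    def test_ld_scores_match_bruteforce_row_sums(self):
        ld = simulate_ld_blocks(1000, 50, 0.9)
        idx = np.arange(50)
        corr = 0.9 ** np.abs(idx[:, None] - idx[None, :])
        expected = np.tile((corr**2).sum(axis=1), 20)
        assert np.allclose(ld.ld_score, expected)

    def test_ld_score_at_least_one_everywhere(self):
        ld = simulate_ld_panel(4000, seed=3)
        assert (ld.ld_score >= 1.0).all()

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            simulate_ld_blocks(100, 10, 1.0)

    def test_indivisible_blocks_rejected(self):
        with pytest.raises(ParameterError):
            simulate_ld_blocks(105, 10, 0.5)


class TestFactorArchitecture:
    def test_no_causals_when_pi_zero(self):
        m = TrueModel(
            n_snps=1000, loadings=np.zeros(2), residual_h2=np.zeros(2),
            factor_h2=0.0, pi_c=0.0, seed=1,
        )
        betas, bf = simulate_factor_architecture(m)
        assert not betas.any() and not bf.any()

    def test_pure_factor_traits_share_effects(self):
        m = TrueModel(
            n_snps=5000, loadings=np.array([1.0, 1.0]),
            residual_h2=np.zeros(2), factor_h2=0.05, pi_c=0.01, seed=2,
        )
        betas, bf = simulate_factor_architecture(m)
        assert np.array_equal(betas[0], betas[1])
        assert np.allclose(np.sum(bf**2), 0.05)

    def test_causal_count_within_binomial_range(self):
        m = TrueModel(
            n_snps=100_000, loadings=np.array([1.0]), residual_h2=np.array([0.0]),
            factor_h2=0.05, pi_c=0.01, seed=3,
        )
        _, bf = simulate_factor_architecture(m)
        n_causal = np.count_nonzero(bf)
        sd = np.sqrt(100_000 * 0.01 * 0.99)
        assert abs(n_causal - 1000) <= 3 * sd

    def test_unattainable_h2_rejected(self):
        m = TrueModel(
            n_snps=1000, loadings=np.array([1.0]), residual_h2=np.array([0.0]),
            factor_h2=0.05, pi_c=0.0, seed=4,
        )
        with pytest.raises(ParameterError):
            simulate_factor_architecture(m)

    def test_trait_variance_invariant_enforced(self):
        with pytest.raises(ParameterError):
            TrueModel(
                n_snps=100, loadings=np.array([2.0]), residual_h2=np.array([0.9]),
                factor_h2=0.5, pi_c=0.1,
            )


class TestSumstats:
    def test_null_gwas_mean_chi2_near_one(self, ld_free):
        m = TrueModel(
            n_snps=20_000, loadings=np.zeros(2), residual_h2=np.zeros(2),
            factor_h2=0.0, pi_c=0.0, seed=5,
        )
        traits = simulate_sumstats(m, ld_free, 50_000)
        chi2 = traits[0]["Z"].to_numpy() ** 2
        assert abs(chi2.mean() - 1.0) < 3 * np.sqrt(2 / len(chi2))

    def test_null_gws_fraction_calibrated(self, ld_free):
        # with no causal effects, P(chi2 > GWS threshold) <= 5e-8 + MC error
        m = TrueModel(
            n_snps=20_000, loadings=np.zeros(4), residual_h2=np.zeros(4),
            factor_h2=0.0, pi_c=0.0, seed=6,
        )
        traits = simulate_sumstats(m, ld_free, 100_000)
        from scipy import stats

        z_c = stats.norm.isf(2.5e-8)
        n_gws = sum((t["Z"].abs() > z_c).sum() for t in traits)
        assert n_gws == 0  # 8e4 draws x 5e-8 expected ~ 4e-3

    def test_no_overlap_gives_uncorrelated_errors(self, ld_free):
        m = TrueModel(
            n_snps=20_000, loadings=np.zeros(2), residual_h2=np.zeros(2),
            factor_h2=0.0, pi_c=0.0, seed=7,
        )
        traits = simulate_sumstats(m, ld_free, 50_000, overlap_fraction=0.0)
        r = np.corrcoef(traits[0]["Z"], traits[1]["Z"])[0, 1]
        assert abs(r) < 3 / np.sqrt(20_000)

    def test_overlap_induces_error_correlation(self, ld_free):
        m = TrueModel(
            n_snps=20_000, loadings=np.zeros(2), residual_h2=np.zeros(2),
            factor_h2=0.0, pi_c=0.0, seed=8,
        )
        traits = simulate_sumstats(
            m, ld_free, 50_000, overlap_fraction=1.0, pheno_corr=0.4
        )
        r = np.corrcoef(traits[0]["Z"], traits[1]["Z"])[0, 1]
        assert abs(r - 0.4) < 3 / np.sqrt(20_000)

    def test_beta_se_consistent_with_z(self, true_model, ld_panel):
        t = simulate_sumstats(true_model, ld_panel, 100_000)[0]
        assert np.allclose(t["Z"], t["BETA"] / t["SE"])

    def test_seed_determinism(self, true_model, ld_panel):
        a = simulate_sumstats(true_model, ld_panel, 100_000)
        b = simulate_sumstats(true_model, ld_panel, 100_000)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestCohort:
    def test_dosages_within_bounds_and_frequencies_match(self):
        c = simulate_target_cohort(n=256, m=5000, seed=9)
        assert c.dosages.min() >= 0 and c.dosages.max() <= 2
        freq = c.dosages.mean(axis=0) / 2
        maf = c.variants["MAF"].to_numpy()
        se = np.sqrt(maf * (1 - maf) / (2 * 256))
        assert np.mean(np.abs(freq - maf) <= 4 * se) > 0.98

    def test_thresholds_at_minus_inf_endorse_everything(self):
        c = simulate_target_cohort(
            n=50, m=100, thresholds=np.full(4, -np.inf), seed=10
        )
        assert (c.suicidality() == 4).all()

    def test_nan_threshold_rejected(self):
        with pytest.raises(ParameterError):
            simulate_target_cohort(n=10, m=10, thresholds=[0.0, 1.0, np.nan, 1.0])

    def test_missing_items_encoded_as_nan_not_zero(self):
        c = simulate_target_cohort(n=500, m=100, missing_rate=0.2, seed=11)
        assert c.items.isna().to_numpy().mean() > 0.1


class TestAggregation:
    @pytest.mark.parametrize(
        "items, expected",
        [
            (("no", "no", "no", "no"), 0.0),
            (("yes", "yes", "yes", "yes"), 4.0),
            (("yes", "no", "yes", "no"), 2.0),
        ],
    )
    def test_score_counts_endorsed_items(self, items, expected):
        assert aggregate_suicidality(items) == expected

    def test_any_missing_item_gives_missing_score(self):
        assert np.isnan(aggregate_suicidality(("yes", "missing", "yes", "yes")))
        assert np.isnan(aggregate_suicidality((1, 1, None, 0)))

    def test_invalid_item_value_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_suicidality(("yes", "maybe", "no", "no"))

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_suicidality(("yes", "no"))

    def test_exhaustive_enumeration_of_all_16_patterns(self):
        # the score distribution over all yes/no patterns is Binomial(4, 1/2)
        from itertools import product

        counts = np.zeros(5)
        for pattern in product([0, 1], repeat=4):
            counts[int(aggregate_suicidality(pattern))] += 1
        assert np.array_equal(counts, [1, 4, 6, 4, 1])

    def test_frame_aggregation_matches_scalar_path(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 2, size=(200, 4)).astype(float)
        vals[rng.random((200, 4)) < 0.1] = np.nan
        frame = pd.DataFrame(vals, columns=list("abcd"))
        got = aggregate_suicidality_frame(frame)
        want = [aggregate_suicidality(tuple(row)) for row in vals]
        np.testing.assert_array_equal(got.to_numpy(), want)
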