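"""LD-score regression: calibration under the null, recovery under the
generating model, internal consistency of the multivariable covariance
structure, and stratified enrichment."""

import numpy as np
import pandas as pd
import pytest

from sfactor import ldsc, synthetic
from sfactor.synthetic import ParameterError, TrueModel


def _null_model(k=1, m=20_000, seed=0):
    return TrueModel(
        n_snps=m, loadings=np.zeros(k), residual_h2=np.zeros(k),
        factor_h2=0.0, pi_c=0.0, seed=seed,
    )


class TestH2:
    def test_null_h2_and_intercept_calibrated(self, ld_panel):
        traits = synthetic.simulate_sumstats(_null_model(seed=31), ld_panel, 100_000)
        est = ldsc.estimate_h2(traits[0], ld_panel)
        assert abs(est.h2) <= 2 * est.se
        assert abs(est.intercept - 1.0) <= 2 * est.intercept_se

    def test_recovers_generating_h2(self, item_sumstats, ld_panel, true_S):
        # single realization; the 50-replicate coverage experiment lives in
        # the acceptance suite
        for t in range(4):
            est = ldsc.estimate_h2(item_sumstats[t], ld_panel)
            assert est.h2 == pytest.approx(true_S[t, t], abs=3 * est.se)
            assert est.se > 0

    def test_constant_ld_scores_rejected(self, ld_free):
        m = _null_model(seed=32)
        traits = synthetic.simulate_sumstats(m, ld_free, 50_000)
        with pytest.raises(ParameterError, match="singular"):
            ldsc.estimate_h2(traits[0], ld_free)

    def test_block_count_reduced_with_warning_for_small_panels(self):
        ld = synthetic.simulate_ld_panel(200, seed=5)
        m = _null_model(m=200, seed=33)
        traits = synthetic.simulate_sumstats(m, ld, 10_000)
        with pytest.warns(UserWarning, match="blocks"):
            est = ldsc.estimate_h2(traits[0], ld)
        assert est.n_blocks < 200 and est.se > 0

    def test_ldsc_style_chi2_cap_available(self, item_sumstats, ld_panel):
        capped = ldsc.estimate_h2(item_sumstats[0], ld_panel, chi2_max="ldsc")
        assert np.isfinite(capped.h2)


class TestRg:
    def test_trait_against_itself_gives_unit_rg(self, item_sumstats, ld_panel):
        rg = ldsc.estimate_rg(item_sumstats[0], item_sumstats[0], ld_panel)
        assert rg.defined
        assert rg.rg == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_arguments(self, item_sumstats, ld_panel):
        a = ldsc.estimate_rg(item_sumstats[0], item_sumstats[1], ld_panel)
        b = ldsc.estimate_rg(item_sumstats[1], item_sumstats[0], ld_panel)
        assert a.rg == pytest.approx(b.rg, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_shared_factor_traits_strongly_correlated(
        self, item_sumstats, ld_panel, true_S
    ):
        rg = ldsc.estimate_rg(item_sumstats[0], item_sumstats[1], ld_panel)
        truth = true_S[0, 1] / np.sqrt(true_S[0, 0] * true_S[1, 1])
        assert rg.defined
        assert rg.rg == pytest.approx(truth, abs=3 * rg.se)

    def test_independent_architectures_give_null_rg(self, ld_panel):
        one = TrueModel(
            n_snps=20_000, loadings=np.array([1.0]), residual_h2=np.array([0.0]),
            factor_h2=0.05, pi_c=0.01, seed=41,
        )
        other = TrueModel(
            n_snps=20_000, loadings=np.array([1.0]), residual_h2=np.array([0.0]),
            factor_h2=0.05, pi_c=0.01, seed=42,
        )
        s1 = synthetic.simulate_sumstats(one, ld_panel, 100_000)[0]
        s2 = synthetic.simulate_sumstats(other, ld_panel, 100_000)[0]
        rg = ldsc.estimate_rg(s1, s2, ld_panel)
        assert abs(rg.rg) <= 3 * rg.se

    def test_cross_intercept_reflects_sample_overlap(self, true_model, ld_panel):
        traits = synthetic.simulate_sumstats(
            true_model, ld_panel, 100_000, overlap_fraction=1.0, pheno_corr=0.4
        )
        rg = ldsc.estimate_rg(traits[0], traits[1], ld_panel)
        assert rg.cross_intercept > 0.15  # ~0.4 expected under full overlap

    def test_undefined_when_h2_nonpositive(self, ld_panel):
        null = synthetic.simulate_sumstats(_null_model(2, seed=43), ld_panel, 1000)
        rg = ldsc.estimate_rg(null[0], null[1], ld_panel)
        if not rg.defined:
            assert np.isnan(rg.rg)  # flagged, not silently numeric


class TestCovStruct:
    def test_diagonal_matches_univariate_estimates(
        self, item_sumstats, ld_panel, cov_struct
    ):
        for t in range(4):
            est = ldsc.estimate_h2(item_sumstats[t], ld_panel)
            assert cov_struct.S[t, t] == pytest.approx(est.h2, abs=1e-10)
            # V diagonal equals the squared univariate jackknife SE
            q = [0, 2, 5, 9][t]  # diagonal positions in tril order
            assert np.sqrt(cov_struct.V[q, q]) == pytest.approx(est.se, abs=1e-10)

    def test_s_symmetric_and_v_well_formed(self, cov_struct):
        assert np.allclose(cov_struct.S, cov_struct.S.T)
        assert cov_struct.V.shape == (10, 10)
        assert np.allclose(cov_struct.V, cov_struct.V.T)
        assert (np.diag(cov_struct.V) > 0).all()

    def test_converges_to_factor_implied_covariance(self, cov_struct, true_S):
        i, j = np.tril_indices(4)
        se = np.sqrt(np.diag(cov_struct.V))
        assert np.all(np.abs(cov_struct.vech() - true_S[i, j]) <= 3 * se)

    def test_json_round_trip(self, cov_struct):
        back = ldsc.CovStruct.from_json_dict(cov_struct.to_json_dict())
        assert np.allclose(back.S, cov_struct.S)
        assert np.allclose(back.V, cov_struct.V)
        assert back.names == cov_struct.names

    def test_requires_two_traits(self, item_sumstats, ld_panel):
        with pytest.raises(ParameterError):
            ldsc.genetic_covariance([item_sumstats[0]], ld_panel)


@pytest.fixture(scope="module")
def enrichment_setup():
    m = 20_000
    ld = synthetic.simulate_ld_panel(m, seed=99)
    rng = np.random.default_rng(8)
    conserved = np.zeros(m)
    conserved[rng.choice(m, m // 20, replace=False)] = 1
    barren = np.zeros(m)
    barren[rng.choice(np.where(conserved == 0)[0], m // 20, replace=False)] = 1
    lda = synthetic.attach_annotations(
        ld, pd.DataFrame({"conserved": conserved, "barren": barren})
    )
    # 50% of h2 inside the 5% "conserved" annotation, none in "barren"
    h2 = 0.3
    beta = np.zeros(m)
    inside = rng.choice(np.where(conserved == 1)[0], 200, replace=False)
    free = np.where((conserved == 0) & (barren == 0))[0]
    outside = rng.choice(free, 2000, replace=False)
    for idx, share in ((inside, 0.5), (outside, 0.5)):
        beta[idx] = rng.standard_normal(len(idx))
        beta[idx] *= np.sqrt(h2 * share / np.sum(beta[idx] ** 2))
    model = TrueModel(
        n_snps=m, loadings=np.array([1.0]), residual_h2=np.array([0.0]),
        factor_h2=h2, pi_c=0.1, seed=9,
    )
    s = synthetic.simulate_sumstats(model, lda, 100_000, effects=beta[None, :])[0]
    return s, lda


class TestStratified:
    def test_base_annotation_enrichment_exactly_one(self, enrichment_setup):
        s, lda = enrichment_setup
        table = ldsc.stratified_h2(s, lda).table
        base = table.loc[table["annotation"] == "base"].iloc[0]
        assert base["enrichment"] == 1.0

    def test_concentrated_h2_enrichment_near_ten(self, enrichment_setup):
        s, lda = enrichment_setup
        et = ldsc.stratified_h2(s, lda)
        row = et["conserved"]
        assert row["enrichment"] == pytest.approx(10.0, abs=2 * row["se"])
        assert row["p"] < 0.05

    def test_annotation_without_causals_depleted(self, enrichment_setup):
        s, lda = enrichment_setup
        row = ldsc.stratified_h2(s, lda)["barren"]
        assert abs(row["enrichment"]) <= 2 * row["se"]

    def test_total_h2_recovered(self, enrichment_setup):
        s, lda = enrichment_setup
        et = ldsc.stratified_h2(s, lda)
        assert et.h2_total == pytest.approx(0.3, abs=0.1)

    def test_duplicated_annotation_reported_collinear(self, enrichment_setup):
        s, lda = enrichment_setup
        dup = lda.annotations.copy()
        dup["copy"] = dup["conserved"]
        lda_dup = synthetic.attach_annotations(
            synthetic.LDReference(
                table=lda.table, segments=lda.segments
            ),
            dup.drop(columns="base"),
        )
        with pytest.raises(ParameterError, match="collinear"):
            ldsc.stratified_h2(s, lda_dup)

    def test_missing_annotations_rejected(self, enrichment_setup, ld_panel):
        s, _ = enrichment_setup
        with pytest.raises(ParameterError):
            ldsc.stratified_h2(s, ld_panel)
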