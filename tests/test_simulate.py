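"""Genotype/phenotype simulation, association engines and the benchmark."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import overlapmeta as om
import statsmodels.api as sm


class TestGenotypes:
    def test_deterministic_given_seed(self):
        g1, m1 = om.simulate_genotypes(50, 20, rng=123)
        g2, m2 = om.simulate_genotypes(50, 20, rng=123)
        np.testing.assert_array_equal(g1, g2)
        np.testing.assert_array_equal(m1, m2)

    def test_dosage_alphabet(self):
        g, _ = om.simulate_genotypes(200, 50, rng=1)
        assert set(np.unique(g)) <= {0, 1, 2}

    def test_sample_frequency_concentrates(self):
        g, _ = om.simulate_genotypes(100_000, 1, maf_range=(0.5, 0.5), rng=2)
        assert g.mean() / 2 == pytest.approx(0.5, abs=0.01)


class TestOverlappingStudies:
    def test_exact_overlap_counts(self):
        for n_ov in [0, 200, 2000]:
            s1, s2 = om.draw_overlapping_studies(4000 - n_ov, 2000, 2000,
                                                 n_ov, rng=3)
            assert len(s1) == len(s2) == 2000
            assert len(np.intersect1d(s1, s2)) == n_ov

    def test_identical_sets_at_full_overlap(self):
        s1, s2 = om.draw_overlapping_studies(100, 100, 100, 100, rng=4)
        assert set(s1) == set(s2)

    def test_infeasible_sizes(self):
        with pytest.raises(ValueError):
            om.draw_overlapping_studies(100, 80, 80, 10, rng=0)
        with pytest.raises(ValueError):
            om.draw_overlapping_studies(1000, 50, 80, 60, rng=0)


class TestPhenotypes:
    def test_null_unit_variance(self):
        g, mafs = om.simulate_genotypes(2000, 5, rng=5)
        y = om.simulate_phenotype(g, om.NullTrait(), mafs, rng=5)
        assert np.var(y) == pytest.approx(1.0, rel=0.05)

    def test_single_snp_variance_share(self):
        r2 = []
        for seed in range(200):
            g, mafs = om.simulate_genotypes(2000, 1, rng=seed)
            y = om.simulate_phenotype(g, om.SingleSnpTrait(0, 0.01), mafs,
                                      rng=seed + 10_000)
            r2.append(np.corrcoef(g[:, 0], y)[0, 1] ** 2)
        assert np.mean(r2) == pytest.approx(0.01, abs=0.005)

    def test_polygenic_heritability(self):
        # joint regression of the trait on all standardized dosages: the
        # adjusted R^2 estimates the population variance explained, i.e. h2
        n, m, h2 = 2000, 1000, 0.2
        g, mafs = om.simulate_genotypes(n, m, rng=6)
        y = om.simulate_phenotype(g, om.PolygenicTrait(m, h2), mafs, rng=106)
        assert np.var(y) == pytest.approx(1.0, abs=0.1)
        u = (g - 2 * mafs) / np.sqrt(2 * mafs * (1 - mafs))
        x = np.c_[np.ones(n), u]
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(np.sum((y - x @ coef) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        r2_adj = 1 - (rss / (n - m - 1)) / (tss / (n - 1))
        assert r2_adj == pytest.approx(h2, abs=0.05)

    def test_too_many_causal_snps(self):
        g, mafs = om.simulate_genotypes(100, 10, rng=7)
        with pytest.raises(ValueError):
            om.simulate_phenotype(g, om.PolygenicTrait(11, 0.2), mafs, rng=7)


class TestEffectSize:
    def test_maf20_one_percent(self):
        assert om.effect_size_for_h2(0.2, 0.01) == pytest.approx(0.17678,
                                                                 abs=1e-5)

    def test_maf50_one_percent(self):
        assert om.effect_size_for_h2(0.5, 0.01) == pytest.approx(
            np.sqrt(0.02), rel=1e-12
        )

    def test_zero_h2(self):
        assert om.effect_size_for_h2(0.3, 0.0) == 0.0

    def test_degenerate_maf(self):
        with pytest.raises(ValueError):
            om.effect_size_for_h2(0.0, 0.01)


class TestAssociateOLS:
    def test_exact_linear_fit(self):
        g, _ = om.simulate_genotypes(50, 1, rng=8)
        y = 2.0 * g[:, 0].astype(float)
        res = om.associate_ols(g, y)
        assert res["BETA"].iloc[0] == pytest.approx(2.0)
        assert res["P"].iloc[0] <= 1e-280

    def test_matches_statsmodels(self):
        g, mafs = om.simulate_genotypes(300, 3, rng=9)
        y = om.simulate_phenotype(g, om.NullTrait(), mafs, rng=9)
        res = om.associate_ols(g, y)
        for j in range(3):
            fit = sm.OLS(y, sm.add_constant(g[:, j].astype(float))).fit()
            assert res["BETA"].iloc[j] == pytest.approx(fit.params[1],
                                                        rel=1e-10)
            assert res["SE"].iloc[j] == pytest.approx(fit.bse[1], rel=1e-10)
            assert res["P"].iloc[j] == pytest.approx(fit.pvalues[1],
                                                     rel=1e-8)

    def test_null_p_uniform(self):
        g, mafs = om.simulate_genotypes(2000, 500, rng=10)
        y = om.simulate_phenotype(g, om.NullTrait(), mafs, rng=10)
        res = om.associate_ols(g, y)
        ks = stats.kstest(res["P"], "uniform")
        assert ks.pvalue > 0.01

    def test_null_beta_unbiased(self):
        g, mafs = om.simulate_genotypes(500, 2000, rng=11)
        y = om.simulate_phenotype(g, om.NullTrait(), mafs, rng=11)
        res = om.associate_ols(g, y)
        mc_se = res["BETA"].std() / np.sqrt(len(res))
        assert abs(res["BETA"].mean()) < 2 * mc_se + 1e-6

    def test_monomorphic_variant_flagged(self):
        g = np.zeros((100, 2), dtype=np.int8)
        g[:, 1] = np.arange(100) % 3
        y = np.random.default_rng(0).standard_normal(100)
        res = om.associate_ols(g, y)
        assert bool(res["skipped"].iloc[0]) is True
        assert np.isnan(res["BETA"].iloc[0])
        assert bool(res["skipped"].iloc[1]) is False


class TestAssociateMega:
    def test_matches_statsmodels_with_study_covariate(self):
        g, mafs = om.simulate_genotypes(400, 2, rng=12)
        y = om.simulate_phenotype(g, om.NullTrait(), mafs, rng=12)
        labels = np.repeat([0, 1], 200)
        res = om.associate_mega(g, y, labels, dedup=False)
        for j in range(2):
            X = np.c_[np.ones(400), g[:, j].astype(float), labels]
            fit = sm.OLS(y, X).fit()
            assert res["BETA"].iloc[j] == pytest.approx(fit.params[1],
                                                        rel=1e-9)
            assert res["SE"].iloc[j] == pytest.approx(fit.bse[1], rel=1e-9)

    def test_full_duplication_reduces_to_single_study(self):
        g, mafs = om.simulate_genotypes(300, 4, rng=13)
        y = om.simulate_phenotype(g, om.NullTrait(), mafs, rng=13)
        gg = np.vstack([g, g])
        yy = np.concatenate([y, y])
        labels = np.repeat([0, 1], 300)
        ids = np.concatenate([np.arange(300), np.arange(300)])
        res = om.associate_mega(gg, yy, labels, dedup=True, sample_ids=ids)
        single = om.associate_ols(g, y)
        np.testing.assert_allclose(res["BETA"], single["BETA"], rtol=1e-10)
        # one study factor remains, so df differs by 1 from plain OLS
        np.testing.assert_allclose(res["SE"], single["SE"], rtol=2e-3)

    def test_all_overlapping_too_few_distinct(self):
        g = np.ones((4, 1), dtype=np.int8)
        with pytest.raises(ValueError):
            om.associate_mega(g, np.zeros(4), np.array([0, 0, 1, 1]),
                              dedup=True, sample_ids=np.array([1, 2, 1, 2]))


@pytest.fixture(scope="module")
def tiny_result():
    cfg = om.SimConfig(
        n_per_study=300, n_variants=400, overlap_grid=(0.0, 0.25),
        n_repeats=3, alpha=0.01, seed=21, power_alpha=1e-3,
        power_repeats=3, correlation_source="true",
    )
    return cfg, om.run_benchmark(cfg)


class TestBenchmark:
    def test_deterministic(self, tiny_result):
        cfg, res = tiny_result
        res2 = om.run_benchmark(cfg)
        pd.testing.assert_frame_equal(res.rates, res2.rates)
        pd.testing.assert_frame_equal(res.correlations, res2.correlations)

    def test_zero_overlap_corrected_equals_uncorrected(self, tiny_result):
        _, res = tiny_result
        r0 = res.rates[res.rates["overlap"] == 0.0].set_index("method")
        assert r0.loc["beta_corrected", "fpr"] == (
            r0.loc["beta_uncorrected", "fpr"]
        )

    def test_output_shapes_and_ranges(self, tiny_result):
        _, res = tiny_result
        assert set(res.rates["method"]) == set(om.simulate.META_METHODS)
        assert ((res.rates["fpr"] >= res.rates["fpr_lo"] - 1e-12)
                & (res.rates["fpr"] <= res.rates["fpr_hi"] + 1e-12)).all()
        assert res.rates["fpr"].between(0, 1).all()
        assert res.rates["power"].between(0, 1).all()
        assert len(res.correlations) == 2 * 3

    def test_correlation_truth_column(self, tiny_result):
        _, res = tiny_result
        truths = res.correlations.groupby("overlap")["truth"].first()
        assert truths[0.0] == 0.0
        assert truths[0.25] == pytest.approx(0.25)


def test_power_closed_form_matches_normal_theory():
    # ncp = sqrt(N h2 / (1 - h2)); detection prob of |Z| > z_{alpha/2}
    ncp = np.sqrt(4000 * 0.01 / 0.99)
    zc = stats.norm.isf(2.5e-8)
    expect = stats.norm.sf(zc - ncp) + stats.norm.cdf(-zc - ncp)
    assert om.power_closed_form(4000, 0.01, 5e-8) == pytest.approx(expect)
    assert 0.7 < expect < 0.9
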