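"""Meta-analysis estimators: z transforms, weighting, overlap correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import overlapmeta as om

from conftest import make_study


class TestZTransforms:
    def test_p_one_maps_to_zero(self):
        assert om.p_to_z(1.0, 1) == 0.0

    def test_standard_quantile(self):
        assert om.p_to_z(0.05, +1) == pytest.approx(1.95996, abs=1e-5)
        assert om.p_to_z(0.05, -1) == pytest.approx(-1.95996, abs=1e-5)

    def test_z_to_p_values(self):
        assert om.z_to_p(0.0) == 1.0
        assert om.z_to_p(1.95996) == pytest.approx(0.05, rel=1e-4)
        assert om.z_to_p(5.45131) == pytest.approx(5.0e-8, rel=1e-4)

    @given(st.floats(min_value=-280, max_value=-0.0001))
    @settings(deadline=None)
    def test_round_trip_ten_significant_digits(self, log10p):
        p = 10.0**log10p
        assert om.z_to_p(om.p_to_z(p, 1)) == pytest.approx(p, rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            om.p_to_z(0.0, 1)
        with pytest.raises(ValueError):
            om.p_to_z(0.5, 2)
        with pytest.raises(ValueError):
            om.z_to_p(np.inf)


class TestPValueMeta:
    def test_single_study_identity(self):
        z, p = om.meta_p_corrected(np.array([2.5]), np.array([1000.0]),
                                   np.eye(1))
        assert z == pytest.approx(2.5)
        assert p == pytest.approx(om.z_to_p(2.5))

    def test_independent_equal_studies(self):
        z, _ = om.meta_p_corrected(np.array([3.0, 3.0]),
                                   np.array([2000.0, 2000.0]), np.eye(2))
        assert z == pytest.approx(3 / np.sqrt(0.5), rel=1e-12)

    def test_correlated_studies_deflate_z(self):
        omega = np.array([[1.0, 0.5], [0.5, 1.0]])
        z, _ = om.meta_p_corrected(np.array([3.0, 3.0]),
                                   np.array([2000.0, 2000.0]), omega)
        assert z == pytest.approx(3 / np.sqrt(0.75), rel=1e-12)

    def test_uncorrected_stouffer(self):
        z, _ = om.meta_p_uncorrected(np.array([3.0, 3.0]),
                                     np.array([500.0, 500.0]))
        assert z == pytest.approx(6 / np.sqrt(2), rel=1e-12)

    def test_uncorrected_cancellation(self):
        z, p = om.meta_p_uncorrected(np.array([3.0, -3.0]),
                                     np.array([500.0, 500.0]))
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_invalid_omega_rejected(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            om.meta_p_corrected(np.array([1.0, 1.0]),
                                np.array([10.0, 10.0]), bad)


class TestEffectSizeMeta:
    def test_single_study_identity(self):
        b, s, p = om.meta_beta_corrected(np.array([0.4]),
                                         np.array([[0.01]]))
        assert (b, s) == (pytest.approx(0.4), pytest.approx(0.1))

    def test_equal_independent_studies(self):
        b, s, _ = om.meta_beta_uncorrected(np.array([0.5, 0.5]),
                                           np.array([0.1, 0.1]))
        assert b == pytest.approx(0.5)
        assert s == pytest.approx(0.1 / np.sqrt(2), rel=1e-12)

    def test_correlated_studies_inflate_se(self):
        # var = sigma^2 (1 + rho) / 2 for two equal correlated studies
        omega = om.build_covariance_matrices(
            np.array([[1, 0.5], [0.5, 1]]), np.array([0.1, 0.1])
        ).omega_eta
        b, s, _ = om.meta_beta_corrected(np.array([0.5, 0.5]), omega)
        assert b == pytest.approx(0.5)
        assert s == pytest.approx(np.sqrt(0.01 * 1.5 / 2), rel=1e-12)
        assert s == pytest.approx(0.086603, abs=1e-6)

    def test_symmetric_average(self):
        b, _, _ = om.meta_beta_uncorrected(np.array([1.0, 0.0]),
                                           np.array([0.1, 0.1]))
        assert b == pytest.approx(0.5)

    @given(r=st.floats(min_value=0.0, max_value=0.99),
           se2=st.floats(min_value=0.05, max_value=0.3))
    @settings(deadline=None)
    def test_corrected_se_never_below_uncorrected(self, r, se2):
        # positive inter-study correlation inflates the corrected SE as long
        # as r <= 2 s1 s2 / (s1^2 + s2^2); beyond that the generalized
        # least-squares weights exploit the correlation and legitimately beat
        # the naive estimator (equality of SEs makes the bound 1, so the
        # guarantee always holds for equally precise studies)
        s1 = 0.1
        se = np.array([s1, se2])
        if r > 2 * s1 * se2 / (s1**2 + se2**2):
            return
        omega = om.build_covariance_matrices(
            np.array([[1, r], [r, 1]]), se
        ).omega_eta
        _, s_cor, _ = om.meta_beta_corrected(np.array([0.2, 0.3]), omega)
        _, s_unc, _ = om.meta_beta_uncorrected(np.array([0.2, 0.3]), se)
        assert s_cor >= s_unc - 1e-12

    def test_duplicated_study_gains_no_precision(self):
        """Meta-analysing a study with itself at r = cap must not shrink the
        SE below the single-study SE; the naive route halves the variance."""
        se = 0.1
        omega = om.build_covariance_matrices(
            np.array([[1, 0.99], [0.99, 1]]), np.array([se, se])
        ).omega_eta
        _, s_cor, _ = om.meta_beta_corrected(np.array([0.3, 0.3]), omega)
        _, s_unc, _ = om.meta_beta_uncorrected(np.array([0.3, 0.3]),
                                               np.array([se, se]))
        assert s_cor == pytest.approx(se * np.sqrt((1 + 0.99) / 2), rel=1e-9)
        assert s_cor / s_unc >= 1.4


class TestMetaAnalyse:
    def test_zero_correlation_equals_uncorrected(self):
        s1 = make_study("s1", n_variants=50, seed=1)
        s2 = make_study("s2", n_variants=50, seed=2)
        res = om.meta_analyse(om.harmonize([s1, s2]), np.eye(2))
        np.testing.assert_allclose(res["BETA_CORR"], res["BETA_UNCORR"],
                                   rtol=1e-12)
        np.testing.assert_allclose(res["SE_CORR"], res["SE_UNCORR"],
                                   rtol=1e-12)
        # equal n: the two p-route weightings also coincide
        np.testing.assert_allclose(res["Z_CORR"], res["Z_UNCORR"],
                                   rtol=1e-12)

    def test_min_studies_skips_partial_variants(self):
        s1 = make_study("s1", n_variants=10, seed=1)
        s2 = make_study("s2", n_variants=10, seed=2)
        s2 = om.StudySummary("s2", s2.n_total, s2.table.iloc[:5])
        res = om.meta_analyse(om.harmonize([s1, s2]), np.eye(2),
                              min_studies=2)
        assert len(res) == 5
        assert (res["N_STUDIES"] == 2).all()

    def test_p_monotone_in_abs_z(self):
        s1 = make_study("s1", n_variants=100, seed=3)
        s2 = make_study("s2", n_variants=100, seed=4)
        corr = np.array([[1.0, 0.3], [0.3, 1.0]])
        res = om.meta_analyse(om.harmonize([s1, s2]), corr)
        assert len(res) == 100
        order = np.argsort(-np.abs(res["Z_CORR"].to_numpy()))
        p_sorted = res["P_Z_CORR"].to_numpy()[order]
        assert np.all(np.diff(p_sorted) >= -1e-300)

    def test_shared_sign_z_shrinks_under_positive_correlation(self):
        s1 = make_study("s1", n_variants=40, seed=5)
        s2 = om.StudySummary("s2", s1.n_total, s1.table.copy())
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        res = om.meta_analyse(om.harmonize([s1, s2]), corr)
        assert np.all(np.abs(res["Z_CORR"]) <= np.abs(res["Z_UNCORR"]) + 1e-12)


class TestVarianceExplained:
    def test_zero_effect(self):
        assert om.variance_explained(0.0, 0.3) == 0.0

    def test_low_frequency_large_effect(self):
        # x = 2 * 0.013 * 0.987 * 1.134^2 = 0.0330013
        assert om.variance_explained(1.134, 0.013) == pytest.approx(
            0.0330013 / 1.0330013, abs=2e-5
        )

    def test_monotone_in_effect_size(self):
        betas = np.linspace(0.1, 2.0, 20)
        vals = [om.variance_explained(b, 0.1) for b in betas]
        assert np.all(np.diff(vals) > 0)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            om.variance_explained(0.5, 0.0)
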