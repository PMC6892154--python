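"""CFA engine: pooled covariances, ML fitting, fit indices, diagnostics.

Oracles used here are independent of the engine: a brute-force double-loop
pooled covariance, the Spearman closed form for a one-factor triad, plug-in
fit-index arithmetic, and a naive Nelder-Mead minimizer coded directly from
the discrepancy-function definition.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from newsy import (CFAModel, MeasurementModelSpec, SampleMoments,
                   baseline_chi_square, fit_indices, generate_factor_items,
                   pooled_within_covariance, residual_diagnostics, srmr)
from newsy.cfa import CFAError
from newsy.registry import load_builtin_model
from newsy.simulate import implied_item_covariance


def triad_spec(names=("x1", "x2", "x3")):
    return MeasurementModelSpec(items=list(names), factors=["F"],
                                loadings={n: "F" for n in names})


class TestPooledWithinCovariance:
    def test_single_cluster_reduces_to_sample_covariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        mom = pooled_within_covariance(df, np.zeros(30))
        np.testing.assert_allclose(mom.S, np.cov(df.T, ddof=1))
        assert mom.n_effective == 29

    def test_mean_shift_between_clusters_has_no_effect(self, rng):
        base = rng.normal(size=(10, 3))
        df = pd.DataFrame(np.vstack([base, base + 7.5]), columns=list("abc"))
        cl = np.repeat([0, 1], 10)
        mom = pooled_within_covariance(df, cl)
        within = np.cov(base.T, ddof=1)
        # both clusters share the same within covariance; divisor (N-G) pools
        np.testing.assert_allclose(mom.S, within * 18 / 18, atol=1e-12)
        assert mom.n_effective == 18

    def test_matches_brute_force_double_loop(self):
        data = pd.DataFrame({
            "x": [1.0, 2.0, 4.0, 0.0, 3.0, 5.0],
            "y": [2.0, 1.0, 3.0, 5.0, 4.0, 6.0]})
        cl = np.array([0, 0, 0, 1, 1, 1])
        acc = np.zeros((2, 2))
        for g in (0, 1):
            Y = data.to_numpy()[cl == g]
            for row in Y - Y.mean(axis=0):
                acc += np.outer(row, row)
        expected = acc / (6 - 2)
        mom = pooled_within_covariance(data, cl)
        np.testing.assert_allclose(mom.S, expected)
        assert mom.n_effective == 4

    def test_singletons_dropped_and_counted(self, rng):
        df = pd.DataFrame(rng.normal(size=(7, 2)), columns=["a", "b"])
        cl = np.array([0, 0, 0, 1, 2, 2, 2])
        mom = pooled_within_covariance(df, cl)
        assert mom.n_dropped_singletons == 1
        assert mom.n_effective == 6 - 2

    def test_all_singletons_error(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 2)), columns=["a", "b"])
        with pytest.raises(CFAError, match="singleton"):
            pooled_within_covariance(df, np.arange(3))


class TestTriadClosedForm:
    """One-factor, three-item model: lambda_1 = sqrt(r12*r13/r23) etc."""

    def test_known_correlations(self):
        S = np.array([[1.0, 0.72, 0.63], [0.72, 1.0, 0.56], [0.63, 0.56, 1.0]])
        res = CFAModel(SampleMoments(S, 499, ["x1", "x2", "x3"]), triad_spec()).fit()
        np.testing.assert_allclose(res.standardized_loadings.to_numpy(),
                                   [0.9, 0.8, 0.7], atol=1e-6)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)   # just-identified
        assert res.df == 0
        np.testing.assert_allclose(res.Sigma, S, atol=1e-6)

    def test_random_triads(self, rng):
        lam = rng.uniform(0.4, 0.95, 3)
        S = np.outer(lam, lam)
        np.fill_diagonal(S, 1.0)
        res = CFAModel(SampleMoments(S, 199, ["a", "b", "c"]),
                       triad_spec("abc")).fit()
        closed = np.array([
            np.sqrt(S[0, 1] * S[0, 2] / S[1, 2]),
            np.sqrt(S[0, 1] * S[1, 2] / S[0, 2]),
            np.sqrt(S[0, 2] * S[1, 2] / S[0, 1])])
        np.testing.assert_allclose(res.standardized_loadings.to_numpy(),
                                   closed, atol=1e-6)


class TestFitML:
    def test_perfect_fit_recovers_generating_parameters(self, australia_spec):
        Sigma0 = implied_item_covariance(australia_spec, factor_correlation=0.2)
        mom = SampleMoments(Sigma0, 1000, australia_spec.items)
        res = CFAModel(mom, australia_spec).fit()
        assert res.F_min == pytest.approx(0.0, abs=1e-9)
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)
        for item, lam in australia_spec.reference_loadings.items():
            assert res.standardized_loadings[item] == pytest.approx(lam, abs=1e-4)

    def test_loading_recovery_within_003(self, australia_fit_20k, australia_spec):
        est = australia_fit_20k.standardized_loadings
        for item, lam in australia_spec.reference_loadings.items():
            assert est[item] == pytest.approx(lam, abs=0.03)

    def test_all_loadings_significant_in_powered_sample(self, australia_fit_20k):
        tab = australia_fit_20k.wald_tests()
        loads = tab[tab["kind"] == "loading"]
        assert (loads["p"] < 0.001).all()

    def test_scale_invariance(self, australia_spec, australia_items_20k):
        df = australia_items_20k.iloc[:2000]
        res1 = CFAModel.from_data(df, australia_spec).fit()
        scaled = df.copy()
        scaled["AE1"] = scaled["AE1"] * 3.7
        res2 = CFAModel.from_data(scaled, australia_spec).fit()
        assert res2.chi2 == pytest.approx(res1.chi2, rel=1e-4, abs=1e-5)
        assert res2.cfi == pytest.approx(res1.cfi, abs=1e-6)
        assert res2.rmsea == pytest.approx(res1.rmsea, abs=1e-6)
        assert res2.srmr == pytest.approx(res1.srmr, abs=1e-6)
        np.testing.assert_allclose(res2.standardized_loadings,
                                   res1.standardized_loadings, atol=1e-4)

    def test_marker_and_unit_variance_agree(self, australia_spec,
                                            australia_items_20k):
        import copy
        df = australia_items_20k.iloc[:3000]
        unit = CFAModel.from_data(df, australia_spec).fit()
        marker_spec = copy.deepcopy(australia_spec)
        marker_spec.scaling = "marker"
        marker = CFAModel.from_data(df, marker_spec).fit()
        assert marker.chi2 == pytest.approx(unit.chi2, abs=1e-5)
        # standardized solutions agree up to per-factor sign reflection
        np.testing.assert_allclose(np.abs(marker.standardized_loadings),
                                   np.abs(unit.standardized_loadings), atol=1e-4)

    def test_heywood_case_flagged(self):
        # r12*r13/r23 > 1 forces a negative error variance for item 1
        S = np.array([[1.0, 0.90, 0.80], [0.90, 1.0, 0.50], [0.80, 0.50, 1.0]])
        res = CFAModel(SampleMoments(S, 299, list("abc")), triad_spec("abc")).fit()
        assert res.heywood

    def test_agrees_with_naive_nelder_mead(self, rng):
        """Independent oracle: minimize the textbook F_ML written from scratch
        over a plain parameter vector, no shared code with the engine."""
        spec = MeasurementModelSpec(
            items=["a", "b", "c", "d", "e", "f"], factors=["F1", "F2"],
            loadings={"a": "F1", "b": "F1", "c": "F1",
                      "d": "F2", "e": "F2", "f": "F2"})
        true_lam = np.array([0.8, 0.7, 0.6, 0.75, 0.65, 0.55])
        Sigma0 = np.outer(true_lam, true_lam) * 0
        L = np.zeros((6, 2)); L[:3, 0] = true_lam[:3]; L[3:, 1] = true_lam[3:]
        Phi0 = np.array([[1.0, 0.35], [0.35, 1.0]])
        Sigma0 = L @ Phi0 @ L.T + np.diag(1 - true_lam ** 2)
        X = rng.multivariate_normal(np.zeros(6), Sigma0, size=400)
        S = np.cov(X.T, ddof=1)
        res = CFAModel(SampleMoments(S, 399, spec.items), spec).fit()

        sign, logdet_S = np.linalg.slogdet(S)

        def naive_F(theta):
            lam, phi, psi = theta[:6], theta[6], theta[7:]
            if abs(phi) >= 1 or np.any(psi <= 0):
                return 1e6
            Lm = np.zeros((6, 2)); Lm[:3, 0] = lam[:3]; Lm[3:, 1] = lam[3:]
            Ph = np.array([[1.0, phi], [phi, 1.0]])
            Sg = Lm @ Ph @ Lm.T + np.diag(psi)
            s2, ld = np.linalg.slogdet(Sg)
            if s2 <= 0:
                return 1e6
            return ld + np.trace(S @ np.linalg.inv(Sg)) - logdet_S - 6

        x0 = np.concatenate([np.full(6, 0.6), [0.2], np.full(6, 0.5)])
        nm = optimize.minimize(naive_F, x0, method="Nelder-Mead",
                               options={"maxiter": 20000, "xatol": 1e-10,
                                        "fatol": 1e-12})
        assert res.F_min == pytest.approx(nm.fun, abs=1e-6)
        assert 399 * nm.fun == pytest.approx(res.chi2, abs=1e-3)

    def test_null_loading_wald_calibration(self, rng):
        """An item with a true zero loading should be flagged significant in
        about 5% of replicates."""
        base = triad_spec(("a", "b", "c"))
        spec = MeasurementModelSpec(
            items=["a", "b", "c", "d"], factors=["F"],
            loadings={k: "F" for k in "abcd"})
        lam = np.array([0.8, 0.7, 0.6, 0.0])
        Sigma0 = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        np.fill_diagonal(Sigma0, 1.0)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            X = rng.multivariate_normal(np.zeros(4), Sigma0, size=300)
            mom = SampleMoments(np.cov(X.T, ddof=1), 299, spec.items)
            tab = CFAModel(mom, spec).fit().wald_tests()
            z = tab.loc[tab["param"] == "d~F", "z"].iloc[0]
            hits += abs(z) > 1.959964
        assert hits / n_rep < 0.18  # ~5% nominal, binomial noise at 60 reps


class TestBaselineAndIndices:
    def test_diagonal_s_gives_zero_baseline(self):
        mom = SampleMoments(np.diag([1.0, 2.0, 3.0]), 99, list("abc"))
        chi2_b, df_b = baseline_chi_square(mom)
        assert chi2_b == pytest.approx(0.0, abs=1e-10)
        assert df_b == 3

    def test_baseline_df_for_22_items(self, rng):
        A = rng.normal(size=(40, 22))
        S = np.cov(A.T, ddof=1) + np.eye(22) * 5
        _, df_b = baseline_chi_square(SampleMoments(S, 500, [f"i{k}" for k in range(22)]))
        assert df_b == 231

    def test_structured_model_nested_in_baseline(self, australia_spec,
                                                 australia_items_20k):
        df = australia_items_20k.iloc[:1500]
        res = CFAModel.from_data(df, australia_spec).fit()
        assert res.chi2_baseline >= res.chi2

    def test_central_case(self):
        cfi, rmsea, ci, _ = fit_indices(100.0, 100, 800.0, 231, 500)
        assert cfi == 1.0
        assert rmsea == 0.0

    def test_plug_in_arithmetic(self):
        cfi, rmsea, ci, _ = fit_indices(200.0, 100, 2000.0, 231, 1000)
        assert rmsea == pytest.approx(np.sqrt(100 / 100_000), abs=1e-12)
        assert cfi == pytest.approx(1 - 100 / (2000 - 231))
        assert ci[0] <= rmsea <= ci[1]

    def test_rmsea_ci_inverts_noncentral_chi2(self):
        from scipy import stats
        chi2, df, n = 180.0, 120, 400
        _, rmsea, (lo, hi), _ = fit_indices(chi2, df, 900.0, 153, n)
        lam_lo = lo ** 2 * df * n
        lam_hi = hi ** 2 * df * n
        assert stats.ncx2.cdf(chi2, df, lam_lo) == pytest.approx(0.95, abs=1e-6)
        assert stats.ncx2.cdf(chi2, df, lam_hi) == pytest.approx(0.05, abs=1e-6)

    def test_srmr_zero_when_equal(self, rng):
        A = rng.normal(size=(50, 4))
        S = np.cov(A.T, ddof=1)
        assert srmr(S, S) == 0.0

    def test_df_zero_flagged_rmsea_zero(self):
        cfi, rmsea, ci, _ = fit_indices(0.0, 0, 50.0, 3, 100)
        assert rmsea == 0.0 and ci == (0.0, 0.0)


class TestResidualDiagnostics:
    def test_zero_when_equal(self, rng):
        A = rng.normal(size=(50, 4))
        S = np.cov(A.T, ddof=1)
        R, largest = residual_diagnostics(S, S)
        np.testing.assert_allclose(R, 0.0, atol=1e-12)

    def test_perturbed_cell(self):
        S = np.eye(3)
        Sigma = S.copy()
        S2 = S.copy(); S2[0, 1] = S2[1, 0] = 0.1
        R, largest = residual_diagnostics(S2, Sigma, items=list("abc"))
        assert R[0, 1] == pytest.approx(0.1, abs=1e-12)
        assert largest[0][:2] == ("a", "b")
        np.testing.assert_allclose(R, R.T)


class TestModificationIndices:
    def test_flags_omitted_cross_factor_residual_pair(self, rng):
        spec = MeasurementModelSpec(
            items=list("abcdef"), factors=["F1", "F2"],
            loadings={"a": "F1", "b": "F1", "c": "F1",
                      "d": "F2", "e": "F2", "f": "F2"})
        lam = np.array([0.8, 0.7, 0.6, 0.75, 0.65, 0.55])
        L = np.zeros((6, 2)); L[:3, 0] = lam[:3]; L[3:, 1] = lam[3:]
        Phi = np.array([[1.0, 0.3], [0.3, 1.0]])
        Sigma0 = L @ Phi @ L.T + np.diag(1 - lam ** 2)
        Sigma0[1, 3] = Sigma0[3, 1] = Sigma0[1, 3] + 0.20  # plant b~~d
        X = rng.multivariate_normal(np.zeros(6), Sigma0, size=3000)
        mom = SampleMoments(np.cov(X.T, ddof=1), 2999, spec.items)
        mi = CFAModel(mom, spec).fit().modification_indices()
        assert mi.iloc[0]["param"] == "b~~d"
        assert mi.iloc[0]["mod_index"] > 50
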