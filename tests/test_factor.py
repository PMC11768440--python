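"""ML factor analysis: extraction, oblimin rotation, diagnostics, selection."""

import numpy as np
import pytest

from dustrisk import (
    MLFactorAnalysis,
    fa_fit,
    generate_dataset,
    hoffman_complexity,
    oblique_communalities,
    parallel_analysis,
    select_m,
    standardize,
    vss,
)
from conftest import block_loadings, factor_only_config

# reference loading rows of the three-factor urban-dust solution
ZN_ROW = np.array([0.97, -0.03, -0.02])
PB_ROW = np.array([0.47, 0.23, 0.31])
PHI_REF = np.array([[1.0, 0.54, 0.03], [0.54, 1.0, -0.02], [0.03, -0.02, 1.0]])


def _sample_correlation(data):
    z = np.asarray(standardize(data), dtype=float)
    return z.T @ z / (z.shape[0] - 1), z.shape[0]


class TestRowDiagnostics:
    def test_complexity_of_single_factor_row(self):
        assert hoffman_complexity(ZN_ROW[None, :])[0] == pytest.approx(1.0, abs=0.05)

    def test_complexity_of_spread_row(self):
        assert hoffman_complexity(PB_ROW[None, :])[0] == pytest.approx(2.2, abs=0.05)

    def test_complexity_bounds(self):
        rng = np.random.default_rng(0)
        com = hoffman_complexity(rng.uniform(-1, 1, size=(50, 3)))
        assert (com >= 1 - 1e-12).all() and (com <= 3 + 1e-12).all()

    def test_oblique_communality_of_reference_row(self):
        h2 = oblique_communalities(ZN_ROW, PHI_REF)[0]
        assert h2 == pytest.approx(0.91, abs=0.005)

    def test_orthogonal_single_loading_closed_form(self):
        row = np.array([0.8, 0.0, 0.0])
        assert oblique_communalities(row, np.eye(3))[0] == pytest.approx(0.64, rel=1e-12)
        assert hoffman_complexity(row[None, :])[0] == pytest.approx(1.0, rel=1e-12)


class TestMlExtraction:
    def test_matches_factanal_oracle(self):
        # frozen from R stats::factanal (rotation="none", n.obs=200) on the
        # correlation matrix of this exact reproducible sample
        rng = np.random.default_rng(42)
        lam = np.array([[0.8, 0], [0.7, 0], [0.6, 0.3], [0, 0.8], [0, 0.7], [0.2, 0.6]])
        psi = 1 - (lam**2).sum(1)
        F = rng.standard_normal((200, 2))
        X = F @ lam.T + rng.standard_normal((200, 6)) * np.sqrt(psi)
        R = np.corrcoef(X, rowvar=False)
        model = MLFactorAnalysis(n_factors=2, rotation=None).fit_correlation(R, 200)
        factanal_uniq = [0.292653, 0.444403, 0.541406, 0.487870, 0.459006, 0.539300]
        np.testing.assert_allclose(model.uniquenesses_, factanal_uniq, atol=2e-4)
        assert model.fit_stats_.objective == pytest.approx(0.037137, abs=1e-5)
        assert model.fit_stats_.chi_square == pytest.approx(7.235567, abs=1e-3)
        assert model.fit_stats_.p_value == pytest.approx(0.123951, abs=1e-3)

    def test_parameter_recovery_with_strong_loadings(self):
        # known orthogonal Lambda (entries 0.8), unit total variance
        # (noise sd 0.6), n=1000: standardized pattern recovered up to
        # permutation/sign within 0.1
        cfg = factor_only_config(9, n_sites=1000)
        cfg = type(cfg)(**{**cfg.__dict__, "noise_sd": 0.6})
        ds = generate_dataset(cfg)
        model = MLFactorAnalysis(n_factors=3).fit(ds.concentrations)
        lam_true = block_loadings(0.8)
        fitted = model.loadings_
        cost = np.abs(lam_true.T @ fitted)  # alignment by block overlap
        perm = np.argmax(cost, axis=1)
        assert sorted(perm) == [0, 1, 2]
        aligned = fitted[:, perm] * np.sign(np.sum(lam_true * fitted[:, perm], axis=0))
        assert np.abs(aligned - lam_true).max() <= 0.1

    def test_heywood_case_floored_and_flagged(self):
        # this correlation pattern implies a single-factor loading above 1
        # (lambda_1^2 = r12*r13/r23 = 1.2), so the uniqueness is floored
        # at 0.001 and the Heywood flag raised instead of aborting
        R = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.6], [0.8, 0.6, 1.0]])
        model = MLFactorAnalysis(n_factors=1).fit_correlation(R, 50)
        assert model.uniquenesses_.min() >= 1e-3 - 1e-12
        assert model.uniquenesses_.min() == pytest.approx(1e-3, rel=1e-6)
        assert model.heywood_

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="positive definite"):
            MLFactorAnalysis(n_factors=1).fit_correlation(np.ones((3, 3)), 20)
        R = np.eye(4)
        with pytest.raises(ValueError, match="n_factors"):
            MLFactorAnalysis(n_factors=4).fit_correlation(R, 20)


@pytest.fixture(scope="module")
def fitted_pair():
    ds = generate_dataset(factor_only_config(3, n_sites=300))
    R, n = _sample_correlation(ds.concentrations)
    rotated = MLFactorAnalysis(n_factors=3).fit_correlation(R, n)
    unrotated = MLFactorAnalysis(n_factors=3, rotation=None).fit_correlation(R, n)
    return rotated, unrotated


class TestRotation:

    def test_phi_is_a_correlation_matrix(self, fitted_pair):
        phi = fitted_pair[0].factor_corr_
        np.testing.assert_allclose(phi, phi.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(phi), 1.0, atol=1e-10)
        assert np.linalg.eigvalsh(phi).min() > 0

    def test_communalities_rotation_invariant(self, fitted_pair):
        rotated, unrotated = fitted_pair
        np.testing.assert_allclose(
            rotated.communalities_, unrotated.communalities_, atol=1e-6
        )

    def test_chi_square_rotation_invariant(self, fitted_pair):
        rotated, unrotated = fitted_pair
        assert rotated.fit_stats_.chi_square == pytest.approx(
            unrotated.fit_stats_.chi_square, abs=1e-6
        )

    def test_h2_plus_u2_near_one(self, fitted_pair):
        model = fitted_pair[0]
        assert np.abs(model.communalities_ + model.uniquenesses_ - 1).max() < 0.02


class TestFitStatistics:
    def test_reference_degrees_of_freedom_and_pvalue(self):
        from scipy.stats import chi2
        p, m = 10, 3
        df = ((p - m) ** 2 - (p + m)) // 2
        assert df == 18
        assert chi2.sf(11.23, df) == pytest.approx(0.885, abs=0.005)

    def test_information_criteria_identities(self):
        ds = generate_dataset(factor_only_config(5, n_sites=200))
        R, n = _sample_correlation(ds.concentrations)
        stats = fa_fit(R, 3, n).fit_stats_
        assert stats.aic - stats.bic == pytest.approx(4 * stats.df, rel=1e-12)
        assert stats.bic == pytest.approx(stats.chi_square - 2 * stats.df, rel=1e-12)

    def test_perfect_fit_gives_zero_chi_square(self):
        lam = np.array([[0.9], [0.8], [0.7], [0.6]])
        R = lam @ lam.T + np.diag(1 - (lam**2).ravel())
        stats = fa_fit(R, 1, 100).fit_stats_
        assert stats.chi_square == pytest.approx(0.0, abs=1e-6)
        assert stats.rmsr == pytest.approx(0.0, abs=1e-6)


class TestParallelAnalysis:
    def test_two_strong_factors_detected(self):
        lam = np.zeros((10, 3))
        lam[:5, 0] = 0.8
        lam[5:, 1] = 0.8
        hits = 0
        for seed in range(20):
            cfg = factor_only_config(seed, n_sites=200)
            cfg = type(cfg)(**{**cfg.__dict__, "loadings_true": lam})
            data = generate_dataset(cfg).concentrations
            hits += parallel_analysis(data, reps=50, seed=seed).pa_retained == 2
        assert hits >= 18

    def test_pure_noise_keeps_few_factors(self):
        # with the mean-eigenvalue rule the top observed eigenvalue beats
        # the random mean about half the time, so on pure noise the
        # retained count is small but not almost-surely <= 1
        retained = []
        for seed in range(20):
            data = np.random.default_rng(1000 + seed).standard_normal((200, 8))
            retained.append(parallel_analysis(data, reps=50, seed=seed).pa_retained)
        assert sum(r <= 2 for r in retained) >= 18
        assert np.median(retained) <= 1

    def test_random_eigen_means_decreasing(self):
        rng = np.random.default_rng(4)
        sel = parallel_analysis(rng.standard_normal((60, 6)), reps=40, seed=0)
        assert (np.diff(sel.random_eigen_means) < 0).all()

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            parallel_analysis(np.random.default_rng(0).standard_normal((30, 4)), reps=5)


class TestVss:
    def test_exact_single_factor_model_scores_near_one(self):
        lam = np.array([[0.9], [0.85], [0.8], [0.75], [0.7]])
        R = lam @ lam.T + np.diag(1 - (lam**2).ravel())
        curves = vss(R, n=100, m_max=2)
        assert curves[1][1] > 0.99

    def test_complexity_two_dominates_complexity_one(self):
        ds = generate_dataset(factor_only_config(6, n_sites=150))
        R, n = _sample_correlation(ds.concentrations)
        curves = vss(R, n, m_max=4)
        for m in curves[1]:
            assert curves[2][m] >= curves[1][m] - 1e-9


class TestSelectM:
    def test_recovers_three_factors(self):
        ds = generate_dataset(factor_only_config(7, n_sites=500))
        R, n = _sample_correlation(ds.concentrations)
        sel = select_m(R, n, data=ds.concentrations, reps=50, seed=7)
        assert sel.selected_m["default"] == 3
        assert sel.selected_m["parallel_analysis"] == 3

    def test_argmin_argmax_bookkeeping(self):
        ds = generate_dataset(factor_only_config(8, n_sites=150))
        R, n = _sample_correlation(ds.concentrations)
        sel = select_m(R, n)
        assert sel.aic_curve[sel.selected_m["aic"]] == min(sel.aic_curve.values())
        assert sel.bic_curve[sel.selected_m["bic"]] == min(sel.bic_curve.values())
        for c, curve in sel.vss_curve.items():
            assert curve[sel.selected_m[f"vss_c{c}"]] == max(curve.values())


class TestFactorScores:
    def test_noiseless_model_has_perfect_adequacy(self):
        lam = np.array([[0.999], [0.995], [0.997]])
        R = lam @ lam.T + np.diag(1 - (lam**2).ravel())
        model = MLFactorAnalysis(n_factors=1).fit_correlation(R, 500)
        adequacy = model.score_adequacy_
        assert adequacy["r_square"].iloc[0] > 0.99
        assert adequacy["min_correlation"].iloc[0] > 0.98

    def test_r_square_bounded(self):
        for seed in range(5):
            ds = generate_dataset(factor_only_config(seed, n_sites=80))
            model = MLFactorAnalysis(n_factors=3).fit(ds.concentrations)
            r2 = model.score_adequacy_["r_square"].to_numpy()
            assert (r2 >= 0).all() and (r2 <= 1).all()

    def test_scores_correlate_with_true_factors(self):
        # simulation oracle: regression scores track the planted factors
        ds = generate_dataset(factor_only_config(12, n_sites=800))
        model = MLFactorAnalysis(n_factors=3).fit(ds.concentrations)
        scores = model.scores()
        corr = np.abs(np.corrcoef(scores.T, ds.factors_true.T)[:3, 3:])
        matched = corr.max(axis=1)
        assert (matched > 0.85).all()
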