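"""Estimation checks: hand oracles, grid-search oracle, statsmodels cross-check."""

import numpy as np
import pytest

from longmed import (
    MediationDataset,
    SimulationConfig,
    fit_mediation,
    fit_ols,
    fit_random_intercept,
    simulate_dataset,
)
from longmed.power import _fit_paths_batch, _simulate_batch

from conftest import grid_ml_oracle, make_mediation_fit


def _single_level(x, y):
    x = np.asarray(x, float)[:, None]
    return MediationDataset(x=x, m=np.zeros_like(x), y=np.asarray(y, float)[:, None])


class TestOLS:
    def test_perfect_fit_zero_noise(self):
        d = _single_level(np.arange(10.0), np.arange(10.0))
        f = fit_ols(d, "y", ["x"])
        assert f.coef("x") == pytest.approx(1.0, abs=1e-12)
        assert f.sigma_sq_hat == pytest.approx(0.0, abs=1e-20)
        assert f.tau_sq_hat == 0.0
        assert f.converged

    def test_hand_computed_normal_equations(self):
        # {(0,0),(1,1),(2,2),(3,4)}: Sxy/Sxx = 6.5/5 = 1.3, b0 = 1.75-1.3*1.5
        d = _single_level([0, 1, 2, 3], [0, 1, 2, 4])
        f = fit_ols(d, "y", ["x"])
        assert f.coef("x") == pytest.approx(1.3, abs=1e-12)
        assert f.intercept[0] == pytest.approx(-0.2, abs=1e-12)

    def test_ols_mean_recovery_over_replicates(self):
        # single-level consistency: mean slope over replicates near beta_a
        cfg = SimulationConfig(beta_a=0.14, beta_b=0.14, icc=0.0,
                               n_subjects=667, n_measures=1, seed=3)
        x, m, y = _simulate_batch(cfg, range(50), seed=3)
        slopes = np.array([
            fit_ols(MediationDataset(x=x[r], m=m[r], y=y[r]), "m", ["x"]).coef("x")
            for r in range(50)
        ])
        assert slopes.mean() == pytest.approx(
            0.14, abs=3 * slopes.std(ddof=1) / np.sqrt(len(slopes))
        )

    def test_repeated_measures_rejected(self):
        d = simulate_dataset(SimulationConfig(
            beta_a=0.1, beta_b=0.1, icc=0.1, n_subjects=10, n_measures=2, seed=0))
        with pytest.raises(ValueError, match="fit_random_intercept"):
            fit_ols(d, "y", ["x"])


class TestRandomIntercept:
    def test_grid_oracle_agreement_small_dataset(self, small_dataset):
        """ML estimates match brute-force grid maximization to 3 decimals."""
        for outcome, preds in (("m", ["x"]), ("y", ["x", "m"])):
            fit = fit_random_intercept(small_dataset, outcome, preds)
            ll, beta, tau2, sig2 = grid_ml_oracle(small_dataset, outcome, preds)
            assert fit.loglik >= ll - 1e-6
            for i, name in enumerate(preds):
                assert fit.coef(name) == pytest.approx(beta[i + 1], abs=1e-3)
            assert fit.tau_sq_hat == pytest.approx(tau2, abs=1.5e-3)
            assert fit.sigma_sq_hat == pytest.approx(sig2, abs=1.5e-3)

    @pytest.mark.parametrize("mm,J,seed", [(2, 6, 1), (3, 8, 2), (4, 10, 3), (5, 7, 4)])
    def test_optimizer_never_loses_to_grid(self, mm, J, seed):
        cfg = SimulationConfig(beta_a=0.39, beta_b=0.39, icc=0.4,
                               n_subjects=J, n_measures=mm, seed=seed)
        d = simulate_dataset(cfg)
        fit = fit_random_intercept(d, "y", ["x", "m"])
        ll, *_ = grid_ml_oracle(d, "y", ["x", "m"])
        assert fit.loglik >= ll - 1e-6

    def test_statsmodels_mixedlm_cross_check(self, medium_dataset):
        """Independent mixed-model routine agrees on the ML optimum."""
        smf = pytest.importorskip("statsmodels.formula.api")
        df = medium_dataset.to_frame()
        fit = fit_random_intercept(medium_dataset, "y", ["x", "m"])
        ref = smf.mixedlm("y ~ x + m", df, groups=df["subject"]).fit(reml=False)
        assert fit.coef("x") == pytest.approx(ref.params["x"], abs=1e-4)
        assert fit.coef("m") == pytest.approx(ref.params["m"], abs=1e-4)
        assert fit.intercept[0] == pytest.approx(ref.params["Intercept"], abs=1e-4)
        assert fit.tau_sq_hat == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-3)
        assert fit.sigma_sq_hat == pytest.approx(ref.scale, abs=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_reml_option_matches_independent_routine(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        cfg = SimulationConfig(beta_a=0.39, beta_b=0.39, icc=0.3,
                               n_subjects=60, n_measures=3, seed=17)
        d = simulate_dataset(cfg)
        df = d.to_frame()
        fit = fit_random_intercept(d, "y", ["x", "m"], reml=True)
        assert fit.method == "reml_random_intercept"
        ref = smf.mixedlm("y ~ x + m", df, groups=df["subject"]).fit(reml=True)
        assert fit.coef("m") == pytest.approx(ref.params["m"], abs=1e-4)
        assert fit.tau_sq_hat == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                               abs=1e-3)
        assert fit.sigma_sq_hat == pytest.approx(ref.scale, abs=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        # REML shrinks less: its tau^2 estimate exceeds the ML one
        ml = fit_random_intercept(d, "y", ["x", "m"])
        assert fit.tau_sq_hat > ml.tau_sq_hat

    def test_standard_errors_match_dense_inverse_information(self, medium_dataset):
        fit = fit_random_intercept(medium_dataset, "m", ["x"])
        mm = medium_dataset.n_measures
        V = fit.sigma_sq_hat * np.eye(mm) + fit.tau_sq_hat * np.ones((mm, mm))
        Vi = np.linalg.inv(V)
        info = np.zeros((2, 2))
        for j in range(medium_dataset.n_subjects):
            X = np.column_stack([np.ones(mm), medium_dataset.x[j]])
            info += X.T @ Vi @ X
        se = np.sqrt(np.linalg.inv(info)[1, 1])
        assert fit.se("x") == pytest.approx(se, rel=1e-8)

    def test_icc_zero_matches_pooled_ols(self):
        cfg = SimulationConfig(beta_a=0.3, beta_b=0.3, icc=0.0, n_subjects=400,
                               n_measures=2, seed=2, x_mode="iid_standard_normal")
        d = simulate_dataset(cfg)
        fri = fit_random_intercept(d, "m", ["x"])
        pooled = MediationDataset(
            x=d.x.reshape(-1, 1), m=d.m.reshape(-1, 1), y=d.y.reshape(-1, 1))
        fo = fit_ols(pooled, "m", ["x"])
        assert fri.coef("x") == pytest.approx(fo.coef("x"), abs=1e-3)

    def test_boundary_tau_reproduces_ols_exactly(self):
        # a dataset whose tau^2 MLE sits at the 0 boundary: point estimates
        # must equal pooled OLS to floating precision
        for seed in range(20):
            cfg = SimulationConfig(beta_a=0.3, beta_b=0.3, icc=0.0,
                                   n_subjects=30, n_measures=2, seed=seed,
                                   x_mode="iid_standard_normal")
            d = simulate_dataset(cfg)
            fri = fit_random_intercept(d, "m", ["x"])
            if fri.tau_sq_hat == 0.0:
                pooled = MediationDataset(
                    x=d.x.reshape(-1, 1), m=d.m.reshape(-1, 1),
                    y=d.y.reshape(-1, 1))
                fo = fit_ols(pooled, "m", ["x"])
                assert fri.coef("x") == pytest.approx(fo.coef("x"), abs=1e-10)
                assert fri.intercept[0] == pytest.approx(fo.intercept[0], abs=1e-10)
                break
        else:
            pytest.fail("no boundary case encountered in 20 seeds")

    def test_location_shift_invariance(self, medium_dataset):
        d = medium_dataset
        shifted = MediationDataset(x=d.x, m=d.m, y=d.y + 500.0)
        f1 = fit_random_intercept(d, "y", ["x", "m"])
        f2 = fit_random_intercept(shifted, "y", ["x", "m"])
        assert f2.coef("m") == pytest.approx(f1.coef("m"), abs=1e-10)
        assert f2.se("m") == pytest.approx(f1.se("m"), abs=1e-10)
        assert f2.tau_sq_hat == pytest.approx(f1.tau_sq_hat, abs=1e-10)
        assert f2.sigma_sq_hat == pytest.approx(f1.sigma_sq_hat, abs=1e-10)
        assert f2.intercept[0] - f1.intercept[0] == pytest.approx(500.0, abs=1e-6)

    def test_parameter_recovery_monte_carlo(self):
        # 500 datasets at J=200, m=3: mean slope within 3 SD/sqrt(500) of truth
        cfg = SimulationConfig(beta_a=0.39, beta_b=0.39, icc=0.3,
                               n_subjects=200, n_measures=3, seed=5)
        x, m, y = _simulate_batch(cfg, range(500), seed=5)
        slopes = np.array([
            fit_random_intercept(
                MediationDataset(x=x[r], m=m[r], y=y[r]), "m", ["x"]).coef("x")
            for r in range(500)
        ])
        mc_se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert slopes.mean() == pytest.approx(0.39, abs=3 * mc_se)

    def test_single_measure_delegates_to_ols(self):
        d = simulate_dataset(SimulationConfig(
            beta_a=0.2, beta_b=0.2, icc=0.0, n_subjects=50, n_measures=1, seed=1))
        f = fit_random_intercept(d, "m", ["x"])
        assert f.method == "ols"

    def test_unknown_variable_name_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown variable"):
            fit_random_intercept(small_dataset, "z", ["x"])
        with pytest.raises(ValueError, match="unknown variable"):
            fit_random_intercept(small_dataset, "y", ["w"])

    def test_too_few_subjects_rejected(self):
        d = simulate_dataset(SimulationConfig(
            beta_a=0.1, beta_b=0.1, icc=0.1, n_subjects=2, n_measures=2, seed=0))
        with pytest.raises(ValueError, match="3 subjects"):
            fit_random_intercept(d, "m", ["x"])


class TestMediationFit:
    def test_product_and_sobel_se_by_hand(self):
        fit = make_mediation_fit(0.4, 0.1, 0.5, 0.1)
        assert fit.ab_hat == pytest.approx(0.20)
        assert fit.sobel_se == pytest.approx(np.sqrt(0.0041), abs=1e-12)
        assert fit.sobel_se == pytest.approx(0.06403, abs=1e-5)

    def test_zero_a_path_collapses_sobel_se(self):
        fit = make_mediation_fit(0.0, 0.07, 0.8, 0.2)
        assert fit.ab_hat == 0.0
        assert fit.sobel_se == pytest.approx(0.07 * 0.8, abs=1e-12)

    def test_consistency_at_large_j(self):
        # (beta_a, beta_b) = (0.59, 0.14): ab converges to 0.0826
        cfg = SimulationConfig(beta_a=0.59, beta_b=0.14, icc=0.9,
                               n_subjects=5000, n_measures=3, seed=6)
        fit = fit_mediation(simulate_dataset(cfg))
        assert fit.converged
        assert fit.ab_hat == pytest.approx(0.0826, abs=3 * fit.sobel_se)

    def test_paths_use_correct_regressions(self, medium_dataset):
        fit = fit_mediation(medium_dataset)
        assert set(fit.a_path.coefficients) == {"x"}
        assert set(fit.b_path.coefficients) == {"x", "m"}
        a = fit_random_intercept(medium_dataset, "m", ["x"])
        assert fit.a_path.coef("x") == a.coef("x")

    def test_single_level_mediation_uses_ols(self):
        d = simulate_dataset(SimulationConfig(
            beta_a=0.3, beta_b=0.3, icc=0.0, n_subjects=100, n_measures=1, seed=8))
        fit = fit_mediation(d)
        assert fit.a_path.method == "ols"
        assert fit.b_path.method == "ols"
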