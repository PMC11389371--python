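"""Generalized Lotka-Volterra system building, the three estimators, and
one-step prediction."""

import numpy as np
import pytest

import mbinterp as mi
from mbinterp.glv import GLVModel

from conftest import glv_oracle_system


def constant_profile(n=6, m=4):
    x = np.full(m, 1.0 / m)
    return mi.LongitudinalProfile("c", np.arange(float(n)),
                                  tuple(f"t{i}" for i in range(m)),
                                  np.tile(x, (n, 1)))


class TestBuildRegression:
    def test_constant_profile_gives_zero_rates(self):
        mats = mi.build_glv_regression(constant_profile())
        np.testing.assert_allclose(mats.F, 0.0, atol=1e-12)
        assert mats.n_pairs == 5
        np.testing.assert_allclose(mats.Y[-1], 1.0)

    def test_exponential_growth_rate_recovered_exactly(self):
        # single taxon x(t) = x0 exp(beta t) in absolute-abundance mode:
        # every F entry equals beta regardless of the sampling grid
        beta = 0.37
        rng = np.random.default_rng(5)
        times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.2, 3.0, 9))])
        x = 0.4 * np.exp(beta * times)
        prof = mi.LongitudinalProfile("e", times, ("t0",), x[:, None],
                                      simplex=False)
        mats = mi.build_glv_regression(prof)
        np.testing.assert_allclose(mats.F, beta, atol=1e-10)

    def test_pair_count_and_single_sample_error(self):
        prof = constant_profile(n=9)
        assert mi.build_glv_regression(prof).n_pairs == 8
        with pytest.raises(ValueError):
            mi.LongitudinalProfile("x", [0.0], ("a",), [[1.0]])


class TestMSE:
    def test_noise_free_recovery(self, glv_oracle):
        params, profile = glv_oracle
        est = mi.fit_glv_mse(mi.build_glv_regression(profile))
        np.testing.assert_allclose(est.A, params.A, atol=1e-6)
        np.testing.assert_allclose(est.B, params.B, atol=1e-6)

    def test_zero_rates_give_zero_parameters(self):
        mats = mi.build_glv_regression(constant_profile())
        est = mi.fit_glv_mse(mats)
        np.testing.assert_allclose(est.A, 0.0, atol=1e-9)
        np.testing.assert_allclose(est.B, 0.0, atol=1e-9)

    def test_duplicate_columns_yield_min_norm_consistent_solution(self):
        # 2-taxon toy with duplicated pairs: residual must be 0 and the
        # solution must match the pseudoinverse oracle
        Y = np.array([[0.3, 0.3, 0.6], [0.7, 0.7, 0.4], [1.0, 1.0, 1.0]])
        F = np.array([[0.1, 0.1, 0.2], [-0.05, -0.05, 0.3]])
        mats = mi.GLVRegressionMatrices(F=F, Y=Y, pair_deltas=np.ones(3),
                                        taxa=("a", "b"))
        est = mi.fit_glv_mse(mats)
        coef = np.column_stack([est.A, est.B])
        np.testing.assert_allclose(coef @ Y, F, atol=1e-10)
        oracle = (np.linalg.pinv(Y.T) @ F.T).T
        np.testing.assert_allclose(coef, oracle, atol=1e-10)

    def test_residual_is_locally_optimal(self, glv_oracle):
        _, profile = glv_oracle
        mats = mi.build_glv_regression(profile)
        est = mi.fit_glv_mse(mats)
        coef = np.column_stack([est.A, est.B])
        base = np.linalg.norm(mats.F - coef @ mats.Y) ** 2
        rng = np.random.default_rng(0)
        for _ in range(20):
            pert = coef.copy()
            i, j = rng.integers(coef.shape[0]), rng.integers(coef.shape[1])
            pert[i, j] += rng.choice([-1e-3, 1e-3])
            assert np.linalg.norm(mats.F - pert @ mats.Y) ** 2 >= base


class TestMLRR:
    def test_lambda_zero_matches_least_squares(self, glv_oracle):
        _, profile = glv_oracle
        mats = mi.build_glv_regression(profile)
        mse = mi.fit_glv_mse(mats)
        ridge = mi.fit_glv_mlrr(mats, lambda_ridge=0.0)
        np.testing.assert_allclose(ridge.A, mse.A, atol=1e-9)
        np.testing.assert_allclose(ridge.B, mse.B, atol=1e-9)

    def test_small_lambda_recovers_truth(self, glv_oracle):
        params, profile = glv_oracle
        est = mi.fit_glv_mlrr(mi.build_glv_regression(profile),
                              lambda_ridge=1e-8)
        np.testing.assert_allclose(est.A, params.A, atol=1e-4)
        np.testing.assert_allclose(est.B, params.B, atol=1e-4)

    def test_shrinkage_monotone_along_grid(self):
        params, x0, times = glv_oracle_system(seed=3, n_taxa=3, n_samples=25)
        prof = mi.simulate_glv_profile(params, x0, times, noise_sd=0.05,
                                       seed=1, closure=False)
        mats = mi.build_glv_regression(prof)
        norms = []
        for lam in [1e-2, 1e-1, 1.0, 10.0, 100.0]:
            est = mi.fit_glv_mlrr(mats, lambda_ridge=lam)
            norms.append(np.linalg.norm(np.column_stack([est.A, est.B])))
        assert all(np.diff(norms) < 0)

    def test_ridge_residual_dominates_ols_residual(self, glv_oracle):
        _, profile = glv_oracle
        model = GLVModel(profile)
        ols = model.fit("mse")
        for lam in [0.1, 1.0]:
            assert model.fit("mlrr", lambda_ridge=lam).residual_mse >= \
                ols.residual_mse

    def test_cross_validated_lambda_is_reasonable(self, glv_oracle):
        params, profile = glv_oracle
        est = mi.fit_glv_mlrr(mi.build_glv_regression(profile))  # CV lambda
        # noise-free, well-conditioned system: CV must pick tiny shrinkage
        np.testing.assert_allclose(est.A, params.A, atol=1e-2)


class TestLIMITS:
    def _diagonal_system(self, seed=0, m=4, n=60, noise=0.01):
        rng = np.random.default_rng(seed)
        A = np.diag(rng.uniform(-0.5, -0.3, m))
        B = rng.uniform(0.2, 0.4, m)
        x0 = mi.normalize(rng.uniform(0.5, 1.5, m))
        times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.5, 1.5, n - 1))])
        prof = mi.simulate_glv_profile(mi.GLVParameters(A=A, B=B), x0, times,
                                       noise_sd=noise, seed=seed,
                                       closure=False)
        return A, mi.build_glv_regression(prof)

    def test_diagonal_truth_yields_sparse_off_diagonals(self):
        A, mats = self._diagonal_system()
        est = mi.fit_glv_limits(mats, n_bootstrap=20, seed=0)
        off = est.A[~np.eye(A.shape[0], dtype=bool)]
        assert np.mean(off == 0.0) >= 0.9

    def test_seeded_determinism(self, glv_oracle):
        _, profile = glv_oracle
        mats = mi.build_glv_regression(profile)
        a = mi.fit_glv_limits(mats, n_bootstrap=1, seed=42)
        b = mi.fit_glv_limits(mats, n_bootstrap=1, seed=42)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.B, b.B)

    def test_strong_interaction_detected_with_right_sign(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            m = 3
            A = np.diag([-0.4, -0.4, -0.4]).astype(float)
            A[0, 1] = 0.8  # strong true cross-interaction
            B = np.array([0.2, 0.25, 0.3])
            x0 = mi.normalize(rng.uniform(0.5, 1.5, m))
            times = np.concatenate([[0.0],
                                    np.cumsum(rng.uniform(0.5, 1.5, 49))])
            prof = mi.simulate_glv_profile(
                mi.GLVParameters(A=A, B=B), x0, times, noise_sd=0.02,
                seed=seed, closure=False,
            )
            est = mi.fit_glv_limits(mi.build_glv_regression(prof),
                                    n_bootstrap=20, seed=seed)
            if est.A[0, 1] > 0:
                hits += 1
        assert hits >= 18

    def test_support_shrinks_with_stricter_threshold(self):
        _, mats = self._diagonal_system(seed=2, noise=0.05)
        sizes = []
        for thr in [1e-4, 1e-2, 0.5]:
            est = mi.fit_glv_limits(mats, n_bootstrap=5,
                                    improvement_threshold=thr, seed=1)
            sizes.append(int(np.count_nonzero(est.A)))
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestPredict:
    def test_null_parameters_return_previous_sample(self):
        m = 4
        params = mi.GLVParameters(A=np.zeros((m, m)), B=np.zeros(m))
        prev = mi.normalize([0.4, 0.3, 0.2, 0.1])
        np.testing.assert_allclose(
            mi.predict_glv(params, prev, 2.0).values, prev.values, atol=1e-12
        )

    def test_single_taxon_log_growth_is_beta_dt(self):
        params = mi.GLVParameters(A=np.zeros((1, 1)), B=np.array([0.3]))
        prev = np.array([0.2])
        # pre-normalization log abundance increases by exactly beta*dt
        pred = mi.predict_glv(params, prev, 4.0)
        np.testing.assert_allclose(pred.values, [1.0])
        # verify against the closed form on a 2-taxon system where only
        # taxon 0 grows: ratio must be exp(beta*dt)
        params2 = mi.GLVParameters(A=np.zeros((2, 2)), B=np.array([0.3, 0.0]))
        pred2 = mi.predict_glv(params2, np.array([0.5, 0.5]), 4.0)
        assert pred2.values[0] / pred2.values[1] == pytest.approx(
            np.exp(0.3 * 4.0)
        )

    def test_fitted_params_reproduce_held_out_samples(self, glv_oracle):
        _, profile = glv_oracle
        est = mi.fit_glv_mse(mi.build_glv_regression(profile))
        for k in range(1, profile.n_samples):
            pred = mi.predict_glv(
                est, profile.abundances[k - 1],
                float(profile.times[k] - profile.times[k - 1]),
            )
            truth = profile.abundances[k] / profile.abundances[k].sum()
            np.testing.assert_allclose(pred.values, truth, atol=1e-6)

    def test_explosive_rates_clamped_with_warning(self):
        params = mi.GLVParameters(A=np.zeros((2, 2)), B=np.array([100.0, 0.0]))
        with pytest.warns(RuntimeWarning, match="clamped"):
            out = mi.predict_glv(params, np.array([0.5, 0.5]), 10.0)
        assert np.isfinite(out.values).all()

    def test_dimension_mismatch_rejected(self):
        params = mi.GLVParameters(A=np.zeros((2, 2)), B=np.zeros(2))
        with pytest.raises(ValueError):
            mi.predict_glv(params, np.array([1.0]), 1.0)


def test_model_results_surface(glv_oracle):
    params, profile = glv_oracle
    res = GLVModel(profile).fit("mse")
    assert res.residual_mse == pytest.approx(0.0, abs=1e-12)
    assert "Lotka-Volterra" in res.summary()
    frame = res.params.to_frame()
    assert "growth_rate" in frame.columns
    np.testing.assert_allclose(frame["growth_rate"], params.B, atol=1e-6)
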