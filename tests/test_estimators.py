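"""HRF estimators: OLS, AR(1) prewhitening, Tikhonov and mixed-norm."""

import numpy as np
import pytest
from scipy import optimize

from mnhrf.design import DesignSet
from mnhrf.estimators import (
    EstimatorConfig,
    HRFRegressorMixedNorm,
    HRFRegressorMixedNormCV,
    estimate_ar1,
    fit_lsar,
    fit_mn,
    fit_ols,
    fit_tikhonov,
    select_regularization,
    whitening_transform,
)
from mnhrf.simulate import canonical_hrf

from conftest import random_schedule


def mn_objective(params, S, P, D, C, y, delta, gamma):
    L = S.shape[1]
    h, b = params[:L], params[L:]
    r = S @ h + P @ b - y
    return (r @ r + delta ** 2 * np.sum((D @ h) ** 2)
            + gamma ** 2 * np.sum((C @ h) ** 2))


def augmented_lstsq_minimizer(design, y, delta, gamma):
    """Independent numeric minimizer of the penalized objective: least
    squares on the penalty-augmented stacked system."""
    S, P, D, C = design.S, design.P, design.D, design.C
    L, B = S.shape[1], P.shape[1]
    A = np.vstack([
        np.hstack([S, P]),
        np.hstack([delta * D, np.zeros((D.shape[0], B))]),
        np.hstack([gamma * C, np.zeros((L, B))]),
    ])
    rhs = np.concatenate([y, np.zeros(D.shape[0] + L)])
    coef, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return coef[:L], coef[L:]


def random_problem(rng, n_min=40, n_max=100, l_max=12):
    sched = random_schedule(rng, n_volumes=int(rng.integers(n_min, n_max)),
                            n_trials=int(rng.integers(5, 12)))
    L = int(rng.integers(5, l_max + 1))
    design = DesignSet.from_schedule(sched, L)
    y = rng.standard_normal(sched.run_length)
    return design, y


class TestOLS:
    def test_noiseless_recovery(self, design, hrf, rng):
        b_true = rng.standard_normal(4)
        y = design.S @ hrf + design.P @ b_true
        est = fit_ols(y, design)
        np.testing.assert_allclose(est.h, hrf, atol=1e-8)
        np.testing.assert_allclose(est.b, b_true, atol=1e-8)
        assert est.method == "OLS" and est.delta == est.gamma == 0.0

    def test_orthogonal_target_gives_zero(self, design):
        W = np.hstack([design.S, design.P])
        Q, _ = np.linalg.qr(W)
        y = np.ones(design.n_volumes)
        y = y - Q @ (Q.T @ y)  # orthogonal to the column space
        est = fit_ols(y, design)
        np.testing.assert_allclose(est.h, 0, atol=1e-8)
        np.testing.assert_allclose(est.b, 0, atol=1e-8)

    def test_matches_numeric_minimizer(self, rng):
        design, y = random_problem(rng, n_min=55, n_max=65, l_max=8)
        est = fit_ols(y, design)
        res = optimize.minimize(
            mn_objective, np.zeros(design.L + 4),
            args=(design.S, design.P, design.D, design.C, y, 0.0, 0.0),
            method="BFGS", options={"gtol": 1e-12, "maxiter": 5000},
        )
        np.testing.assert_allclose(est.h, res.x[:design.L], atol=1e-6)

    def test_rejects_rank_deficient_design(self):
        # a lone trial at the very last volume leaves every shifted column
        # of S beyond the first identically zero
        from mnhrf.design import EventSchedule

        sched = EventSchedule(onsets=np.array([58.0]),
                              durations=np.array([2.0]),
                              labels=np.array([0]), run_length=30, tr=2.0)
        design = DesignSet.from_schedule(sched, 8)
        with pytest.raises(np.linalg.LinAlgError, match=r"\[S P\]"):
            fit_ols(np.zeros(30), design)


class TestAR1:
    def test_white_noise_limit(self, rng):
        assert abs(estimate_ar1(rng.standard_normal(5000))) < 0.05

    def test_recovers_ar_coefficient(self, rng):
        e = rng.standard_normal(5001)
        x = np.empty(5001)
        x[0] = e[0]
        for t in range(1, 5001):
            x[t] = 0.4 * x[t - 1] + e[t]
        assert 0.35 <= estimate_ar1(x) <= 0.45

    def test_constant_residuals_degenerate_branch(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert estimate_ar1(np.full(50, 3.14)) == 0.0

    def test_whitening_transform_decorrelates(self, rng):
        rho, n = 0.6, 2000
        e = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
        e[0] = rng.standard_normal()
        x = np.empty(n)
        x[0] = e[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + e[t]
        w = whitening_transform(rho, n).transform @ x
        assert abs(estimate_ar1(w)) < 0.08


class TestLSAR:
    def test_equals_ols_under_white_noise(self, design, hrf, rng):
        y = design.S @ hrf + 0.05 * rng.standard_normal(design.n_volumes)
        ols, lsar = fit_ols(y, design), fit_lsar(y, design)
        # whitening with rho ~ 0 barely changes the solution
        np.testing.assert_allclose(lsar.h, ols.h, atol=5e-3)

    def test_noiseless_exact_recovery(self, design, hrf):
        y = design.S @ hrf
        np.testing.assert_allclose(fit_lsar(y, design).h, hrf, atol=1e-8)

    def test_whitened_residual_autocorrelation_shrinks(self, rng):
        from mnhrf.simulate import SimulationSpec, simulate_voxel_timeseries

        lags = []
        for r in range(50):
            spec = SimulationSpec(n_trials=25, snr_db=0.0, ar_coefficient=0.4,
                                  drift_coefficients=(0.0, 1.0, 0.5, 0.2),
                                  seed=900 + r)
            y, truth = simulate_voxel_timeseries(spec)
            design = DesignSet.from_schedule(truth["schedule"], 13)
            est0 = fit_ols(y, design)
            rho = estimate_ar1(y - design.S @ est0.h - design.P @ est0.b)
            Lw = whitening_transform(rho, len(y)).transform
            est = fit_ols(Lw @ y, DesignSet(
                S=Lw @ design.S, P=np.linalg.qr(Lw @ design.P)[0],
                D=design.D, C=design.C, L=13, tr=2.0))
            resid = Lw @ y - Lw @ design.S @ est.h - Lw @ design.P @ np.linalg.lstsq(
                Lw @ design.P, Lw @ y - Lw @ design.S @ est.h, rcond=None)[0]
            lags.append(abs(estimate_ar1(resid)))
        assert np.mean(lags) < 0.1


class TestMixedNorm:
    def test_unregularized_limit_equals_ols(self, design, hrf, rng):
        y = design.S @ hrf + 0.1 * rng.standard_normal(design.n_volumes)
        np.testing.assert_allclose(fit_mn(y, design, 0.0, 0.0).h,
                                   fit_ols(y, design).h, atol=1e-8)

    def test_matches_numeric_minimizer_bfgs(self, rng):
        design, y = random_problem(rng, n_min=75, n_max=85, l_max=10)
        delta, gamma = 2.0, 3.0
        est = fit_mn(y, design, delta, gamma)
        res = optimize.minimize(
            mn_objective, np.zeros(design.L + 4),
            args=(design.S, design.P, design.D, design.C, y, delta, gamma),
            method="BFGS", options={"gtol": 1e-12, "maxiter": 5000},
        )
        np.testing.assert_allclose(est.h, res.x[:design.L], atol=1e-6)

    def test_matches_augmented_lstsq_on_random_problems(self, rng):
        for _ in range(50):
            design, y = random_problem(rng)
            delta, gamma = 10.0 * rng.random(2)
            est = fit_mn(y, design, delta, gamma)
            h_ref, _ = augmented_lstsq_minimizer(design, y, delta, gamma)
            np.testing.assert_allclose(est.h, h_ref, atol=1e-6)

    def test_large_gamma_pins_onset_and_tail(self, design, hrf, rng):
        y = design.S @ hrf + 0.1 * rng.standard_normal(design.n_volumes)
        h = fit_mn(y, design, 1.0, 1e6).h
        tail = np.arange(design.L) * design.tr > design.t_base
        assert abs(h[0]) < 1e-3
        assert np.all(np.abs(h[tail]) < 1e-3)

    def test_penalty_monotonicity_in_weights(self, design, rng):
        y = rng.standard_normal(design.n_volumes)
        deltas = [0.0, 0.1, 1.0, 10.0, 100.0]
        smooth = [np.sum((design.D @ fit_mn(y, design, d, 0.5).h) ** 2)
                  for d in deltas]
        assert np.all(np.diff(smooth) <= 1e-10)
        gammas = [0.0, 0.1, 1.0, 10.0, 100.0]
        shape = [np.sum((design.C @ fit_mn(y, design, 0.5, g).h) ** 2)
                 for g in gammas]
        assert np.all(np.diff(shape) <= 1e-10)


class TestTikhonov:
    def test_zero_delta_equals_ols(self, design, rng):
        y = rng.standard_normal(design.n_volumes)
        np.testing.assert_allclose(fit_tikhonov(y, design, 0.0).h,
                                   fit_ols(y, design).h, atol=1e-8)

    def test_nests_in_mixed_norm(self, rng):
        for _ in range(20):
            design, y = random_problem(rng)
            delta = 10.0 * rng.random()
            np.testing.assert_allclose(fit_tikhonov(y, design, delta).h,
                                       fit_mn(y, design, delta, 0.0).h,
                                       atol=1e-10)

    def test_identity_penalty_closed_form(self, rng):
        # ridge special case: D = I, no drift basis -> (A'A + d^2 I)^-1 A'y
        A = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        delta = 1.7
        # build a DesignSet whose projector is trivial (P has 1 column of
        # zeros is invalid; use an orthonormal column orthogonal to data)
        q = np.linalg.qr(rng.standard_normal((40, 1)))[0]
        y_perp = y - q @ (q.T @ y)
        design = DesignSet(S=A, P=q, D=np.eye(6), C=np.zeros((6, 6)),
                           L=6, tr=2.0)
        h = fit_mn(y_perp, design, delta, 0.0).h
        J = np.eye(40) - q @ q.T
        expected = np.linalg.solve(A.T @ J @ A + delta ** 2 * np.eye(6),
                                   A.T @ J @ y_perp)
        np.testing.assert_allclose(h, expected, atol=1e-10)


class TestRegularizationSelection:
    def test_single_element_grids(self, design, rng):
        y = rng.standard_normal(design.n_volumes)
        cfg = EstimatorConfig(delta_grid=(0.3,), gamma_grid=(0.7,))
        assert select_regularization(y, design, cfg) == (0.3, 0.7)

    def test_noiseless_data_selects_zero(self, design, hrf):
        y = design.S @ hrf
        cfg = EstimatorConfig(delta_grid=(0.0, 1.0, 10.0),
                              gamma_grid=(0.0, 1.0, 10.0))
        assert select_regularization(y, design, cfg) == (0.0, 0.0)

    def test_selected_pair_minimizes_heldout_error(self, design, hrf, rng):
        y = design.S @ hrf + 0.5 * rng.standard_normal(design.n_volumes)
        grid = (0.1, 1.0, 10.0)
        est = HRFRegressorMixedNormCV(delta_grid=grid, gamma_grid=grid,
                                      selection="kfold").fit(design, y)
        # exhaustive oracle over the 9 candidates
        from mnhrf.estimators import _kfold_prediction_error

        pairs = [(d, g) for d in grid for g in grid]
        errs = _kfold_prediction_error(design, y, pairs, 5)
        assert (est.delta_, est.gamma_) == pairs[int(np.argmin(errs))]
        assert est.scores_[np.argmin(est.scores_)] == errs.min()

    def test_gcv_rule_runs_and_is_deterministic(self, design, hrf, rng):
        y = design.S @ hrf + 0.5 * rng.standard_normal(design.n_volumes)
        cfg = EstimatorConfig(selection_rule="GCV",
                              delta_grid=(0.1, 1.0), gamma_grid=(0.1, 1.0))
        assert (select_regularization(y, design, cfg)
                == select_regularization(y, design, cfg))


def test_sklearn_protocol(design, hrf, rng):
    """Estimators expose get_params/set_params/predict and fitted attrs."""
    y = design.S @ hrf + 0.1 * rng.standard_normal(design.n_volumes)
    est = HRFRegressorMixedNorm(delta=1.0, gamma=2.0)
    assert est.get_params() == {"delta": 1.0, "gamma": 2.0}
    est.set_params(gamma=0.5).fit(design, y)
    assert est.h_.shape == (design.L,)
    pred = est.predict(design)
    assert pred.shape == y.shape
    # clone-compatibility
    from sklearn.base import clone

    est2 = clone(est)
    assert est2.get_params() == est.get_params()
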