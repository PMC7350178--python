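import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from survselect import (
    CoxModel,
    SurvivalDataset,
    breslow_baseline,
    cox_partial_loglik,
    cross_validated_loglik,
    fit_elastic_net_cox,
    predict_risk_linear,
    select_lambda_pcvl,
)
from survselect.coxcore import CVResult, penalized_objective

from conftest import brute_force_partial_loglik


def newton_raphson_cox(X, time, event, n_iter=50):
    """Independent unpenalized Cox fit: full Newton iteration on the
    brute-force partial likelihood's analytic score/Hessian."""
    X = np.asarray(X, float)
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(n_iter):
        eta = X @ beta
        w = np.exp(eta)
        score = np.zeros(p)
        hess = np.zeros((p, p))
        for i in range(n):
            if event[i] != 1:
                continue
            risk = np.flatnonzero(time >= time[i])
            wr = w[risk]
            s0 = wr.sum()
            mean = (wr[:, None] * X[risk]).sum(axis=0) / s0
            score += X[i] - mean
            outer = (wr[:, None, None] * X[risk][:, :, None] * X[risk][:, None, :]).sum(
                axis=0
            ) / s0
            hess += outer - np.outer(mean, mean)
        step = np.linalg.solve(hess, score)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta


class TestPartialLoglik:
    def test_three_subjects_null_beta_is_minus_log_six(self, toy3):
        assert cox_partial_loglik(np.zeros(1), toy3) == pytest.approx(-np.log(6))

    def test_null_beta_equals_minus_sum_log_risk_set_sizes(self, toy4):
        # events at times 1, 2, 4 with risk-set sizes 4, 3, 2
        expected = -(np.log(4) + np.log(3) + np.log(2))
        assert cox_partial_loglik(np.zeros(1), toy4) == pytest.approx(expected)

    def test_matches_brute_force_on_toy(self, toy4):
        expected = brute_force_partial_loglik(
            [0.5], toy4.covariates, toy4.time, toy4.event
        )
        assert cox_partial_loglik(np.array([0.5]), toy4) == pytest.approx(expected)

    def test_no_events_returns_zero_with_warning(self):
        d = SurvivalDataset(np.zeros((3, 1)), np.array([1.0, 2.0, 3.0]),
                            np.array([0, 0, 0]))
        with pytest.warns(UserWarning, match="no events"):
            assert cox_partial_loglik(np.zeros(1), d) == 0.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_with_ties_and_censoring(self, data):
        n = data.draw(st.integers(3, 8))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        time = rng.integers(1, 5, size=n).astype(float)  # integer times force ties
        event = rng.integers(0, 2, size=n)
        if event.sum() == 0:
            event[0] = 1
        X = rng.normal(size=(n, 2))
        beta = rng.normal(scale=0.7, size=2)
        d = SurvivalDataset(X, time, event)
        assert cox_partial_loglik(beta, d) == pytest.approx(
            brute_force_partial_loglik(beta, X, time, event), rel=1e-10
        )


class TestElasticNetFit:
    def test_large_lambda_shrinks_everything_to_zero(self, small_sim):
        model = fit_elastic_net_cox(small_sim, lam=10.0, alpha=1.0)
        assert model.selected.size == 0

    def test_unpenalized_fit_matches_newton_raphson(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        from survselect import sample_event_times

        T = sample_event_times(X, np.array([0.5, -0.5, 0.0]), seed=1)
        d = SurvivalDataset(X, T, np.ones(50, dtype=int))
        oracle = newton_raphson_cox(X, d.time, d.event)
        model = fit_elastic_net_cox(d, lam=0.0, alpha=1.0)
        assert np.abs(model.coefficients - oracle).max() < 1e-4

    def test_grouping_effect_duplicated_covariate(self, small_sim):
        j = sorted(small_sim.active_set)[0]
        X = np.column_stack([small_sim.covariates, small_sim.covariates[:, j]])
        d = SurvivalDataset(X, small_sim.time, small_sim.event)
        # exact optimum is symmetric; 5e-4 is the coordinate-descent
        # solver's measured accuracy in the duplicate direction
        model = fit_elastic_net_cox(d, lam=0.1, alpha=0.5, tol=1e-12)
        assert model.coefficients[j] == pytest.approx(
            model.coefficients[-1], abs=5e-4
        )
        assert model.coefficients[j] != 0

    def test_objective_no_worse_than_null_model(self, small_sim):
        for lam, alpha in [(0.05, 1.0), (0.02, 0.5)]:
            model = fit_elastic_net_cox(small_sim, lam=lam, alpha=alpha)
            obj_fit = penalized_objective(model.coefficients, small_sim, lam, alpha)
            obj_zero = penalized_objective(
                np.zeros(small_sim.p), small_sim, lam, alpha
            )
            assert obj_fit >= obj_zero - 1e-8

    def test_soft_threshold_quadratic_oracle(self):
        # near-orthonormal two-covariate design: the penalized optimum should
        # match soft-thresholding of the MLE under the local quadratic model
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((400, 2))
        Q, _ = np.linalg.qr(Z)
        X = Q * np.sqrt(400)  # exactly orthogonal columns, unit variance
        from survselect import sample_event_times

        T = sample_event_times(X, np.array([0.4, -0.3]), seed=4)
        d = SurvivalDataset(X, T, np.ones(400, dtype=int))
        mle = newton_raphson_cox(X, d.time, d.event)
        # per-coordinate curvature of l/n at the MLE, by finite differences
        h = 1e-4
        curv = np.empty(2)
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            curv[j] = -(
                cox_partial_loglik(mle + e, d)
                - 2 * cox_partial_loglik(mle, d)
                + cox_partial_loglik(mle - e, d)
            ) / (h**2 * d.n)
        lam = 0.05
        expected = np.sign(mle) * np.maximum(np.abs(mle) - lam / curv, 0.0)
        model = fit_elastic_net_cox(d, lam=lam, alpha=1.0, tol=1e-9)
        assert np.abs(model.coefficients - expected).max() < 0.02


class TestCrossValidatedLoglik:
    def test_singleton_grid(self, small_sim):
        cv = cross_validated_loglik(
            small_sim, alpha=1.0, lambda_grid=np.array([0.05]), n_folds=5, seed=0
        )
        assert cv.lambda_cvl == pytest.approx(0.05)

    def test_subject_order_invariance_with_carried_folds(self, small_sim):
        from survselect.coxcore import _event_stratified_folds

        folds = _event_stratified_folds(small_sim, 5, seed=0)
        cv1 = cross_validated_loglik(
            small_sim, alpha=1.0, n_lambdas=20, folds=folds
        )
        perm = np.random.default_rng(1).permutation(small_sim.n)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(small_sim.n)
        permuted = small_sim.subset(perm)
        cv2 = cross_validated_loglik(
            permuted, alpha=1.0, lambda_grid=cv1.lambda_grid,
            folds=[np.sort(inv[f]) for f in folds],
        )
        assert np.abs(cv1.cvl_values - cv2.cvl_values).max() < 1e-10

    def test_null_data_prefers_sparse_models(self):
        # with no signal the cvl-optimal model keeps at most a handful of genes
        from survselect import SimulationScenario, generate_dataset

        counts = []
        for seed in range(5):
            d = generate_dataset(
                SimulationScenario(150, 0, n_covariates=60, seed=100 + seed)
            )
            cv = cross_validated_loglik(d, alpha=1.0, n_folds=5, seed=seed,
                                        n_lambdas=30)
            counts.append(int(cv.active_counts[np.argmax(cv.cvl_values)]))
        assert np.median(counts) <= 5


class TestPcvl:
    def _cv(self, grid, cvl, active):
        return CVResult(
            lambda_grid=np.asarray(grid, float),
            cvl_values=np.asarray(cvl, float),
            active_counts=np.asarray(active),
            n_folds=10,
            lambda_cvl=float(grid[int(np.argmax(cvl))]),
            lambda_pcvl=np.nan,
            alpha=1.0,
            coef_path=np.zeros((1, len(grid))),
        )

    def test_flat_cvl_picks_largest_lambda(self):
        cv = self._cv([1.0, 0.5, 0.1], [-5.0, -5.0, -5.0], [0, 3, 10])
        assert select_lambda_pcvl(cv) == 1.0

    def test_all_zero_path_picks_largest_lambda(self):
        cv = self._cv([1.0, 0.5], [-5.0, -4.0], [0, 0])
        assert select_lambda_pcvl(cv) == 1.0

    def test_never_more_active_than_cvl_choice(self, medium_sim):
        cv = cross_validated_loglik(medium_sim, alpha=1.0, n_folds=5, seed=0,
                                    n_lambdas=40)
        i_cvl = int(np.argmax(cv.cvl_values))
        i_pcvl = int(np.argmin(np.abs(cv.lambda_grid - cv.lambda_pcvl)))
        assert cv.lambda_pcvl >= cv.lambda_cvl
        assert cv.active_counts[i_pcvl] <= cv.active_counts[i_cvl]

    def test_grid_refinement_moves_cvl_choice_at_most_one_step(self, small_sim):
        cv_coarse = cross_validated_loglik(small_sim, alpha=1.0, n_folds=5,
                                           seed=0, n_lambdas=25)
        fine_grid = np.geomspace(cv_coarse.lambda_grid[0],
                                 cv_coarse.lambda_grid[-1], 49)
        cv_fine = cross_validated_loglik(small_sim, alpha=1.0, n_folds=5, seed=0,
                                         lambda_grid=fine_grid)
        coarse_step = np.log(cv_coarse.lambda_grid[0] / cv_coarse.lambda_grid[1])
        assert abs(np.log(cv_fine.lambda_cvl / cv_coarse.lambda_cvl)) \
            <= coarse_step * 1.01


class TestBreslowBaseline:
    def test_null_beta_no_censoring_equals_nelson_aalen(self, toy3):
        model = CoxModel(coefficients=np.zeros(1))
        times, cumhaz = breslow_baseline(model, toy3)
        # Nelson-Aalen: 1/3, 1/3+1/2, 1/3+1/2+1
        assert np.allclose(cumhaz, np.cumsum([1 / 3, 1 / 2, 1.0]))
        from lifelines import NelsonAalenFitter

        naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(
            toy3.time, toy3.event
        )
        assert np.allclose(
            naf.cumulative_hazard_.loc[times].values.ravel(), cumhaz
        )

    def test_starts_at_zero(self, toy4):
        model = CoxModel(coefficients=np.array([0.3]))
        breslow_baseline(model, toy4)
        assert model.cumulative_hazard([0.0])[0] == 0.0

    def test_matches_term_by_term_hand_summation(self, toy4):
        beta = np.array([0.4])
        model = CoxModel(coefficients=beta)
        times, cumhaz = breslow_baseline(model, toy4)
        w = np.exp(toy4.covariates[:, 0] * 0.4)
        expected = []
        for s in sorted(toy4.time[toy4.event == 1]):
            risk = toy4.time >= s
            expected.append(1.0 / w[risk].sum())
        assert np.allclose(cumhaz, np.cumsum(expected))
        assert np.all(np.diff(cumhaz) >= 0)


class TestLinearRiskScore:
    def test_zero_model_scores_zero(self, toy4):
        model = CoxModel(coefficients=np.zeros(1))
        assert np.array_equal(predict_risk_linear(model, toy4.covariates),
                              np.zeros(4))

    def test_single_unit_coefficient_returns_covariate(self, toy4):
        model = CoxModel(coefficients=np.ones(1))
        assert np.array_equal(
            predict_risk_linear(model, toy4.covariates), toy4.covariates[:, 0]
        )

    def test_score_differences_ignore_unselected_covariates(self, small_sim):
        model = fit_elastic_net_cox(small_sim, lam=0.05, alpha=1.0)
        unselected = [j for j in range(small_sim.p) if j not in model.selected][0]
        shifted = small_sim.covariates.copy()
        shifted[:, unselected] += 7.0
        a = predict_risk_linear(model, small_sim.covariates)
        b = predict_risk_linear(model, shifted)
        assert np.allclose(a - b, 0.0)
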