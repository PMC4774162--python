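"""Kaplan-Meier estimation, conditional-mean imputation, penalized AFT fits."""

import numpy as np
import pytest

from semisurv import (
    AFTL12,
    SurvivalDataset,
    cv_tune_aft,
    fit_aft_l12,
    km_estimator,
    km_mean_impute,
    predict_log_time,
    stratified_kfold,
)


class TestKMEstimator:
    def test_hand_product_limit(self, toy_km_dataset):
        km = km_estimator(toy_km_dataset.time, toy_km_dataset.status)
        np.testing.assert_allclose(km.event_times, [1, 3, 4])
        np.testing.assert_allclose(km.surv, [0.75, 0.375, 0.0], atol=1e-12)
        np.testing.assert_allclose(km.steps, [0.25, 0.375, 0.375], atol=1e-12)

    def test_no_censoring_is_empirical_survivor(self):
        km = km_estimator(np.array([1, 2, 3, 4.0]), np.ones(4, int))
        np.testing.assert_allclose(km.surv, [0.75, 0.5, 0.25, 0.0], atol=1e-12)
        assert km.steps.sum() == pytest.approx(1.0)

    def test_all_censored_flat_curve(self):
        km = km_estimator(np.array([1, 2, 3.0]), np.zeros(3, int))
        assert km.event_times.size == 0
        assert km.evaluate(99.0) == 1.0

    def test_step_function_sides(self, toy_km_dataset):
        km = km_estimator(toy_km_dataset.time, toy_km_dataset.status)
        assert km.evaluate(3.0) == pytest.approx(0.375)       # right-continuous
        assert km.evaluate(3.0, side="left") == pytest.approx(0.75)
        assert km.evaluate(0.5) == 1.0


class TestImputation:
    def test_hand_value_log_scale(self, toy_km_dataset):
        res = km_mean_impute(toy_km_dataset)
        expected = (np.log(3) * 0.375 + np.log(4) * 0.375) / 0.75
        assert res.h_star[1] == pytest.approx(expected, abs=1e-12)
        assert res.was_imputed[1] and not res.undefined_tail[1]

    def test_events_pass_through(self, toy_km_dataset):
        res = km_mean_impute(toy_km_dataset)
        for i in (0, 2, 3):
            assert res.h_star[i] == pytest.approx(np.log(toy_km_dataset.time[i]))
            assert not res.was_imputed[i]

    def test_no_censoring_identity(self):
        ds = SurvivalDataset(X=np.zeros((3, 1)), time=[1, 2, 3], status=[1, 1, 1])
        res = km_mean_impute(ds)
        np.testing.assert_allclose(res.h_star, np.log(ds.time), atol=1e-12)

    def test_censored_beyond_last_event_flagged(self):
        ds = SurvivalDataset(X=np.zeros((3, 1)), time=[1, 2, 5], status=[1, 1, 0])
        res = km_mean_impute(ds)
        assert res.undefined_tail[2]
        assert res.h_star[2] == pytest.approx(np.log(2))  # last-event fallback

    def test_imputation_exceeds_censored_time(self):
        rng = np.random.default_rng(0)
        time = rng.uniform(0.5, 5, 60)
        status = rng.integers(0, 2, 60)
        status[np.argmax(time)] = 1  # keep tails defined
        ds = SurvivalDataset(X=np.zeros((60, 1)), time=time, status=status)
        res = km_mean_impute(ds)
        cens = (status == 0) & ~res.undefined_tail
        assert np.all(res.h_star[cens] > np.log(time[cens]))

    def test_tie_uses_strictly_later_events(self):
        # censored exactly at an event time: only later events enter the sum
        ds = SurvivalDataset(X=np.zeros((4, 1)), time=[1, 2, 2, 3], status=[1, 1, 0, 1])
        res = km_mean_impute(ds)
        km = km_estimator(ds.time, ds.status)
        step3 = km.steps[km.event_times == 3][0]
        expected = np.log(3) * step3 / km.evaluate(2.0)
        assert res.h_star[2] == pytest.approx(expected, abs=1e-12)


class TestAFTFit:
    def test_unpenalized_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + 0.1 * rng.standard_normal(50)
        fit = fit_aft_l12(X, y, lam=0.0)
        A = np.column_stack([np.ones(50), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert fit.intercept == pytest.approx(coef[0], abs=1e-6)
        np.testing.assert_allclose(fit.beta, coef[1:], atol=1e-6)

    def test_large_lambda_null_model(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        fit = fit_aft_l12(X, y, lam=100.0)
        assert fit.selected.size == 0
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-12)

    def test_noiseless_round_trip(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 4))
        y = X @ np.array([2.0, 0.0, -1.0, 0.5])
        fit = fit_aft_l12(X, y, lam=1e-10)
        np.testing.assert_allclose(predict_log_time(fit, X), y, atol=1e-6)

    def test_predict_constant_when_null(self):
        fit = fit_aft_l12(np.random.default_rng(4).standard_normal((20, 2)),
                          np.full(20, 1.7), lam=10.0)
        np.testing.assert_allclose(predict_log_time(fit, np.eye(2)), 1.7, atol=1e-12)

    def test_zero_censoring_pipeline_equals_penalized_ls(self, small_sim):
        ds = small_sim.dataset
        no_cens = SurvivalDataset(X=ds.X, time=ds.time, status=np.ones(ds.n_samples, int))
        res = km_mean_impute(no_cens)
        fit_pipe = fit_aft_l12(no_cens.X, res.h_star, lam=0.3)
        fit_direct = fit_aft_l12(no_cens.X, np.log(no_cens.time), lam=0.3)
        np.testing.assert_allclose(fit_pipe.beta, fit_direct.beta, atol=1e-12)


class TestAFTCVTuning:
    def test_single_lambda(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        folds = stratified_kfold(SurvivalDataset(X=X, time=np.ones(30),
                                                 status=np.ones(30, int)), K=3, seed=0)
        lam, table = cv_tune_aft(X, y, folds, [0.5])
        assert lam == 0.5

    def test_pure_noise_prefers_sparse_end(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 30))
        y = rng.standard_normal(60)
        est = AFTL12(lam="auto", n_lambdas=10, random_state=0).fit(X, y)
        assert est.lambda_ >= np.median(est.lambdas_)
        assert est.selected_.size <= 4

    def test_strong_signal_interior_minimum(self, small_sim):
        ds = small_sim.dataset
        res = km_mean_impute(ds)
        est = AFTL12(lam="auto", random_state=0).fit(ds.X, res.h_star,
                                                     loss_mask=ds.status == 1)
        cv = np.asarray(est.cv_scores_)
        assert np.argmin(cv) > 0  # not the null end of the path
        hits = len(set(est.selected_) & set(small_sim.true_support))
        assert hits >= 3
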