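"""L1/2 Cox model: partial likelihood, IRLS fitting, baseline, risk classes."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from semisurv import (
    CoxL12,
    SurvivalDataset,
    classify_risk,
    cox_partial_loglik,
    cv_tune_cox,
    fit_cox_l12,
    stratified_kfold,
)
from semisurv.cox import _breslow


def naive_partial_loglik(beta, ds):
    """Direct double-loop Breslow evaluation, independent of the package path."""
    eta = ds.X @ np.asarray(beta, float)
    total = 0.0
    for i in range(ds.n_samples):
        if ds.status[i] != 1:
            continue
        risk = np.flatnonzero(ds.time >= ds.time[i])
        total += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return total / ds.n_samples


class TestPartialLoglik:
    def test_null_three_events(self):
        ds = SurvivalDataset(X=np.zeros((3, 2)), time=[1, 2, 3], status=[1, 1, 1])
        expected = (np.log(1 / 3) + np.log(1 / 2) + np.log(1.0)) / 3
        assert cox_partial_loglik(np.zeros(2), ds) == pytest.approx(expected, abs=1e-12)

    def test_all_censored_is_zero(self):
        ds = SurvivalDataset(X=np.zeros((4, 1)), time=[1, 2, 3, 4], status=[0, 0, 0, 0])
        assert cox_partial_loglik(np.zeros(1), ds) == 0.0

    def test_matches_naive_evaluation(self):
        x = np.array([[0.5], [-1.2], [0.3], [2.0], [-0.7]])
        ds = SurvivalDataset(X=x, time=[2, 5, 1, 4, 3], status=[1, 0, 1, 1, 1])
        beta = np.array([0.8])
        assert cox_partial_loglik(beta, ds) == pytest.approx(
            naive_partial_loglik(beta, ds), abs=1e-10)

    def test_matches_naive_with_ties(self):
        x = np.array([[0.5], [-1.2], [0.3], [2.0], [-0.7], [0.1]])
        ds = SurvivalDataset(X=x, time=[2, 2, 1, 4, 3, 3], status=[1, 1, 1, 0, 1, 1])
        beta = np.array([-0.6])
        assert cox_partial_loglik(beta, ds) == pytest.approx(
            naive_partial_loglik(beta, ds), abs=1e-10)

    def test_centering_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        ds1 = SurvivalDataset(X=X, time=rng.uniform(1, 5, 20),
                              status=rng.integers(0, 2, 20))
        ds2 = SurvivalDataset(X=X + 7.0, time=ds1.time, status=ds1.status)
        beta = np.array([0.3, -0.4, 0.1])
        assert cox_partial_loglik(beta, ds1) == pytest.approx(
            cox_partial_loglik(beta, ds2), abs=1e-10)


class TestFit:
    def test_unpenalized_matches_lifelines(self, lowdim_sim):
        ds = lowdim_sim.dataset
        est = CoxL12(lam=0.0).fit(ds.X, time=ds.time, status=ds.status)
        df = pd.DataFrame(ds.X, columns=["a", "b", "c"])
        df["T"], df["E"] = ds.time, ds.status
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(est.coef_, cph.params_.values, atol=1e-3)

    def test_large_lambda_gives_null_model(self, lowdim_sim):
        ds = lowdim_sim.dataset
        est = CoxL12(lam=50.0).fit(ds.X, time=ds.time, status=ds.status)
        assert est.selected_.size == 0
        assert cox_partial_loglik(est.coef_, ds) == pytest.approx(
            cox_partial_loglik(np.zeros(3), ds), abs=1e-12)

    def test_no_events_fails(self):
        ds = SurvivalDataset(X=np.zeros((4, 2)), time=[1, 2, 3, 4], status=[0] * 4)
        with pytest.raises(ValueError, match="event"):
            CoxL12(lam=1.0).fit(ds.X, time=ds.time, status=ds.status)

    def test_cv_recovers_signal_support(self, small_sim):
        ds = small_sim.dataset
        est = CoxL12(lam="auto", random_state=0).fit(ds.X, time=ds.time,
                                                     status=ds.status)
        assert est.selected_.size > 0
        # most selected features should be informative at this signal strength
        hits = len(set(est.selected_) & set(small_sim.true_support))
        assert hits >= 3


class TestBreslowBaseline:
    def test_null_equals_nelson_aalen(self):
        ds = SurvivalDataset(X=np.zeros((4, 1)), time=[1, 2, 3, 4], status=[1, 1, 1, 1])
        times, cumhaz = _breslow(np.zeros(4), ds.time, ds.status)
        # Nelson-Aalen: 1/4, 1/4+1/3, ...
        np.testing.assert_allclose(
            cumhaz, np.cumsum([1 / 4, 1 / 3, 1 / 2, 1 / 1]), atol=1e-12)

    def test_hand_computation_with_covariates(self):
        x = np.array([[1.0], [0.0], [-1.0], [0.5]])
        ds = SurvivalDataset(X=x, time=[1, 2, 3, 4], status=[1, 1, 0, 1])
        beta = np.array([0.5])
        eta = (x @ beta).ravel()
        e = np.exp(eta)
        expected = [1 / e.sum(), 1 / e.sum() + 1 / e[1:].sum(),
                    1 / e.sum() + 1 / e[1:].sum() + 1 / e[3]]
        fit = fit_cox_l12(ds, lam=0.0)
        # force the hand beta to isolate the baseline formula
        fit.beta = beta
        fit.intercept_shift = 0.0
        from semisurv import breslow_baseline

        times, cumhaz = breslow_baseline(fit, ds)
        np.testing.assert_allclose(times, [1, 2, 4])
        np.testing.assert_allclose(cumhaz, expected, atol=1e-12)

    def test_survival_starts_at_one(self, lowdim_sim):
        ds = lowdim_sim.dataset
        est = CoxL12(lam=0.0).fit(ds.X, time=ds.time, status=ds.status)
        S = est.predict_survival_function(ds.X[:5], [0.0])
        np.testing.assert_allclose(S, 1.0, atol=1e-12)


class TestRiskClasses:
    def test_median_split(self):
        ds = SurvivalDataset(X=np.array([[-2.], [-1.], [1.], [2.]]),
                             time=[1, 2, 3, 4], status=[1, 1, 1, 1])
        fit = fit_cox_l12(ds, lam=0.0)
        fit.beta = np.array([1.0])
        fit.intercept_shift = 0.0
        part = classify_risk(fit, ds)
        assert list(part.labels) == ["low", "low", "high", "high"]

    def test_empty_model_fails(self, lowdim_sim):
        ds = lowdim_sim.dataset
        fit = fit_cox_l12(ds, lam=50.0)
        with pytest.raises(ValueError, match="lambda"):
            classify_risk(fit, ds)

    def test_high_class_has_higher_event_rate(self, small_sim):
        ds = small_sim.dataset
        fit = fit_cox_l12(ds, lam="auto", random_state=0)
        part = classify_risk(fit, ds)
        hi = ds.status[part.labels == "high"].mean()
        lo = ds.status[part.labels == "low"].mean()
        assert hi > lo


class TestCVTuning:
    def test_single_candidate_returned(self, lowdim_sim):
        ds = lowdim_sim.dataset
        folds = stratified_kfold(ds, K=3, seed=0)
        lam, table = cv_tune_cox(ds, folds, [0.25])
        assert lam == 0.25 and len(table["lambda"]) == 1

    def test_pure_noise_prefers_sparse_end(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((80, 40))
        ds = SurvivalDataset(X=X, time=rng.uniform(0.5, 4, 80),
                             status=rng.integers(0, 2, 80))
        est = CoxL12(lam="auto", n_lambdas=10, random_state=0)
        est.fit(ds.X, time=ds.time, status=ds.status)
        # on noise the selected penalty sits in the top (sparse) half of the grid
        assert est.lambda_ >= np.median(est.lambdas_)
        assert est.selected_.size <= 5
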