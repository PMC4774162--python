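"""Kaplan-Meier imputation and the L1/2-penalized accelerated failure time model.

The AFT model regresses a monotone transform of the survival time (here the
log) linearly on covariates: h(t_i) = beta_0 + x_i' beta + eps_i. Censored
responses cannot enter least squares directly, so each censored h(t_i) is
replaced by its Kaplan-Meier conditional mean

    h(t_i*) = S(t_i)^{-1} * sum_{t_(r) > t_i} h(t_(r)) * dS(t_(r)),

the survivor-weighted average of the transformed event times beyond t_i. A
censored sample with no later event time has an empty sum; it receives the
last event time as the conventional redistribute-to-the-right fallback and is
flagged ``undefined_tail`` so callers may exclude it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import FoldAssignment, SurvivalDataset, standardize_features, stratified_kfold
from .solver import PenalizedProblem, coordinate_descent, lambda_path

__all__ = [
    "KMCurve",
    "AFTFit",
    "ImputationResult",
    "AFTL12",
    "km_estimator",
    "km_mean_impute",
    "fit_aft_l12",
    "predict_log_time",
    "cv_tune_aft",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate, reduced to its jumps.

    ``event_times`` are the distinct times with at least one event, ``surv``
    the Kaplan-Meier estimate just after each, and ``steps`` the drops
    S(t_(r-1)) - S(t_(r)) used as imputation weights.
    """

    event_times: np.ndarray
    surv: np.ndarray
    steps: np.ndarray

    def evaluate(self, t, side: str = "right"):
        """S(t); right-continuous by default, ``side="left"`` gives S(t-)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side=side) - 1
        s = np.where(idx >= 0, np.concatenate(([1.0], self.surv))[idx + 1], 1.0)
        return float(s) if s.ndim == 0 else s


def km_estimator(time, status) -> KMCurve:
    """Kaplan-Meier curve of (time, status); censoring shrinks risk sets only."""
    time = np.asarray(time, float)
    status = np.asarray(status, int)
    if time.size == 0:
        raise ValueError("empty sample")
    if status.sum() == 0:
        return KMCurve(event_times=np.array([]), surv=np.array([]), steps=np.array([]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf = KaplanMeierFitter().fit(time, status)
    ev = np.unique(time[status == 1])
    surv = kmf.survival_function_at_times(ev).to_numpy()
    prev = np.concatenate(([1.0], surv[:-1]))
    return KMCurve(event_times=ev, surv=surv, steps=prev - surv)


@dataclass
class ImputationResult:
    """Observed/imputed responses on the h-scale."""

    h_star: np.ndarray
    was_imputed: np.ndarray
    undefined_tail: np.ndarray


def km_mean_impute(ds: SurvivalDataset, h=np.log, km: KMCurve = None) -> ImputationResult:
    """Replace censored responses by their KM conditional means on the h scale.

    Events pass through as h(t_i). ``km`` may supply an externally estimated
    curve (e.g. a within-risk-class curve); it defaults to the curve of
    ``ds`` itself.
    """
    if km is None:
        km = km_estimator(ds.time, ds.status)
    return _impute_against_curve(ds.time, ds.status, km, h)


def _impute_against_curve(time, status, km: KMCurve, h=np.log) -> ImputationResult:
    time = np.asarray(time, float)
    status = np.asarray(status, int)
    n = len(time)
    h_star = np.where(status == 1, h(time), np.nan)
    was_imputed = np.zeros(n, dtype=bool)
    undefined = np.zeros(n, dtype=bool)
    ev, steps = km.event_times, km.steps
    h_ev = h(ev) if len(ev) else np.array([])
    for i in np.flatnonzero(status == 0):
        later = ev > time[i]  # strictly later events only
        if not later.any():
            undefined[i] = True
            h_star[i] = h_ev[-1] if len(ev) else np.nan
            was_imputed[i] = len(ev) > 0
            continue
        s_ti = km.evaluate(time[i])
        h_star[i] = float(np.dot(h_ev[later], steps[later]) / s_ti)
        was_imputed[i] = True
    return ImputationResult(h_star=h_star, was_imputed=was_imputed, undefined_tail=undefined)


@dataclass
class AFTFit:
    """A fitted L1/2 AFT model on the original feature scale."""

    intercept: float
    beta: np.ndarray
    lam: float
    selected: np.ndarray
    standardization: object = None
    cv_table: object = None

    def predict(self, X) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.beta


class AFTL12(BaseEstimator, RegressorMixin):
    """L1/2-penalized least squares for log survival times.

    ``fit(X, h)`` expects a complete (already imputed) response vector on the
    h scale. The intercept is the response mean (features are centered); the
    slopes come from half-threshold coordinate descent on standardized
    features and are returned on the original scale.

    When ``lam="auto"`` the penalty minimizes K-fold held-out mean squared
    error on the h scale; ``loss_mask`` restricts the held-out loss to
    trustworthy responses (observed events or validated imputations) so that
    tuning never scores predictions against fabricated targets. Ties prefer
    the larger (sparser) lambda.
    """

    def __init__(self, lam="auto", n_lambdas=15, lambda_min_ratio=0.05, cv=5,
                 tol_cd=1e-5, max_sweeps=10_000, random_state=0):
        self.lam = lam
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.tol_cd = tol_cd
        self.max_sweeps = max_sweeps
        self.random_state = random_state

    def _path(self, Xs, yc, lambdas):
        betas = np.zeros((len(lambdas), Xs.shape[1]))
        beta = np.zeros(Xs.shape[1])
        for i, lam in enumerate(lambdas):
            res = coordinate_descent(PenalizedProblem(X=Xs, y=yc, lam=lam),
                                     beta_init=beta, tol=self.tol_cd,
                                     max_sweeps=self.max_sweeps)
            beta = res.beta
            betas[i] = beta
        return betas

    def fit(self, X, y, *, loss_mask=None, strata=None):
        """Fit on (X, h_star); see class docstring for ``loss_mask``.

        ``strata`` (0/1 per sample) controls fold stratification; it defaults
        to ``loss_mask`` so every fold holds out scoreable samples.
        """
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite responses; impute before fitting")
        ds_like = SurvivalDataset(X=X, time=np.ones(len(y)),
                                  status=np.ones(len(y), int))
        std, params = standardize_features(ds_like)
        Xs = np.ascontiguousarray(std.X)
        mask = np.ones(len(y), bool) if loss_mask is None else np.asarray(loss_mask, bool)
        if self.lam == "auto":
            yc = y - y.mean()
            lambdas = lambda_path(Xs, yc, self.n_lambdas, self.lambda_min_ratio)
            strat = mask.astype(int) if strata is None else np.asarray(strata, int)
            folds = stratified_kfold(
                SurvivalDataset(X=np.zeros((len(y), 1)), time=np.ones(len(y)), status=strat),
                K=self.cv, seed=self.random_state)
            sse = np.zeros(len(lambdas))
            cnt = np.zeros(len(lambdas))
            for k in range(folds.K):
                tr, te = folds.train_test(k)
                te = te[mask[te]]
                if te.size == 0:
                    continue
                mu = y[tr].mean()
                betas = self._path(Xs[tr], y[tr] - mu, lambdas)
                pred = betas @ Xs[te].T + mu
                sse += np.sum((pred - y[te]) ** 2, axis=1)
                cnt += te.size
            cv_mse = sse / np.maximum(cnt, 1)
            best = int(np.argmin(cv_mse))  # descending grid: first min = largest lam
            lam = float(lambdas[best])
            self.lambdas_ = lambdas
            self.cv_scores_ = cv_mse
            beta_std = self._path(Xs, yc, lambdas[: best + 1])[-1]
        else:
            lam = float(self.lam)
            self.lambdas_ = np.array([lam])
            self.cv_scores_ = None
            res = coordinate_descent(PenalizedProblem(X=Xs, y=y - y.mean(), lam=lam),
                                     tol=self.tol_cd, max_sweeps=self.max_sweeps)
            beta_std = res.beta
        self.lambda_ = lam
        self.coef_, shift = params.invert_coef(beta_std, X.shape[1])
        self.intercept_ = float(y.mean() + shift)
        self.selected_ = np.flatnonzero(self.coef_)
        self.standardization_ = params
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted response on the h (log-time) scale."""
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X, float) @ self.coef_

    def _to_fit(self) -> AFTFit:
        cv_table = None
        if getattr(self, "cv_scores_", None) is not None:
            cv_table = {"lambda": self.lambdas_.tolist(),
                        "cv_mse": self.cv_scores_.tolist()}
        return AFTFit(intercept=self.intercept_, beta=self.coef_, lam=self.lambda_,
                      selected=self.selected_, standardization=self.standardization_,
                      cv_table=cv_table)


def fit_aft_l12(X, h_star, lam, **kwargs) -> AFTFit:
    """Penalized least-squares AFT fit at a fixed penalty (or "auto")."""
    est = AFTL12(lam=lam, **kwargs).fit(X, h_star)
    return est._to_fit()


def predict_log_time(fit: AFTFit, X) -> np.ndarray:
    """beta_0 + x'beta on the h scale; exponentiate for the time scale."""
    return fit.predict(X)


def cv_tune_aft(X, h_star, folds: FoldAssignment, lambdas, loss_mask=None):
    """Held-out h-scale MSE over a fixed grid; ties -> larger lambda."""
    X = np.asarray(X, float)
    y = np.asarray(h_star, float)
    std, _ = standardize_features(SurvivalDataset(
        X=X, time=np.ones(len(y)), status=np.ones(len(y), int)))
    Xs = np.ascontiguousarray(std.X)
    mask = np.ones(len(y), bool) if loss_mask is None else np.asarray(loss_mask, bool)
    lambdas = np.asarray(lambdas, float)
    lambdas = lambdas[np.argsort(-lambdas)]
    est = AFTL12()
    sse = np.zeros(len(lambdas))
    cnt = np.zeros(len(lambdas))
    for k in range(folds.K):
        tr, te = folds.train_test(k)
        te = te[mask[te]]
        if te.size == 0:
            continue
        mu = y[tr].mean()
        betas = est._path(Xs[tr], y[tr] - mu, lambdas)
        pred = betas @ Xs[te].T + mu
        sse += np.sum((pred - y[te]) ** 2, axis=1)
        cnt += te.size
    cv_mse = sse / np.maximum(cnt, 1)
    best = int(np.argmin(cv_mse))
    return float(lambdas[best]), {"lambda": lambdas.tolist(), "cv_mse": cv_mse.tolist()}
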