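"""L1/2-penalized Cox proportional hazards model.

The negative log partial likelihood is minimized by iteratively reweighted
least squares: at the current linear predictor eta = X beta the gradient and
diagonal Hessian with respect to eta define a weighted working response, and
the resulting penalized least-squares problem is solved by the half-threshold
coordinate descent of :mod:`semisurv.solver`. Ties are handled by the Breslow
convention throughout, including the Breslow baseline cumulative hazard used
to turn a fit into predicted survival curves.

Penalty tuning follows the cross-validated partial likelihood of Verweij and
van Houwelingen: for each fold, cvl_k = l_full(beta_{-k}) - l_{-k}(beta_{-k});
the selected lambda maximizes the sum over folds, with ties broken toward the
larger (sparser) lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datasets import FoldAssignment, SurvivalDataset, standardize_features, stratified_kfold
from .solver import PenalizedProblem, coordinate_descent, lambda_max

__all__ = [
    "CoxFit",
    "RiskPartition",
    "CoxL12",
    "cox_partial_loglik",
    "fit_cox_l12",
    "breslow_baseline",
    "classify_risk",
    "cv_tune_cox",
]

_MIN_WEIGHT = 1e-8


def _partial_loglik_eta(eta, time, status, normalize=True):
    """Breslow log partial likelihood at linear predictor eta.

    (1/n) sum_{i in D} [eta_i - log sum_{j: t_j >= t_i} exp(eta_j)]
    (unnormalized sum when ``normalize`` is False). Guarded by
    max-subtraction against overflow.
    """
    eta = np.asarray(eta, float)
    n = len(eta)
    if status.sum() == 0:
        return 0.0
    order = np.argsort(-time, kind="stable")  # descending time
    e = eta[order]
    m = e.max()
    # log of suffix risk-set sums via cumulative sum over descending times
    csum = np.maximum(np.cumsum(np.exp(e - m)), 1e-300)  # underflow guard
    log_risk_desc = m + np.log(csum)
    t_desc = time[order]
    # with ties, every event at time t uses the risk set {t_j >= t}: take the
    # last index among equal times in the descending order
    last_of_tie = np.searchsorted(-t_desc, -t_desc, side="right") - 1
    log_risk = log_risk_desc[last_of_tie]
    d = status[order] == 1
    ll = float(np.sum(e[d] - log_risk[d]))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite partial likelihood")
    return ll / n if normalize else ll


def cox_partial_loglik(beta, ds: SurvivalDataset) -> float:
    """Normalized Breslow log partial likelihood at coefficient vector beta."""
    beta = np.asarray(beta, float)
    return _partial_loglik_eta(ds.X @ beta, ds.time, ds.status)


def _irls_weights(eta, time, status):
    """Gradient g_i and diagonal Hessian w_i of the log partial likelihood wrt eta.

    Breslow form: with S_r = sum_{j in R_r} exp(eta_j) over event times t_(r),
      g_i = delta_i - exp(eta_i) * A_i,   A_i = sum_{r: t_(r) <= t_i} d_r / S_r
      w_i = exp(eta_i) * A_i - exp(2 eta_i) * B_i,  B_i = sum d_r / S_r^2.
    """
    n = len(eta)
    m = eta.max()
    ex = np.exp(eta - m)
    order = np.argsort(-time, kind="stable")
    t_desc = time[order]
    csum = np.cumsum(ex[order])
    last_of_tie = np.searchsorted(-t_desc, -t_desc, side="right") - 1
    risk_desc = csum[last_of_tie]  # S_r / e^m at each sample's time
    # event times and counts, ascending
    ev_desc = status[order] == 1
    inv_s = np.zeros(n)
    inv_s2 = np.zeros(n)
    inv_s[ev_desc] = 1.0 / risk_desc[ev_desc]
    inv_s2[ev_desc] = 1.0 / risk_desc[ev_desc] ** 2
    # A_i = sum over event times <= t_i: in descending order that is a suffix sum
    A_desc = np.cumsum(inv_s[::-1])[::-1]
    B_desc = np.cumsum(inv_s2[::-1])[::-1]
    # but events tied with t_i count as <= t_i: take suffix starting at the
    # first index of the tie block
    first_of_tie = np.searchsorted(-t_desc, -t_desc, side="left")
    A_i = A_desc[first_of_tie]
    B_i = B_desc[first_of_tie]
    g = np.empty(n)
    w = np.empty(n)
    exo = ex[order]
    # the e^m scaling cancels: A_i, B_i carry 1/S_r in units of e^m, exo in e^-m
    g[order] = status[order] - exo * A_i
    w[order] = exo * A_i - exo**2 * B_i
    np.clip(w, _MIN_WEIGHT, None, out=w)
    return g, w


@dataclass
class CoxFit:
    """A fitted L1/2 Cox model on the original feature scale."""

    beta: np.ndarray
    intercept_shift: float
    lam: float
    selected: np.ndarray
    baseline_times: np.ndarray = None
    baseline_cumhaz: np.ndarray = None
    standardization: object = None
    cv_table: object = None

    def linear_predictor(self, X) -> np.ndarray:
        """eta on the scale used during fitting (standardized features)."""
        return np.asarray(X, float) @ self.beta + self.intercept_shift

    def survival_function(self, X, times) -> np.ndarray:
        """S(t|x) = exp(-H0(t) exp(eta)); rows = samples, cols = times."""
        if self.baseline_times is None:
            raise ValueError("no baseline hazard attached; call breslow_baseline first")
        eta = self.linear_predictor(X)
        idx = np.searchsorted(self.baseline_times, np.asarray(times, float), side="right") - 1
        H0 = np.where(idx >= 0, self.baseline_cumhaz[np.maximum(idx, 0)], 0.0)
        return np.exp(-np.outer(np.exp(eta), H0))


@dataclass
class RiskPartition:
    """Low/high prognostic classes from the Cox linear predictor."""

    scores: np.ndarray
    labels: np.ndarray  # "low" / "high"
    threshold: float


class CoxL12(BaseEstimator):
    """L1/2-regularized Cox proportional hazards estimator.

    Parameters
    ----------
    lam : float or "auto"
        Penalty weight; "auto" tunes by K-fold cross-validated partial
        likelihood over a log-spaced path.
    n_lambdas, lambda_min_ratio : path geometry used when ``lam="auto"``.
    cv : int
        Number of folds, stratified on the event indicator.
    tol_cd, max_sweeps : inner coordinate-descent controls.
    tol_irls : convergence threshold on the max change of eta between outer
        reweighting cycles.
    max_irls : cap on outer cycles.
    random_state : fold shuffling seed.

    Attributes
    ----------
    coef_ : ndarray (p,) — coefficients on the original feature scale.
    intercept_shift_ : float — makes ``X @ coef_ + intercept_shift_`` equal the
        standardized-scale linear predictor.
    lambda_ : float — penalty actually used.
    selected_ : ndarray — indices with nonzero coefficients.
    lambdas_, cv_scores_ : the tuning path and its CV criterion (when tuned).
    baseline_times_, baseline_cumhaz_ : Breslow baseline (training data).
    """

    def __init__(self, lam="auto", n_lambdas=15, lambda_min_ratio=0.05, cv=5,
                 tol_cd=1e-5, max_sweeps=10_000, tol_irls=1e-4, max_irls=100,
                 random_state=0):
        self.lam = lam
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.tol_cd = tol_cd
        self.max_sweeps = max_sweeps
        self.tol_irls = tol_irls
        self.max_irls = max_irls
        self.random_state = random_state

    # -- internal path machinery (standardized scale) -----------------------

    def _fit_one(self, Xs, time, status, lam, beta0):
        """IRLS with step-halving safeguard; returns beta (standardized scale)."""
        beta = beta0.copy()
        eta = Xs @ beta
        n = len(time)
        pen = lambda b: lam * np.sum(np.sqrt(np.abs(b)))
        obj = -_partial_loglik_eta(eta, time, status) + pen(beta)
        for it in range(self.max_irls):
            g, w = _irls_weights(eta, time, status)
            z = eta + g / w
            try:
                res = coordinate_descent(
                    PenalizedProblem(X=Xs, y=z, lam=lam, weights=w / 2.0),
                    beta_init=beta, tol=self.tol_cd, max_sweeps=self.max_sweeps,
                )
            except FloatingPointError:
                return beta, it  # diverging inner problem: keep last finite iterate
            beta_new = res.beta
            # step-halving: the quadratic model can overshoot the nonconvex objective
            for _ in range(12):
                eta_new = Xs @ beta_new
                with np.errstate(over="ignore"):
                    obj_new = (-_partial_loglik_eta(eta_new, time, status)
                               + pen(beta_new))
                if np.isfinite(obj_new) and obj_new <= obj + 1e-10:
                    break
                beta_new = 0.5 * (beta_new + beta)
            else:
                # no improving step: accept current iterate as converged
                return beta, it
            delta = np.max(np.abs(eta_new - eta))
            beta, eta, obj = beta_new, eta_new, obj_new
            if delta < self.tol_irls:
                return beta, it + 1
        return beta, self.max_irls

    def _path(self, Xs, time, status, lambdas):
        """Warm-started fits along a descending lambda path."""
        betas = np.zeros((len(lambdas), Xs.shape[1]))
        beta = np.zeros(Xs.shape[1])
        for i, lam in enumerate(lambdas):
            beta, _ = self._fit_one(Xs, time, status, lam, beta)
            betas[i] = beta
        return betas

    def _lambda_grid(self, Xs, time, status):
        g, w = _irls_weights(np.zeros(len(time)), time, status)
        z = g / w
        lmax = lambda_max(Xs, z, weights=w / 2.0)
        if self.n_lambdas == 1:
            return np.array([lmax])
        return np.geomspace(lmax, self.lambda_min_ratio * lmax, self.n_lambdas)

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y=None, *, time=None, status=None):
        """Fit on (X, time, status); ``y`` may be a (time, status) tuple or a
        structured array with 'time'/'event' fields (scikit-survival style)."""
        time, status = _unpack_y(y, time, status)
        ds = SurvivalDataset(X=np.asarray(X, float), time=time, status=status)
        if ds.n_events == 0:
            raise ValueError("cannot fit a Cox model with no observed events")
        std, params = standardize_features(ds)
        Xs = np.ascontiguousarray(std.X)

        if self.lam == "auto":
            lambdas = self._lambda_grid(Xs, ds.time, ds.status)
            folds = stratified_kfold(ds, K=self.cv, seed=self.random_state)
            cv_scores = np.zeros(len(lambdas))
            for k in range(folds.K):
                tr, _ = folds.train_test(k)
                if ds.status[tr].sum() == 0:
                    raise ValueError(f"training fold {k} has no events")
                betas = self._path(Xs[tr], ds.time[tr], ds.status[tr], lambdas)
                for i, b in enumerate(betas):
                    l_full = _partial_loglik_eta(Xs @ b, ds.time, ds.status,
                                                 normalize=False)
                    l_tr = _partial_loglik_eta(Xs[tr] @ b, ds.time[tr],
                                               ds.status[tr], normalize=False)
                    cv_scores[i] += l_full - l_tr
            best = int(np.argmax(cv_scores))  # descending grid: first max = largest lam
            lam = float(lambdas[best])
            self.lambdas_ = lambdas
            self.cv_scores_ = cv_scores
            # warm-started refit down the path to the selected lambda
            self.path_betas_ = self._path(Xs, ds.time, ds.status, lambdas[: best + 1])
            beta_std = self.path_betas_[-1]
        else:
            lam = float(self.lam)
            self.lambdas_ = np.array([lam])
            self.cv_scores_ = None
            self.path_betas_ = None
            beta_std, _ = self._fit_one(Xs, ds.time, ds.status, lam, np.zeros(Xs.shape[1]))

        self.lambda_ = lam
        self.coef_std_ = beta_std
        self.coef_, self.intercept_shift_ = params.invert_coef(beta_std, ds.n_features)
        self.selected_ = np.flatnonzero(self.coef_)
        self.standardization_ = params
        eta = Xs @ beta_std
        self.baseline_times_, self.baseline_cumhaz_ = _breslow(eta, ds.time, ds.status)
        self.train_scores_ = eta
        self.n_features_in_ = ds.n_features
        return self

    def predict(self, X) -> np.ndarray:
        """Prognostic index (higher = higher hazard = shorter survival)."""
        check_is_fitted(self, "coef_")
        return np.asarray(X, float) @ self.coef_ + self.intercept_shift_

    def predict_survival_function(self, X, times) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._to_fit().survival_function(X, times)

    def score(self, X, y=None, *, time=None, status=None) -> float:
        """Normalized log partial likelihood on new data (higher is better)."""
        time, status = _unpack_y(y, time, status)
        return _partial_loglik_eta(self.predict(X), np.asarray(time, float),
                                   np.asarray(status, int))

    def _to_fit(self) -> CoxFit:
        cv_table = None
        if getattr(self, "cv_scores_", None) is not None:
            cv_table = {"lambda": self.lambdas_.tolist(),
                        "cv_partial_loglik": self.cv_scores_.tolist()}
        return CoxFit(
            beta=self.coef_, intercept_shift=self.intercept_shift_,
            lam=self.lambda_, selected=self.selected_,
            baseline_times=self.baseline_times_,
            baseline_cumhaz=self.baseline_cumhaz_,
            standardization=self.standardization_, cv_table=cv_table,
        )


def _unpack_y(y, time, status):
    if time is not None and status is not None:
        return np.asarray(time, float), np.asarray(status, int)
    if y is None:
        raise ValueError("supply y or time=/status=")
    if hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = y.dtype.names
        tname = next(n for n in names if n.lower() in ("time", "futime", "t"))
        sname = next(n for n in names if n.lower() in ("event", "status", "delta"))
        return np.asarray(y[tname], float), np.asarray(y[sname], int)
    time, status = y
    return np.asarray(time, float), np.asarray(status, int)


def _breslow(eta, time, status):
    """Breslow cumulative baseline hazard at the distinct event times."""
    ev_times = np.unique(time[status == 1])
    ex = np.exp(eta - eta.max())
    scale = np.exp(eta.max())
    H = np.empty(len(ev_times))
    acc = 0.0
    for i, t in enumerate(ev_times):
        d = int(np.sum((time == t) & (status == 1)))
        S = ex[time >= t].sum() * scale
        acc += d / S
        H[i] = acc
    return ev_times, H


# -- module-level operation wrappers ----------------------------------------


def fit_cox_l12(ds: SurvivalDataset, lam, **kwargs) -> CoxFit:
    """Fit an L1/2 Cox model at a fixed penalty (or "auto" for CV tuning)."""
    est = CoxL12(lam=lam, **kwargs).fit(ds.X, time=ds.time, status=ds.status)
    return est._to_fit()


def breslow_baseline(fit: CoxFit, ds: SurvivalDataset):
    """(Re)compute the Breslow baseline cumulative hazard of ``fit`` on ``ds``."""
    eta = fit.linear_predictor(ds.X)
    times, cumhaz = _breslow(eta, ds.time, ds.status)
    fit.baseline_times = times
    fit.baseline_cumhaz = cumhaz
    return times, cumhaz


def classify_risk(fit: CoxFit, ds: SurvivalDataset, threshold_rule: str = "median",
                  train_scores=None) -> RiskPartition:
    """Split samples into low/high prognostic classes by the Cox score.

    The threshold is the median prognostic index of the training samples
    (pass ``train_scores``; defaults to the scores of ``ds`` itself) or 0
    under ``threshold_rule="zero"``. High risk means score strictly above the
    threshold.
    """
    scores = fit.linear_predictor(ds.X)
    if np.ptp(scores) == 0:
        raise ValueError("constant prognostic scores (empty model); refit with a "
                         "smaller lambda")
    if threshold_rule == "median":
        ref = scores if train_scores is None else np.asarray(train_scores, float)
        thr = float(np.median(ref))
    elif threshold_rule == "zero":
        thr = 0.0
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    labels = np.where(scores > thr, "high", "low")
    return RiskPartition(scores=scores, labels=labels, threshold=thr)


def cv_tune_cox(ds: SurvivalDataset, folds: FoldAssignment, lambdas):
    """Verweij-van Houwelingen CV over a fixed lambda grid; ties -> larger lambda."""
    std, _ = standardize_features(ds)
    Xs = np.ascontiguousarray(std.X)
    est = CoxL12()
    lambdas = np.asarray(lambdas, float)
    order = np.argsort(-lambdas)
    lambdas = lambdas[order]
    scores = np.zeros(len(lambdas))
    for k in range(folds.K):
        tr, _ = folds.train_test(k)
        betas = est._path(Xs[tr], ds.time[tr], ds.status[tr], lambdas)
        for i, b in enumerate(betas):
            scores[i] += (_partial_loglik_eta(Xs @ b, ds.time, ds.status, normalize=False)
                          - _partial_loglik_eta(Xs[tr] @ b, ds.time[tr], ds.status[tr],
                                                normalize=False))
    best = int(np.argmax(scores))
    return float(lambdas[best]), {"lambda": lambdas.tolist(),
                                  "cv_partial_loglik": scores.tolist()}
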