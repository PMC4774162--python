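"""The semi-supervised Cox/AFT loop for censored survival data.

Each iteration: (1) a CV-tuned L1/2 Cox model is fitted on the current
training set (originally complete samples plus previously validated
imputations, the latter entering as events at their imputed times); (2) all
samples are classified into low/high prognostic classes by the median of the
training scores; (3) within each class, censored samples receive Kaplan-Meier
conditional-mean imputations computed from that class's training samples;
(4) a CV-tuned L1/2 AFT model is fitted on the training samples together with
the class-imputed censored samples and re-evaluates every censored sample's
survival time; (5) each censored sample's accepted imputation is the AFT
re-evaluation when that prediction is itself consistent with the censoring
(strictly exceeds the censored time) and the class conditional mean otherwise;
a sample whose imputation still does not exceed its censored time — which
happens when the sample lies beyond the last event time of its risk class, so
the conditional-mean sum degenerates — is an "error estimation" and is
excluded from training. The loop stops when the usable set stabilizes or
after ``max_iters`` iterations, and the final Cox/AFT models are (re)fitted
on the terminal augmented set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .aft import AFTL12, _impute_against_curve, km_estimator
from .cox import CoxL12
from .datasets import SurvivalDataset
from .metrics import selection_precision
from .simulate import SimulatedTruth

logger = logging.getLogger(__name__)

__all__ = [
    "SemiSupConfig",
    "SemiSupervisedResult",
    "SemiSupervisedCoxAFT",
    "validate_imputations",
    "run_semisupervised",
    "compare_single_vs_semi",
]


def validate_imputations(imputed_time, censored_time) -> np.ndarray:
    """Usable iff the imputed survival time strictly exceeds the censored time."""
    imputed_time = np.asarray(imputed_time, float)
    censored_time = np.asarray(censored_time, float)
    return imputed_time > censored_time


@dataclass
class SemiSupConfig:
    """Controls of the semi-supervised loop (see module docstring)."""

    max_iters: int = 5
    folds: int = 5
    n_lambdas: int = 15
    lambda_min_ratio: float = 0.05
    seed: int = 0
    threshold_rule: str = "median"
    restrict_aft_to_cox_genes: bool = False

    def __post_init__(self):
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class SemiSupervisedResult:
    cox: object  # fitted CoxL12
    aft: object  # fitted AFTL12
    partition: object  # RiskPartition over all samples
    augmented: SurvivalDataset
    excluded_ids: list
    validated_times: dict  # censored sample index -> accepted imputed time
    per_iteration: list = field(default_factory=list)
    n_iterations: int = 0


class SemiSupervisedCoxAFT(BaseEstimator):
    """Semi-supervised survival estimator combining Cox and AFT models.

    Parameters mirror :class:`SemiSupConfig`. After ``fit`` the estimator
    exposes the final Cox model (``cox_``), final AFT model (``aft_``), the
    risk partition over all samples (``partition_``), the augmented training
    set (``augmented_``), the indices of censored samples whose imputations
    never validated (``excluded_``), and a per-iteration log (``history_``).
    """

    def __init__(self, max_iters=5, folds=5, n_lambdas=15, lambda_min_ratio=0.05,
                 threshold_rule="median", restrict_aft_to_cox_genes=False,
                 random_state=0):
        self.max_iters = max_iters
        self.folds = folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.threshold_rule = threshold_rule
        self.restrict_aft_to_cox_genes = restrict_aft_to_cox_genes
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _fit_cox_nonempty(self, ds_train: SurvivalDataset, seed: int) -> CoxL12:
        """CV-tuned Cox fit; walks down the lambda grid if the tuned model is empty."""
        cox = CoxL12(lam="auto", n_lambdas=self.n_lambdas,
                     lambda_min_ratio=self.lambda_min_ratio, cv=self.folds,
                     random_state=seed)
        cox.fit(ds_train.X, time=ds_train.time, status=ds_train.status)
        if cox.selected_.size == 0 and cox.path_betas_ is not None:
            start = len(cox.path_betas_)
            beta = cox.path_betas_[-1].copy()
            std, params = None, cox.standardization_
            Xs = np.ascontiguousarray(params.transform(ds_train.X))
            for lam in cox.lambdas_[start:]:
                beta, _ = cox._fit_one(Xs, ds_train.time, ds_train.status, lam, beta)
                if np.any(beta != 0):
                    logger.info("empty CV-tuned Cox model; descended to lambda=%.4g", lam)
                    cox.lambda_ = float(lam)
                    cox.coef_std_ = beta
                    cox.coef_, cox.intercept_shift_ = params.invert_coef(
                        beta, ds_train.n_features)
                    cox.selected_ = np.flatnonzero(cox.coef_)
                    cox.train_scores_ = Xs @ beta
                    break
        return cox

    def fit(self, X, y=None, *, time=None, status=None):
        from .cox import _unpack_y

        time, status = _unpack_y(y, time, status)
        ds = SurvivalDataset(X=np.asarray(X, float), time=time, status=status)
        complete = np.flatnonzero(ds.status == 1)
        censored = np.flatnonzero(ds.status == 0)
        if complete.size == 0:
            raise ValueError("no complete samples to start from")

        validated: dict[int, float] = {}
        history = []
        cox = aft = None
        stale = True  # do the final fits need recomputing?

        for it in range(self.max_iters):
            seed_it = (self.random_state + 13 * it) % (2**31)
            train_idx = np.concatenate((complete, np.array(sorted(validated), int)))
            train_times = np.concatenate((
                ds.time[complete], np.array([validated[i] for i in sorted(validated)])))
            ds_train = SurvivalDataset(
                X=ds.X[train_idx], time=train_times,
                status=np.ones(len(train_idx), int),
                sample_ids=[ds.sample_ids[i] for i in train_idx],
                feature_names=ds.feature_names)

            cox = self._fit_cox_nonempty(ds_train, seed_it)
            log = {"iteration": it, "n_train": len(train_idx),
                   "lambda_cox": cox.lambda_, "cox_support": int(cox.selected_.size)}

            if cox.selected_.size == 0:
                # nothing to classify with: loop cannot progress
                log["note"] = "empty Cox model at every lambda; stopping"
                history.append(log)
                stale = False
                break

            scores_all = cox.predict(ds.X)
            thr = (float(np.median(cox.predict(ds_train.X)))
                   if self.threshold_rule == "median" else 0.0)
            labels_all = np.where(scores_all > thr, "high", "low")

            # within-class KM conditional-mean imputation of every censored
            # sample from the *original complete* samples of its class; a
            # censored time beyond the class's last complete event stays
            # unimputable no matter how the training set grows
            h_imp = np.full(ds.n_samples, np.nan)
            imp_ok = np.zeros(ds.n_samples, bool)
            for cls in ("low", "high"):
                members_c = np.array([i for i in complete if labels_all[i] == cls], int)
                cls_cens = [i for i in censored if labels_all[i] == cls]
                if len(cls_cens) == 0:
                    continue
                if members_c.size == 0:
                    logger.info("iteration %d: empty %s-risk complete class; "
                                "censored samples carried over unimputed", it, cls)
                    continue
                km = km_estimator(ds.time[members_c],
                                  np.ones(members_c.size, int))
                res = _impute_against_curve(ds.time[cls_cens],
                                            np.zeros(len(cls_cens), int), km)
                for pos, i in enumerate(cls_cens):
                    if not res.undefined_tail[pos] and np.isfinite(res.h_star[pos]):
                        h_imp[i] = res.h_star[pos]
                        imp_ok[i] = True

            # AFT design: training samples + class-imputed unvalidated censored
            extra = np.array([i for i in np.flatnonzero(imp_ok)
                              if i not in validated], int)
            aft_idx = np.concatenate((train_idx, extra))
            h_resp = np.concatenate((np.log(train_times), h_imp[extra]))
            trusted = np.concatenate((np.ones(len(train_idx), bool),
                                      np.zeros(len(extra), bool)))
            X_aft = ds.X[aft_idx]
            feat_subset = None
            if self.restrict_aft_to_cox_genes:
                feat_subset = cox.selected_
                X_aft = X_aft[:, feat_subset]
            aft = AFTL12(lam="auto", n_lambdas=self.n_lambdas,
                         lambda_min_ratio=self.lambda_min_ratio, cv=self.folds,
                         random_state=seed_it)
            aft.fit(X_aft, h_resp, loss_mask=trusted)
            aft._feature_subset = feat_subset

            # re-evaluate every censored sample with the AFT model; the AFT
            # prediction is authoritative when it is itself consistent with
            # the censoring (exceeds the censored time), else the class
            # conditional mean stands; samples with neither (degenerate
            # class-tail imputations) are the "error estimations"
            Xc = ds.X[censored]
            if feat_subset is not None:
                Xc = Xc[:, feat_subset]
            pred_t = np.exp(aft.predict(Xc))
            eq3_t = np.where(imp_ok[censored], np.exp(h_imp[censored]), -np.inf)
            final_t = np.where(pred_t > ds.time[censored], pred_t, eq3_t)
            usable = validate_imputations(final_t, ds.time[censored])
            new_validated = {int(i): float(ft)
                             for i, ft, u in zip(censored, final_t, usable) if u}
            log.update({"lambda_aft": aft.lambda_, "aft_support": int(aft.selected_.size),
                        "n_validated": len(new_validated),
                        "n_aft_consistent": int(np.sum(pred_t > ds.time[censored])),
                        "n_imputed_eq3": int(imp_ok.sum())})
            history.append(log)

            partition_scores = scores_all
            partition_thr = thr
            if set(new_validated) == set(validated):
                validated = new_validated
                stale = False  # fits were trained on this same (index-wise) set
                break
            validated = new_validated
            stale = True
        self.n_iterations_ = len(history)

        if stale and cox is not None and cox.selected_.size > 0:
            # usable set changed on the last allowed iteration: refit on terminal set
            train_idx = np.concatenate((complete, np.array(sorted(validated), int)))
            train_times = np.concatenate((
                ds.time[complete], np.array([validated[i] for i in sorted(validated)])))
            ds_train = SurvivalDataset(X=ds.X[train_idx], time=train_times,
                                       status=np.ones(len(train_idx), int),
                                       feature_names=ds.feature_names)
            cox = self._fit_cox_nonempty(ds_train, (self.random_state + 997) % (2**31))
            if cox.selected_.size > 0:
                partition_scores = cox.predict(ds.X)
                partition_thr = float(np.median(cox.predict(ds_train.X))) \
                    if self.threshold_rule == "median" else 0.0
            aft = AFTL12(lam="auto", n_lambdas=self.n_lambdas,
                         lambda_min_ratio=self.lambda_min_ratio, cv=self.folds,
                         random_state=(self.random_state + 997) % (2**31))
            aft.fit(ds.X[train_idx], np.log(train_times))
            aft._feature_subset = None

        from .cox import RiskPartition

        self.cox_ = cox
        self.aft_ = aft
        if cox is not None and cox.selected_.size > 0:
            self.partition_ = RiskPartition(scores=partition_scores,
                                            labels=np.where(partition_scores > partition_thr,
                                                            "high", "low"),
                                            threshold=partition_thr)
        else:
            self.partition_ = None
        self.validated_ = dict(validated)
        self.excluded_ = [int(i) for i in censored if int(i) not in validated]
        aug_idx = np.concatenate((complete, np.array(sorted(validated), int))) \
            if validated else complete
        aug_times = np.concatenate((
            ds.time[complete],
            np.array([validated[i] for i in sorted(validated)]))) if validated \
            else ds.time[complete]
        self.augmented_ = SurvivalDataset(
            X=ds.X[aug_idx], time=aug_times, status=np.ones(len(aug_idx), int),
            sample_ids=[ds.sample_ids[i] for i in aug_idx],
            feature_names=ds.feature_names)
        self.history_ = history
        self._censored_idx = censored
        return self

    def predict(self, X):
        """Cox prognostic index of the final model."""
        return self.cox_.predict(X)

    def predict_log_time(self, X):
        X = np.asarray(X, float)
        if getattr(self.aft_, "_feature_subset", None) is not None:
            X = X[:, self.aft_._feature_subset]
        return self.aft_.predict(X)


def run_semisupervised(ds: SurvivalDataset, config: SemiSupConfig = None) -> SemiSupervisedResult:
    """Functional wrapper over :class:`SemiSupervisedCoxAFT`."""
    config = config or SemiSupConfig()
    est = SemiSupervisedCoxAFT(
        max_iters=config.max_iters, folds=config.folds, n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio, threshold_rule=config.threshold_rule,
        restrict_aft_to_cox_genes=config.restrict_aft_to_cox_genes,
        random_state=config.seed,
    ).fit(ds.X, time=ds.time, status=ds.status)
    return SemiSupervisedResult(
        cox=est.cox_, aft=est.aft_, partition=est.partition_,
        augmented=est.augmented_,
        excluded_ids=[ds.sample_ids[i] for i in est.excluded_],
        validated_times=est.validated_, per_iteration=est.history_,
        n_iterations=est.n_iterations_,
    )


def _true_risk_labels(truth: SimulatedTruth) -> np.ndarray:
    eta = truth.dataset.X @ truth.beta_true
    return np.where(eta > np.median(eta), "high", "low")


def compare_single_vs_semi(truth: SimulatedTruth, config: SemiSupConfig = None,
                           return_fits: bool = False):
    """Fit single Cox, single AFT, and the semi-supervised pipeline on one
    simulated dataset; report selection counts/precision and risk-classification
    accuracy against the true linear-predictor median split.

    With ``return_fits=True`` returns ``(report, fits)`` where ``fits`` holds
    the fitted single-Cox, single-AFT and semi-supervised estimators.
    """
    config = config or SemiSupConfig()
    ds = truth.dataset
    support = truth.true_support
    report = {}

    # single Cox: complete samples only
    complete = ds.subset(ds.status == 1)
    cox = CoxL12(lam="auto", n_lambdas=config.n_lambdas,
                 lambda_min_ratio=config.lambda_min_ratio, cv=config.folds,
                 random_state=config.seed)
    cox.fit(complete.X, time=complete.time, status=complete.status)
    rep = selection_precision(cox.selected_, support)
    report["cox"] = {"correct": rep.n_correct, "selected": rep.n_selected,
                     "precision": rep.precision}

    # single AFT: global KM conditional-mean imputation, all samples
    from .aft import km_mean_impute

    imp = km_mean_impute(ds)
    aft = AFTL12(lam="auto", n_lambdas=config.n_lambdas,
                 lambda_min_ratio=config.lambda_min_ratio, cv=config.folds,
                 random_state=config.seed)
    aft.fit(ds.X, imp.h_star, loss_mask=ds.status == 1)
    rep = selection_precision(aft.selected_, support)
    report["aft"] = {"correct": rep.n_correct, "selected": rep.n_selected,
                     "precision": rep.precision}

    # semi-supervised pipeline
    semi = SemiSupervisedCoxAFT(
        max_iters=config.max_iters, folds=config.folds, n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio, threshold_rule=config.threshold_rule,
        restrict_aft_to_cox_genes=config.restrict_aft_to_cox_genes,
        random_state=config.seed,
    ).fit(ds.X, time=ds.time, status=ds.status)
    rep_c = selection_precision(semi.cox_.selected_, support)
    rep_a = selection_precision(semi.aft_.selected_, support)
    n_cens = int((ds.status == 0).sum())
    report["semi_cox"] = {"correct": rep_c.n_correct, "selected": rep_c.n_selected,
                          "precision": rep_c.precision}
    report["semi_aft"] = {"correct": rep_a.n_correct, "selected": rep_a.n_selected,
                          "precision": rep_a.precision}
    report["unrecovered_fraction"] = (len(semi.excluded_) / n_cens) if n_cens else 0.0
    report["n_iterations"] = semi.n_iterations_

    # risk-classification accuracy vs the true split
    true_labels = _true_risk_labels(truth)
    if cox.selected_.size > 0:
        sc = cox.predict(ds.X)
        thr = float(np.median(cox.predict(complete.X)))
        single_labels = np.where(sc > thr, "high", "low")
        report["cox_class_accuracy"] = float(np.mean(single_labels == true_labels))
    else:
        report["cox_class_accuracy"] = 0.5  # empty model: no better than chance
    if semi.partition_ is not None:
        report["semi_class_accuracy"] = float(
            np.mean(semi.partition_.labels == true_labels))
    else:
        report["semi_class_accuracy"] = 0.5
    if return_fits:
        return report, {"cox": cox, "aft": aft, "semi": semi}
    return report
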