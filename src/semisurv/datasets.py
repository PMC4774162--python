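"""Survival tables: container, delimited I/O, standardization, stratified folds.

A :class:`SurvivalDataset` is the universal input of the package: an ``n x p``
expression matrix together with an observed time ``t_i > 0`` and an event
indicator ``delta_i`` (1 = event observed, 0 = right censored) per sample.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "StandardizationParams",
    "FoldAssignment",
    "read_survival_table",
    "write_survival_table",
    "standardize_features",
    "stratified_kfold",
]


@dataclass
class SurvivalDataset:
    """Right-censored survival data with covariates.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Covariate (expression) matrix, no missing values.
    time : ndarray of shape (n,)
        Observed times, strictly positive.
    status : ndarray of shape (n,)
        Event indicators in {0, 1}; 1 means the event was observed.
    sample_ids : list of str, optional
        Defaults to ``s0 .. s{n-1}``.
    feature_names : list of str, optional
        Defaults to ``g0 .. g{p-1}``; must be unique.
    """

    X: np.ndarray
    time: np.ndarray
    status: np.ndarray
    sample_ids: list = field(default=None)
    feature_names: list = field(default=None)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        n, p = self.X.shape
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if self.feature_names is None:
            self.feature_names = [f"g{j}" for j in range(p)]
        self.sample_ids = list(self.sample_ids)
        self.feature_names = list(self.feature_names)
        self._validate()

    def _validate(self):
        n, p = self.X.shape
        if not (len(self.time) == len(self.status) == len(self.sample_ids) == n):
            raise ValueError(
                f"inconsistent lengths: X has {n} rows, time {len(self.time)}, "
                f"status {len(self.status)}, sample_ids {len(self.sample_ids)}"
            )
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} feature names for {p} columns")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names are not unique")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"non-finite covariate at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        bad = np.flatnonzero(~(np.isfinite(self.time) & (self.time > 0)))
        if bad.size:
            raise ValueError(
                f"non-positive or non-finite time for sample {self.sample_ids[bad[0]]!r}"
            )
        bad = np.flatnonzero(~np.isin(self.status, (0, 1)))
        if bad.size:
            raise ValueError(
                f"status outside {{0,1}} for sample {self.sample_ids[bad[0]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def censoring_rate(self) -> float:
        return 1.0 - self.status.mean()

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset (copy), preserving order of ``idx``."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SurvivalDataset(
            X=self.X[idx].copy(),
            time=self.time[idx].copy(),
            status=self.status[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=list(self.feature_names),
        )

    def to_frame(self, time_col: str = "time", status_col: str = "status") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names, index=self.sample_ids)
        df.insert(0, status_col, self.status)
        df.insert(0, time_col, self.time)
        df.index.name = "sample_id"
        return df


@dataclass
class StandardizationParams:
    """Per-feature centering/scaling constants (see :func:`standardize_features`).

    ``transform`` maps raw columns x to (x - mean) / scale; ``invert_coef``
    maps coefficients fitted on the standardized scale back to the raw scale.
    """

    means: np.ndarray
    scales: np.ndarray
    kept: np.ndarray  # indices of retained (non-constant) columns

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept] - self.means) / self.scales

    def invert_coef(self, beta_std: np.ndarray, p_original: int):
        """Return (beta_raw of length p_original, intercept_shift).

        A linear predictor b'z on the standardized scale equals
        beta_raw'x + intercept_shift on the raw scale.
        """
        beta_raw = np.zeros(p_original)
        beta_raw[self.kept] = beta_std / self.scales
        shift = -float(np.dot(self.means / self.scales, beta_std))
        return beta_raw, shift


@dataclass
class FoldAssignment:
    """Cross-validation folds stratified on the event indicator."""

    fold_of_sample: np.ndarray
    K: int
    seed: int

    def train_test(self, k: int):
        test = np.flatnonzero(self.fold_of_sample == k)
        train = np.flatnonzero(self.fold_of_sample != k)
        return train, test

    def to_tsv(self, path, sample_ids=None) -> None:
        """Write a two-column (sample_id, fold) table."""
        ids = sample_ids or [f"s{i}" for i in range(len(self.fold_of_sample))]
        pd.DataFrame({"sample_id": ids, "fold": self.fold_of_sample}).to_csv(
            path, sep="\t", index=False)


def read_survival_table(path, time_col: str = "time", status_col: str = "status") -> SurvivalDataset:
    """Read a delimited survival table (CSV, or TSV for .tsv/.txt extensions).

    The table must have a header; ``time_col`` and ``status_col`` are required
    columns and every remaining numeric column is treated as a feature. A
    leading ``sample_id`` column (or an unnamed first column) supplies sample
    identifiers.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.columns[0] in ("sample_id", "Unnamed: 0", ""):
        df = df.set_index(df.columns[0])
        df.index = df.index.astype(str)
        ids = list(df.index)
    else:
        ids = [f"s{i}" for i in range(len(df))]
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {os.path.basename(str(path))}")
    feat_cols = [c for c in df.columns if c not in (time_col, status_col)]
    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    if feats.isna().any().any():
        col = feats.columns[feats.isna().any()][0]
        row = ids[int(np.flatnonzero(feats[col].isna())[0])]
        raise ValueError(f"non-numeric or missing value in feature {col!r}, sample {row!r}")
    status = pd.to_numeric(df[status_col], errors="coerce")
    bad = np.flatnonzero(~status.isin((0, 1)))
    if bad.size:
        raise ValueError(f"status value {df[status_col].iloc[bad[0]]!r} outside {{0,1}} "
                         f"for sample {ids[bad[0]]!r}")
    return SurvivalDataset(
        X=feats.to_numpy(float),
        time=pd.to_numeric(df[time_col]).to_numpy(float),
        status=status.to_numpy(int),
        sample_ids=ids,
        feature_names=feat_cols,
    )


def write_survival_table(ds: SurvivalDataset, path, time_col: str = "time",
                         status_col: str = "status") -> None:
    """Write a dataset in the same delimited format ``read_survival_table`` reads."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    ds.to_frame(time_col, status_col).to_csv(path, sep=sep)


def standardize_features(ds: SurvivalDataset):
    """Center each feature to mean 0 and scale it so that sum(x^2) = n.

    With this column scaling the coordinate-wise L1/2 subproblem solved by
    :func:`semisurv.solver.half_threshold` is exact. Constant columns are
    dropped with a warning (they carry no information and cannot be scaled).

    Returns
    -------
    (SurvivalDataset, StandardizationParams)
    """
    X = ds.X
    means = X.mean(axis=0)
    # population scaling: sum((x-mean)^2) = n  <=>  divide by ddof=0 std
    scales = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(scales > 0)
    if kept.size == 0:
        raise ValueError("all feature columns are constant; nothing to standardize")
    if kept.size < X.shape[1]:
        dropped = [ds.feature_names[j] for j in np.flatnonzero(scales == 0)]
        logger.warning("dropping %d constant feature(s): %s", len(dropped), dropped[:5])
    params = StandardizationParams(means=means[kept], scales=scales[kept], kept=kept)
    std = SurvivalDataset(
        X=params.transform(X),
        time=ds.time.copy(),
        status=ds.status.copy(),
        sample_ids=list(ds.sample_ids),
        feature_names=[ds.feature_names[j] for j in kept],
    )
    return std, params


def stratified_kfold(ds: SurvivalDataset, K: int = 5, seed: int = 0) -> FoldAssignment:
    """K folds stratified on the event indicator, deterministic given seed.

    Censoring imbalance across folds is what destabilizes cross-validated
    partial likelihood, so the stratification variable is ``status`` alone.
    """
    n = ds.n_samples
    if K > n:
        raise ValueError(f"K={K} exceeds n={n}")
    if K < 2:
        raise ValueError("K must be >= 2")
    fold = np.empty(n, dtype=int)
    counts = np.bincount(ds.status, minlength=2)
    if counts.min() >= K:
        skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        for k, (_, test) in enumerate(skf.split(np.zeros(n), ds.status)):
            fold[test] = k
    else:
        # a stratum smaller than K: degrade to a plain shuffle split
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        for k in range(K):
            fold[perm[k::K]] = k
    return FoldAssignment(fold_of_sample=fold, K=K, seed=seed)
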