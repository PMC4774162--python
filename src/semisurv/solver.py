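"""L1/2-penalized least squares by coordinate descent with half-thresholding.

The penalty ``lam * sum_j |beta_j|^{1/2}`` is nonconvex but its scalar
proximal problem has a closed form: the half-thresholding operator sets a
coefficient to zero when the univariate regression coefficient ``omega`` falls
below ``(54^{1/3}/4) * lam^{2/3}`` and otherwise shrinks it through a cosine
expression. With columns scaled to ``sum(x^2) = n`` and the quadratic loss
``(1/n)||y - X beta||^2``, the operator is the exact minimizer of each
coordinate subproblem, so cyclic descent monotonically decreases

    F(beta) = (1/n) ||y - X beta||^2 + lam * sum_j |beta_j|^{1/2}.

The objective admits multiple local minima; the contract of the solver is a
non-increasing objective and a fixed point of the operator under the fixed
conventions (cyclic order, zero initialization, warm starts along the path),
not global optimality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._cd import _C_THRESH, cd_weighted

__all__ = [
    "PenalizedProblem",
    "SolverResult",
    "half_threshold",
    "threshold_boundary",
    "coordinate_descent",
    "lambda_path",
    "lambda_max",
]


def threshold_boundary(lam):
    """Zeroing threshold of the half-thresholding operator: (54^{1/3}/4) lam^{2/3}."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lam must be >= 0")
    out = _C_THRESH * lam ** (2.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def half_threshold(omega, lam):
    """Univariate half-thresholding operator.

    Exact global minimizer of ``g(b) = (b - omega)^2 + lam * |b|^{1/2}``:

        0                                                if |omega| <= (54^{1/3}/4) lam^{2/3}
        (2/3) omega (1 + cos(2 (pi - phi_lam(omega))/3)) otherwise,

    with ``phi_lam(omega) = arccos((lam/8) (|omega|/3)^{-3/2})``. Odd in
    ``omega``; shrinks (|output| <= |omega|, equality iff lam = 0); returns 0
    at the threshold boundary itself (strict inequality).
    """
    omega = np.asarray(omega, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lam must be >= 0")
    absw = np.abs(omega)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        arg = (lam / 8.0) * (absw / 3.0) ** (-1.5)
        phi = np.arccos(np.clip(arg, -1.0, 1.0))
        val = (2.0 / 3.0) * omega * (1.0 + np.cos(2.0 * (np.pi - phi) / 3.0))
    out = np.where(absw > _C_THRESH * lam ** (2.0 / 3.0), val, 0.0)
    out = np.where(lam == 0, omega, out)
    return float(out) if out.ndim == 0 else out


@dataclass
class PenalizedProblem:
    """One weighted L1/2 least-squares problem.

    ``X`` should have columns scaled to ``sum(x^2) = n`` for the unweighted
    case (see :func:`semisurv.datasets.standardize_features`); under weights
    the solver rescales each coordinate subproblem exactly, so any column
    scaling is handled, at the price of a per-coordinate effective penalty.
    """

    X: np.ndarray
    y: np.ndarray
    lam: float
    weights: np.ndarray = None

    def __post_init__(self):
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.weights is None:
            self.weights = np.ones_like(self.y)
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class SolverResult:
    beta: np.ndarray
    n_iter: int
    converged: bool
    objective_trace: np.ndarray = field(repr=False, default=None)


def coordinate_descent(problem: PenalizedProblem, beta_init=None, tol: float = 1e-5,
                       max_sweeps: int = 10_000) -> SolverResult:
    """Cyclic coordinate descent on a :class:`PenalizedProblem`.

    Stops when the largest coefficient change in a full sweep is below
    ``tol``. Raises if non-finite values appear (diverging inputs).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    p = problem.X.shape[1]
    beta = np.zeros(p) if beta_init is None else np.array(beta_init, dtype=float)
    XT = np.ascontiguousarray(problem.X.T)
    n_iter, converged, trace = cd_weighted(
        XT, problem.y, problem.weights, float(problem.lam), beta,
        float(tol), int(max_sweeps),
    )
    if not np.all(np.isfinite(beta)):
        raise FloatingPointError(f"non-finite coefficients after sweep {n_iter}")
    return SolverResult(beta=beta, n_iter=n_iter, converged=bool(converged),
                        objective_trace=trace)


def lambda_max(X, y, weights=None) -> float:
    """Smallest lam at which a zero-initialized fit stays identically zero.

    From the threshold condition, coordinate j dies at
    ``lam_j = (4 |omega_j| / 54^{1/3})^{3/2} * a_j^{... }`` where under
    weights the subproblem is rescaled; unweighted with sum(x^2)=n columns
    this is ``(4 |omega_j| / 54^{1/3})^{3/2}`` with
    ``omega_j = (1/n) sum_i x_ij y_i``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if weights is None:
        weights = np.ones(n)
    v = np.asarray(weights, float)
    a = (v @ (X * X)) / n
    c = (X.T @ (v * y)) / n
    ok = a > 1e-12
    if not np.any(ok) or not np.any(c[ok] != 0):
        raise ValueError("response is orthogonal to every feature (all-zero omega)")
    # zero iff |c/a| <= C (lam/a)^{2/3}  =>  lam >= (|c|/(a C))^{3/2} a
    lam_j = (np.abs(c[ok]) / (a[ok] * _C_THRESH)) ** 1.5 * a[ok]
    return float(lam_j.max())


def lambda_path(X, y, n_lambda: int = 15, ratio: float = 0.05, weights=None) -> np.ndarray:
    """Log-spaced descending penalty grid from ``lambda_max`` to ``ratio*lambda_max``."""
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    lmax = lambda_max(X, y, weights)
    if n_lambda == 1:
        return np.array([lmax])
    return np.geomspace(lmax, ratio * lmax, n_lambda)
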