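"""Numba kernels for L1/2 coordinate descent.

The working objective is

    F(beta) = (1/n) * sum_i v_i * (y_i - x_i' beta)^2 + lam * sum_j |beta_j|^{1/2}

with observation weights ``v`` (all ones for plain least squares, IRLS weights
for the Cox working problem). Each coordinate subproblem is solved exactly by
the analytic half-thresholding operator, so the objective never increases.

``XT`` is the transposed design (p x n, C-contiguous) so that each coordinate
update streams one contiguous row.
"""

import numpy as np
from numba import njit

_C_THRESH = 54.0 ** (1.0 / 3.0) / 4.0


@njit(cache=True)
def _half_scalar(omega, lam):
    """Exact minimizer of (b - omega)^2 + lam * sqrt(|b|)."""
    if lam <= 0.0:
        return omega
    a = abs(omega)
    if a <= _C_THRESH * lam ** (2.0 / 3.0):
        return 0.0
    phi = np.arccos((lam / 8.0) * (a / 3.0) ** (-1.5))
    return (2.0 / 3.0) * omega * (1.0 + np.cos(2.0 * (np.pi - phi) / 3.0))


@njit(cache=True, fastmath=True)
def _objective(r, v, beta, lam, n):
    obj = 0.0
    for i in range(r.shape[0]):
        obj += v[i] * r[i] * r[i]
    obj /= n
    pen = 0.0
    for j in range(beta.shape[0]):
        pen += np.sqrt(abs(beta[j]))
    return obj + lam * pen


@njit(cache=True, fastmath=True)
def _sweep(XT, r, v, a, beta, lam, n, active_only):
    """One pass over coordinates; returns max absolute coefficient change."""
    p = beta.shape[0]
    m = r.shape[0]
    maxd = 0.0
    for j in range(p):
        if active_only and beta[j] == 0.0:
            continue
        if a[j] <= 1e-12:
            continue
        g = 0.0
        for i in range(m):
            g += v[i] * XT[j, i] * r[i]
        omega = beta[j] + g / (n * a[j])
        bnew = _half_scalar(omega, lam / a[j])
        d = bnew - beta[j]
        if d != 0.0:
            for i in range(m):
                r[i] -= d * XT[j, i]
            beta[j] = bnew
            ad = abs(d)
            if ad > maxd:
                maxd = ad
    return maxd


@njit(cache=True, fastmath=True)
def cd_weighted(XT, y, v, lam, beta, tol, max_sweeps):
    """Cyclic coordinate descent with active-set inner loops.

    ``beta`` is updated in place (warm start). Returns
    (n_sweeps, converged, objective_trace) where the trace holds the
    objective after every sweep. Termination requires a *full* sweep whose
    largest coefficient change is below ``tol``.
    """
    p, m = XT.shape
    n = float(m)
    r = y.copy()
    for j in range(p):
        if beta[j] != 0.0:
            for i in range(m):
                r[i] -= beta[j] * XT[j, i]
    a = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(m):
            s += v[i] * XT[j, i] * XT[j, i]
        a[j] = s / n
    trace = np.empty(max_sweeps)
    sweep = 0
    converged = False
    while sweep < max_sweeps:
        maxd = _sweep(XT, r, v, a, beta, lam, n, False)
        trace[sweep] = _objective(r, v, beta, lam, n)
        sweep += 1
        if maxd < tol:
            converged = True
            break
        while sweep < max_sweeps:
            maxd = _sweep(XT, r, v, a, beta, lam, n, True)
            trace[sweep] = _objective(r, v, beta, lam, n)
            sweep += 1
            if maxd < tol:
                break
    return sweep, converged, trace[:sweep]
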