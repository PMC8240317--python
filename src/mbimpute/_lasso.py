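"""Coordinate-descent solver for the weighted-L1 least-squares problem.

Minimizes  ||y - X b||^2 + lam * sum_j w_j |b_j|  over a sparse CSC design.
Columns with weight 0 are never penalized (plain least-squares updates).
The update for column j with partial residual r is the soft threshold
S(x_j' r, lam * w_j / 2) / ||x_j||^2 — the factor 1/2 because the squared
loss here carries no 1/(2N) normalization.

Convergence uses an active-set strategy: iterate over the currently
nonzero (plus unpenalized) columns until stable, then confirm with a full
sweep. The tolerance is relative to ||y|| and measured as the largest
change any single update makes to the fitted-value norm.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _one_sweep(data, indices, indptr, col_sq, pen_w, lam, resid, beta,
               active_only):
    n_cols = col_sq.shape[0]
    max_delta = 0.0
    for j in range(n_cols):
        cj = col_sq[j]
        if cj <= 0.0:
            continue
        bj = beta[j]
        if active_only and bj == 0.0 and pen_w[j] > 0.0:
            continue
        start = indptr[j]
        end = indptr[j + 1]
        rho = cj * bj
        for idx in range(start, end):
            rho += data[idx] * resid[indices[idx]]
        thr = 0.5 * lam * pen_w[j]
        if rho > thr:
            bnew = (rho - thr) / cj
        elif rho < -thr:
            bnew = (rho + thr) / cj
        else:
            bnew = 0.0
        d = bnew - bj
        if d != 0.0:
            for idx in range(start, end):
                resid[indices[idx]] -= d * data[idx]
            beta[j] = bnew
            ad = abs(d) * np.sqrt(cj)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def _cd_solve(data, indices, indptr, col_sq, pen_w, lam, resid, beta,
              max_sweeps, tol_abs):
    sweeps = 0
    while sweeps < max_sweeps:
        max_delta = _one_sweep(data, indices, indptr, col_sq, pen_w, lam,
                               resid, beta, False)
        sweeps += 1
        if max_delta < tol_abs:
            return sweeps, True
        while sweeps < max_sweeps:
            max_delta = _one_sweep(data, indices, indptr, col_sq, pen_w, lam,
                                   resid, beta, True)
            sweeps += 1
            if max_delta < tol_abs:
                break
    return sweeps, False


def solve_weighted_lasso(X_csc, y, pen_w, lam, beta0=None, max_sweeps=2000,
                         tol=1e-6):
    """Solve one (lam) point, optionally warm-started at ``beta0``.

    ``tol`` is relative to ||y||. Returns (beta, residual, n_sweeps,
    converged).
    """
    n_rows, n_cols = X_csc.shape
    col_sq = np.asarray(X_csc.multiply(X_csc).sum(axis=0)).ravel()
    beta = np.zeros(n_cols) if beta0 is None else beta0.copy()
    if beta0 is None or not beta.any():
        resid = y.astype(float).copy()
    else:
        resid = y - X_csc @ beta
    tol_abs = tol * max(np.linalg.norm(y), 1e-12)
    sweeps, converged = _cd_solve(
        X_csc.data, X_csc.indices, X_csc.indptr, col_sq,
        np.asarray(pen_w, dtype=float), float(lam), resid, beta,
        max_sweeps, tol_abs,
    )
    return beta, resid, sweeps, converged


def lambda_max(X_csc, y, pen_w, max_sweeps=2000, tol=1e-10):
    """Smallest lam at which every penalized coefficient is zero.

    Found from the residual after fitting the unpenalized columns alone:
    lam_max = max_j 2 |x_j' r| / w_j over columns with w_j > 0.
    """
    pen_w = np.asarray(pen_w, dtype=float)
    huge = 1e30
    _, resid, _, _ = solve_weighted_lasso(
        X_csc, y, pen_w, huge, max_sweeps=max_sweeps, tol=tol
    )
    grad = np.abs(X_csc.T @ resid)
    pen = pen_w > 0
    if not pen.any():
        return 0.0
    return float(np.max(2.0 * grad[pen] / pen_w[pen]))


def objective(X_csc, y, pen_w, lam, beta):
    resid = y - X_csc @ beta
    return float(resid @ resid + lam * np.abs(beta) @ pen_w)
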