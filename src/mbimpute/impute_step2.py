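"""Step 2: impute the flagged abundances with a penalized linear model.

A single joint linear model predicts every trusted entry (i, j) of the
abundance matrix from three information sources:

    Y_ij = Y_i. ' kappa_j  +  Y_.j ' tau_i  +  X_i. ' zeta_j  + noise,

i.e. the abundances of the k phylogenetically nearest taxa in the same
sample, the abundances of the same taxon in all other samples, and the
sample covariates. Training is restricted to the entries judged reliable
in step 1 (Omega); the coefficients are estimated by a weighted-L1
(Lasso) fit where the penalty weight of a taxon-taxon coefficient
kappa_{jj'} is D_{jj'}^psi, so distant taxa are shrunk harder, sample
coefficients tau carry unit weight, and covariate coefficients zeta are
unpenalized. (lambda, psi) are chosen by cross-validation over Omega
entries. Flagged entries are then replaced by the model prediction; all
others are passed through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from ._lasso import lambda_max, objective, solve_weighted_lasso
from .io_preprocess import (
    ABUNDANCE_FLOOR,
    PSEUDO_OFFSET,
    TOTAL_COUNT,
    AbundanceMatrix,
    CovariateMatrix,
    PhyloDistanceMatrix,
)
from .mixture_step1 import MissingMask

DEFAULT_PSI_GRID = (0.0, 0.5, 1.0, 2.0)
DEFAULT_N_LAMBDA = 30
DEFAULT_LAMBDA_MIN_RATIO = 1e-3


@dataclass
class NeighborSets:
    """Per taxon, the k nearest other taxa (ascending distance, index tie-break)."""

    indices: np.ndarray  # (m, k) integer array
    k: int


@dataclass
class DesignProblem:
    """Sparse regression problem over the trusted entries Omega.

    One row per (i, j) in Omega with exactly k + (n-1) + q structural
    nonzeros; columns are ordered [kappa block | tau block | zeta block].
    """

    matrix: sparse.csc_matrix
    response: np.ndarray
    entry_rows: np.ndarray  # sample index i per design row
    entry_cols: np.ndarray  # taxon index j per design row
    neighbors: NeighborSets
    n: int
    m: int
    q: int
    psi: float
    penalty_weights: np.ndarray

    @property
    def n_params(self) -> int:
        return self.m * self.neighbors.k + self.n * (self.n - 1) + self.m * self.q


@dataclass
class ImputationModel:
    kappa: np.ndarray  # (m, m), kappa[j, j'] predicts taxon j from taxon j'
    tau: np.ndarray  # (n, n), tau[i, i'] predicts sample i from sample i'
    zeta: np.ndarray  # (m, q)
    lambda_selected: float
    psi_selected: float
    k: int
    cv_table: pd.DataFrame


@dataclass
class ImputedResult:
    Y_imputed: AbundanceMatrix
    mask: MissingMask
    counts_normalized: np.ndarray | None = None
    counts_original_scale: np.ndarray | None = None


def select_neighbor_taxa(D: PhyloDistanceMatrix, k: int) -> NeighborSets:
    """The k taxa closest to each taxon, excluding itself.

    Ties broken by ascending taxon index (np.argsort stable on the
    index-ordered distances).
    """
    m = D.values.shape[0]
    if not 1 <= k <= m - 1:
        raise ValueError(f"k must be in [1, {m - 1}], got {k}")
    Dv = D.values.copy()
    np.fill_diagonal(Dv, np.inf)
    order = np.argsort(Dv, axis=1, kind="stable")
    return NeighborSets(order[:, :k].astype(np.int64), k)


def build_design(
    Y: AbundanceMatrix,
    X: CovariateMatrix | None,
    mask: MissingMask,
    neighbors: NeighborSets,
    D: PhyloDistanceMatrix,
    psi: float,
) -> DesignProblem:
    """Assemble the sparse design over Omega (the unflagged entries).

    Predictor values at flagged positions are the observed pre-imputation
    abundances: the model is trained and applied in a single pass.
    """
    Yv = Y.values
    n, m = Yv.shape
    q = 0 if X is None else X.values.shape[1]
    k = neighbors.k
    keep = ~mask.flags
    entries = np.argwhere(keep)
    if entries.shape[0] == 0:
        raise ValueError("no trusted entries to train on")
    i_idx = entries[:, 0]
    j_idx = entries[:, 1]
    R = entries.shape[0]
    P = m * k + n * (n - 1) + m * q

    blocks_cols = []
    blocks_vals = []
    # kappa block: column j*k + c holds Y[., neighbors[j][c]] for rows of taxon j
    neigh = neighbors.indices
    blocks_cols.append(j_idx[:, None] * k + np.arange(k)[None, :])
    blocks_vals.append(Yv[i_idx[:, None], neigh[j_idx]])
    # tau block: column m*k + i*(n-1) + pos holds Y[other_sample, j]
    others = np.array([[ip for ip in range(n) if ip != i] for i in range(n)])
    blocks_cols.append(m * k + i_idx[:, None] * (n - 1) + np.arange(n - 1)[None, :])
    blocks_vals.append(Yv[others[i_idx], j_idx[:, None]])
    # zeta block: column m*k + n*(n-1) + j*q + l holds X[i, l]
    if q:
        blocks_cols.append(
            m * k + n * (n - 1) + j_idx[:, None] * q + np.arange(q)[None, :]
        )
        blocks_vals.append(np.broadcast_to(X.values[i_idx], (R, q)))

    cols = np.concatenate([b.ravel() for b in blocks_cols])
    vals = np.concatenate([np.ascontiguousarray(b).ravel() for b in blocks_vals])
    rows = np.concatenate(
        [np.repeat(np.arange(R), b.shape[1]) for b in blocks_cols]
    )
    mat = sparse.csc_matrix((vals, (rows, cols)), shape=(R, P))

    pen_w = np.empty(P)
    pen_w[: m * k] = (D.values[np.repeat(np.arange(m), k), neigh.ravel()]) ** psi
    pen_w[m * k : m * k + n * (n - 1)] = 1.0
    pen_w[m * k + n * (n - 1) :] = 0.0
    return DesignProblem(mat, Yv[i_idx, j_idx], i_idx, j_idx, neighbors,
                         n, m, q, psi, pen_w)


def _penalty_weights(problem: DesignProblem, D: PhyloDistanceMatrix,
                     psi: float) -> np.ndarray:
    m, k = problem.m, problem.neighbors.k
    w = problem.penalty_weights.copy()
    w[: m * k] = (
        D.values[np.repeat(np.arange(m), k), problem.neighbors.indices.ravel()]
        ** psi
    )
    return w


def _lambda_path(lam_max: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _canonical_folds(problem: DesignProblem, sample_ids, taxon_ids,
                     cv_folds: int, seed: int) -> np.ndarray:
    """Fold labels over Omega entries, invariant to row/column permutations.

    Entries are put in the canonical order of their (sample id, taxon id)
    string pair before the seeded shuffle, so reordering the input matrix
    does not change which entry lands in which fold.
    """
    keys = [
        (sample_ids[i], taxon_ids[j])
        for i, j in zip(problem.entry_rows, problem.entry_cols)
    ]
    canon = np.argsort(
        np.array([f"{s}\x00{t}" for s, t in keys], dtype=object), kind="stable"
    )
    rng = np.random.default_rng(seed)
    labels_canon = rng.permutation(len(keys)) % cv_folds
    folds = np.empty(len(keys), dtype=np.int64)
    folds[canon] = labels_canon
    return folds


def _unpack(beta: np.ndarray, problem: DesignProblem) -> tuple:
    n, m, q, k = problem.n, problem.m, problem.q, problem.neighbors.k
    kappa = np.zeros((m, m))
    for j in range(m):
        kappa[j, problem.neighbors.indices[j]] = beta[j * k : (j + 1) * k]
    tau = np.zeros((n, n))
    others = [[ip for ip in range(n) if ip != i] for i in range(n)]
    base = m * k
    for i in range(n):
        tau[i, others[i]] = beta[base + i * (n - 1) : base + (i + 1) * (n - 1)]
    zeta = np.zeros((m, max(q, 0)))
    if q:
        zeta = beta[base + n * (n - 1) :].reshape(m, q)
    return kappa, tau, zeta


def fit_penalized(
    Y: AbundanceMatrix,
    X: CovariateMatrix | None,
    mask: MissingMask,
    neighbors: NeighborSets,
    D: PhyloDistanceMatrix,
    psi_grid=DEFAULT_PSI_GRID,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    cv_folds: int = 5,
    seed: int = 0,
) -> ImputationModel:
    """Cross-validated weighted-Lasso fit of the joint imputation model.

    For each psi in the grid, a descending lambda path (30 log-spaced
    points from the data-derived lambda_max by default) is solved with
    warm-started coordinate descent on each training fold; (psi, lambda)
    minimizing the mean validation squared error is selected and the model
    refit on all of Omega. Fold assignment is a seeded uniform split of
    the Omega entries. When the distance matrix carries no information
    (all off-diagonal distances equal), the psi grid collapses to {0}.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    psi_grid = list(psi_grid)
    if not psi_grid:
        raise ValueError("psi grid is empty")
    off = D.values[~np.eye(D.values.shape[0], dtype=bool)]
    if np.ptp(off) == 0:
        psi_grid = [0.0]

    problem = build_design(Y, X, mask, neighbors, D, psi_grid[0])
    y = problem.response
    folds = _canonical_folds(problem, Y.sample_ids, Y.taxon_ids, cv_folds, seed)
    csr = problem.matrix.tocsr()

    records = []
    best = None
    for psi in psi_grid:
        w = _penalty_weights(problem, D, psi)
        if lambda_grid is None:
            lam_max = lambda_max(problem.matrix, y, w)
            lams = _lambda_path(lam_max, n_lambda, lambda_min_ratio)
        else:
            lams = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        val_err = np.zeros((len(lams), cv_folds))
        ok = np.ones(len(lams), dtype=bool)
        for f in range(cv_folds):
            train = folds != f
            Xtr = csr[train].tocsc()
            Xva = csr[~train]
            ytr, yva = y[train], y[~train]
            beta = None
            for li, lam in enumerate(lams):
                beta, _, _, conv = solve_weighted_lasso(
                    Xtr, ytr, w, lam, beta0=beta, tol=1e-5,
                    max_sweeps=20000,
                )
                if not conv:
                    warnings.warn(
                        f"coordinate descent did not converge at psi={psi}, "
                        f"lambda={lam:.4g}; grid point skipped"
                    )
                    ok[li] = False
                    continue
                pred = Xva @ beta
                val_err[li, f] = float(np.mean((yva - pred) ** 2))
        mean_err = val_err.mean(axis=1)
        for li, lam in enumerate(lams):
            if not ok[li]:
                continue
            records.append({"psi": psi, "lambda": lam, "cv_mse": mean_err[li]})
            if best is None or mean_err[li] < best[0]:
                best = (mean_err[li], psi, lam)
    if best is None:
        raise RuntimeError("every (psi, lambda) grid point failed")
    _, psi_sel, lam_sel = best

    w = _penalty_weights(problem, D, psi_sel)
    # warm path down to the selected lambda for the final refit
    if lambda_grid is None:
        lam_max_full = lambda_max(problem.matrix, y, w)
        path = _lambda_path(lam_max_full, n_lambda, lambda_min_ratio)
        path = np.append(path[path > lam_sel], lam_sel)
    else:
        path = [lam_sel]
    beta = None
    for lam in path:
        beta, _, _, _ = solve_weighted_lasso(
            problem.matrix, y, w, lam, beta0=beta, tol=1e-7,
            max_sweeps=20000,
        )
    kappa, tau, zeta = _unpack(beta, problem)
    return ImputationModel(
        kappa, tau, zeta, float(lam_sel), float(psi_sel), neighbors.k,
        pd.DataFrame.from_records(records),
    )


def fit_no_covariates(
    Y: AbundanceMatrix,
    mask: MissingMask,
    neighbors: NeighborSets,
    D: PhyloDistanceMatrix,
    **kwargs,
) -> ImputationModel:
    """Covariate-free variant: the zeta block is absent (P = mk + n(n-1))."""
    return fit_penalized(Y, None, mask, neighbors, D, **kwargs)


def predict_matrix(
    Y: AbundanceMatrix, model: ImputationModel, X: CovariateMatrix | None
) -> np.ndarray:
    """Linear predictions for every entry from the observed abundances."""
    pred = Y.values @ model.kappa.T + model.tau @ Y.values
    if X is not None and model.zeta.size:
        pred = pred + X.values @ model.zeta.T
    return pred


def impute(
    Y: AbundanceMatrix,
    model: ImputationModel,
    mask: MissingMask,
    X: CovariateMatrix | None = None,
) -> ImputedResult:
    """Replace flagged entries by model predictions; keep the rest bit-exact.

    Predictions are clamped below at log10(1.01) so back-transformed
    counts stay nonnegative.
    """
    pred = predict_matrix(Y, model, X)
    out = Y.values.copy()
    out[mask.flags] = np.maximum(pred[mask.flags], ABUNDANCE_FLOOR)
    return ImputedResult(
        AbundanceMatrix(out, Y.sample_ids, Y.taxon_ids), mask
    )


def back_transform(
    result: ImputedResult, library_sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Undo the log and normalization transforms.

    counts_normalized = max(10^Y - 1.01, 0);
    counts_original_scale rescales each row by library_size / 10^6.
    """
    library_sizes = np.asarray(library_sizes, dtype=float)
    counts_norm = np.maximum(10.0 ** result.Y_imputed.values - PSEUDO_OFFSET, 0.0)
    counts_orig = counts_norm * (library_sizes[:, None] / TOTAL_COUNT)
    result.counts_normalized = counts_norm
    result.counts_original_scale = counts_orig
    return counts_norm, counts_orig
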