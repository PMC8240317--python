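"""End-to-end orchestration: counts in, imputed matrices out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import impute_step2, io_preprocess, mixture_step1
from .impute_step2 import (
    DEFAULT_LAMBDA_MIN_RATIO,
    DEFAULT_N_LAMBDA,
    DEFAULT_PSI_GRID,
    ImputationModel,
    ImputedResult,
)
from .io_preprocess import (
    AbundanceMatrix,
    CountMatrix,
    CovariateMatrix,
    PhyloDistanceMatrix,
)
from .mixture_step1 import MissingMask


@dataclass
class RunResult:
    Y: AbundanceMatrix
    mask: MissingMask
    model: ImputationModel | None
    imputed: ImputedResult
    X: CovariateMatrix
    D: PhyloDistanceMatrix
    library_sizes: np.ndarray

    @property
    def Y_imputed(self) -> AbundanceMatrix:
        return self.imputed.Y_imputed


def default_k(m: int, has_tree: bool) -> int:
    """k nearest taxa: 5 with a tree; min(m-1, 20) when distances carry no
    order (neighbor choice is then arbitrary, so more neighbors are kept)."""
    return min(m - 1, 5) if has_tree else min(m - 1, 20)


def impute_abundance(
    Y: AbundanceMatrix,
    X: CovariateMatrix,
    D: PhyloDistanceMatrix,
    library_sizes: np.ndarray | None = None,
    d_thre: float = 0.5,
    alpha_lrt: float = 0.05,
    k: int | None = None,
    psi_grid=DEFAULT_PSI_GRID,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    cv_folds: int = 5,
    seed: int = 0,
) -> RunResult:
    """Run both steps on an already-transformed abundance matrix."""
    n, m = Y.values.shape
    mask = mixture_step1.identify_missing(Y, X, d_thre=d_thre, alpha_lrt=alpha_lrt)
    if library_sizes is None:
        library_sizes = np.full(n, io_preprocess.TOTAL_COUNT)
    if mask.n_flagged == 0:
        imputed = ImputedResult(
            AbundanceMatrix(Y.values.copy(), Y.sample_ids, Y.taxon_ids), mask
        )
        impute_step2.back_transform(imputed, library_sizes)
        return RunResult(Y, mask, None, imputed, X, D, library_sizes)
    off = D.values[~np.eye(m, dtype=bool)]
    has_tree = np.ptp(off) > 0
    if k is None:
        k = default_k(m, has_tree)
    neighbors = impute_step2.select_neighbor_taxa(D, k)
    model = impute_step2.fit_penalized(
        Y, X, mask, neighbors, D,
        psi_grid=psi_grid, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, cv_folds=cv_folds, seed=seed,
    )
    imputed = impute_step2.impute(Y, model, mask, X)
    impute_step2.back_transform(imputed, library_sizes)
    return RunResult(Y, mask, model, imputed, X, D, library_sizes)


def run(
    counts: CountMatrix,
    covariates: pd.DataFrame | None = None,
    tree: str | None = None,
    distance_table: pd.DataFrame | None = None,
    normalize: bool = True,
    include_libsize: bool = True,
    min_nonzero_fraction: float = 0.0,
    **kwargs,
) -> RunResult:
    """Full pipeline from a raw count matrix.

    Filters rare taxa (optional), normalizes each sample to 10^6 total
    counts (optional for pre-normalized input; library sizes are still
    taken from the row sums), log-transforms, assembles covariates, builds
    taxon distances, then runs detection and imputation. Extra keyword
    arguments are forwarded to :func:`impute_abundance`.
    """
    if min_nonzero_fraction > 0:
        counts = io_preprocess.filter_taxa(counts, min_nonzero_fraction)
    if normalize:
        Mn = io_preprocess.normalize_counts(counts)
    else:
        Mn = io_preprocess.NormalizedMatrix(
            counts.values.copy(), counts.values.sum(axis=1),
            counts.sample_ids, counts.taxon_ids,
        )
    Y = io_preprocess.log_transform(Mn)
    X = io_preprocess.build_covariates(
        covariates, Mn.library_sizes, include_libsize=include_libsize,
        sample_ids=counts.sample_ids,
    )
    D = io_preprocess.phylo_distances(tree, counts.taxon_ids, distance_table)
    return impute_abundance(Y, X, D, library_sizes=Mn.library_sizes, **kwargs)
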