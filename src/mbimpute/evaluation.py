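"""Accuracy metrics for imputation and missing-zero detection.

All comparisons are on the log10 abundance scale: mean squared error
(optionally restricted to the imputed entries), per-taxon Pearson
correlation, whole-matrix Pearson correlation, the Wasserstein-1 distance
between the two matrices' distributions of per-taxon mean/SD ratios, and
sensitivity/specificity of a predicted missingness mask against a known
truth mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import AbundanceMatrix
from .mixture_step1 import MissingMask


def _values(A) -> np.ndarray:
    return A.values if isinstance(A, AbundanceMatrix) else np.asarray(A, float)


def mse(A, B, entries: np.ndarray | str = "all") -> float:
    """Mean squared difference over all entries or a boolean entry mask."""
    Av, Bv = _values(A), _values(B)
    if Av.shape != Bv.shape:
        raise ValueError(f"shape mismatch: {Av.shape} vs {Bv.shape}")
    diff2 = (Av - Bv) ** 2
    if isinstance(entries, str):
        if entries != "all":
            raise ValueError("entries must be 'all' or a boolean mask")
        return float(diff2.mean())
    sel = np.asarray(entries, dtype=bool)
    if not sel.any():
        raise ValueError("empty entry selection")
    return float(diff2[sel].mean())


def per_taxon_pearson(A, B) -> tuple[np.ndarray, float]:
    """Columnwise Pearson correlations; zero-variance columns become NaN
    and are excluded from the mean."""
    Av, Bv = _values(A), _values(B)
    if Av.shape != Bv.shape:
        raise ValueError("shape mismatch")
    Ac = Av - Av.mean(axis=0)
    Bc = Bv - Bv.mean(axis=0)
    sa = np.sqrt((Ac**2).sum(axis=0))
    sb = np.sqrt((Bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac * Bc).sum(axis=0) / (sa * sb)
    r[(sa == 0) | (sb == 0)] = np.nan
    return r, float(np.nanmean(r))


def wasserstein_mean_sd(A, B) -> float:
    """W1 distance between the two matrices' taxon mean/SD ratio vectors.

    Zero-SD taxa are excluded from both vectors. For equal-length sorted
    vectors this is the mean absolute difference of order statistics.
    """
    ratios = []
    for M in (A, B):
        Mv = _values(M)
        mean = Mv.mean(axis=0)
        sd = Mv.std(axis=0)
        ratios.append(mean[sd > 0] / sd[sd > 0])
    return float(stats.wasserstein_distance(ratios[0], ratios[1]))


def detection_scores(mask_predicted, truth_mask) -> tuple[float, float]:
    """(sensitivity, specificity) of predicted missing entries vs truth.

    Sensitivity is NaN when the truth mask is empty; specificity is NaN
    when it is full.
    """
    pred = np.asarray(
        mask_predicted.flags if isinstance(mask_predicted, MissingMask)
        else mask_predicted,
        dtype=bool,
    )
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    n_true = truth.sum()
    n_false = (~truth).sum()
    sens = float((pred & truth).sum() / n_true) if n_true else float("nan")
    spec = float((~pred & ~truth).sum() / n_false) if n_false else float("nan")
    return sens, spec


def matrix_pearson(A, B) -> float:
    """Pearson correlation of the flattened matrices (log scale)."""
    Av, Bv = _values(A).ravel(), _values(B).ravel()
    if Av.shape != Bv.shape:
        raise ValueError("shape mismatch")
    if np.std(Av) == 0 or np.std(Bv) == 0:
        raise ValueError("zero-variance matrix")
    return float(np.corrcoef(Av, Bv)[0, 1])


@dataclass
class EvalReport:
    mse_all: float
    mse_masked: float | None
    per_taxon_pearson: np.ndarray
    mean_pearson: float
    wasserstein_mean_sd: float
    matrix_pearson: float
    detection_sensitivity: float | None = None
    detection_specificity: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "mse_all": self.mse_all,
            "mse_masked": self.mse_masked,
            "mean_pearson": self.mean_pearson,
            "wasserstein_mean_sd": self.wasserstein_mean_sd,
            "matrix_pearson": self.matrix_pearson,
            "detection_sensitivity": self.detection_sensitivity,
            "detection_specificity": self.detection_specificity,
        }
        return pd.DataFrame(
            {"metric": list(rows), "value": list(rows.values())}
        )


def evaluate(imputed, complete, truth_mask=None, predicted_mask=None
             ) -> EvalReport:
    """Full report comparing an imputed matrix against the complete truth."""
    r, mean_r = per_taxon_pearson(imputed, complete)
    sens = spec = None
    if truth_mask is not None and predicted_mask is not None:
        sens, spec = detection_scores(predicted_mask, truth_mask)
    return EvalReport(
        mse_all=mse(imputed, complete),
        mse_masked=(
            mse(imputed, complete, truth_mask) if truth_mask is not None
            and np.asarray(truth_mask).any() else None
        ),
        per_taxon_pearson=r,
        mean_pearson=mean_r,
        wasserstein_mean_sd=wasserstein_mean_sd(imputed, complete),
        matrix_pearson=matrix_pearson(imputed, complete),
        detection_sensitivity=sens,
        detection_specificity=spec,
    )
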