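"""Step 1: flag abundances that look like non-biological zeros.

Each taxon's log-scale abundances y (one column of Y) are modelled as a
two-component mixture

    y_i ~ p * Gamma(alpha, beta) + (1 - p) * Normal(x_i' gamma, sigma^2),

where the Gamma component, with mean alpha/beta close to zero, absorbs
false zeros and suspiciously low counts, and the normal component carries
the taxon's real abundances with a covariate-dependent mean. The mixture
is fit by EM; a likelihood ratio test against the plain normal model
(chi-square with 3 degrees of freedom, the mixture's three extra
parameters) screens out unimodal taxa for which the mixture is not
warranted. Entries whose posterior probability of belonging to the Gamma
component reaches ``d_thre`` (default 0.5) are flagged for imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .io_preprocess import ABUNDANCE_FLOOR, AbundanceMatrix, CovariateMatrix

P_MIN = 1e-6
SD_FLOOR = 1e-6


@dataclass
class NormalFit:
    coefs: np.ndarray
    sd: float
    loglik: float


@dataclass
class MixtureFit:
    p: float
    gamma_shape: float
    gamma_rate: float
    normal_coefs: np.ndarray
    normal_sd: float
    loglik_mixture: float
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list, repr=False)


@dataclass
class TaxonScreen:
    lrt_stat: float
    lrt_pvalue: float
    use_mixture: bool
    posteriors: np.ndarray
    mixture: MixtureFit | None = None
    normal: NormalFit | None = None


@dataclass
class MissingMask:
    """Boolean n x m partition: True = entry needs imputation (Omega^c)."""

    flags: np.ndarray
    threshold: float
    screens: list = field(default_factory=list, repr=False)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def fit_normal(y: np.ndarray, X: CovariateMatrix) -> NormalFit:
    """Gaussian MLE of y on X: OLS coefficients, sd with divisor n."""
    y = np.asarray(y, dtype=float)
    Xv = X.values
    n, q = Xv.shape
    if n <= q:
        raise ValueError(f"need n > q, got n={n}, q={q}")
    rank = np.linalg.matrix_rank(Xv)
    if rank < q:
        raise ValueError(
            f"covariate matrix is rank deficient (rank {rank} < {q} columns)"
        )
    coefs, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ coefs
    sd = float(np.sqrt(np.mean(resid**2)))
    if sd < SD_FLOOR:
        warnings.warn("residual variance ~ 0; flooring sd at 1e-6")
        sd = SD_FLOOR
    loglik = float(np.sum(stats.norm.logpdf(y, Xv @ coefs, sd)))
    return NormalFit(coefs, sd, loglik)


def _weighted_gamma_mle(y, w, max_iter=50):
    """Weighted Gamma MLE via Newton on the shape (digamma equation).

    Maximizes sum_i w_i log f_Gamma(y_i; a, b). Rate given shape:
    b = a * sum(w) / sum(w y). Shape solves log(a) - digamma(a) = s with
    s = log(weighted mean) - weighted mean of logs.
    """
    wsum = w.sum()
    mean = float(np.dot(w, y) / wsum)
    mean_log = float(np.dot(w, np.log(y)) / wsum)
    s = np.log(mean) - mean_log
    if s <= 1e-12:  # degenerate: (near) zero dispersion
        a = 1e6
    else:
        a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
        for _ in range(max_iter):
            g = np.log(a) - special.digamma(a) - s
            gp = 1.0 / a - special.polygamma(1, a)
            step = g / gp
            a_new = a - step
            if a_new <= 0:
                a_new = a / 2.0
            if abs(a_new - a) < 1e-10 * a:
                a = a_new
                break
            a = a_new
    a = float(np.clip(a, 1e-3, 1e6))
    b = a / mean
    return a, b


def _mixture_loglik(y, Xv, p, a, b, coefs, sd):
    lg = stats.gamma.logpdf(y, a, scale=1.0 / b)
    ln = stats.norm.logpdf(y, Xv @ coefs, sd)
    stacked = np.stack([np.log(p) + lg, np.log1p(-p) + ln])
    return float(special.logsumexp(stacked, axis=0).sum())


def fit_mixture_em(
    y: np.ndarray,
    X: CovariateMatrix,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> MixtureFit:
    """Fit the Gamma-normal mixture by EM.

    E-step: responsibilities r_i that y_i came from the Gamma component.
    M-step: p = mean(r); normal coefficients by responsibility-weighted
    least squares with weighted residual variance; Gamma parameters by
    responsibility-weighted MLE. Responsibilities start at 1 for entries
    within 0.3 of the abundance floor (a normalized count below ~1) and 0
    elsewhere; if that split is empty on either side, the lower 20%
    quantile of y is used instead.

    The final fit is compared against the boundary solution p -> 0 (the
    plain normal fit) and the better log-likelihood is kept, so the
    mixture never scores below its nested normal model. If the fitted
    Gamma mean exceeds the average fitted normal mean, the labels have
    switched and the boundary solution is kept too.
    """
    y = np.asarray(y, dtype=float)
    Xv = X.values
    n, q = Xv.shape
    if n <= q + 3:
        raise ValueError(f"need n > q + 3, got n={n}, q={q}")
    if np.any(y <= 0):
        raise ValueError("abundances must be strictly positive")

    norm0 = fit_normal(y, X)
    boundary = MixtureFit(
        p=P_MIN,
        gamma_shape=2.0,
        gamma_rate=2.0 / max(ABUNDANCE_FLOOR, np.min(y)),
        normal_coefs=norm0.coefs,
        normal_sd=norm0.sd,
        loglik_mixture=norm0.loglik,
        converged=False,
        n_iter=0,
    )

    r = (y < ABUNDANCE_FLOOR + 0.3).astype(float)
    if r.sum() == 0 or r.sum() == n:
        r = (y <= np.quantile(y, 0.2)).astype(float)
    if r.sum() == 0 or r.sum() == n:
        return boundary

    p = float(np.clip(r.mean(), P_MIN, 1 - P_MIN))
    ll_prev = -np.inf
    trace: list[float] = []
    a = b = None
    coefs, sd = norm0.coefs, norm0.sd
    converged = False
    it = 0
    try:
        for it in range(1, max_iter + 1):
            # M-step
            p = float(np.clip(r.mean(), P_MIN, 1 - P_MIN))
            wn = 1.0 - r
            if r.sum() < 1e-8 or wn.sum() <= q:
                return boundary
            a, b = _weighted_gamma_mle(y, np.maximum(r, 1e-12))
            W = np.sqrt(wn)
            coefs, *_ = np.linalg.lstsq(W[:, None] * Xv, W * y, rcond=None)
            resid = y - Xv @ coefs
            sd = float(np.sqrt(np.dot(wn, resid**2) / wn.sum()))
            sd = max(sd, SD_FLOOR)
            # E-step
            lg = np.log(p) + stats.gamma.logpdf(y, a, scale=1.0 / b)
            ln = np.log1p(-p) + stats.norm.logpdf(y, Xv @ coefs, sd)
            mx = np.maximum(lg, ln)
            denom = mx + np.log(np.exp(lg - mx) + np.exp(ln - mx))
            r = np.exp(lg - denom)
            ll = float(denom.sum())
            trace.append(ll)
            if np.isfinite(ll) and abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
                converged = True
                ll_prev = ll
                break
            if not np.isfinite(ll):
                return boundary
            ll_prev = ll
    except (np.linalg.LinAlgError, FloatingPointError, ValueError):
        return boundary

    if a is None or not np.isfinite(ll_prev):
        return boundary
    # label-switching guard: the Gamma mode must be a genuinely low mode,
    # well below the normal component, not a relabelled left tail; the
    # half-mean alternative keeps taxa whose normal sd is inflated
    mean_norm = float(np.mean(Xv @ coefs))
    if a / b > max(mean_norm - 2.0 * sd, 0.5 * mean_norm):
        return boundary
    if ll_prev < boundary.loglik_mixture:
        return boundary
    return MixtureFit(p, float(a), float(b), coefs, sd, ll_prev, converged,
                      it, trace)


def lrt_screen(mix: MixtureFit, norm: NormalFit) -> tuple[float, float]:
    """Likelihood ratio statistic and its chi-square(3) upper-tail p-value."""
    lam = max(0.0, 2.0 * (mix.loglik_mixture - norm.loglik))
    pvalue = float(stats.chi2.sf(lam, df=3))
    return lam, pvalue


def posterior_missing(
    y: np.ndarray, X: CovariateMatrix, mix: MixtureFit
) -> np.ndarray:
    """Posterior probability each entry came from the Gamma (missing) mode."""
    y = np.asarray(y, dtype=float)
    lg = np.log(mix.p) + stats.gamma.logpdf(
        y, mix.gamma_shape, scale=1.0 / mix.gamma_rate
    )
    ln = np.log1p(-mix.p) + stats.norm.logpdf(
        y, X.values @ mix.normal_coefs, mix.normal_sd
    )
    mx = np.maximum(lg, ln)
    d = np.exp(lg - mx) / (np.exp(lg - mx) + np.exp(ln - mx))
    return np.clip(d, 0.0, 1.0)


def screen_taxon(
    y: np.ndarray, X: CovariateMatrix, alpha_lrt: float = 0.05
) -> TaxonScreen:
    """Fit both models for one taxon and decide whether to trust the mixture."""
    n = len(y)
    q = X.q
    fallback = TaxonScreen(0.0, 1.0, False, np.zeros(n))
    if n < q + 4 or np.ptp(y) == 0:
        return fallback
    try:
        norm = fit_normal(y, X)
        mix = fit_mixture_em(y, X)
    except (ValueError, np.linalg.LinAlgError):
        return fallback
    lam, pvalue = lrt_screen(mix, norm)
    use_mixture = pvalue <= alpha_lrt
    if use_mixture:
        d = posterior_missing(y, X, mix)
    else:
        d = np.zeros(n)
    return TaxonScreen(lam, pvalue, use_mixture, d, mix, norm)


def identify_missing(
    Y: AbundanceMatrix,
    X: CovariateMatrix,
    d_thre: float = 0.5,
    alpha_lrt: float = 0.05,
) -> MissingMask:
    """Partition all (sample, taxon) entries into keep (Omega) and impute.

    Per taxon: fit the normal and mixture models, run the LRT screen, and
    flag entries with posterior d >= d_thre. Taxa whose fits fail fall
    back to "keep everything" rather than aborting the matrix.
    """
    n, m = Y.values.shape
    if X.values.shape[0] != n:
        raise ValueError("covariate rows do not match sample count")
    flags = np.zeros((n, m), dtype=bool)
    screens = []
    for j in range(m):
        screen = screen_taxon(Y.values[:, j], X, alpha_lrt)
        flags[:, j] = screen.posteriors >= d_thre
        screens.append(screen)
    return MissingMask(flags, d_thre, screens)
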