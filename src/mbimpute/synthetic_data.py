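"""Synthetic microbiome abundance data with known ground truth.

The generator produces complete log10-scale abundance matrices whose
signal can be encoded in any combination of three sources — sample
covariates (per-taxon regression coefficients), latent sample clusters
(shared row shifts), and phylogenetic taxon blocks (per-sample latent
factors shared by tree-adjacent taxa) — and then corrupts them with
non-biological zeros, either mixture-style (each entry independently
replaced, with a probability that grows as taxon mean abundance falls, by
a draw from a near-zero Gamma mode) or by proportional downsampling of
counts (larger counts are more likely to survive). The truth mask of
corrupted entries makes detection and recovery mechanically checkable.

Independent RNG streams are used for the tree, the signal, the noise, and
the missingness so that changing one leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io_preprocess import (
    ABUNDANCE_FLOOR,
    AbundanceMatrix,
    CountMatrix,
    CovariateMatrix,
    PhyloDistanceMatrix,
    phylo_distances,
)

SCHEMES = ("covariates-only", "samples-only", "taxa-only", "all")


@dataclass
class SimulationConfig:
    n: int = 50
    m: int = 60
    q_user: int = 2  # user covariates, before the intercept
    scheme: str = "all"
    seed: int = 0
    # complete-data signal
    mu_low: float = 2.5
    mu_high: float = 5.5
    covariate_coef_sd: float = 0.6
    n_sample_clusters: int = 3
    sample_cluster_sd: float = 1.0
    taxon_block_size: int = 10
    taxon_block_sd: float = 1.0
    noise_sd: float = 0.5
    # missingness: p_j = expit(logit(base_rate) + rate_slope * (mean mu - mu_j))
    base_missing_rate: float = 0.3
    rate_slope: float = 0.5
    gamma_shape: float = 2.0
    gamma_rate: float = 20.0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.n < 2 or self.m < 2:
            raise ValueError("need n >= 2 and m >= 2")
        if not 0.0 <= self.base_missing_rate < 1.0:
            raise ValueError("base_missing_rate must be in [0, 1)")


@dataclass
class SimulatedDataset:
    Y_complete: AbundanceMatrix
    Y_observed: AbundanceMatrix
    truth_mask: np.ndarray
    X: CovariateMatrix
    D: PhyloDistanceMatrix
    newick: str
    params: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def _streams(seed: int):
    root = np.random.SeedSequence(seed)
    keys = ("tree", "signal", "noise", "missing")
    return dict(zip(keys, (np.random.default_rng(s) for s in root.spawn(4))))


def _random_subtree(leaves: list[str], rng) -> str:
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [x for idx, x in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def gen_tree_and_distances(
    m: int, seed: int, taxon_ids: list[str] | None = None,
    block_size: int | None = None,
) -> tuple[PhyloDistanceMatrix, str, np.ndarray]:
    """Random binary tree over m leaves; branch-count distances.

    With ``block_size``, leaves are grouped into contiguous blocks that
    are each built as a subtree before the subtrees are joined, so block
    members are guaranteed tree-adjacent. Returns (D, newick, block ids).
    """
    if m < 2:
        raise ValueError("need at least two taxa")
    if taxon_ids is None:
        taxon_ids = [f"taxon_{j}" for j in range(m)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if block_size is None or block_size >= m:
        blocks = np.zeros(m, dtype=np.int64)
        newick = _random_subtree(list(taxon_ids), rng) + ";"
    else:
        blocks = np.arange(m) // block_size
        subtrees = []
        for b in np.unique(blocks):
            members = [taxon_ids[j] for j in np.flatnonzero(blocks == b)]
            subtrees.append(
                members[0] if len(members) == 1 else _random_subtree(members, rng)
            )
        newick = _random_subtree(subtrees, rng) + ";"
    D = phylo_distances(newick, taxon_ids)
    return D, newick, blocks


def abundant_taxa_config(seed: int, **overrides) -> SimulationConfig:
    """Complete-data profile for downsampling experiments.

    Emulates a low-zero sub-matrix of abundant taxa (the kind obtained by
    keeping only taxa observed in nearly all samples): taxon means are
    drawn from the upper abundance range, so the complete matrix carries
    essentially no entries at the detection floor, and no mixture-style
    missingness is injected — the only zeros are the ones downsampling
    introduces.
    """
    defaults = dict(mu_low=3.5, mu_high=5.5, base_missing_rate=0.0)
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


def gen_complete(config: SimulationConfig) -> SimulatedDataset:
    """Draw a complete (no missing entries) abundance matrix.

    Y_ij = mu_j + a_i + f_{i,block(j)} + X_i' gamma_j + eps_ij, with the
    three signal blocks gated by the scheme, floored at log10(1.01).
    """
    n, m, q = config.n, config.m, config.q_user
    streams = _streams(config.seed)
    sample_ids = [f"sample_{i}" for i in range(n)]
    taxon_ids = [f"taxon_{j}" for j in range(m)]

    D, newick, blocks = gen_tree_and_distances(
        m, config.seed, taxon_ids, block_size=config.taxon_block_size
    )
    sig = streams["signal"]
    mu = sig.uniform(config.mu_low, config.mu_high, size=m)
    Xu = sig.standard_normal((n, q))
    gamma = sig.normal(0.0, config.covariate_coef_sd, size=(m, q))
    clusters = sig.integers(0, config.n_sample_clusters, size=n)
    cluster_eff = sig.normal(0.0, config.sample_cluster_sd,
                             size=config.n_sample_clusters)
    n_blocks = int(blocks.max()) + 1
    block_factors = sig.normal(0.0, config.taxon_block_sd, size=(n, n_blocks))

    use_cov = config.scheme in ("covariates-only", "all")
    use_samp = config.scheme in ("samples-only", "all")
    use_taxa = config.scheme in ("taxa-only", "all")

    Y = np.tile(mu, (n, 1))
    if use_cov:
        Y = Y + Xu @ gamma.T
    if use_samp:
        Y = Y + cluster_eff[clusters][:, None]
    if use_taxa:
        Y = Y + block_factors[:, blocks]
    Y = Y + streams["noise"].normal(0.0, config.noise_sd, size=(n, m))
    Y = np.maximum(Y, ABUNDANCE_FLOOR)

    X = CovariateMatrix(
        np.column_stack([np.ones(n), Xu]),
        ["intercept"] + [f"cov_{l}" for l in range(q)],
    )
    complete = AbundanceMatrix(Y, sample_ids, taxon_ids)
    params = {
        "mu": mu, "gamma": gamma, "clusters": clusters,
        "cluster_eff": cluster_eff, "blocks": blocks,
    }
    return SimulatedDataset(
        complete, complete, np.zeros((n, m), dtype=bool), X, D, newick,
        params, config,
    )


def inject_missing(dataset: SimulatedDataset,
                   config: SimulationConfig | None = None) -> SimulatedDataset:
    """Mixture-style corruption: replace entries by near-zero Gamma draws.

    Per taxon j, each entry is independently replaced with probability
    p_j = expit(logit(base rate) + slope * (mean mu - mu_j)), so sparser
    (lower-abundance) taxa lose more entries. Replacement values are
    Gamma(shape, rate) draws truncated to >= log10(1.01).
    """
    config = config or dataset.config
    rng = _streams(config.seed)["missing"]
    Yc = dataset.Y_complete.values
    n, m = Yc.shape
    mu = dataset.params["mu"]
    if config.base_missing_rate == 0.0:
        p_taxon = np.zeros(m)
    else:
        logit_base = np.log(
            config.base_missing_rate / (1 - config.base_missing_rate)
        )
        p_taxon = expit(logit_base + config.rate_slope * (mu.mean() - mu))
    mask = rng.random((n, m)) < p_taxon[None, :]
    draws = rng.gamma(config.gamma_shape, 1.0 / config.gamma_rate, size=(n, m))
    # truncate to the abundance floor by redrawing the rare under-floor values
    for _ in range(100):
        low = mask & (draws < ABUNDANCE_FLOOR)
        if not low.any():
            break
        draws[low] = rng.gamma(config.gamma_shape, 1.0 / config.gamma_rate,
                               size=int(low.sum()))
    draws = np.maximum(draws, ABUNDANCE_FLOOR)
    Yo = Yc.copy()
    Yo[mask] = draws[mask]
    observed = AbundanceMatrix(Yo, dataset.Y_complete.sample_ids,
                               dataset.Y_complete.taxon_ids)
    params = dict(dataset.params, p_taxon=p_taxon)
    return SimulatedDataset(dataset.Y_complete, observed, mask, dataset.X,
                            dataset.D, dataset.newick, params, config)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Complete data plus mixture-style missingness, in one call."""
    return inject_missing(gen_complete(config))


def to_counts(Y: AbundanceMatrix, library_sizes: np.ndarray | None = None
              ) -> CountMatrix:
    """Map log-scale abundances back to integer counts.

    Rounds 10^Y - 1.01 (so the floor maps to count 0); optional per-sample
    rescaling by library size / 10^6 is skipped when sizes are not given,
    leaving the rows on the normalized scale.
    """
    counts = np.maximum(np.round(10.0 ** Y.values - 1.01), 0.0)
    if library_sizes is not None:
        counts = np.round(
            counts * np.asarray(library_sizes, dtype=float)[:, None] / 1e6
        )
    return CountMatrix(counts, Y.sample_ids, Y.taxon_ids)


def downsample(M: CountMatrix, keep_fraction: float, seed: int
               ) -> tuple[CountMatrix, np.ndarray]:
    """Proportional downsampling of nonzero counts, per sample.

    In each sample, ceil(keep_fraction * #nonzero) of the nonzero taxa are
    retained, sampled without replacement with inclusion probability
    proportional to count; the rest are set to zero and recorded in the
    returned truth mask. keep_fraction 0.6 / 0.3 correspond to removal
    rates of 40% / 70%.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    values = M.values.copy()
    mask = np.zeros(values.shape, dtype=bool)
    if keep_fraction == 1.0:
        return CountMatrix(values, M.sample_ids, M.taxon_ids), mask
    for i in range(values.shape[0]):
        nz = np.flatnonzero(values[i] > 0)
        if nz.size == 0:
            continue
        n_keep = int(np.ceil(keep_fraction * nz.size))
        probs = values[i, nz] / values[i, nz].sum()
        kept = rng.choice(nz, size=n_keep, replace=False, p=probs)
        dropped = np.setdiff1d(nz, kept)
        values[i, dropped] = 0.0
        mask[i, dropped] = True
    return CountMatrix(values, M.sample_ids, M.taxon_ids), mask


def gen_outlier_samples(dataset: SimulatedDataset, n_outliers: int,
                        n_boosted_taxa: int, seed: int) -> SimulatedDataset:
    """Append aberrant samples: large abundances on a few rare taxa, zero rest.

    Emulates contaminated or mislabelled samples; the boosted taxa are the
    lowest-abundance ones, raised to the top of the observed range, with
    every other taxon at the abundance floor. Outlier rows are flagged in
    ``params['outlier_rows']``.
    """
    if n_outliers == 0:
        return dataset
    Yc = dataset.Y_complete.values
    n, m = Yc.shape
    if n_boosted_taxa >= m:
        raise ValueError("n_boosted_taxa must be < m")
    rng = np.random.default_rng(seed)
    mu = dataset.params["mu"]
    boosted = np.argsort(mu)[:n_boosted_taxa]
    high = np.quantile(Yc, 0.99)
    rows_c = np.full((n_outliers, m), ABUNDANCE_FLOOR)
    rows_c[:, boosted] = rng.normal(high, 0.2, size=(n_outliers, n_boosted_taxa))
    sample_ids = dataset.Y_complete.sample_ids + [
        f"outlier_{i}" for i in range(n_outliers)
    ]
    taxon_ids = dataset.Y_complete.taxon_ids
    Yc2 = np.vstack([Yc, rows_c])
    Yo2 = np.vstack([dataset.Y_observed.values, rows_c])
    mask2 = np.vstack([dataset.truth_mask,
                       np.zeros((n_outliers, m), dtype=bool)])
    q = dataset.X.values.shape[1]
    X2 = CovariateMatrix(
        np.vstack([dataset.X.values,
                   np.column_stack([np.ones((n_outliers, 1)),
                                    rng.standard_normal((n_outliers, q - 1))])]),
        dataset.X.column_names,
    )
    params = dict(dataset.params,
                  outlier_rows=np.arange(n, n + n_outliers))
    return SimulatedDataset(
        AbundanceMatrix(Yc2, sample_ids, taxon_ids),
        AbundanceMatrix(Yo2, sample_ids, taxon_ids),
        mask2, X2, dataset.D, dataset.newick, params, dataset.config,
    )
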