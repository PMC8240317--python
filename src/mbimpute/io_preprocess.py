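"""Input parsing, normalization, log transform, covariates, and taxon distances.

The imputation model operates on a sample-by-taxon abundance matrix
``Y = log10(M_norm + 1.01)``, where ``M_norm`` is the count matrix rescaled
so that every sample (row) totals 10^6 reads. The pseudo-offset 1.01 keeps
every abundance strictly positive, which the downstream Gamma mixture
component requires. This module owns those transforms plus the two side
inputs: the sample covariate matrix X (intercept first, optionally the
log10 library size) and the taxon-by-taxon phylogenetic distance matrix D
(branch counts on the tree path between two leaves, or all-ones when no
tree is available).
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

TOTAL_COUNT = 1e6
PSEUDO_OFFSET = 1.01
#: smallest possible abundance: log10(1.01), the transform of a zero count
ABUNDANCE_FLOOR = float(np.log10(PSEUDO_OFFSET))


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural requirement."""


@dataclass
class CountMatrix:
    """Raw (or pre-normalized) nonnegative counts, samples in rows."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValidationError(
                f"need at least 2 samples and 2 taxa, got {n}x{m}"
            )
        if len(self.sample_ids) != n or len(self.taxon_ids) != m:
            raise ValidationError("id lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        if len(set(self.taxon_ids)) != m:
            raise ValidationError("taxon ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite entries")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizedMatrix:
    """Counts rescaled so each row sums to 10^6; original row totals kept."""

    values: np.ndarray
    library_sizes: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]


@dataclass
class AbundanceMatrix:
    """Strictly positive log10-scale abundances Y."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]


@dataclass
class CovariateMatrix:
    """Sample covariates X (n x q); first column is the intercept."""

    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValidationError("first covariate column must be the intercept")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("covariate matrix contains non-finite values")
        for l, name in enumerate(self.column_names[1:], start=1):
            if np.ptp(self.values[:, l]) == 0:
                raise ValidationError(f"covariate {name!r} has zero variance")

    @property
    def q(self) -> int:
        return self.values.shape[1]


@dataclass
class PhyloDistanceMatrix:
    """Symmetric taxon-by-taxon distances with zero diagonal."""

    values: np.ndarray
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.shape[0] != D.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(D, D.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        off = D[~np.eye(D.shape[0], dtype=bool)]
        if np.any(off <= 0):
            raise ValidationError("off-diagonal distances must be positive")
        self.values = D


def _read_table(path_or_buf, sep: str | None = None) -> pd.DataFrame:
    if sep is None and isinstance(path_or_buf, (str, os.PathLike)):
        sep = "," if str(path_or_buf).lower().endswith(".csv") else "\t"
    return pd.read_csv(path_or_buf, sep=sep or "\t", index_col=0)


def read_count_matrix(path, orientation: str = "samples-in-rows") -> CountMatrix:
    """Parse a delimited count table into samples-by-taxa orientation.

    The file must carry a header row and an id column. ``orientation``
    says what the file's rows are; the result always has samples in rows.
    """
    if orientation not in ("samples-in-rows", "taxa-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for i, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[int(np.argmax(bad.to_numpy()))]
                raise ValidationError(
                    f"non-numeric cell at row {row!r}, column {col!r}"
                ) from exc
        raise
    if orientation == "taxa-in-rows":
        values = values.T
        sample_ids, taxon_ids = list(df.columns), list(df.index)
    else:
        sample_ids, taxon_ids = list(df.index), list(df.columns)
    return CountMatrix(values, sample_ids, taxon_ids)


def write_count_matrix(M: CountMatrix, path) -> None:
    df = pd.DataFrame(M.values, index=M.sample_ids, columns=M.taxon_ids)
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df.to_csv(path, sep=sep)


def normalize_counts(M: CountMatrix) -> NormalizedMatrix:
    """Total-sum scaling: rescale each sample to a library size of 10^6."""
    row_sums = M.values.sum(axis=1)
    empty = np.flatnonzero(row_sums <= 0)
    if empty.size:
        raise ValidationError(
            f"sample {M.sample_ids[empty[0]]!r} has zero total count"
        )
    values = TOTAL_COUNT * M.values / row_sums[:, None]
    return NormalizedMatrix(values, row_sums.copy(), M.sample_ids, M.taxon_ids)


def log_transform(Mn: NormalizedMatrix) -> AbundanceMatrix:
    """Elementwise ``log10(x + 1.01)``; strictly positive by construction."""
    if np.any(Mn.values < 0):
        raise ValidationError("normalized matrix has negative entries")
    return AbundanceMatrix(
        np.log10(Mn.values + PSEUDO_OFFSET), Mn.sample_ids, Mn.taxon_ids
    )


def build_covariates(
    table: pd.DataFrame | None,
    library_sizes: np.ndarray,
    include_libsize: bool = True,
    sample_ids: list[str] | None = None,
) -> CovariateMatrix:
    """Assemble X = [intercept | log10 library size | user covariates].

    Categorical user columns are expanded to indicator columns, dropping
    the first level as reference. The library size enters on the log10
    scale so its magnitude is comparable to the abundances.
    """
    library_sizes = np.asarray(library_sizes, dtype=float)
    n = library_sizes.shape[0]
    cols = [np.ones(n)]
    names = ["intercept"]
    if include_libsize:
        if np.any(library_sizes <= 0):
            raise ValidationError("library sizes must be positive")
        logsize = np.log10(library_sizes)
        if np.ptp(logsize) == 0:
            # already on a common scale: the column would duplicate the
            # intercept, so leave it out
            warnings.warn(
                "library sizes are constant; omitting the size covariate"
            )
        else:
            cols.append(logsize)
            names.append("log10_library_size")
    if table is not None:
        if len(table) != n:
            raise ValidationError(
                f"covariate table has {len(table)} rows, expected {n}"
            )
        if table.isna().any().any():
            raise ValidationError("covariate table contains missing values")
        if sample_ids is not None and list(table.index) != list(sample_ids):
            if set(table.index) == set(sample_ids):
                table = table.loc[sample_ids]
            else:
                raise ValidationError("covariate rows do not match sample ids")
        expanded = pd.get_dummies(table, drop_first=True, dtype=float)
        for name in expanded.columns:
            cols.append(expanded[name].to_numpy(dtype=float))
            names.append(str(name))
    return CovariateMatrix(np.column_stack(cols), names)


def phylo_distances(
    tree: str | None,
    taxon_ids: list[str],
    distance_table: pd.DataFrame | None = None,
    use_branch_lengths: bool = False,
) -> PhyloDistanceMatrix:
    """Build the taxon distance matrix D.

    From a newick tree, ``D[j, j']`` is the number of branches on the path
    between leaves j and j' (or, with ``use_branch_lengths``, the patristic
    distance). A user distance table overrides the tree. With neither, all
    off-diagonal distances are 1, which makes the phylogenetic penalty
    weights uniform.
    """
    m = len(taxon_ids)
    if distance_table is not None:
        if list(distance_table.index) != list(distance_table.columns):
            raise ValidationError("distance table rows and columns disagree")
        missing = [t for t in taxon_ids if t not in distance_table.index]
        if missing:
            raise ValidationError(f"taxa absent from distance table: {missing}")
        D = distance_table.loc[taxon_ids, taxon_ids].to_numpy(dtype=float)
        return PhyloDistanceMatrix(D, list(taxon_ids))
    if tree is None:
        D = np.ones((m, m)) - np.eye(m)
        return PhyloDistanceMatrix(D, list(taxon_ids))
    t = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    labels = {taxon.label: taxon for taxon in t.taxon_namespace}
    missing = [tid for tid in taxon_ids if tid not in labels]
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing}")
    keep = set(taxon_ids)
    if len(labels) > m:
        t.retain_taxa_with_labels(list(keep))
        labels = {taxon.label: taxon for taxon in t.taxon_namespace}
    pdm = t.phylogenetic_distance_matrix()
    D = np.zeros((m, m))
    for j in range(m):
        for jp in range(j + 1, m):
            if use_branch_lengths:
                d = pdm.patristic_distance(labels[taxon_ids[j]], labels[taxon_ids[jp]])
            else:
                d = pdm.path_edge_count(labels[taxon_ids[j]], labels[taxon_ids[jp]])
            D[j, jp] = D[jp, j] = float(d)
    return PhyloDistanceMatrix(D, list(taxon_ids))


def filter_taxa(M: CountMatrix, min_nonzero_fraction: float = 0.0) -> CountMatrix:
    """Drop taxa observed (nonzero) in fewer than a fraction of samples."""
    if not 0.0 <= min_nonzero_fraction <= 1.0:
        raise ValueError("min_nonzero_fraction must lie in [0, 1]")
    frac = (M.values > 0).mean(axis=0)
    keep = frac >= min_nonzero_fraction
    if not keep.any():
        raise ValidationError("filter removed every taxon")
    if keep.all():
        return M
    return CountMatrix(
        M.values[:, keep],
        M.sample_ids,
        [t for t, k in zip(M.taxon_ids, keep) if k],
    )
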