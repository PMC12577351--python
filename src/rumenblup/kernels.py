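"""Relationship-matrix (kernel) construction.

Builds the animal-by-animal (co)variance structures used by the mixed
models: a VanRaden method-1 genomic relationship matrix (GRM) from SNP
dosages, six metagenome relationship matrices (MRMs) from ORF log
relative abundances (two construction methods crossed with naive,
weighted, and data-driven adjustments), Hadamard genome-by-metagenome
interaction kernels, and the diagonal "tuning" that guarantees
invertibility.

Conventions
-----------
* Column variances use the sample (n-1) denominator by default, which
  makes trace(M1) = trace(M2) = n-1 an exact identity; pass ``ddof=0``
  for the population convention.
* Kernels are carried in :class:`RelationshipMatrix`, which records the
  construction kind, whether the kernel has been tuned, and optional
  cluster labels / ORF weights used to build it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "RelationshipMatrix",
    "build_grm",
    "log_relative_abundance",
    "build_mrm",
    "assign_clusters",
    "build_mrm_multipop",
    "hadamard_interaction",
    "tune",
    "is_psd",
]

#: relative tolerance on the smallest eigenvalue of an untuned kernel
PSD_RTOL = 1e-8


@dataclass
class RelationshipMatrix:
    """A symmetric n x n kernel with provenance metadata.

    Parameters
    ----------
    values
        The dense symmetric matrix.
    kind
        Construction tag, e.g. ``"G"``, ``"M1"``, ``"M2W"``, ``"M1P"``,
        ``"J"``.
    tuned
        Whether ``epsilon * I`` has already been added.
    ids
        Optional animal identifiers (row/column order).
    cluster_labels
        Per-animal cluster labels for data-driven kernels.
    weights
        Per-ORF weights (1 - h2_ORF) used for weighted kernels.
    """

    values: np.ndarray
    kind: str
    tuned: bool = False
    ids: list | None = None
    cluster_labels: np.ndarray | None = None
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        ids = self.ids if self.ids is not None else list(range(self.n))
        return pd.DataFrame(self.values, index=ids, columns=ids)


def _as_matrix(x) -> tuple[np.ndarray, list | None]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index)
    return np.asarray(x, dtype=float), None


def is_psd(values: np.ndarray, rtol: float = PSD_RTOL) -> bool:
    """Check positive semidefiniteness up to a trace-relative tolerance."""
    values = np.asarray(values, dtype=float)
    w = np.linalg.eigvalsh(values)
    tol = rtol * max(np.trace(values), 1.0) / values.shape[0]
    return bool(w.min() >= -tol)


def build_grm(genotypes) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = (Q - P)(Q - P)' / (2 * sum_i p_i (1 - p_i)) where Q holds
    alternate-allele dosages in {0, 1, 2}, p_i is the observed
    alternate-allele frequency at SNP i and P has columns 2 p_i.
    Because the frequencies come from the data themselves the columns of
    Q - P are centered, so rows of G sum to zero.
    """
    Q, ids = _as_matrix(genotypes)
    if np.isnan(Q).any():
        raise ValueError("genotypes contain missing values; impute first")
    if Q.shape[1] < 1:
        raise ValueError("need at least one SNP column")
    p = Q.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ZeroDivisionError(
            "all SNP columns are monomorphic: sum 2*p*(1-p) is zero"
        )
    Z = Q - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, kind="G", ids=ids)


def log_relative_abundance(counts) -> pd.DataFrame:
    """Log10 relative abundance with a unit pseudocount.

    S_ij = log10((R_ij + 1) / sum_j (R_ij + 1)), so per row the
    back-transformed abundances 10**S sum to one.
    """
    R, ids = _as_matrix(counts)
    if (R < 0).any():
        raise ValueError("negative read counts")
    shifted = R + 1.0
    S = np.log10(shifted / shifted.sum(axis=1, keepdims=True))
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(S, index=counts.index, columns=counts.columns)
    return pd.DataFrame(S, index=ids)


def _col_var(S: np.ndarray, ddof: int) -> np.ndarray:
    return S.var(axis=0, ddof=ddof)


def build_mrm(S, method: int, weights=None, ddof: int = 1) -> RelationshipMatrix:
    """Metagenome relationship matrix from log relative abundances.

    Method 1 (VanRaden-1 analogue):
        M1 = (S - N) D (S - N)' / sum_j var(s_j)
    Method 2 (column-standardized cross-product):
        M2 = (1/m) C D C',  C_ij = (S_ij - mean_j) / sd_j

    D is diag(weights) (identity when ``weights`` is None).  Weights are
    1 - h2_ORF for the weighted adjustment and must lie in [0, 1].
    """
    Smat, ids = _as_matrix(S)
    n, m = Smat.shape
    if method not in (1, 2):
        raise ValueError("method must be 1 or 2")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (m,):
            raise ValueError("weights must have one entry per ORF")
        if ((weights < 0) | (weights > 1)).any():
            raise ValueError("weights must lie in [0, 1]")
    var = _col_var(Smat, ddof)
    centered = Smat - Smat.mean(axis=0)
    if method == 1:
        denom = var.sum()
        if denom <= 0:
            raise ZeroDivisionError("sum of ORF variances is zero")
        Y = centered if weights is None else centered * np.sqrt(weights)
        M = (Y @ Y.T) / denom
        kind = "M1" if weights is None else "M1W"
    else:
        if (var <= 0).any():
            bad = int(np.flatnonzero(var <= 0)[0])
            raise ZeroDivisionError(
                f"zero-variance ORF column {bad}: method 2 cannot standardize"
            )
        C = centered / np.sqrt(var)
        Y = C if weights is None else C * np.sqrt(weights)
        M = (Y @ Y.T) / m
        kind = "M2" if weights is None else "M2W"
    M = 0.5 * (M + M.T)
    return RelationshipMatrix(M, kind=kind, ids=ids, weights=weights)


def assign_clusters(
    S, n_components: int = 4, k: int = 2, seed: int = 0
) -> np.ndarray:
    """Cluster animals on the leading principal components of S.

    PCA on the ORF matrix followed by k-means (25 restarts, k-means++)
    on the first ``n_components`` scores.  Returns labels in {1..k}.
    """
    Smat, _ = _as_matrix(S)
    n = Smat.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of animals n={n}")
    if k == 1:
        return np.ones(n, dtype=int)
    n_components = min(n_components, min(Smat.shape))
    scores = PCA(n_components=n_components, random_state=seed).fit_transform(Smat)
    km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(scores)
    return km.labels_.astype(int) + 1


def build_mrm_multipop(S, method: int, labels, ddof: int = 1) -> RelationshipMatrix:
    """Multi-population (data-driven) MRM with per-cluster scaling.

    Within-cluster blocks follow the single-population construction
    using that cluster's column means and variances; method-1 cross
    blocks are divided by the geometric mean of the two clusters'
    variance sums, and method-2 cross blocks are (1/m) C_a C_b' with
    each C_c standardized by its own cluster statistics.  Animal order
    of the input is preserved.
    """
    Smat, ids = _as_matrix(S)
    labels = np.asarray(labels)
    n, m = Smat.shape
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per animal")
    uniq = np.unique(labels)
    for c in uniq:
        if (labels == c).sum() < 2:
            raise ValueError(f"cluster {c!r} has fewer than 2 animals")
    if method not in (1, 2):
        raise ValueError("method must be 1 or 2")

    if len(uniq) == 1:
        base = build_mrm(Smat, method, ddof=ddof)
        return RelationshipMatrix(
            base.values, kind=f"M{method}P", ids=ids, cluster_labels=labels
        )

    # Row-wise formulation: center (and for method 2 scale) every row by
    # its own cluster's statistics, then a single cross-product yields
    # all blocks at once; method-1 per-row scale 1/sqrt(sum_j var_cj)
    # reproduces both the within-block denominator and the
    # geometric-mean cross-block scaling.
    Y = np.empty_like(Smat)
    row_scale = np.empty(n)
    for c in uniq:
        idx = labels == c
        block = Smat[idx]
        mean_c = block.mean(axis=0)
        var_c = block.var(axis=0, ddof=ddof)
        if method == 1:
            vs = var_c.sum()
            if vs <= 0:
                raise ZeroDivisionError(f"cluster {c!r} has zero total variance")
            Y[idx] = block - mean_c
            row_scale[idx] = 1.0 / np.sqrt(vs)
        else:
            if (var_c <= 0).any():
                bad = int(np.flatnonzero(var_c <= 0)[0])
                raise ZeroDivisionError(
                    f"zero-variance ORF column {bad} in cluster {c!r}"
                )
            Y[idx] = (block - mean_c) / np.sqrt(var_c)
            row_scale[idx] = 1.0 / np.sqrt(m)
    M = (Y * row_scale[:, None]) @ (Y * row_scale[:, None]).T
    M = 0.5 * (M + M.T)
    return RelationshipMatrix(
        M, kind=f"M{method}P", ids=ids, cluster_labels=labels
    )


def hadamard_interaction(
    G: RelationshipMatrix, M: RelationshipMatrix
) -> RelationshipMatrix:
    """Genome-by-metagenome interaction kernel J = G o M (elementwise).

    Both inputs must be untuned: the interaction covariance is the
    Hadamard product of the raw (co)variance structures, and the Schur
    product theorem then guarantees J is PSD whenever G and M are.
    """
    if G.tuned or M.tuned:
        raise ValueError(
            "hadamard_interaction requires untuned kernels: the product of "
            "tuned matrices is not the intended interaction covariance"
        )
    if G.values.shape != M.values.shape:
        raise ValueError("kernel dimensions differ")
    if G.ids is not None and M.ids is not None and G.ids != M.ids:
        raise ValueError("kernel animal orders differ")
    J = G.values * M.values
    return RelationshipMatrix(J, kind="J", ids=G.ids or M.ids)


def tune(A: RelationshipMatrix, epsilon: float = 0.001) -> RelationshipMatrix:
    """Add ``epsilon * I`` so the kernel is invertible.

    Refuses to tune twice: tuning is a one-shot numerical fix, and
    silently stacking diagonals would change the model.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if A.tuned:
        raise ValueError(f"kernel {A.kind} is already tuned")
    return replace(A, values=A.values + epsilon * np.eye(A.n), tuned=True)
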