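"""Epigenetic population structure: binary encoding, distances, PCoA, AMOVA.

Polymorphic methylation-susceptible loci are recoded as dominant binary
markers (0 = unmethylated type I, 1 = any methylated state).  Individuals
are compared by Euclidean distance over shared non-missing loci, summarized
by principal coordinates analysis (classical metric scaling), and group
differentiation is tested by a distance-based analysis of molecular
variance (AMOVA) with a permutation test on the Phi_st statistic.

AMOVA decomposes the total sum of squared Euclidean distances into
among-group and within-group components:

    SS_total  = sum_{i<j} d_ij^2 / N
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    SS_among  = SS_total - SS_within

    sigma2_within = SS_within / (N - G)
    sigma2_among  = (SS_among/(G-1) - sigma2_within) / n0,
    n0 = (N - sum_g n_g^2 / N) / (G - 1)

    Phi_st = sigma2_among / (sigma2_among + sigma2_within)

The permutation p-value is upper-tailed: individuals are shuffled among
groups holding group sizes fixed, and p = (#{Phi* >= Phi} + 1)/(B + 1).
Phi_st may be slightly negative under the null; it is reported as computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .msap import MSAPMatrix, MSLPartition, MethylationState, MISSING

__all__ = [
    "BinaryEpiMatrix",
    "DistanceMatrix",
    "PCoAResult",
    "AmovaResult",
    "encode_binary",
    "pairwise_distance",
    "pcoa",
    "amova",
]


@dataclass
class BinaryEpiMatrix:
    """Individuals x polymorphic-MSL binary (0/1) matrix; NaN marks missing."""

    individuals: list[str]
    loci: list[str]
    values: np.ndarray  # float64, 0/1/NaN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.individuals), len(self.loci)):
            raise ValueError("values shape does not match individuals x loci")
        ok = np.isnan(self.values) | (self.values == 0) | (self.values == 1)
        if not ok.all():
            raise ValueError("binary matrix entries must be 0, 1 or missing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.individuals, columns=self.loci)
        df.index.name = "individual"
        return df


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix must be square over ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-10).any():
            raise ValueError("distances must be non-negative")
        self.values = v


def encode_binary(matrix: MSAPMatrix, partition: MSLPartition) -> BinaryEpiMatrix:
    """Recode polymorphic MSL as dominant binary markers (type I -> 0, else 1)."""
    loci_set = set(matrix.loci)
    missing_loci = partition.polymorphic_msl - loci_set
    if missing_loci:
        raise ValueError(
            f"partition loci not present in matrix: {sorted(missing_loci)[:5]}"
        )
    locus_index = {l: j for j, l in enumerate(matrix.loci)}
    keep = [l for l in matrix.loci if l in partition.polymorphic_msl]
    idx = [locus_index[l] for l in keep]
    sub = matrix.calls[:, idx]
    values = np.full(sub.shape, np.nan)
    values[sub == MethylationState.TYPE_I] = 0.0
    for s in (2, 3, 4):
        values[sub == s] = 1.0
    return BinaryEpiMatrix(list(matrix.individuals), keep, values)


def pairwise_distance(bin_matrix: BinaryEpiMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Euclidean distance over shared non-missing loci, rescaled by sqrt(L/L_shared).

    The rescaling extrapolates the squared distance observed on the shared
    loci to the full locus panel, so individuals with more missing data are
    comparable to complete pairs.
    """
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    X = bin_matrix.values
    n, L = X.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    if not np.isnan(X).any():
        d = squareform(pdist(X, metric="euclidean"))
        return DistanceMatrix(list(bin_matrix.individuals), d)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(X[i]) & ~np.isnan(X[j])
            ls = int(shared.sum())
            if ls == 0:
                raise ValueError(
                    f"no shared loci between {bin_matrix.individuals[i]!r} "
                    f"and {bin_matrix.individuals[j]!r}"
                )
            sq = float(((X[i, shared] - X[j, shared]) ** 2).sum())
            d[i, j] = d[j, i] = np.sqrt(sq * L / ls)
    return DistanceMatrix(list(bin_matrix.individuals), d)


@dataclass
class PCoAResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame  # individuals x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues
    negative_eigenvalues: np.ndarray  # diagnostics for non-Euclidean input


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Principal coordinates analysis (Gower's classical metric scaling).

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues.  For a Euclidean input
    matrix the embedding over all positive axes reproduces the input
    distances.  Negative eigenvalues (possible when missing-data rescaling
    makes the matrix non-Euclidean) are excluded from the
    variance-explained denominator and reported as diagnostics.
    """
    D2 = d.values**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12 if n else 0.0
    pos = evals > tol
    n_pos = int(pos.sum())
    k = min(n_axes, n_pos)
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
    coords = evecs[:, :k] * np.sqrt(evals[:k]) if k else np.zeros((n, 0))
    pos_sum = evals[pos].sum() if n_pos else 1.0
    prop = evals[:k] / pos_sum if k else np.array([])
    frame = pd.DataFrame(
        coords, index=d.ids, columns=[f"PCo{i + 1}" for i in range(k)]
    )
    frame.index.name = "individual"
    return PCoAResult(
        coordinates=frame,
        eigenvalues=evals,
        proportion_explained=prop,
        negative_eigenvalues=evals[evals < -tol],
    )


@dataclass
class AmovaResult:
    """Distance-based AMOVA with permutation test on Phi_st."""

    phi_st: float
    sigma_among: float
    sigma_within: float
    p_value: float
    n_permutations: int
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among groups", "within groups"],
                "df": [self.df_among, self.df_within],
                "SS": [self.ss_among, self.ss_within],
                "variance": [self.sigma_among, self.sigma_within],
            }
        )


def _phi_components(D2: np.ndarray, codes: np.ndarray, sizes: np.ndarray):
    """Variance components from squared distances given integer group codes."""
    N = D2.shape[0]
    G = len(sizes)
    ss_total = D2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    for g in range(G):
        ix = np.flatnonzero(codes == g)
        sub = D2[np.ix_(ix, ix)]
        ss_within += sub[np.triu_indices(len(ix), 1)].sum() / len(ix)
    ss_among = ss_total - ss_within
    df_among, df_within = G - 1, N - G
    sigma_within = ss_within / df_within
    n0 = (N - (sizes**2).sum() / N) / df_among
    ms_among = ss_among / df_among
    sigma_among = (ms_among - sigma_within) / n0
    denom = sigma_among + sigma_within
    if denom <= 0:
        phi = 1.0 if sigma_among > 0 else 0.0
    else:
        phi = sigma_among / denom
    return phi, sigma_among, sigma_within, ss_among, ss_within, df_among, df_within


def amova(
    bin_matrix: BinaryEpiMatrix,
    groups: Sequence[str],
    n_permutations: int = 9999,
    seed: int | None = None,
) -> AmovaResult:
    """Distance-based AMOVA over a binary epigenotype matrix.

    Parameters
    ----------
    bin_matrix : BinaryEpiMatrix
        Dominant binary markers; distances are Euclidean with missing-data
        rescaling (see :func:`pairwise_distance`).
    groups : sequence of str
        Group label per individual; every group needs >= 2 members.
    n_permutations : int
        Random relabelings (group sizes fixed) for the upper-tail p-value.
    seed : int, optional
        Seed for the permutation generator; fixed seed gives identical output.
    """
    groups = list(groups)
    if len(groups) != len(bin_matrix.individuals):
        raise ValueError("one group label required per individual")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("AMOVA requires at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(labels[g]) for g in np.flatnonzero(sizes < 2)]
        raise ValueError(f"every group needs >= 2 individuals; too small: {small}")
    D2 = pairwise_distance(bin_matrix).values ** 2
    phi, s_a, s_w, ss_a, ss_w, df_a, df_w = _phi_components(D2, codes, sizes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        phi_p = _phi_components(D2, perm, sizes)[0]
        if phi_p >= phi - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AmovaResult(
        phi_st=float(phi),
        sigma_among=float(s_a),
        sigma_within=float(s_w),
        p_value=float(p),
        n_permutations=n_permutations,
        ss_among=float(ss_a),
        ss_within=float(ss_w),
        df_among=df_a,
        df_within=df_w,
    )
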