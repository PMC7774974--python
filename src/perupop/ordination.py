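"""Classical MDS / principal coordinates of genetic distance matrices.

Torgerson's classical scaling: double-center the squared distance matrix,
eigendecompose, and keep axes with positive eigenvalues.  Individual-level
PCoA runs the same machinery on an allele-sharing distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import GenotypeTable

__all__ = [
    "OrdinationResult",
    "classical_mds",
    "allele_sharing_distance",
    "allele_sharing_distance_matrix",
    "pcoa_individuals",
]


@dataclass(frozen=True)
class OrdinationResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray  # (points, axes)
    eigenvalues: np.ndarray  # descending, positive ones retained
    proportion_explained: np.ndarray  # share of positive eigenvalue mass
    negative_eigenvalue_mass: float  # magnitude of dropped negative spectrum


def classical_mds(D: np.ndarray, labels=None, k: int = 2) -> OrdinationResult:
    """Classical (metric) MDS of a symmetric distance matrix.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by sqrt(eigenvalue).  Axes with non-positive eigenvalues are
    dropped (their total magnitude is reported); if fewer than ``k``
    positive axes exist the result is truncated with a warning.  The first
    nonzero loading of each axis is made positive for reproducibility.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = D.shape[0]
    if labels is None:
        labels = tuple(str(i) for i in range(n))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    positive = eigval > tol
    neg_mass = float(-eigval[eigval < -tol].sum())
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating from k={k}", stacklevel=2
        )
    keep = min(k, n_pos)
    vals = eigval[:keep]
    coords = eigvec[:, :keep] * np.sqrt(vals)
    for j in range(keep):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, j] = -col
    pos_sum = eigval[positive].sum()
    prop = vals / pos_sum if pos_sum > 0 else np.zeros(keep)
    return OrdinationResult(tuple(labels), coords, vals, prop, neg_mass)


def allele_sharing_distance(g1, g2) -> float:
    """Mean over comparable loci of 1 - (shared alleles)/2.

    ``g1``/``g2`` are sequences of genotypes, each an (a, b) pair or None;
    shared counts multiset overlap (0, 1 or 2 alleles).  NaN if no locus is
    typed in both individuals.
    """
    total, n_loci = 0.0, 0
    for a, b in zip(g1, g2):
        if a is None or b is None:
            continue
        shared = 0
        pool = list(b)
        for allele in a:
            if allele in pool:
                pool.remove(allele)
                shared += 1
        total += 1.0 - shared / 2.0
        n_loci += 1
    return total / n_loci if n_loci else float("nan")


def allele_sharing_distance_matrix(table: GenotypeTable) -> np.ndarray:
    n = table.n_samples
    L = len(table.locus_names)
    genos = [[table.genotype(i, j) for j in range(L)] for i in range(n)]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = allele_sharing_distance(genos[i], genos[j])
    return D


def pcoa_individuals(table: GenotypeTable, k: int = 2) -> OrdinationResult:
    """Principal coordinates of individuals from allele-sharing distances."""
    if table.n_samples < 3:
        raise ValueError("PCoA needs at least 3 individuals")
    D = allele_sharing_distance_matrix(table)
    if np.isnan(D).any():
        raise ValueError("individual pairs with no comparable loci")
    return classical_mds(D, labels=table.sample_ids, k=k)
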