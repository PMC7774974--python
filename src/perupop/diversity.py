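"""Within-population diversity statistics: h, pi and mean pairwise differences.

Conventions follow Arlequin: haplotype diversity uses the unbiased
n/(n-1) correction; sequence comparisons count substitutions only, with
gap and N columns treated as missing under pairwise deletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING_CHARS, SequenceAlignment, StrHaplotypeTable

__all__ = [
    "DiversityReport",
    "haplotype_diversity",
    "mean_pairwise_differences",
    "nucleotide_diversity",
    "sequence_diff_matrix",
    "str_distance_matrix",
    "diversity_report",
]


@dataclass(frozen=True)
class DiversityReport:
    population: str
    n: int
    h: float | None
    pi: float | None
    mnpd: float | None


def haplotype_diversity(haplotypes) -> float | None:
    """Unbiased h = (n/(n-1)) (1 - sum p_i^2) over distinct haplotypes.

    Returns None (undefined) for n < 2.
    """
    haplotypes = list(haplotypes)
    n = len(haplotypes)
    if n < 2:
        return None
    _, counts = np.unique(np.asarray(haplotypes, dtype=object), return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _active_matrix(aln: SequenceAlignment) -> np.ndarray:
    X = aln.matrix()[:, aln.active_columns()]
    return X


def sequence_diff_matrix(aln: SequenceAlignment, per_site: bool = False) -> np.ndarray:
    """Pairwise substitution counts over active sites with pairwise deletion.

    ``per_site=True`` divides each pair by its comparable-site count.
    Entries are NaN for pairs with no comparable site.
    """
    X = _active_matrix(aln)
    valid = ~np.isin(X, [c.encode() for c in MISSING_CHARS])
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diffs = ((X[i] != X[i + 1:]) & both).sum(axis=1).astype(float)
        if per_site:
            comp = both.sum(axis=1).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                diffs = np.where(comp > 0, diffs / comp, np.nan)
        else:
            diffs = np.where(both.any(axis=1), diffs, np.nan)
        D[i, i + 1:] = diffs
        D[i + 1:, i] = diffs
    return D


def str_distance_matrix(table: StrHaplotypeTable, metric: str = "squared") -> np.ndarray:
    """Pairwise STR distances: 'squared' (sum of squared repeat differences,
    RST-like) or 'loci' (count of differing loci); pairwise deletion."""
    rc = table.repeat_counts
    valid = rc != -1
    n = rc.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        if metric == "squared":
            d = (((rc[i] - rc[i + 1:]) ** 2) * both).sum(axis=1).astype(float)
        elif metric == "loci":
            d = ((rc[i] != rc[i + 1:]) & both).sum(axis=1).astype(float)
        else:
            raise ValueError(f"unknown STR metric {metric!r}")
        d = np.where(both.any(axis=1), d, np.nan)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


def _mean_offdiag(D: np.ndarray) -> float:
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = D[iu]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no comparable pairs")
    return float(vals.mean())


def mean_pairwise_differences(data) -> float | None:
    """MNPD: average pairwise differing sites (sequences) or loci (STR).

    Pairs with no comparable site are excluded; None for n < 2.
    """
    if isinstance(data, SequenceAlignment):
        if data.n_samples < 2:
            return None
        return _mean_offdiag(sequence_diff_matrix(data))
    if isinstance(data, StrHaplotypeTable):
        if data.n_samples < 2:
            return None
        return _mean_offdiag(str_distance_matrix(data, metric="loci"))
    raise TypeError(f"unsupported data type {type(data).__name__}")


def nucleotide_diversity(aln: SequenceAlignment) -> float | None:
    """Per-site pi: mean over pairs of (differences / comparable sites)."""
    if aln.n_samples < 2:
        return None
    return _mean_offdiag(sequence_diff_matrix(aln, per_site=True))


def diversity_report(data, popmap, level: str = "subgroup") -> list[DiversityReport]:
    """Per-population h, pi (sequences only) and MNPD."""
    reports = []
    for pop, members in popmap.populations(level).items():
        members = [s for s in members if s in set(data.sample_ids)]
        sub = data.subset(members)
        n = len(members)
        if n < 2:
            reports.append(DiversityReport(pop, n, None, None, None))
            continue
        if isinstance(data, SequenceAlignment):
            cols = sub.active_columns()
            haps = ["".join(s[c] for c in cols) for s in sub.sequences]
            pi = nucleotide_diversity(sub)
        else:
            haps = [tuple(r) for r in sub.repeat_counts]
            pi = None
        reports.append(
            DiversityReport(pop, n, haplotype_diversity(haps), pi, mean_pairwise_differences(sub))
        )
    return reports
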